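"""Train and evaluate the random-forest classifier on a synthetic table.

Uses the direct feature-table generator (114 true + 342 false rows, the
default effect model), runs repeated cross-validation against the
label-permutation null, and ranks features by permutation importance.
A reduced tree count keeps the example quick; the analysis default is 1000.
"""

from regrecur import (randomize_labels, repeated_cv, simulate_feature_table,
                      variable_importance)

table = simulate_feature_table(n_true=114, n_false=342, seed=0)

report = repeated_cv(table, folds=5, repeats=3, n_trees=200, seed=0)
print(f"mean AUC (signal):    {report.mean_auc:.3f}  "
      f"(per-repeat: {[round(a, 3) for a in report.aucs]})")

null = repeated_cv(randomize_labels(table, seed=1), folds=5, repeats=3,
                   n_trees=200, seed=1)
print(f"mean AUC (permuted):  {null.mean_auc:.3f}")

imp = variable_importance(table, n_trees=200, seed=0)
top = sorted(imp.mda_percent.items(), key=lambda kv: -kv[1])[:8]
print("\ntop features by mean decrease accuracy (%):")
for name, mda in top:
    print(f"  {name:<28} {mda:6.2f}")
# The signal table separates well above the permuted null (~0.5), and the
# most important features are the ones the effect model actually shifts:
# chromatin accessibility, GWAS proximity and the network scores.
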