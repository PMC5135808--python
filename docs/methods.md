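# Methods

## Recurrence model

A mutation's raw recurrence x counts cohort mutation *records* (all samples,
any allele) whose 1-based position falls in the w-bp window centred on the
focal site. Window centring is fixed as [pos − ⌊w/2⌋, pos + ⌈w/2⌉ − 1]: even
windows are left-heavy, always contain the focal position, and have exact
width w. The focal record itself counts, so x ≥ 1 whenever the focal
mutation is in the counting cohort — this matches a raw-recurrence
thresholding scheme whose lowest interesting cutoff is x ≥ 2.

The significance model tests x against a local null. The per-bp background
rate p is n_bg/B', where n_bg is the record count in a B-bp window centred
on the site and B' the window width after clipping to [1, chromosome
length] (clipping renormalizes rather than pads). The p-value is the upper
Poisson tail P(X ≥ x) with mean λ = w·p. By default the background window
*includes* the recurrence window's records — simpler and slightly
conservative; `exclude_core_from_background` switches to the leave-out
estimate. No multiple-testing correction is applied: labeling operates on
fixed p-value cutoffs (default 5×10⁻⁶), not on FDR.

Numerics: for x ≤ λ the scipy survival function is used. In the deep upper
tail (x > λ) the implementation switches to direct summation of
e^(−λ)λ^x/x! · (1 + λ/(x+1) + …). The terms are positive and decreasing, so
the sum has no cancellation and keeps full double relative precision down to
the underflow limit (~1e-300); the incomplete-gamma route loses about five
significant digits around p ≈ 1e-58. The first term is computed in log
space via lgamma.

The test is a screening statistic, not a calibrated hypothesis test: because
the focal record is conditioned on (it always contributes 1 to x), the
probability that a random background site reaches x ≥ 2 is ≈ wp, not
P(X ≥ 2). The discreteness also makes the achievable p-values jump between
atoms (≈λ for singletons, ≈λ²/2 for doubles). Both properties are inherent
to the self-inclusive counting definition; the labeling cutoffs sit far
below the singleton atom in the intended density regime (cohort density
~1e-3/bp gives a singleton atom near 0.01 versus a cutoff of 5e-6).

## Training-set construction

True set: sites passing the threshold (raw count ≥ c, or p < cutoff),
deduplicated by substitution key (chrom:pos:ref>alt) — the same substitution
carried by several samples is one labeled site, represented by its
lexicographically first carrier for sample-aware evaluation. False set: a
seeded uniform sample without replacement, three times the true-set size,
drawn from sites with raw count exactly 1 (and, under the significance
model, p-value above the cutoff). If fewer non-recurrent sites exist, all
are used with a warning.

## Target genes and the regulatory filter

Enhancer–promoter pairs are looked up first; among overlapping enhancers
the highest pairing score wins, ties broken by smaller interval then
lexicographic gene id. Mutations outside every EP enhancer fall back to a
distal-DHS/promoter correlation map (argmax of the maximum cross-cell-type
correlation). Mutations covered by neither are excluded from features and
training entirely: regulatory-region membership is the candidate filter.
No distance cap is re-checked at lookup time — proximity is a construction
property of the input maps. The motif-scanning region is the DHS peak
containing the mutation; for EP-mapped mutations without a covering peak,
the enhancer interval itself.

## Motif scores

PWMs are position probability matrices over A/C/G/T with a background model
(uniform by default). Window scores are log₂ likelihood ratios, discretised
to 1e-3-wide integer bins; the null distribution of a single window's score
under the background is computed exactly by convolving the per-position
score atoms, and a match p-value is P(score ≥ observed) in that null — the
classic exact scan null, with no correction across offsets. Zero matrix
entries are floored at 1e-10 so degenerate consensus matrices stay finite.
N bases score 0 (background). Reverse-strand matches are scored through the
reverse-complemented matrix (with complemented background), and the best
match over both strands and all offsets is reported; ties prefer the
leftmost forward-strand window.

For a candidate mutation, each PWM's best match p-value is computed over
the windows overlapping the mutated base, for the wild-type and the mutant
sequence. With match threshold α (default 1e-4): gain ⇔ only the mutant
passes, loss ⇔ only the wild type passes. If any PWM changes, the changed
PWM with the largest |(−log₁₀ p_wt) − (−log₁₀ p_mut)| supplies
diff = (−log₁₀ p_wt) − (−log₁₀ p_mut) (positive for losses),
avg = the mean of the two −log₁₀ p-values, Gain_or_Loss = ±1, and the bound
TF. Otherwise diff = 0, Gain_or_Loss = 0, and avg/bound TF come from the
best wild-type match anywhere in the DHS region. A FIMO-style TSV ingestion
path can replace the built-in scanner bit-for-bit at the score-combination
layer.

## Gene, genetic and epigenetic features

- DEG score: two-sample two-sided t-test (pooled-variance Student by
  default, Welch by option) between tumor and normal expression; score
  x/(x+1) with x = −log₁₀ p, p clamped at 1e-300. Bounded in [0,1),
  strictly decreasing in p.
- RegNet.DEG_score: sum of DEG scores over distinct genes reachable within
  3 directed hops downstream (source excluded, cycles visited once).
- CGS_L1/L2: cancer genes at shortest-path distance exactly 1 / exactly 2
  (the suffix is read as the hop count; a cumulative ≤2 reading is
  available by flag). The source never counts itself.
- Distance.to.GWAS: raw bp distance to the nearest same-chromosome catalog
  SNP; 2.5×10⁸ (beyond any chromosome) when the chromosome has none.
- Early-to-late ratio: (G1B+S1)/(S4+G2) of the replication-timing fraction
  values at the site; capped at 100 when the late fractions are zero.
- Conservation and the 17 chromatin marks: single-base track value at the
  mutated position, 0 where uncovered (an optional mean-over-±k window
  exists for smoother tracks). TF-level gene features use the TF's own gene
  node in all networks; they are zero only when no TF was identified at all.

The assembled vector has exactly 35 named features in fixed order
(6 target + 6 TF + 3 TFBS + 6 cancer-cell marks + 3 genetic + 11
origin-cell marks); assembly fails loudly on a missing track or non-finite
value.

## Classifier and evaluation

The forest is 1000 bagged CART trees (scikit-learn trees; mtry = ⌊√35⌋ = 5,
unlimited depth, minimum node size 1, bootstrap with replacement — the
standard classification defaults of this family of forests). Bagging is
implemented in the package with explicit per-tree bootstrap weights so that
each tree's out-of-bag rows are exact, votes are per-tree majority-leaf
classes, and everything is bit-reproducible per seed.

- AUC: Mann–Whitney rank statistic with midranks (equals the tie-aware
  trapezoidal ROC area).
- Repeated CV: stratified fold assignment per repeat (stratification keeps
  per-fold class counts stable with ~100 positives); per-repeat AUC pools
  the five folds' held-out votes; the "average AUC" is the mean over 10
  repeats.
- Label randomization: uniform permutation of the label column, preserving
  class balance — the null control band.
- LOOCV by sample: for each held-out sample, the training set keeps every
  true row of the other samples and redraws the false rows from those
  samples at ratio 3; an assertion guarantees the held-out sample never
  appears in training.
- Variable importance: per-tree accuracy on its out-of-bag rows minus
  accuracy after permuting one feature's values among those rows, averaged
  over trees, in percentage points (mean decrease accuracy). Near-zero and
  slightly negative values for uninformative features are expected
  permutation noise.

## External revalidation

Top-k selections (by raw count, p-value, or forest vote proportion; ties
broken by genomic position) are rechecked against an added cohort whose
sample roster must be disjoint from training (asserted). A selection is
"revealed" when ≥1 new-cohort mutation falls in the 10- or 100-bp check
window (same centring convention as recurrence). Revealed counts are
monotone in both k and window size.

## Synthetic data: what it emulates, and what it does not

The generator realises the model the analysis assumes: per-sample
homogeneous Poisson background mutations plus planted hotspots — each
hotspot is `multiplicity` mutations in distinct samples within ±max_spread
bp, sharing ref/alt (cross-patient recurrent substitutions). Background
positions within 10 bp of a hotspot are rejected so planted hotspots are
the only recurrences and ground-truth labels are exact. Presets:

- `tiny` — 1 chrom × 100 kbp, 5 samples, 3 hotspots (multiplicity 4–5,
  spread ±2), background 2e-4/bp/sample: end-to-end runs in seconds.
- `default` — 2 chroms × 1 Mbp, 20 samples, background 5e-5/bp/sample
  (cohort ≈ 1e-3/bp), 114 hotspots of multiplicity 4–8 with zero spread,
  so the significance-model true set is exactly the 114 planted sites and
  the false set 342 — the true-set size regime the thresholds target. At
  this density λ ≈ 0.01–0.02, so multiplicity ≥ 4 gives tail probabilities
  below 10⁻⁸, guaranteeing full recovery at the 5×10⁻⁶ cutoff, while a
  background site needs 2 chance neighbours (probability ≈ 5×10⁻⁵) to be
  flagged.
- `null` — default dimensions, no hotspots, zero feature effects.

Annotation resources are wired to the hotspots: a random genome with each
hotspot's TF consensus (strong 0.91/0.03 PWMs, length 8 — one mismatch
fails the 1e-4 match threshold, so hotspot substitutions register as
losses); 1-kbp regulatory tiles covering 60% via EP pairs, 20% via the DHS
map, 20% uncovered (exercising the exclusion path), hotspot tiles always
EP-covered; signal tracks in 250-bp bins with standardized shifts at
hotspot bins; GWAS SNPs near hotspots; cancer genes wired adjacent to (and
chained behind) hotspot target genes; hotspot genes differentially
expressed and connected to strongly-DE downstream genes; replication
fractions with elevated early/late ratio at hotspots.

For classifier-scale experiments a direct table generator draws each
feature as a monotone, feature-appropriate transform of a standard-normal
latent value, with true rows shifted by the per-feature effect (in latent
SD units). Decision trees are invariant to monotone per-feature transforms,
so the latent shift model controls separability exactly. The default effect
panel (≈12 informative features, shifts 0.4–1.0 SD, combined latent
separation d ≈ 2.5) produces mean CV AUCs near 0.9; the zero-effect model
produces ≈ 0.5.

What the fixtures do *not* emulate: trinucleotide mutational signatures and
rate heterogeneity, hypermutator samples, realistic peak shapes or
correlated tracks, linkage between features beyond the shared hotspot
labels, and real enhancer–gene maps. Passing tests therefore demonstrate
the correctness and calibration of the machinery — counting, the Poisson
tail, the score formulas, the CV/importance harness — not the real-data
discriminative power of the 35 features.

## Problem sizes and determinism

The test suite runs the statistical oracles at full grid size (≥500-point
Poisson grid at 80-digit precision; exhaustive 4^L motif nulls for L ≤ 6;
1,000-query window-count scans) and the CV experiments at the full table
size (456 rows, 1000 trees, 10×5 CV), with three permutation seeds in the
suite; the acceptance script runs the full ten. All stochastic procedures
take explicit seeds; fixture generation, labeling, fold assignment,
bootstrap and permutation draws are bit-reproducible given (seed, input),
and seeds derived from a run seed stay below 2³¹.

## Known limitations

- The background-rate estimate is purely windowed; no covariate model
  (replication timing, expression, chromatin) adjusts the local rate, so
  regions with strongly varying mutability can inflate or deflate
  significance.
- Only single-nucleotide substitutions are modelled; indel rows are
  skipped at parse time.
- Germline filtering is position-based, not allele-aware.
- The motif null is per-window; no correction for scanning multiple
  offsets, and no q-values.
- EP/DHS maps are trusted as given; a mutation maps to exactly one gene.
- The forest vote proportion is a ranking score, not a calibrated
  probability.
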