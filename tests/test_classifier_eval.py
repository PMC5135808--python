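import numpy as np
import pandas as pd
import pytest

from regrecur.classifier_eval import (RandomForest, VoteRecord,
                                      loocv_by_sample, predict_votes,
                                      randomize_labels, repeated_cv, roc_auc,
                                      train_forest, variable_importance)
from regrecur.feature_assembly import FEATURE_NAMES
from regrecur.synthetic_data import simulate_feature_table


def separable_table(n=60, seed=0):
    """Two features carry a clean +6-sigma shift for the true class."""
    rng = np.random.default_rng(seed)
    label = np.arange(n) % 4 == 0
    X = rng.normal(size=(n, 5))
    X[label, 0] += 6.0
    X[label, 1] += 6.0
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
    df.insert(0, "mutation_key", [f"k{i}" for i in range(n)])
    df.insert(1, "sample_id", [f"s{i % 3}" for i in range(n)])
    df.insert(2, "label", label)
    return df


class TestTrainForest:
    def test_separable_fixture_votes_high(self):
        table = separable_table()
        handle = train_forest(table, n_trees=200, seed=1)
        votes = handle.train_votes[table["label"].to_numpy()]
        assert (votes > 0.9).all()

    def test_same_seed_is_bit_reproducible(self):
        table = separable_table()
        a = train_forest(table, n_trees=100, seed=7)
        b = train_forest(table, n_trees=100, seed=7)
        assert np.array_equal(a.train_votes, b.train_votes)
        assert np.array_equal(a.oob_votes, b.oob_votes, equal_nan=True)

    def test_different_seed_changes_forest(self):
        table = separable_table()
        a = train_forest(table, n_trees=100, seed=7)
        b = train_forest(table, n_trees=100, seed=8)
        assert not np.array_equal(a.train_votes, b.train_votes)

    def test_single_class_rejected(self):
        table = separable_table()
        table["label"] = True
        with pytest.raises(ValueError, match="both classes"):
            train_forest(table, n_trees=10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            RandomForest(n_trees=5).fit(np.zeros((1, 3)), np.array([1.0]))

    def test_oob_masks_cover_unsampled_rows(self):
        table = separable_table(n=40)
        handle = train_forest(table, n_trees=50, seed=3)
        oob = handle.forest.oob
        # bootstrap leaves ~36.8% of rows out per tree
        frac = oob.mean()
        assert 0.25 < frac < 0.45


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [True, False] * 3) == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_concordance_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.integers(0, 5, size=n).astype(float)  # many ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        pos = scores[labels]
        neg = scores[~labels]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        want = conc / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(want)


class TestRepeatedCV:
    def test_one_auc_per_repeat(self):
        table = separable_table(n=80)
        report = repeated_cv(table, folds=5, repeats=10, n_trees=30, seed=0)
        assert len(report.aucs) == 10
        assert report.mean_auc == pytest.approx(np.mean(report.aucs))

    def test_informative_table_scores_high(self):
        table = simulate_feature_table(50, 150, seed=2)
        report = repeated_cv(table, folds=5, repeats=2, n_trees=200, seed=2)
        assert report.mean_auc > 0.9

    def test_roc_points_monotone(self):
        table = separable_table(n=80)
        report = repeated_cv(table, folds=5, repeats=2, n_trees=30, seed=0)
        fpr, tpr = report.roc_points
        assert fpr[0] == 0.0 and fpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_too_few_class_rows_rejected(self):
        table = separable_table(n=12)   # 3 true rows < 5 folds
        with pytest.raises(ValueError, match="folds"):
            repeated_cv(table, folds=5, repeats=1, n_trees=10)

    def test_reproducible_per_seed(self):
        table = separable_table(n=80)
        a = repeated_cv(table, folds=5, repeats=2, n_trees=30, seed=5)
        b = repeated_cv(table, folds=5, repeats=2, n_trees=30, seed=5)
        assert a.aucs == b.aucs


class TestRandomizeLabels:
    def test_preserves_class_balance(self):
        table = separable_table()
        out = randomize_labels(table, seed=3)
        assert out["label"].sum() == table["label"].sum()
        assert not out["label"].equals(table["label"])

    def test_same_seed_same_permutation(self):
        table = separable_table()
        assert randomize_labels(table, seed=3)["label"].equals(
            randomize_labels(table, seed=3)["label"])

    def test_features_untouched(self):
        table = separable_table()
        out = randomize_labels(table, seed=3)
        assert out[[f"f{i}" for i in range(5)]].equals(
            table[[f"f{i}" for i in range(5)]])


class TestLOOCV:
    def test_every_row_gets_exactly_one_vote(self):
        table = separable_table(n=60)
        records = loocv_by_sample(table, n_trees=30, seed=0)
        assert len(records) == len(table)
        got = sorted(r.mutation_key for r in records)
        assert got == sorted(table["mutation_key"])
        assert all(0.0 <= r.vote <= 1.0 for r in records)

    def test_single_sample_rejected(self):
        table = separable_table()
        table["sample_id"] = "only"
        with pytest.raises(ValueError, match="2 distinct samples"):
            loocv_by_sample(table, n_trees=10)

    def test_held_out_sample_never_trains(self, monkeypatch):
        """The fold builder must exclude every row of the held-out sample."""
        import regrecur.classifier_eval as ce

        table = separable_table(n=60)
        # encode the sample index into a dedicated feature so the spy can see it
        table["f4"] = table["sample_id"].str.lstrip("s").astype(float)
        seen: list[tuple[str, set]] = []
        orig_fit = ce.RandomForest.fit

        class SpyForest(ce.RandomForest):
            def fit(self, X, y):
                seen.append(set(np.asarray(X)[:, -1].tolist()))
                return orig_fit(self, X, y)

        monkeypatch.setattr(ce, "RandomForest", SpyForest)
        records = loocv_by_sample(table, n_trees=5, seed=0)
        held_order = sorted({r.sample_id for r in records})
        assert len(seen) == len(held_order)
        for held, trained_ids in zip(held_order, seen):
            assert float(held.lstrip("s")) not in trained_ids

    def test_hotspot_linked_rows_get_higher_votes(self):
        table = simulate_feature_table(40, 120, seed=4, n_samples=6)
        records = loocv_by_sample(table, n_trees=150, seed=4)
        votes = {r.mutation_key: r.vote for r in records}
        true_votes = [votes[k] for k in
                      table.loc[table["label"], "mutation_key"]]
        false_votes = [votes[k] for k in
                       table.loc[~table["label"], "mutation_key"]]
        assert np.median(true_votes) > np.median(false_votes)


class TestVariableImportance:
    def test_constant_feature_has_zero_importance(self):
        table = separable_table(n=80)
        table["f3"] = 1.0
        report = variable_importance(table, n_trees=100, seed=0)
        assert abs(report.mda_percent["f3"]) < 1.0

    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 120
        label = np.arange(n) % 4 == 0
        X = rng.normal(size=(n, 6))
        X[label, 2] += 3.0
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        df.insert(0, "mutation_key", [f"k{i}" for i in range(n)])
        df.insert(1, "sample_id", "s1")
        df.insert(2, "label", label)
        report = variable_importance(df, n_trees=150, seed=1)
        best = max(report.mda_percent, key=report.mda_percent.get)
        assert best == "f2"

    def test_one_entry_per_feature(self):
        table = simulate_feature_table(30, 90, seed=6)
        report = variable_importance(table, n_trees=60, seed=0)
        assert set(report.mda_percent) == set(FEATURE_NAMES)


class TestPredictVotes:
    def test_votes_near_one_for_training_trues(self):
        table = separable_table()
        handle = train_forest(table, n_trees=100, seed=0)
        records = predict_votes(handle, table)
        votes = np.array([r.vote for r in records])
        assert (votes[table["label"].to_numpy()] > 0.9).all()

    def test_renamed_column_is_schema_error(self):
        table = separable_table()
        handle = train_forest(table, n_trees=10, seed=0)
        bad = table.rename(columns={"f0": "renamed"})
        with pytest.raises(ValueError, match="schema mismatch"):
            predict_votes(handle, bad)

    def test_vote_record_bounds_enforced(self):
        with pytest.raises(ValueError):
            VoteRecord("k", "s", 1.5)
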