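import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regrecur.io_formats import CohortIndex, Mutation
from regrecur.recurrence import (background_rate, build_labeled_set,
                                 count_raw_recurrence, recurrence_pvalue,
                                 score_cohort, window_bounds)
from regrecur.synthetic_data import simulate_uniform_cohort


def _mut(pos, sample="s1", chrom="chr1"):
    return Mutation(chrom, pos, "A", "C", sample)


def poisson_sf_oracle(x: int, lam: float) -> float:
    """Upper tail P(X >= x) by extended-precision pmf summation.

    The upper tail is summed term by term (no cancellation), at 80 decimal
    digits, until terms stop contributing.
    """
    if x == 0:
        return 1.0
    with mpmath.workdps(80):
        lam_mp = mpmath.mpf(lam)
        total = mpmath.mpf(0)
        k = x
        while True:
            term = mpmath.exp(-lam_mp) * lam_mp**k / mpmath.factorial(k)
            total += term
            if term < total * mpmath.mpf("1e-40") or k > x + 2000:
                break
            k += 1
        return float(total)


class TestWindowCounting:
    def test_left_heavy_centering(self):
        assert window_bounds(1000, 10) == (995, 1004)
        assert window_bounds(1000, 5) == (998, 1002)
        assert window_bounds(1000, 1) == (1000, 1000)

    def test_count_in_even_window(self):
        cohort = CohortIndex([_mut(p, f"s{i}") for i, p in
                              enumerate([996, 1000, 1004, 1005])])
        assert count_raw_recurrence(_mut(1000), cohort, 10) == 3

    def test_focal_absent_and_no_neighbors(self):
        cohort = CohortIndex([_mut(5000)])
        assert count_raw_recurrence(_mut(1000), cohort, 10) == 0

    def test_degenerate_window_counts_exact_position(self):
        cohort = CohortIndex([_mut(1000, "s1"), _mut(1000, "s2"), _mut(1001, "s3")])
        assert count_raw_recurrence(_mut(1000), cohort, 1) == 2

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            count_raw_recurrence(_mut(10), CohortIndex([_mut(10)]), 0)

    def test_matches_naive_scan_on_random_queries(self, rng):
        cohort = simulate_uniform_cohort(5, 300, chrom_length=50_000, seed=11)
        positions = cohort.positions("chr1")
        for _ in range(1000):
            pos = int(rng.integers(1, 50_000))
            w = int(rng.choice([1, 5, 10, 20, 101]))
            lo, hi = window_bounds(pos, w)
            naive = int(np.sum((positions >= max(lo, 1)) & (positions <= hi)))
            assert count_raw_recurrence(_mut(pos), cohort, w) == naive


class TestBackgroundRate:
    def test_uniform_rate_arithmetic(self):
        cohort = CohortIndex([_mut(5000 + 1000 * i, f"s{i}") for i in range(10)],
                             chrom_lengths={"chr1": 1_000_000})
        n_bg, p, eff = background_rate(_mut(9500), cohort, 10_000)
        assert eff == 10_000
        assert p == n_bg / 10_000

    def test_left_clipping_renormalizes(self):
        cohort = CohortIndex([_mut(100)], chrom_lengths={"chr1": 1_000_000})
        n_bg, p, eff = background_rate(_mut(100), cohort, 1000)
        # window [100-500, 100+499] clipped to [1, 599]
        assert eff == 599
        assert n_bg == 1
        assert p == pytest.approx(1 / 599)

    def test_right_clipping_at_chromosome_end(self):
        cohort = CohortIndex([_mut(990)], chrom_lengths={"chr1": 1000})
        _, _, eff = background_rate(_mut(990), cohort, 1000)
        assert eff == 1000 - max(990 - 500, 1) + 1

    def test_empty_neighborhood_rate_zero(self):
        cohort = CohortIndex([_mut(900_000)], chrom_lengths={"chr1": 1_000_000})
        n_bg, p, _ = background_rate(_mut(5000), cohort, 1000)
        assert (n_bg, p) == (0, 0.0)

    def test_background_must_contain_recurrence_window(self):
        cohort = CohortIndex([_mut(100)])
        with pytest.raises(ValueError, match="exceed"):
            background_rate(_mut(100), cohort, 10, w=10)

    def test_exclude_core_removes_window_counts(self):
        cohort = CohortIndex([_mut(1000, f"s{i}") for i in range(5)]
                             + [_mut(1300)], chrom_lengths={"chr1": 10_000})
        n_bg, _, _ = background_rate(_mut(1000), cohort, 1000, w=10,
                                     exclude_core=True)
        assert n_bg == 1


class TestRecurrencePvalue:
    def test_zero_count_is_certain(self):
        assert recurrence_pvalue(0, 10, 0.5) == 1.0

    def test_single_count_closed_form(self):
        assert recurrence_pvalue(1, 10, 0.001) == pytest.approx(
            1 - math.exp(-0.01), rel=1e-12)

    def test_deep_tail_value(self):
        # lambda = 1e-3, x = 4: 1 - e^-l (1 + l + l^2/2 + l^3/6)
        assert recurrence_pvalue(4, 10, 1e-4) == pytest.approx(4.163e-14,
                                                               rel=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            recurrence_pvalue(-1, 10, 0.1)
        with pytest.raises(ValueError):
            recurrence_pvalue(1, 10, -0.1)

    @pytest.mark.parametrize("lam", [1e-6, 1e-3, 0.1, 1.0, 10.0])
    def test_matches_extended_precision_oracle(self, lam):
        for x in range(0, 51, 5):
            got = recurrence_pvalue(x, 1, lam)
            want = poisson_sf_oracle(x, lam)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(x=st.integers(0, 50), lam=st.floats(1e-6, 10.0))
    def test_monotone_in_count_and_rate(self, x, lam):
        p = recurrence_pvalue(x, 1, lam)
        assert recurrence_pvalue(x + 1, 1, lam) <= p
        assert recurrence_pvalue(x, 1, lam * 1.5) >= p


class TestScoreCohort:
    def test_singleton_cohort(self):
        cohort = CohortIndex([_mut(5000)], chrom_lengths={"chr1": 1_000_000})
        (rec,) = score_cohort(cohort, cohort, w=10, B=10_000)
        assert rec.x == 1
        assert rec.p_value == pytest.approx(1 - math.exp(-rec.lam))

    def test_planted_hotspot_is_significant(self, rng):
        muts = [Mutation("chr1", int(p), "A", "C", f"bg{i}")
                for i, p in enumerate(rng.integers(1, 100_000, size=100))]
        hot = [Mutation("chr1", 50_000 + o, "G", "T", f"h{o}")
               for o in range(5)]  # 5 mutations within 4 bp
        cohort = CohortIndex(muts + hot, chrom_lengths={"chr1": 100_000})
        focal = CohortIndex(hot, chrom_lengths={"chr1": 100_000})
        for rec in score_cohort(focal, cohort, w=10, B=10_000):
            if rec.x >= 5:
                assert rec.p_value < 5e-6

    def test_null_cohort_calibration(self):
        # cohort density 2e-3/bp puts the singleton p-value atom (~lambda =
        # 0.02) above alpha, so the alpha = 1e-2 rate measures genuine
        # within-window co-occurrence
        cohort = simulate_uniform_cohort(10, 200, chrom_length=1_000_000, seed=5)
        records = score_cohort(cohort, cohort, w=10, B=100_000)
        frac = np.mean([r.p_value < 1e-2 for r in records])
        # order-of-magnitude calibration under the null (discrete test: the
        # achievable p-values jump, so only the magnitude is meaningful)
        assert 1e-3 < frac < 5e-2


class TestBuildLabeledSet:
    def test_false_set_is_three_times_true_set(self, default_manifest):
        man = default_manifest
        records = score_cohort(man.cohort, man.cohort, w=10, B=10_000)
        labeled = build_labeled_set(records, "significance", 5e-6, seed=1)
        assert len(labeled.false_ids) == 3 * len(labeled.true_ids)

    def test_same_seed_reproduces(self, tiny_manifest):
        records = score_cohort(tiny_manifest.cohort, tiny_manifest.cohort,
                               w=10, B=10_000)
        a = build_labeled_set(records, "significance", 5e-6, seed=42)
        b = build_labeled_set(records, "significance", 5e-6, seed=42)
        assert a == b

    def test_empty_true_set_is_error(self, tiny_manifest):
        records = score_cohort(tiny_manifest.cohort, tiny_manifest.cohort,
                               w=10, B=10_000)
        with pytest.raises(ValueError, match="threshold"):
            build_labeled_set(records, "raw", 10**9)

    def test_raw_model_thresholds(self, tiny_manifest):
        records = score_cohort(tiny_manifest.cohort, tiny_manifest.cohort,
                               w=10, B=10_000)
        labeled = build_labeled_set(records, "raw", 4, seed=0)
        xs = {r.mutation.key: r.x for r in records}
        assert all(xs[k] >= 4 for k in labeled.true_ids)
        assert all(xs[k] == 1 for k in labeled.false_ids)

    def test_shortfall_uses_all_available(self, caplog):
        muts = ([Mutation("chr1", 1000, "A", "C", f"s{i}") for i in range(5)]
                + [Mutation("chr1", 5000 + 100 * i, "G", "T", "s0")
                   for i in range(2)])
        cohort = CohortIndex(muts, chrom_lengths={"chr1": 100_000})
        records = score_cohort(cohort, cohort, w=10, B=10_000)
        labeled = build_labeled_set(records, "raw", 5, ratio=3, seed=0)
        assert len(labeled.true_ids) == 1
        assert len(labeled.false_ids) == 2  # wanted 3 but only 2 singletons exist
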