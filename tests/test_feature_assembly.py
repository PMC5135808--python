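import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from regrecur.feature_assembly import (CANCER_MARKS, FEATURE_NAMES,
                                       ORIGIN_MARKS, adjacency, cgs,
                                       deg_score, deg_score_from_pvalue,
                                       distance_to_gwas, early_late_ratio,
                                       regnet_deg_score, signal_at)
from regrecur.io_formats import GenomicInterval, Mutation, SignalTrack


def _mut(pos, chrom="chr1"):
    return Mutation(chrom, pos, "A", "C", "s1")


class TestDEGScore:
    def test_formula_fixed_points(self):
        assert deg_score_from_pvalue(1.0) == 0.0
        assert deg_score_from_pvalue(0.1) == pytest.approx(0.5)
        assert deg_score_from_pvalue(0.01) == pytest.approx(2 / 3)

    def test_identical_groups_score_zero(self):
        assert deg_score([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 0.0

    def test_matches_hand_computed_t_test(self):
        tumor = np.array([10.0, 10.1, 9.9])
        normal = np.array([0.0, 0.1, -0.1])
        # pooled-variance Student t by hand, p from the t survival function
        n1, n2 = 3, 3
        sp2 = ((n1 - 1) * tumor.var(ddof=1) + (n2 - 1) * normal.var(ddof=1)) / (n1 + n2 - 2)
        t = (tumor.mean() - normal.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
        x = -math.log10(max(p, 1e-300))
        assert deg_score(tumor, normal) == pytest.approx(x / (x + 1), rel=1e-12)

    def test_strictly_decreasing_in_pvalue(self):
        ps = [1.0, 0.5, 0.1, 1e-3, 1e-10, 1e-300]
        scores = [deg_score_from_pvalue(p) for p in ps]
        assert all(a < b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s < 1.0 for s in scores)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            deg_score([1.0], [1.0, 2.0])


class TestRegnetDEGScore:
    def test_three_hop_chain(self):
        adj = adjacency({("g", "a"), ("a", "b"), ("b", "c"), ("c", "d")})
        deg = {k: 0.1 for k in "gabcd"}
        assert regnet_deg_score("g", adj, deg, hops=3) == pytest.approx(0.3)

    def test_cycle_counted_once_source_excluded(self):
        adj = adjacency({("g", "a"), ("a", "g")})
        assert regnet_deg_score("g", adj, {"a": 0.4, "g": 9.9}) == pytest.approx(0.4)

    def test_source_absent_from_network(self):
        assert regnet_deg_score("nowhere", {}, {"a": 1.0}) == 0.0

    def test_monotone_in_hops(self, rng):
        edges = {(f"n{rng.integers(30)}", f"n{rng.integers(30)}")
                 for _ in range(60)}
        adj = adjacency({(a, b) for a, b in edges if a != b})
        deg = {f"n{i}": float(rng.random()) for i in range(30)}
        prev = 0.0
        for k in range(1, 6):
            cur = regnet_deg_score("n0", adj, deg, hops=k)
            assert cur >= prev - 1e-12
            prev = cur

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(40, 0.08, directed=True, seed=int(seed))
        adj = adjacency({(f"n{a}", f"n{b}") for a, b in g.edges})
        deg = {f"n{i}": float(rng.random()) for i in range(40)}
        src = "n0"
        lengths = nx.single_source_shortest_path_length(g, 0, cutoff=3)
        want = sum(deg[f"n{n}"] for n, d in lengths.items() if 1 <= d <= 3)
        assert regnet_deg_score(src, adj, deg, hops=3) == pytest.approx(want)


class TestCGS:
    def test_direct_neighbor(self):
        adj = adjacency({("g", "A"), ("A", "g"), ("g", "B"), ("B", "g")})
        assert cgs("g", adj, {"A"}, level=1) == 1
        assert cgs("g", adj, {"A"}, level=2) == 0

    def test_two_hop_only(self):
        adj = adjacency({("g", "x"), ("x", "g"), ("x", "c"), ("c", "x")})
        assert cgs("g", adj, {"c"}, level=1) == 0
        assert cgs("g", adj, {"c"}, level=2) == 1

    def test_source_never_counts_itself(self):
        adj = adjacency({("g", "a"), ("a", "g")})
        assert cgs("g", adj, {"g"}, level=1) == 0

    def test_isolated_gene(self):
        assert cgs("lonely", {}, {"A"}, level=1) == 0

    def test_cumulative_level2_includes_ring1(self):
        adj = adjacency({("g", "A"), ("A", "g"), ("A", "B"), ("B", "A")})
        assert cgs("g", adj, {"A", "B"}, level=2) == 1
        assert cgs("g", adj, {"A", "B"}, level=2, cumulative=True) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_distance_oracle(self, seed):
        g = nx.gnm_random_graph(40, 200, seed=seed)
        adj = adjacency({(f"n{a}", f"n{b}") for a, b in g.edges}
                        | {(f"n{b}", f"n{a}") for a, b in g.edges})
        rng = np.random.default_rng(seed)
        cancer = {f"n{i}" for i in rng.choice(40, size=8, replace=False)}
        for src in rng.choice(40, size=10, replace=False):
            lengths = nx.single_source_shortest_path_length(g, int(src), cutoff=2)
            for level in (1, 2):
                want = sum(1 for n, d in lengths.items()
                           if d == level and f"n{n}" in cancer)
                assert cgs(f"n{src}", adj, cancer, level=level) == want

    def test_l1_plus_l2_bounded_by_cancer_set(self, rng):
        g = nx.gnm_random_graph(30, 120, seed=9)
        adj = adjacency({(f"n{a}", f"n{b}") for a, b in g.edges}
                        | {(f"n{b}", f"n{a}") for a, b in g.edges})
        cancer = {f"n{i}" for i in range(6)}
        for i in range(30):
            total = cgs(f"n{i}", adj, cancer, 1) + cgs(f"n{i}", adj, cancer, 2)
            assert total <= len(cancer)


class TestGeneticFeatures:
    def test_gwas_distance_examples(self):
        catalog = {"chr1": np.array([90, 250])}
        assert distance_to_gwas(_mut(100), catalog) == 10
        assert distance_to_gwas(_mut(90), catalog) == 0
        assert distance_to_gwas(_mut(400, chrom="chr2"), catalog) == 2.5e8

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            distance_to_gwas(_mut(100), {})

    def test_early_late_ratio_arithmetic(self):
        assert early_late_ratio(1, 1, 1, 1) == 1.0
        assert early_late_ratio(2, 1, 1, 0.5) == 2.0
        assert early_late_ratio(0, 0, 1, 1) == 0.0

    def test_early_late_zero_denominator_capped(self):
        assert early_late_ratio(1, 1, 0, 0) == 100.0
        assert early_late_ratio(1, 1, 0, 0, cap=7.0) == 7.0

    def test_early_late_negative_rejected(self):
        with pytest.raises(ValueError):
            early_late_ratio(-1, 0, 1, 1)


class TestSignalAt:
    def test_value_and_uncovered_default(self):
        track = SignalTrack("t", [GenomicInterval("chr1", 0, 10, 2.5)])
        assert signal_at(track, _mut(5)) == 2.5
        assert signal_at(track, _mut(50)) == 0.0

    def test_random_lookups_match_linear_scan(self, rng):
        ivs = []
        pos = 0
        for _ in range(300):
            pos += int(rng.integers(1, 30))
            end = pos + int(rng.integers(1, 20))
            ivs.append(GenomicInterval("chr1", pos, end, float(rng.normal())))
            pos = end
        track = SignalTrack("t", ivs)
        for _ in range(1000):
            q = int(rng.integers(1, pos + 100))
            want = 0.0
            for iv in ivs:
                if iv.start <= q - 1 < iv.end:
                    want = iv.value
                    break
            assert signal_at(track, _mut(q)) == want


class TestAssembleFeatures:
    def test_schema_is_exactly_35_features(self):
        assert len(FEATURE_NAMES) == 35
        assert len(set(FEATURE_NAMES)) == 35
        assert len(CANCER_MARKS) == 6 and len(ORIGIN_MARKS) == 11

    def test_end_to_end_vector_finite(self, tiny_manifest):
        from regrecur.feature_assembly import assemble_features
        from regrecur.motif_features import tfbs_scores
        from regrecur.target_mapping import assign_targets

        man = tiny_manifest
        res = man.resources
        muts = [man.hotspot_members[0][0]]
        (assignment,) = assign_targets(muts, res.ep_pairs, res.dhs_map,
                                       res.dhs_peaks)
        tb = tfbs_scores(muts[0], assignment.dhs_region, res.pwms, res.genome)
        vec = assemble_features(muts[0], assignment, tb, res.feature_resources())
        assert list(vec) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vec.values())

    def test_no_bound_tf_zeroes_tf_block(self, tiny_manifest):
        from regrecur.feature_assembly import assemble_features
        from regrecur.motif_features import TFBSScores
        from regrecur.target_mapping import assign_targets

        man = tiny_manifest
        res = man.resources
        muts = [man.hotspot_members[0][0]]
        (assignment,) = assign_targets(muts, res.ep_pairs, res.dhs_map,
                                       res.dhs_peaks)
        tb = TFBSScores(0.0, 0.0, 0, None)
        vec = assemble_features(muts[0], assignment, tb, res.feature_resources())
        assert all(vec[f"tf.{s}"] == 0.0 for s in
                   ("HumanNet.CGS_L1", "HumanNet.CGS_L2", "InteractNet.CGS_L1",
                    "InteractNet.CGS_L2", "RegNet.DEG_score", "DEG_score"))

    def test_missing_track_is_named_error(self, tiny_manifest):
        from regrecur.feature_assembly import FeatureResources

        res = tiny_manifest.resources
        tracks = dict(res.cancer_tracks)
        tracks.pop("H3K27ac")
        with pytest.raises(ValueError, match="H3K27ac"):
            FeatureResources(
                humannet={}, interactnet={}, regnet={}, cancer_genes=set(),
                deg={}, gwas=res.gwas, replication=res.replication,
                phastcons=res.phastcons, cancer_tracks=tracks,
                origin_tracks=res.origin_tracks)
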