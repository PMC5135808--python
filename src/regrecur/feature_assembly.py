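"""Assembly of the 35-feature profile of a candidate regulatory mutation.

Feature groups (names follow the feature-table schema exactly):

- ``target.*`` / ``tf.*``  — six gene-level scores for the mutation's target
  gene and for the TF whose binding the mutation affects: cancer-gene
  scores (CGS) at network distance 1 and 2 in a functional network
  (HumanNet) and a physical interactome, a regulatory-network downstream
  differential-expression sum (RegNet.DEG_score), and the gene's own
  differential-expression score (DEG_score).
- ``tfbs.*``               — the three binding-site scores (motif module).
- ``cancer.*`` / ``origin.*`` — chromatin signal at the mutated base in the
  cancer cell line (6 tracks) and the cell of origin (11 tracks).
- ``genetic.*``            — distance to the nearest cancer GWAS SNP,
  replication-timing early-to-late ratio, and a conservation score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, Mutation, SignalTrack
from .motif_features import TFBSScores
from .target_mapping import TargetAssignment

CANCER_MARKS = ("DnaseSig", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me3",
                "H3K9me3")
ORIGIN_MARKS = ("DnaseSig", "H3K27ac", "H3K27me3", "H3K36me3", "H3K4me1",
                "H3K4me2", "H3K4me3", "H3K79me2", "H3K9ac", "H3K9me3",
                "H4K20me1")
_GENE_SCORES = ("HumanNet.CGS_L1", "HumanNet.CGS_L2", "InteractNet.CGS_L1",
                "InteractNet.CGS_L2", "RegNet.DEG_score", "DEG_score")

#: The full 35-column feature schema, in fixed output order.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"target.{s}" for s in _GENE_SCORES)
    + tuple(f"tf.{s}" for s in _GENE_SCORES)
    + ("tfbs.diff_Log_Pval_FIMO", "tfbs.avg_Log_Pval_FIMO", "tfbs.Gain_or_Loss")
    + tuple(f"cancer.{m}" for m in CANCER_MARKS)
    + ("genetic.Distance.to.GWAS", "genetic.Early.to.late_Rate",
       "genetic.PhastCons")
    + tuple(f"origin.{m}" for m in ORIGIN_MARKS)
)

DEFAULT_GWAS_SENTINEL = 2.5e8   # no same-chromosome SNP: beyond any chromosome
DEFAULT_ELR_CAP = 100.0         # early-to-late ratio when S4 + G2 = 0


def deg_score_from_pvalue(p: float) -> float:
    """The bounded differential-expression map x/(x+1), x = -log10(p).

    0 for p = 1, 0.5 for p = 0.1, approaching 1 as p -> 0; p is clamped
    below at 1e-300.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    x = -math.log10(max(float(p), 1e-300))
    return x / (x + 1.0)


def deg_score(tumor_values: Sequence[float], normal_values: Sequence[float],
              equal_var: bool = True) -> float:
    """Differential-expression score of a tumor-vs-normal comparison.

    A two-sample two-sided t-test (classic pooled-variance Student by
    default; ``equal_var=False`` switches to Welch) gives the p-value, which
    ``deg_score_from_pvalue`` maps into [0, 1).
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if len(t) < 2 or len(n) < 2:
        raise ValueError("deg_score needs >= 2 values per group")
    with warnings.catch_warnings():
        # (near-)constant groups are a legitimate degenerate input here;
        # a NaN p-value from zero variance maps to "no change" below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(t, n, equal_var=equal_var).pvalue
    if math.isnan(p):   # zero variance in both groups with equal means
        p = 1.0
    return deg_score_from_pvalue(float(p))


def deg_table(expr: ExpressionMatrix, equal_var: bool = True) -> dict[str, float]:
    """DEG score for every gene in an expression matrix."""
    return {gene: deg_score(*expr.group_values(gene), equal_var=equal_var)
            for gene in expr.values.index}


def adjacency(edges: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    """Edge set -> adjacency map (edges are followed as stored, so an
    undirected network must already contain both orientations)."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
    return adj


def regnet_deg_score(source: str, regnet_adj: Mapping[str, set[str]],
                     deg: Mapping[str, float], hops: int = 3) -> float:
    """Sum of DEG scores over distinct genes reachable within ``hops``
    directed steps downstream of ``source`` (source excluded, each gene
    counted once; genes without a DEG score contribute 0)."""
    if hops < 1:
        raise ValueError("hops must be >= 1")
    visited = {source}
    frontier = {source}
    reached: set[str] = set()
    for _ in range(hops):
        nxt: set[str] = set()
        for node in frontier:
            nxt |= regnet_adj.get(node, set()) - visited
        visited |= nxt
        reached |= nxt
        frontier = nxt
        if not frontier:
            break
    return float(sum(deg.get(g, 0.0) for g in reached))


def cgs(source: str, net_adj: Mapping[str, set[str]],
        cancer_genes: set[str], level: int,
        cumulative: bool = False) -> int:
    """Cancer gene score: known cancer genes at network distance exactly
    ``level`` (1 or 2) from ``source``; the source never counts.  With
    ``cumulative`` level 2 counts distance <= 2."""
    if level not in (1, 2):
        raise ValueError("CGS level must be 1 or 2")
    d1 = net_adj.get(source, set()) - {source}
    if level == 1:
        return len(d1 & cancer_genes)
    d2: set[str] = set()
    for node in d1:
        d2 |= net_adj.get(node, set())
    d2 -= d1
    d2.discard(source)
    ring = (d2 | d1) if cumulative else d2
    return len(ring & cancer_genes)


def distance_to_gwas(mutation: Mutation,
                     catalog: Mapping[str, np.ndarray],
                     sentinel: float = DEFAULT_GWAS_SENTINEL) -> float:
    """bp distance to the nearest same-chromosome GWAS SNP (sentinel if none)."""
    if not catalog:
        raise ValueError("empty GWAS catalog")
    snps = catalog.get(mutation.chrom)
    if snps is None or len(snps) == 0:
        return float(sentinel)
    i = int(np.searchsorted(snps, mutation.pos))
    cands = []
    if i < len(snps):
        cands.append(abs(int(snps[i]) - mutation.pos))
    if i > 0:
        cands.append(abs(int(snps[i - 1]) - mutation.pos))
    return float(min(cands))


def early_late_ratio(g1b: float, s1: float, s4: float, g2: float,
                     cap: float = DEFAULT_ELR_CAP) -> float:
    """Replication-timing early-to-late ratio (G1B + S1) / (S4 + G2)."""
    for v in (g1b, s1, s4, g2):
        if v < 0:
            raise ValueError("replication fractions must be non-negative")
    late = s4 + g2
    if late == 0:
        return float(cap)
    return (g1b + s1) / late


def signal_at(track: SignalTrack, mutation: Mutation) -> float:
    """Track value at the mutated base; 0 where no interval covers it."""
    return track.value_at(mutation.chrom, mutation.pos)


@dataclass
class FeatureResources:
    """Everything assemble_features needs besides the mutation itself."""

    humannet: Mapping[str, set[str]]          # undirected functional network
    interactnet: Mapping[str, set[str]]       # undirected physical interactome
    regnet: Mapping[str, set[str]]            # directed regulatory network
    cancer_genes: set[str]
    deg: Mapping[str, float]                  # gene -> DEG score
    gwas: Mapping[str, np.ndarray]            # chrom -> sorted SNP positions
    replication: Mapping[str, SignalTrack]    # G1B/S1/S4/G2 fraction tracks
    phastcons: SignalTrack
    cancer_tracks: Mapping[str, SignalTrack]  # the 6 cancer-cell marks
    origin_tracks: Mapping[str, SignalTrack]  # the 11 cell-of-origin marks
    gwas_sentinel: float = DEFAULT_GWAS_SENTINEL
    elr_cap: float = DEFAULT_ELR_CAP
    cgs_cumulative: bool = False
    regnet_hops: int = 3

    def __post_init__(self) -> None:
        missing = [m for m in CANCER_MARKS if m not in self.cancer_tracks]
        missing += [f"origin:{m}" for m in ORIGIN_MARKS
                    if m not in self.origin_tracks]
        if missing:
            raise ValueError(f"missing configured signal tracks: {missing}")


def _gene_scores(gene: str | None, res: FeatureResources) -> dict[str, float]:
    if gene is None:
        return {name: 0.0 for name in _GENE_SCORES}
    return {
        "HumanNet.CGS_L1": cgs(gene, res.humannet, res.cancer_genes, 1),
        "HumanNet.CGS_L2": cgs(gene, res.humannet, res.cancer_genes, 2,
                               cumulative=res.cgs_cumulative),
        "InteractNet.CGS_L1": cgs(gene, res.interactnet, res.cancer_genes, 1),
        "InteractNet.CGS_L2": cgs(gene, res.interactnet, res.cancer_genes, 2,
                                  cumulative=res.cgs_cumulative),
        "RegNet.DEG_score": regnet_deg_score(gene, res.regnet, res.deg,
                                             hops=res.regnet_hops),
        "DEG_score": float(res.deg.get(gene, 0.0)),
    }


def assemble_features(mutation: Mutation, assignment: TargetAssignment,
                      tfbs: TFBSScores,
                      res: FeatureResources) -> dict[str, float]:
    """The full 35-feature vector of one candidate mutation, in schema order.

    The six ``tf.*`` scores are computed for the TF identified by the motif
    module (the changed motif's TF, or the region's best-bound TF when no
    motif changed) and are all zero only when no TF was identified at all.
    """
    out: dict[str, float] = {}
    for k, v in _gene_scores(assignment.gene_id, res).items():
        out[f"target.{k}"] = float(v)
    for k, v in _gene_scores(tfbs.bound_tf, res).items():
        out[f"tf.{k}"] = float(v)
    out["tfbs.diff_Log_Pval_FIMO"] = tfbs.diff_log_pval
    out["tfbs.avg_Log_Pval_FIMO"] = tfbs.avg_log_pval
    out["tfbs.Gain_or_Loss"] = float(tfbs.gain_or_loss)
    for mark in CANCER_MARKS:
        out[f"cancer.{mark}"] = signal_at(res.cancer_tracks[mark], mutation)
    out["genetic.Distance.to.GWAS"] = distance_to_gwas(
        mutation, res.gwas, sentinel=res.gwas_sentinel)
    fr = {f: signal_at(res.replication[f], mutation)
          for f in ("G1B", "S1", "S4", "G2")}
    out["genetic.Early.to.late_Rate"] = early_late_ratio(
        fr["G1B"], fr["S1"], fr["S4"], fr["G2"], cap=res.elr_cap)
    out["genetic.PhastCons"] = signal_at(res.phastcons, mutation)
    for mark in ORIGIN_MARKS:
        out[f"origin.{mark}"] = signal_at(res.origin_tracks[mark], mutation)
    vec = {name: out[name] for name in FEATURE_NAMES}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features for {mutation.key}: {bad}")
    return vec
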