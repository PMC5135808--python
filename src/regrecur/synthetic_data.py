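"""Internally consistent synthetic fixtures for every pipeline stage.

The generator realises the statistical structure the analysis assumes — a
homogeneous per-sample Poisson background of somatic substitutions plus
planted cross-sample hotspots — together with every annotation resource the
feature layer consumes: a toy genome with TF consensus sites written under
the hotspots, PWMs, enhancer-promoter pairs and a DHS correlation map
covering the genome, signal tracks enriched at hotspots, regulatory and
interaction networks whose hotspot target genes sit next to cancer genes,
a tumor/normal expression matrix, GWAS SNPs near hotspots, and
replication-timing fractions.

Effect sizes are standardised mean shifts per feature (units of one latent
standard deviation), so the separability of the true/false classes — and
hence the expected cross-validation AUC regime — is controlled directly.
Decision trees are invariant to monotone per-feature transforms, so the
latent shift survives the realistic per-feature output scales unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_assembly import (CANCER_MARKS, FEATURE_NAMES, ORIGIN_MARKS,
                               FeatureResources, adjacency, deg_table)
from .io_formats import (CohortIndex, ExpressionMatrix, GenomicInterval,
                         Mutation, SignalTrack, write_edge_list,
                         write_expression_matrix, write_genome_fasta,
                         write_mutations, write_signal_track)
from .motif_features import ALPHABET, PWM, write_meme_motifs
from .target_mapping import DHSCorrEntry, EPPair

logger = logging.getLogger(__name__)

TRACK_BIN = 250          # bp per signal-track bin
TILE = 1000              # bp per enhancer/DHS tile
MOTIF_LEN = 8
_MAX_SEED = 2**31 - 1

#: Default per-feature standardised mean shifts between hotspot-linked and
#: background mutations.  The informative panel mirrors the feature groups
#: that dominate real classifiers of this kind: chromatin accessibility,
#: proximity to known risk loci, and the target gene's network context.
DEFAULT_EFFECT: dict[str, float] = {
    "cancer.DnaseSig": 1.0,
    "origin.DnaseSig": 1.0,
    "genetic.Distance.to.GWAS": -0.8,
    "target.InteractNet.CGS_L1": 0.8,
    "target.InteractNet.CGS_L2": 0.8,
    "target.RegNet.DEG_score": 0.8,
    "target.DEG_score": 0.5,
    "target.HumanNet.CGS_L1": 0.4,
    "target.HumanNet.CGS_L2": 0.4,
    "cancer.H3K27me3": 0.6,
    "origin.H3K4me1": 0.6,
    "origin.H3K36me3": 0.6,
    "cancer.H3K9me3": 0.5,
    "tfbs.avg_Log_Pval_FIMO": 0.5,
    "genetic.Early.to.late_Rate": 0.4,
}


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    pos: int
    multiplicity: int
    max_spread: int = 2

    def __post_init__(self) -> None:
        if self.multiplicity < 2:
            raise ValueError("hotspot multiplicity must be >= 2")
        if self.max_spread < 0:
            raise ValueError("max_spread must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    genome: tuple[tuple[str, int], ...]
    n_samples: int
    background_rate: float            # mutations per bp per sample
    hotspots: tuple[Hotspot, ...]
    n_genes: int = 40
    n_tfs: int = 4
    n_cancer_genes: int = 8
    effect: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        lengths = dict(self.genome)
        for h in self.hotspots:
            if h.chrom not in lengths or not 1 <= h.pos <= lengths[h.chrom]:
                raise ValueError(f"hotspot {h} outside the genome")
            if h.multiplicity > self.n_samples:
                raise ValueError(f"hotspot multiplicity {h.multiplicity} exceeds "
                                 f"{self.n_samples} samples")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.genome)


Preset = Literal["tiny", "default", "null"]


def preset_config(preset: Preset, seed: int = 0) -> SimulationConfig:
    """The three study presets.

    tiny    — 1 chrom x 100 kbp, 5 samples, 3 hotspots: fast end-to-end runs.
    default — 2 chroms x 1 Mbp, 20 samples, 114 hotspots of multiplicity
              4..8 (the true-set size regime the recurrence thresholds are
              tuned for), cohort background ~1e-3 mutations/bp.
    null    — default dimensions, no hotspots, all feature effects zero.
    """
    rng = np.random.default_rng(seed)
    if preset == "tiny":
        genome = (("chr1", 100_000),)
        hs = tuple(Hotspot("chr1", int(p), m) for p, m in
                   zip((20_000, 50_000, 80_000), (4, 5, 4)))
        return SimulationConfig(genome=genome, n_samples=5,
                                background_rate=2e-4, hotspots=hs,
                                n_genes=30, n_tfs=4, n_cancer_genes=8,
                                seed=seed)
    if preset in ("default", "null"):
        genome = (("chr1", 1_000_000), ("chr2", 1_000_000))
        hs: tuple[Hotspot, ...] = ()
        effect: Mapping[str, float] = dict(DEFAULT_EFFECT)
        if preset == "default":
            spots = []
            mults = (4, 5, 6, 7, 8)
            for i in range(114):
                chrom = "chr1" if i < 57 else "chr2"
                base = 12_000 + (i % 57) * 17_000
                pos = base + int(rng.integers(0, 5_000))
                # zero spread: each hotspot is one recurrent substitution, so
                # the number of hotspots equals the number of true-set sites
                spots.append(Hotspot(chrom, pos, mults[i % len(mults)],
                                     max_spread=0))
            hs = tuple(spots)
        else:
            effect = {}
        return SimulationConfig(genome=genome, n_samples=20,
                                background_rate=5e-5, hotspots=hs,
                                n_genes=60, n_tfs=6, n_cancer_genes=12,
                                effect=effect, seed=seed)
    raise ValueError(f"unknown preset {preset!r}")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _random_base(rng: np.random.Generator, exclude: str = "") -> str:
    choices = [b for b in ALPHABET if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(cfg: SimulationConfig,
                    genome_seq: Mapping[str, str] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[CohortIndex, list[list[Mutation]]]:
    """Background Poisson mutations plus planted hotspot mutations.

    Each hotspot contributes ``multiplicity`` mutations in distinct samples
    within +-max_spread bp of its position, all carrying the same alternate
    allele (one recurrent substitution seen across patients).  Background
    positions landing within 10 bp of a hotspot are dropped so that planted
    hotspots are the cohort's only recurrences and ground-truth labels are
    exact.  When a genome is supplied, reference alleles are read from it;
    hotspot members mutate away from the planted consensus base.  Returns
    the cohort and the per-hotspot member mutations (the ground truth).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    samples = _sample_ids(cfg.n_samples)
    muts: list[Mutation] = []
    exclusion = {chrom: np.sort(np.array([h.pos for h in cfg.hotspots
                                          if h.chrom == chrom], dtype=np.int64))
                 for chrom, _ in cfg.genome}

    def near_hotspot(chrom: str, pos: int) -> bool:
        arr = exclusion[chrom]
        if len(arr) == 0:
            return False
        i = int(np.searchsorted(arr, pos))
        return ((i < len(arr) and arr[i] - pos <= 10)
                or (i > 0 and pos - arr[i - 1] <= 10))

    def ref_at(chrom: str, pos: int) -> str:
        if genome_seq is not None:
            base = genome_seq[chrom][pos - 1]
            return base if base in ALPHABET else "A"
        return _random_base(rng)

    for sid in samples:
        for chrom, length in cfg.genome:
            n = int(rng.poisson(cfg.background_rate * length))
            positions = rng.integers(1, length + 1, size=n)
            for pos in sorted(positions.tolist()):
                if near_hotspot(chrom, pos):
                    continue
                ref = ref_at(chrom, pos)
                muts.append(Mutation(chrom, int(pos), ref,
                                     _random_base(rng, exclude=ref), sid, "synthetic"))
    members: list[list[Mutation]] = []
    lengths = cfg.chrom_lengths
    for h in cfg.hotspots:
        carriers = rng.choice(cfg.n_samples, size=h.multiplicity, replace=False)
        group = []
        allele_for: dict[int, tuple[str, str]] = {}   # shared ref/alt per position
        for ci in sorted(carriers.tolist()):
            off = int(rng.integers(-h.max_spread, h.max_spread + 1))
            pos = int(np.clip(h.pos + off, 1, lengths[h.chrom]))
            if pos not in allele_for:
                ref = ref_at(h.chrom, pos)
                allele_for[pos] = (ref, _random_base(rng, exclude=ref))
            ref, alt = allele_for[pos]
            m = Mutation(h.chrom, pos, ref, alt, samples[ci], "synthetic")
            group.append(m)
            muts.append(m)
        members.append(group)
    return CohortIndex(muts, chrom_lengths=lengths), members


def simulate_uniform_cohort(n_samples: int, n_per_sample: int,
                            chrom: str = "chr1", chrom_length: int = 1_000_000,
                            seed: int = 0) -> CohortIndex:
    """Exactly ``n_samples * n_per_sample`` records, positions drawn without
    replacement within each sample (no within-sample duplicates to collapse)."""
    rng = np.random.default_rng(seed)
    muts = []
    for sid in _sample_ids(n_samples):
        positions = rng.choice(chrom_length, size=n_per_sample, replace=False) + 1
        for pos in sorted(positions.tolist()):
            ref = _random_base(rng)
            muts.append(Mutation(chrom, int(pos), ref,
                                 _random_base(rng, exclude=ref), sid, "synthetic"))
    return CohortIndex(muts, chrom_lengths={chrom: chrom_length})


# ---------------------------------------------------------------------------
# genome + motifs


def simulate_pwms(cfg: SimulationConfig, rng: np.random.Generator) -> list[PWM]:
    """Strong-consensus PWMs (0.91 on the consensus base, 0.03 elsewhere):
    a full consensus match passes the default match threshold, one mismatch
    does not, so a substitution in a planted site registers as a motif loss."""
    pwms = []
    for i in range(cfg.n_tfs):
        consensus = rng.integers(0, 4, size=MOTIF_LEN)
        mat = np.full((MOTIF_LEN, 4), 0.03)
        mat[np.arange(MOTIF_LEN), consensus] = 0.91
        pwms.append(PWM(f"TF{i + 1:03d}", mat))
    return pwms


def simulate_genome(cfg: SimulationConfig, pwms: Sequence[PWM],
                    rng: np.random.Generator) -> dict[str, str]:
    """Random genome with each hotspot's assigned TF consensus written over
    the hotspot position (the motif starts 4 bp left of the hotspot)."""
    arrays = {chrom: rng.integers(0, 4, size=length).astype(np.int8)
              for chrom, length in cfg.genome}
    for i, h in enumerate(cfg.hotspots):
        pwm = pwms[i % len(pwms)]
        consensus = pwm.matrix.argmax(axis=1).astype(np.int8)
        start = h.pos - 1 - MOTIF_LEN // 2          # 0-based motif start
        arr = arrays[h.chrom]
        if 0 <= start and start + MOTIF_LEN <= len(arr):
            arr[start:start + MOTIF_LEN] = consensus
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return {chrom: lut[arr.astype(np.intp)].tobytes().decode("ascii")
            for chrom, arr in arrays.items()}


# ---------------------------------------------------------------------------
# annotation resources


@dataclass
class SimulatedResources:
    """All annotation inputs the feature layer consumes, plus raw tables."""

    genome: dict[str, str]
    pwms: list[PWM]
    ep_pairs: list[EPPair]
    dhs_map: list[DHSCorrEntry]
    dhs_peaks: list[GenomicInterval]
    humannet_edges: set[tuple[str, str]]
    interactnet_edges: set[tuple[str, str]]
    regnet_edges: set[tuple[str, str]]
    cancer_genes: set[str]
    expression: ExpressionMatrix
    gwas: dict[str, np.ndarray]
    replication: dict[str, SignalTrack]
    phastcons: SignalTrack
    cancer_tracks: dict[str, SignalTrack]
    origin_tracks: dict[str, SignalTrack]
    hotspot_genes: dict[str, str]       # hotspot "chrom:pos" -> target gene

    def feature_resources(self) -> FeatureResources:
        return FeatureResources(
            humannet=adjacency(self.humannet_edges),
            interactnet=adjacency(self.interactnet_edges),
            regnet=adjacency(self.regnet_edges),
            cancer_genes=set(self.cancer_genes),
            deg=deg_table(self.expression),
            gwas=self.gwas,
            replication=self.replication,
            phastcons=self.phastcons,
            cancer_tracks=self.cancer_tracks,
            origin_tracks=self.origin_tracks)


def _binned_track(name: str, cfg: SimulationConfig, z: dict[str, np.ndarray],
                  transform) -> SignalTrack:
    ivs = []
    for chrom, length in cfg.genome:
        vals = transform(z[chrom])
        for i, v in enumerate(vals):
            start = i * TRACK_BIN
            ivs.append(GenomicInterval(chrom, start, min(start + TRACK_BIN, length),
                                       float(v)))
    return SignalTrack(name, ivs)


def _latent_bins(cfg: SimulationConfig, rng: np.random.Generator,
                 shift: float) -> dict[str, np.ndarray]:
    """Standard-normal bin values, shifted by ``shift`` at hotspot bins."""
    z = {}
    for chrom, length in cfg.genome:
        n_bins = (length + TRACK_BIN - 1) // TRACK_BIN
        z[chrom] = rng.normal(size=n_bins)
    for h in cfg.hotspots:
        z[h.chrom][(h.pos - 1) // TRACK_BIN] += shift
    return z


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def simulate_resources(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       pwms: Sequence[PWM] | None = None,
                       genome: Mapping[str, str] | None = None,
                       ) -> SimulatedResources:
    """Generate every annotation resource, wired to the hotspots.

    Coverage: the genome is tiled in 1 kbp regulatory tiles; 3 of every 5
    tiles carry an enhancer-promoter pair, 1 a DHS-correlation entry and 1
    nothing (exercising the exclusion path).  Hotspot tiles always carry an
    EP pair to the hotspot's designated target gene.  Feature effects from
    ``cfg.effect`` are planted into the corresponding resource: shifted
    signal bins, nearby GWAS SNPs, cancer-gene edges around hotspot target
    genes, differential expression of hotspot genes and their regulatory
    targets, and early-replicating hotspot neighbourhoods.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    eff = dict(cfg.effect)
    if pwms is None:
        pwms = simulate_pwms(cfg, rng)
    if genome is None:
        genome = simulate_genome(cfg, pwms, rng)
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    tf_ids = [p.tf_id for p in pwms]

    # --- regulatory tiling: EP pairs, DHS correlation map, DHS peaks
    hotspot_genes: dict[str, str] = {}
    # hotspot targets draw from the first half of the gene list, leaving the
    # rest free to act as cancer genes and downstream DE genes
    n_hot_pool = max(1, cfg.n_genes // 2)
    for i, h in enumerate(cfg.hotspots):
        hotspot_genes[f"{h.chrom}:{h.pos}"] = genes[i % n_hot_pool]
    hot_tiles = {(h.chrom, (h.pos - 1) // TILE): f"{h.chrom}:{h.pos}"
                 for h in cfg.hotspots}
    ep_pairs: list[EPPair] = []
    dhs_map: list[DHSCorrEntry] = []
    dhs_peaks: list[GenomicInterval] = []
    for chrom, length in cfg.genome:
        for t in range((length + TILE - 1) // TILE):
            start, end = t * TILE, min((t + 1) * TILE, length)
            iv = GenomicInterval(chrom, start, end)
            gene = genes[(t * 7 + (0 if chrom == "chr1" else 3)) % cfg.n_genes]
            if (chrom, t) in hot_tiles:
                gene = hotspot_genes[hot_tiles[(chrom, t)]]
                ep_pairs.append(EPPair(iv, gene, "synthetic",
                                       float(rng.uniform(0.6, 1.0))))
            elif t % 5 < 3:
                ep_pairs.append(EPPair(iv, gene, "synthetic",
                                       float(rng.uniform(0.2, 1.0))))
            elif t % 5 == 3:
                dhs_map.append(DHSCorrEntry(iv, gene, float(rng.uniform(0.3, 0.95))))
            # t % 5 == 4: uncovered tile
            if t % 10 == 0:
                dhs_peaks.append(GenomicInterval(chrom, start + 200, start + 500))
    for h in cfg.hotspots:
        dhs_peaks.append(GenomicInterval(h.chrom, max(0, h.pos - 31), h.pos + 30))

    # --- networks
    hot_gene_set = sorted(set(hotspot_genes.values()))
    cancer_pool = [g for g in genes if g not in hot_gene_set]
    cancer_genes = set(cancer_pool[:cfg.n_cancer_genes])
    cg = sorted(cancer_genes)
    nodes = genes + tf_ids

    def random_undirected(per_node: int) -> set[tuple[str, str]]:
        edges: set[tuple[str, str]] = set()
        for a in nodes:
            for b in rng.choice(len(nodes), size=per_node, replace=False):
                if nodes[b] != a:
                    edges.add((a, nodes[b]))
                    edges.add((nodes[b], a))
        return edges

    def wire_cancer(edges: set[tuple[str, str]], n_links: int) -> None:
        # hotspot genes adjacent to cancer genes; cancer genes chained so the
        # second ring (distance exactly 2) also carries signal
        for i, g in enumerate(hot_gene_set):
            for j in range(n_links):
                c = cg[(i + j) % len(cg)]
                edges.add((g, c))
                edges.add((c, g))
        for i in range(len(cg) - 1):
            edges.add((cg[i], cg[i + 1]))
            edges.add((cg[i + 1], cg[i]))

    interactnet = random_undirected(2)
    humannet = random_undirected(3)
    if eff.get("target.InteractNet.CGS_L1", 0) or eff.get("target.InteractNet.CGS_L2", 0):
        wire_cancer(interactnet, 2)
    if eff.get("target.HumanNet.CGS_L1", 0) or eff.get("target.HumanNet.CGS_L2", 0):
        wire_cancer(humannet, 1)

    regnet: set[tuple[str, str]] = set()
    for a in nodes:
        for b in rng.choice(len(nodes), size=2, replace=False):
            if nodes[b] != a:
                regnet.add((a, nodes[b]))
    de_genes = [g for g in genes if g not in hot_gene_set][-max(cfg.n_genes // 6, 3):]
    if eff.get("target.RegNet.DEG_score", 0):
        for i, g in enumerate(hot_gene_set + tf_ids):
            for j in range(3):
                regnet.add((g, de_genes[(i + j) % len(de_genes)]))

    # --- expression (5 tumor vs 5 normal)
    cols = [f"T{i + 1}" for i in range(5)] + [f"N{i + 1}" for i in range(5)]
    status = pd.Series(["tumor"] * 5 + ["normal"] * 5, index=cols)
    base = rng.normal(10.0, 1.0, size=(len(nodes), 10))
    expr = pd.DataFrame(base, index=nodes, columns=cols)
    de_shift = 2.5
    strong_de = set(de_genes)
    if eff.get("target.DEG_score", 0):
        strong_de |= set(hot_gene_set)
    for g in sorted(strong_de):
        expr.loc[g, status == "tumor"] += de_shift
    expression = ExpressionMatrix(values=expr, status=status)

    # --- GWAS catalog
    gwas: dict[str, list[int]] = {chrom: [] for chrom, _ in cfg.genome}
    for chrom, length in cfg.genome:
        for p in range(25_000, length, 50_000):
            gwas[chrom].append(p + int(rng.integers(0, 10_000)))
    if eff.get("genetic.Distance.to.GWAS", 0) < 0:
        for h in cfg.hotspots:
            gwas[h.chrom].append(int(np.clip(
                h.pos + int(rng.normal(0, 2_000)), 1, cfg.chrom_lengths[h.chrom])))
    gwas_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in gwas.items()
                if v}

    # --- signal tracks
    lognorm = lambda z: np.exp(0.6 * z)
    cancer_tracks = {}
    for mark in CANCER_MARKS:
        z = _latent_bins(cfg, rng, eff.get(f"cancer.{mark}", 0.0))
        cancer_tracks[mark] = _binned_track(mark, cfg, z, lognorm)
    origin_tracks = {}
    for mark in ORIGIN_MARKS:
        z = _latent_bins(cfg, rng, eff.get(f"origin.{mark}", 0.0))
        origin_tracks[mark] = _binned_track(mark, cfg, z, lognorm)
    zc = _latent_bins(cfg, rng, eff.get("genetic.PhastCons", 0.0))
    phastcons = _binned_track("PhastCons", cfg, zc,
                              lambda z: 1.0 / (1.0 + np.exp(-(z - 1.0))))
    zr = _latent_bins(cfg, rng, eff.get("genetic.Early.to.late_Rate", 0.0))
    replication = {
        "G1B": _binned_track("repli_G1B", cfg, zr, lambda z: _softplus(z) / 2),
        "S1": _binned_track("repli_S1", cfg, zr, lambda z: _softplus(z) / 2),
        "S4": _binned_track("repli_S4", cfg, zr, lambda z: _softplus(-z) / 2 + 0.05),
        "G2": _binned_track("repli_G2", cfg, zr, lambda z: _softplus(-z) / 2 + 0.05),
    }

    return SimulatedResources(
        genome=dict(genome), pwms=list(pwms), ep_pairs=ep_pairs, dhs_map=dhs_map,
        dhs_peaks=dhs_peaks, humannet_edges=humannet, interactnet_edges=interactnet,
        regnet_edges=regnet, cancer_genes=cancer_genes, expression=expression,
        gwas=gwas_arr, replication=replication, phastcons=phastcons,
        cancer_tracks=cancer_tracks, origin_tracks=origin_tracks,
        hotspot_genes=hotspot_genes)


# ---------------------------------------------------------------------------
# direct feature-table generator (CV-scale experiments)


def simulate_feature_table(n_true: int = 114, n_false: int = 342,
                           effect: Mapping[str, float] | None = None,
                           seed: int = 0, n_samples: int = 20) -> pd.DataFrame:
    """Labeled 35-feature table drawn from the latent shift model directly.

    Each feature is a monotone transform of a standard-normal latent value;
    true rows receive the per-feature shift from ``effect``.  Output scales
    are feature-appropriate (counts for CGS, [0,1) scores for DEG and
    conservation, positive signal levels, bp distances, and a consistent
    Gain_or_Loss / diff pair), which leaves tree-based classifiers' behaviour
    identical to the latent model.
    """
    effect = dict(DEFAULT_EFFECT) if effect is None else dict(effect)
    rng = np.random.default_rng(seed)
    n = n_true + n_false
    label = np.zeros(n, dtype=bool)
    label[:n_true] = True
    z = rng.normal(size=(n, len(FEATURE_NAMES)))
    for j, name in enumerate(FEATURE_NAMES):
        z[:n_true, j] += effect.get(name, 0.0)

    cols: dict[str, np.ndarray] = {}
    gol = None
    for j, name in enumerate(FEATURE_NAMES):
        v = z[:, j]
        if ".CGS_" in name:
            cols[name] = np.floor(np.exp(0.7 * (v + 0.5))).clip(min=0)
        elif name.endswith("RegNet.DEG_score"):
            cols[name] = _softplus(v)
        elif name.endswith("DEG_score") or name.endswith("PhastCons"):
            cols[name] = 1.0 / (1.0 + np.exp(-(v - 1.0)))
        elif name == "tfbs.Gain_or_Loss":
            gol = np.where(np.abs(v) > 1.8, np.sign(v), 0.0)
            cols[name] = gol
        elif name == "tfbs.diff_Log_Pval_FIMO":
            pass  # filled after Gain_or_Loss, to keep the pair consistent
        elif name == "tfbs.avg_Log_Pval_FIMO":
            cols[name] = _softplus(v + 1.5)
        elif name == "genetic.Distance.to.GWAS":
            cols[name] = np.exp(10.0 + 1.2 * v)
        elif name == "genetic.Early.to.late_Rate":
            cols[name] = _softplus(v + 1.0)
        else:  # signal tracks
            cols[name] = np.exp(0.6 * v)
    diff_latent = z[:, FEATURE_NAMES.index("tfbs.diff_Log_Pval_FIMO")]
    assert gol is not None
    cols["tfbs.diff_Log_Pval_FIMO"] = np.where(gol == 0, 0.0,
                                               -gol * (2.0 + np.abs(diff_latent)))

    table = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    table.insert(0, "mutation_key", [f"chrS:{i + 1}:A>C" for i in range(n)])
    sids = _sample_ids(n_samples)
    table.insert(1, "sample_id", [sids[int(i)] for i in rng.integers(0, n_samples, n)])
    table.insert(2, "label", label)
    return table.sample(frac=1.0, random_state=int(rng.integers(_MAX_SEED))
                        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# bundles


@dataclass
class FixtureManifest:
    config: SimulationConfig
    cohort: CohortIndex
    hotspot_members: list[list[Mutation]]
    resources: SimulatedResources
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def hotspots(self) -> tuple[Hotspot, ...]:
        return self.config.hotspots

    def ground_truth_keys(self, min_multiplicity: int = 2) -> set[str]:
        """Mutation keys of members of hotspots at or above a multiplicity."""
        out: set[str] = set()
        for h, members in zip(self.config.hotspots, self.hotspot_members):
            if h.multiplicity >= min_multiplicity:
                out |= {m.key for m in members}
        return out


def make_fixture_bundle(preset: Preset, seed: int = 0,
                        out_dir: str | Path | None = None) -> FixtureManifest:
    """Generate the full fixture bundle for a preset; optionally write it out."""
    cfg = preset_config(preset, seed)
    rng = np.random.default_rng(seed)
    pwms = simulate_pwms(cfg, rng)
    genome = simulate_genome(cfg, pwms, rng)
    cohort, members = simulate_cohort(cfg, genome_seq=genome, rng=rng)
    resources = simulate_resources(cfg, rng=rng, pwms=pwms, genome=genome)
    manifest = FixtureManifest(config=cfg, cohort=cohort,
                               hotspot_members=members, resources=resources)
    if out_dir is not None:
        manifest.paths = write_bundle(manifest, Path(out_dir))
    return manifest


def write_bundle(manifest: FixtureManifest, out_dir: Path) -> dict[str, Path]:
    """Write every artifact as plain text and return the path manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    res = manifest.resources
    paths: dict[str, Path] = {}

    def put(key: str, fname: str) -> Path:
        paths[key] = out_dir / fname
        return paths[key]

    write_mutations(manifest.cohort, put("mutations", "mutations.tsv"))
    write_genome_fasta(res.genome, put("genome", "genome.fa"))
    write_meme_motifs(res.pwms, put("motifs", "motifs.meme"))
    with open(put("ep_pairs", "ep_pairs.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tcell_type\tscore\n")
        for p in res.ep_pairs:
            fh.write(f"{p.enhancer.chrom}\t{p.enhancer.start}\t{p.enhancer.end}"
                     f"\t{p.gene_id}\t{p.cell_type}\t{p.score:.4f}\n")
    with open(put("dhs_map", "dhs_corr_map.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tmax_corr\n")
        for e in res.dhs_map:
            fh.write(f"{e.distal.chrom}\t{e.distal.start}\t{e.distal.end}"
                     f"\t{e.gene_id}\t{e.max_corr:.4f}\n")
    with open(put("dhs_peaks", "dhs_peaks.bed"), "w") as fh:
        for iv in res.dhs_peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    write_edge_list(res.humannet_edges, put("humannet", "humannet.tsv"),
                    directed=False)
    write_edge_list(res.interactnet_edges, put("interactnet", "interactnet.tsv"),
                    directed=False)
    write_edge_list(res.regnet_edges, put("regnet", "regnet.tsv"), directed=True)
    with open(put("cancer_genes", "cancer_genes.tsv"), "w") as fh:
        for g in sorted(res.cancer_genes):
            fh.write(g + "\n")
    write_expression_matrix(res.expression, put("expression", "expression.tsv"))
    with open(put("gwas", "gwas.tsv"), "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom in sorted(res.gwas):
            for p in res.gwas[chrom]:
                fh.write(f"{chrom}\t{int(p)}\n")
    for frac, track in res.replication.items():
        write_signal_track(track, put(f"repli_{frac}", f"replication_{frac}.bedgraph"))
    write_signal_track(res.phastcons, put("phastcons", "phastcons.bedgraph"))
    for mark, track in res.cancer_tracks.items():
        write_signal_track(track, put(f"cancer_{mark}", f"cancer_{mark}.bedgraph"))
    for mark, track in res.origin_tracks.items():
        write_signal_track(track, put(f"origin_{mark}", f"origin_{mark}.bedgraph"))
    with open(put("ground_truth", "ground_truth.tsv"), "w") as fh:
        fh.write("hotspot_chrom\thotspot_pos\tmultiplicity\tmember_key\tsample\n")
        for h, members in zip(manifest.config.hotspots, manifest.hotspot_members):
            for m in members:
                fh.write(f"{h.chrom}\t{h.pos}\t{h.multiplicity}\t{m.key}"
                         f"\t{m.sample_id}\n")
    with open(put("manifest", "manifest.tsv"), "w") as fh:
        fh.write("key\tpath\n")
        for key, p in sorted(paths.items()):
            fh.write(f"{key}\t{p.name}\n")
    return paths
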