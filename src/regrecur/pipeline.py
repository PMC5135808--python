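"""End-to-end glue: labeled recurrence sets -> assembled feature tables.

Keeps the per-module surfaces thin by owning the one place where mutation
keys, target assignments, motif scores and annotation lookups are joined
into the labeled feature table the classifier consumes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .feature_assembly import FEATURE_NAMES, FeatureResources, assemble_features
from .io_formats import CohortIndex, GenomicInterval, Mutation
from .motif_features import DEFAULT_ALPHA, PWM, tfbs_scores
from .recurrence import LabeledSet
from .target_mapping import DHSCorrEntry, EPPair, assign_targets

logger = logging.getLogger(__name__)


def load_bundle(bundle_dir) -> dict:
    """Load a written fixture bundle back through the standard file readers.

    Returns the keyword pieces ``extract_feature_table`` needs, plus the
    cohort, rebuilt entirely from the on-disk text formats.
    """
    from pathlib import Path

    from . import io_formats as io
    from .feature_assembly import CANCER_MARKS, ORIGIN_MARKS
    from .motif_features import read_meme_motifs
    from .target_mapping import load_dhs_peaks, read_dhs_corr_map, read_ep_pairs
    from .feature_assembly import adjacency, deg_table

    d = Path(bundle_dir)
    paths = {row.split("\t")[0]: d / row.split("\t")[1].strip()
             for row in (d / "manifest.tsv").read_text().splitlines()[1:]}
    genome = io.read_genome_fasta(paths["genome"])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    cohort = io.read_mutations(paths["mutations"], chrom_lengths=chrom_lengths)
    expression = io.read_expression_matrix(paths["expression"])
    resources = FeatureResources(
        humannet=adjacency(io.read_edge_list(paths["humannet"], directed=False)),
        interactnet=adjacency(io.read_edge_list(paths["interactnet"], directed=False)),
        regnet=adjacency(io.read_edge_list(paths["regnet"], directed=True)),
        cancer_genes={line.strip() for line in
                      open(paths["cancer_genes"]) if line.strip()},
        deg=deg_table(expression),
        gwas=io.read_gwas_catalog(paths["gwas"]),
        replication=io.read_replication_timing(
            {f: paths[f"repli_{f}"] for f in io.REPLICATION_FRACTIONS}),
        phastcons=io.read_signal_track(paths["phastcons"], "PhastCons"),
        cancer_tracks={m: io.read_signal_track(paths[f"cancer_{m}"], m)
                       for m in CANCER_MARKS},
        origin_tracks={m: io.read_signal_track(paths[f"origin_{m}"], m)
                       for m in ORIGIN_MARKS})
    return {
        "cohort": cohort,
        "genome": genome,
        "pwms": read_meme_motifs(paths["motifs"]),
        "ep_pairs": read_ep_pairs(paths["ep_pairs"]),
        "dhs_map": read_dhs_corr_map(paths["dhs_map"]),
        "dhs_peaks": load_dhs_peaks(paths["dhs_peaks"]),
        "resources": resources,
    }


def representative_mutations(cohort: CohortIndex,
                             keys: Sequence[str]) -> list[Mutation]:
    """One Mutation per key; the carrier with the smallest sample_id represents
    a substitution shared by several samples."""
    by_key: dict[str, Mutation] = {}
    for m in cohort:   # cohort iterates in sorted order, so first wins
        by_key.setdefault(m.key, m)
    missing = [k for k in keys if k not in by_key]
    if missing:
        raise KeyError(f"keys not in cohort: {missing[:5]}")
    return [by_key[k] for k in keys]


def extract_feature_table(labeled: LabeledSet, cohort: CohortIndex,
                          ep_pairs: Sequence[EPPair],
                          dhs_map: Sequence[DHSCorrEntry],
                          dhs_peaks: Sequence[GenomicInterval],
                          pwms: Sequence[PWM],
                          genome: Mapping[str, str],
                          resources: FeatureResources,
                          alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Labeled feature table for a training set.

    Mutations that map to no target gene are dropped (with a log line):
    regulatory-region membership is the candidate filter, so they carry no
    features and never reach the classifier.
    """
    keys = list(labeled.true_ids) + list(labeled.false_ids)
    labels = [True] * len(labeled.true_ids) + [False] * len(labeled.false_ids)
    label_by_key = dict(zip(keys, labels))
    mutations = representative_mutations(cohort, keys)
    assignments = assign_targets(mutations, ep_pairs, dhs_map, dhs_peaks)
    assigned = {a.mutation_key: a for a in assignments}
    rows = []
    n_dropped = 0
    for m in mutations:
        a = assigned.get(m.key)
        if a is None:
            n_dropped += 1
            continue
        tfbs = tfbs_scores(m, a.dhs_region, pwms, genome, alpha=alpha)
        vec = assemble_features(m, a, tfbs, resources)
        rows.append({"mutation_key": m.key, "sample_id": m.sample_id,
                     "label": label_by_key[m.key], **vec})
    if n_dropped:
        logger.info("feature extraction dropped %d non-regulatory mutations",
                    n_dropped)
    if not rows:
        raise ValueError("no labeled mutation maps to a regulatory region")
    return pd.DataFrame(rows, columns=["mutation_key", "sample_id", "label",
                                       *FEATURE_NAMES])
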