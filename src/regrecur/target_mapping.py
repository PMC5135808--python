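"""Assign each candidate mutation to the gene its regulatory region controls.

Enhancer-promoter (EP) pair tables take precedence; mutations not covered by
any EP enhancer fall back to a distal-DHS/promoter correlation map.  A
mutation covered by neither is dropped from all downstream feature extraction
and training — regulatory-region membership is the candidate filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .io_formats import FormatError, GenomicInterval, Mutation, read_bed_intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EPPair:
    enhancer: GenomicInterval
    gene_id: str
    cell_type: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("EP pair needs a gene_id")


@dataclass(frozen=True)
class DHSCorrEntry:
    distal: GenomicInterval
    gene_id: str
    max_corr: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.max_corr <= 1.0:
            raise ValueError(f"DHS correlation {self.max_corr} outside [-1, 1]")


@dataclass(frozen=True)
class TargetAssignment:
    mutation_key: str
    gene_id: str
    source: Literal["EP", "DHS_CORR"]
    dhs_region: GenomicInterval


def read_ep_pairs(path: str | Path) -> list[EPPair]:
    """TSV: chrom, start, end, gene, cell_type, score (header optional)."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "end", "gene", "cell_type", "score"],
                     comment="#")
    if df.iloc[0]["chrom"] == "chrom":
        df = df.iloc[1:]
    try:
        return [EPPair(GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                       str(r.gene), str(r.cell_type), float(r.score))
                for r in df.itertuples()]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed EP pair table ({exc})") from exc


def read_dhs_corr_map(path: str | Path) -> list[DHSCorrEntry]:
    """TSV: chrom, start, end, gene, max_corr."""
    df = pd.read_csv(path, sep="\t",
                     names=["chrom", "start", "end", "gene", "max_corr"],
                     comment="#")
    if df.iloc[0]["chrom"] == "chrom":
        df = df.iloc[1:]
    try:
        return [DHSCorrEntry(GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                             str(r.gene), float(r.max_corr))
                for r in df.itertuples()]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed DHS correlation map ({exc})") from exc


def map_by_ep(mutation: Mutation, ep_pairs: Sequence[EPPair]) -> EPPair | None:
    """Best EP pair whose enhancer contains the mutation, or None.

    Among overlapping enhancers the highest pairing score wins; ties break to
    the smallest interval, then lexicographic gene_id, so assignment never
    depends on input row order.
    """
    hits = [p for p in ep_pairs
            if p.enhancer.chrom == mutation.chrom
            and p.enhancer.contains_pos(mutation.pos)]
    if not hits:
        return None
    return min(hits, key=lambda p: (-p.score, p.enhancer.width, p.gene_id))


def map_by_dhs_corr(mutation: Mutation,
                    dhs_map: Sequence[DHSCorrEntry]) -> DHSCorrEntry | None:
    """Entry with the largest max_corr among distal DHSs containing the site."""
    hits = [e for e in dhs_map
            if e.distal.chrom == mutation.chrom
            and e.distal.contains_pos(mutation.pos)]
    if not hits:
        return None
    return min(hits, key=lambda e: (-e.max_corr, e.gene_id))


def _containing_dhs(mutation: Mutation,
                    dhs_peaks: Sequence[GenomicInterval]) -> GenomicInterval | None:
    hits = [iv for iv in dhs_peaks
            if iv.chrom == mutation.chrom and iv.contains_pos(mutation.pos)]
    if not hits:
        return None
    return min(hits, key=lambda iv: (iv.width, iv.start))


def assign_targets(mutations: Sequence[Mutation],
                   ep_pairs: Sequence[EPPair],
                   dhs_map: Sequence[DHSCorrEntry],
                   dhs_peaks: Sequence[GenomicInterval] = ()) -> list[TargetAssignment]:
    """EP mapping first, DHS-correlation fallback second; unmapped are dropped.

    ``dhs_region`` (used later for motif scanning) is the DHS peak containing
    the mutation; when an EP-mapped mutation has no covering peak, the
    enhancer interval itself serves as the scan region.
    """
    out: list[TargetAssignment] = []
    n_excluded = 0
    for m in mutations:
        peak = _containing_dhs(m, dhs_peaks)
        ep = map_by_ep(m, ep_pairs)
        if ep is not None:
            region = peak if peak is not None else ep.enhancer
            out.append(TargetAssignment(m.key, ep.gene_id, "EP", region))
            continue
        entry = map_by_dhs_corr(m, dhs_map)
        if entry is not None:
            region = peak if peak is not None else entry.distal
            out.append(TargetAssignment(m.key, entry.gene_id, "DHS_CORR", region))
            continue
        n_excluded += 1
    logger.info("target mapping: %d assigned, %d excluded (non-regulatory)",
                len(out), n_excluded)
    if not out:
        raise ValueError("no regulatory mutations: nothing maps to a target gene")
    return out


def load_dhs_peaks(path: str | Path) -> list[GenomicInterval]:
    return read_bed_intervals(path)
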