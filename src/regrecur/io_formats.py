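"""Readers, writers and core containers for cohort mutation tables and genomic tracks.

All interval-like data (BED, bedGraph, enhancer tables) use 0-based half-open
coordinates internally.  Mutation positions are kept 1-based as read from the
mutation table and converted exactly once, at window-query time, so that the
two conventions never mix silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "cancer_type"]
_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class Mutation:
    """A single somatic single-nucleotide substitution call.

    ``pos`` is 1-based.  Only substitutions are modelled: ``ref`` and ``alt``
    are single, distinct bases.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"mutation position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref}) at "
                             f"{self.chrom}:{self.pos}")
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with an optional numeric payload."""

    chrom: str
    start: int
    end: int
    value: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def contains_pos(self, pos_1based: int) -> bool:
        """True if the 1-based position falls inside the interval."""
        return self.start <= pos_1based - 1 < self.end

    @property
    def width(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Per-chromosome sorted, non-overlapping intervals carrying numeric values.

    Used for every continuous annotation the pipeline consumes: DNase/histone
    ChIP signal, conservation scores and replication-timing fractions.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        self.name = name
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            if iv.value is None or not np.isfinite(iv.value):
                raise ValueError(f"track {name!r}: non-finite value in "
                                 f"{iv.chrom}:{iv.start}-{iv.end}")
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"track {name!r}: overlapping intervals "
                        f"{chrom}:{a.start}-{a.end} and {chrom}:{b.start}-{b.end}")
            self._starts[chrom] = np.array([i.start for i in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([i.end for i in ivs], dtype=np.int64)
            self._values[chrom] = np.array([i.value for i in ivs], dtype=float)

    def value_at(self, chrom: str, pos_1based: int) -> float:
        """Track value at a 1-based position; 0.0 where no interval covers it."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0
        p = pos_1based - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i >= 0 and p < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._starts):
            for s, e, v in zip(self._starts[chrom], self._ends[chrom],
                               self._values[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e), float(v)))
        return out

    def __eq__(self, other) -> bool:
        return (isinstance(other, SignalTrack) and self.name == other.name
                and self.intervals() == other.intervals())


class CohortIndex:
    """Deduplicated mutation cohort with per-chromosome sorted position arrays.

    The positional index is what makes windowed recurrence counting O(log n)
    per query; ``positions(chrom)`` returns the sorted 1-based array including
    one entry per mutation *record* (recurrence counts records, not samples).
    """

    def __init__(self, mutations: Sequence[Mutation],
                 chrom_lengths: Mapping[str, int] | None = None):
        seen: set[tuple] = set()
        unique: list[Mutation] = []
        for m in mutations:
            k = (m.chrom, m.pos, m.ref, m.alt, m.sample_id)
            if k not in seen:
                seen.add(k)
                unique.append(m)
        unique.sort(key=lambda m: (m.chrom, m.pos, m.ref, m.alt, m.sample_id))
        self._mutations = unique
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else {}
        self._pos: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[int]] = {}
        for m in unique:
            per_chrom.setdefault(m.chrom, []).append(m.pos)
        for chrom, ps in per_chrom.items():
            self._pos[chrom] = np.array(ps, dtype=np.int64)  # already sorted

    @property
    def mutations(self) -> list[Mutation]:
        return list(self._mutations)

    @property
    def samples(self) -> list[str]:
        return sorted({m.sample_id for m in self._mutations})

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, lo_1based: int, hi_1based: int) -> int:
        """Number of mutation records with lo <= pos <= hi (1-based inclusive)."""
        arr = self.positions(chrom)
        return int(np.searchsorted(arr, hi_1based, side="right")
                   - np.searchsorted(arr, lo_1based, side="left"))

    def chrom_length(self, chrom: str) -> int | None:
        return self.chrom_lengths.get(chrom)

    def __len__(self) -> int:
        return len(self._mutations)

    def __iter__(self):
        return iter(self._mutations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.chrom, m.pos, m.ref, m.alt, m.sample_id, m.cancer_type)
             for m in self._mutations], columns=MUTATION_COLUMNS)


# ---------------------------------------------------------------------------
# mutation tables


def read_mutations(path: str | Path, cancer_type: str = "",
                   chrom_lengths: Mapping[str, int] | None = None,
                   strip_chr_prefix: bool = False) -> CohortIndex:
    """Read a TSV mutation table (header: chrom, pos, ref, alt, sample).

    Exact duplicate records are collapsed.  Rows whose alleles are not single
    A/C/G/T bases (indels, MNVs) are skipped with a logged warning: downstream
    motif scoring is defined for point substitutions only.
    """
    path = Path(path)
    muts: list[Mutation] = []
    n_skipped = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty mutation table")
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        try:
            idx = {name: cols.index(name) for name in ("chrom", "pos", "ref", "alt")}
            idx["sample"] = cols.index("sample") if "sample" in cols else cols.index("sample_id")
        except ValueError as exc:
            raise FormatError(f"{path}: missing required column ({exc})") from exc
        ct_col = cols.index("cancer_type") if "cancer_type" in cols else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(idx.values()):
                raise FormatError(f"{path}:{lineno}: expected >= {len(idx)} columns")
            try:
                pos = int(parts[idx["pos"]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position "
                                  f"{parts[idx['pos']]!r}") from None
            ref = parts[idx["ref"]].upper()
            alt = parts[idx["alt"]].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                n_skipped += 1
                continue
            chrom = parts[idx["chrom"]]
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            ct = parts[ct_col] if ct_col is not None and ct_col < len(parts) else cancer_type
            try:
                muts.append(Mutation(chrom, pos, ref, alt, parts[idx["sample"]], ct))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if n_skipped:
        logger.warning("%s: skipped %d non-SNV rows", path, n_skipped)
    if not muts:
        raise FormatError(f"{path}: no usable mutation records")
    return CohortIndex(muts, chrom_lengths=chrom_lengths)


def write_mutations(cohort: CohortIndex, path: str | Path) -> None:
    cohort.to_frame().rename(columns={"sample_id": "sample"}).to_csv(
        path, sep="\t", index=False)


def read_known_sites(path: str | Path) -> set[tuple[str, int]]:
    """Known-variant positions for germline filtering.

    Accepts a 2-column TSV (chrom, 1-based pos) or a BED-like 3-column file
    (chrom, start, end; every position in the interval is marked known).
    A header line is detected by a non-integer second field and skipped.
    """
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                a = int(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if len(parts) >= 3 and parts[2].lstrip("-").isdigit():
                for p in range(a + 1, int(parts[2]) + 1):  # BED: 0-based half-open
                    sites.add((parts[0], p))
            else:
                sites.add((parts[0], a))
    return sites


def filter_germline(cohort: CohortIndex,
                    known_sites: set[tuple[str, int]]) -> CohortIndex:
    """Remove mutations whose (chrom, pos) matches a known germline variant site.

    Matching is by position only, not allele: any somatic call that coincides
    with a catalogued population variant is treated as suspect.
    """
    kept = [m for m in cohort if (m.chrom, m.pos) not in known_sites]
    removed = len(cohort) - len(kept)
    logger.info("germline filter removed %d of %d records", removed, len(cohort))
    return CohortIndex(kept, chrom_lengths=cohort.chrom_lengths)


# ---------------------------------------------------------------------------
# tracks and intervals


def read_signal_track(path: str | Path, name: str) -> SignalTrack:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                     float(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    try:
        return SignalTrack(name, intervals)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in track.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value!r}\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Plain BED3+ reader; extra columns are ignored."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs 3 columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# networks


def read_edge_list(path: str | Path, directed: bool) -> set[tuple[str, str]]:
    """Two-column TSV edge list.

    Self-loops are dropped and duplicates collapsed.  Undirected edges are
    stored symmetrically (both orientations present in the returned set), so
    neighbourhood queries need no orientation logic.
    """
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: edge list needs 2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                continue
            edges.add((a, b))
            if not directed:
                edges.add((b, a))
    return edges


def write_edge_list(edges: set[tuple[str, str]], path: str | Path,
                    directed: bool = True) -> None:
    written = set()
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            if not directed and (b, a) in written:
                continue
            fh.write(f"{a}\t{b}\n")
            written.add((a, b))


# ---------------------------------------------------------------------------
# expression, GWAS, replication timing


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with a tumor/normal status per sample."""

    values: pd.DataFrame              # genes in index, samples in columns
    status: pd.Series                 # per-sample: "tumor" | "normal"

    def __post_init__(self) -> None:
        st = self.status.reindex(self.values.columns)
        if st.isna().any():
            raise ValueError("every expression sample needs a tumor/normal status")
        bad = set(st.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown sample status values: {sorted(bad)}")
        if (st == "tumor").sum() < 2 or (st == "normal").sum() < 2:
            raise ValueError("need >= 2 tumor and >= 2 normal samples")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        self.status = st

    def group_values(self, gene: str) -> tuple[np.ndarray, np.ndarray] | None:
        if gene not in self.values.index:
            return None
        row = self.values.loc[gene]
        return (row[self.status == "tumor"].to_numpy(float),
                row[self.status == "normal"].to_numpy(float))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """TSV: first row ``gene<TAB>S1...``, second row ``__status__`` with
    tumor/normal per sample, remaining rows one gene each."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "__status__" not in df.index:
        raise FormatError(f"{path}: missing __status__ row")
    status = df.loc["__status__"].astype(str)
    values = df.drop(index="__status__").astype(float)
    return ExpressionMatrix(values=values, status=status)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    out = pd.concat([mat.status.to_frame("__status__").T, mat.values])
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_gwas_catalog(path: str | Path) -> dict[str, np.ndarray]:
    """TSV with chrom/pos columns; returns per-chromosome sorted 1-based arrays."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "chrom" not in cols or "pos" not in cols:
        raise FormatError(f"{path}: GWAS catalog needs chrom and pos columns")
    out: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby(cols["chrom"]):
        out[str(chrom)] = np.sort(grp[cols["pos"]].astype(np.int64).to_numpy())
    return out


REPLICATION_FRACTIONS = ("G1B", "S1", "S4", "G2")


def read_replication_timing(paths: Mapping[str, str | Path]) -> dict[str, SignalTrack]:
    """One bedGraph per cell-cycle fraction (G1B, S1, S4, G2)."""
    missing = [f for f in REPLICATION_FRACTIONS if f not in paths]
    if missing:
        raise FormatError(f"replication timing: missing fractions {missing}")
    return {f: read_signal_track(paths[f], name=f"repli_{f}")
            for f in REPLICATION_FRACTIONS}


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (toy-scale) genome into memory as upper-case sequence strings."""
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | Path,
                       width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
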