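"""TF binding-site gain/loss detection and the three TFBS scores.

A point mutation can create or destroy a transcription-factor binding motif.
Wild-type and mutant sequences are scanned against each PWM; a match's
p-value is the probability, under the background base distribution, that a
random sequence of motif length scores at least as high (the classic exact
null, computed by dynamic programming over the discretised per-position
score distribution).  A motif is *gained* when only the mutant sequence has
a match below the threshold, *lost* when only the wild type does.

Scores exposed per mutation (feature-table columns):

- ``diff_Log_Pval_FIMO`` = (-log10 p_wt) - (-log10 p_mut): positive for
  losses, negative for gains, 0 when no motif changes.
- ``avg_Log_Pval_FIMO``  = mean of the two -log10 p-values for the changed
  motif; with no change, -log10 of the best match p-value anywhere in the
  surrounding DHS region (wild-type sequence).
- ``Gain_or_Loss``       = +1 gain / -1 loss / 0 no change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import FormatError, GenomicInterval, Mutation

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DEFAULT_ALPHA = 1e-4     # match-declaring p-value threshold
SCORE_BIN = 1e-3         # discretisation of log2-ratio scores for the DP null
_MIN_PROB = 1e-10        # floor for zero matrix/background entries


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PWM:
    """Position probability matrix over A/C/G/T with a background model.

    ``matrix`` has one row per motif position; each row sums to 1.  Scores
    are log2 likelihood ratios against ``background`` (uniform by default),
    discretised to ``SCORE_BIN``-wide integer bins so that the null score
    distribution can be computed exactly by convolution.
    """

    def __init__(self, tf_id: str, matrix: np.ndarray,
                 background: Sequence[float] | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4:
            raise ValueError(f"PWM {tf_id}: matrix must be L x 4")
        if matrix.shape[0] < 4:
            raise ValueError(f"PWM {tf_id}: motif length must be >= 4")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {tf_id}: rows must sum to 1")
        self.tf_id = tf_id
        self.matrix = matrix
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"PWM {tf_id}: background must be 4 probabilities")
        self.background = bg
        # integer bin scores; _MIN_PROB floors zeros so degenerate matrices
        # stay finite while keeping non-consensus windows far below any cutoff
        ratio = np.log2(np.maximum(matrix, _MIN_PROB) / np.maximum(bg, _MIN_PROB))
        self.int_scores = np.rint(ratio / SCORE_BIN).astype(np.int64)
        self._null_sf: np.ndarray | None = None
        self._null_offset: int = 0
        self._rc: PWM | None = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        """PWM matching the reverse strand (rows reversed, columns complemented)."""
        if self._rc is None:
            self._rc = PWM(self.tf_id, self.matrix[::-1, ::-1],
                           self.background[::-1])
        return self._rc

    # -- exact null ---------------------------------------------------------

    def _null(self) -> tuple[np.ndarray, int]:
        """Survival function of the window score under the background.

        Returns ``(sf, offset)`` where ``sf[s - offset] = P(S >= s)`` for
        integer bin scores ``s``; built once per PWM by convolving the four
        per-position score atoms weighted by the background.
        """
        if self._null_sf is None:
            dist = {0: 1.0}
            for row in self.int_scores:
                new: dict[int, float] = {}
                for s, q in dist.items():
                    for j in range(4):
                        key = s + int(row[j])
                        new[key] = new.get(key, 0.0) + q * self.background[j]
                dist = new
            lo = min(dist)
            hi = max(dist)
            pmf = np.zeros(hi - lo + 1)
            for s, q in dist.items():
                pmf[s - lo] = q
            self._null_sf = np.cumsum(pmf[::-1])[::-1]
            self._null_offset = lo
        return self._null_sf, self._null_offset

    def score_pvalue(self, int_score: int) -> float:
        sf, offset = self._null()
        i = int_score - offset
        if i < 0:
            return 1.0
        if i >= len(sf):
            return 0.0
        return float(min(sf[i], 1.0))

    def window_score(self, window: str) -> int:
        """Integer bin score of one motif-length window; N scores 0."""
        s = 0
        for i, base in enumerate(window):
            j = ALPHABET.find(base)
            if j >= 0:
                s += int(self.int_scores[i, j])
        return s

    def all_window_scores(self, codes: np.ndarray) -> np.ndarray:
        """Integer scores for every offset of an encoded sequence.

        ``codes`` holds 0..3 for A/C/G/T and 4 for N; N contributes 0.
        """
        L = len(self)
        n = len(codes) - L + 1
        if n < 1:
            raise ValueError("sequence shorter than motif")
        # column 4 = score 0 for N
        padded = np.hstack([self.int_scores,
                            np.zeros((L, 1), dtype=np.int64)])
        total = np.zeros(n, dtype=np.int64)
        for i in range(L):
            total += padded[i, codes[i:i + n]]
        return total


@dataclass(frozen=True)
class MotifMatch:
    tf_id: str
    start: int          # 1-based on the scanned sequence
    strand: str         # "+" or "-"
    score: float        # log2 likelihood ratio
    p_value: float


@dataclass(frozen=True)
class TFBSScores:
    diff_log_pval: float
    avg_log_pval: float
    gain_or_loss: int
    bound_tf: str | None

    def __post_init__(self) -> None:
        if self.gain_or_loss not in (-1, 0, 1):
            raise ValueError(f"gain_or_loss must be in {{-1,0,1}}")
        if self.gain_or_loss == 0 and self.diff_log_pval != 0.0:
            raise ValueError("no motif change implies zero diff_Log_Pval_FIMO")


def scan_best_match(pwm: PWM, sequence: str) -> MotifMatch:
    """Best match of ``pwm`` in ``sequence`` over both strands and all offsets.

    The p-value is the per-window exact null probability of the best score
    (no multiple-testing correction across offsets, matching the convention
    of motif-scanning tools).  Ties prefer the leftmost offset on the
    forward strand.
    """
    sequence = sequence.upper()
    L = len(pwm)
    if len(sequence) < L:
        raise ValueError(f"sequence of length {len(sequence)} shorter than "
                         f"motif {pwm.tf_id} (length {L})")
    codes = encode_sequence(sequence)
    best: tuple[int, int, str, PWM] | None = None  # (int_score, start0, strand, used_pwm)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = mat.all_window_scores(codes)
        off = int(np.argmax(scores))        # argmax takes the leftmost on ties
        s = int(scores[off])
        if best is None or s > best[0]:
            best = (s, off, strand, mat)
    s, off, strand, mat = best
    return MotifMatch(tf_id=pwm.tf_id, start=off + 1, strand=strand,
                      score=s * SCORE_BIN, p_value=mat.score_pvalue(s))


def classify_change(p_wt: float, p_mut: float,
                    alpha: float = DEFAULT_ALPHA) -> str:
    """'gain' if only the mutant matches (p < alpha), 'loss' if only the
    wild type does, 'none' when both or neither pass."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    wt_hit = p_wt < alpha
    mut_hit = p_mut < alpha
    if mut_hit and not wt_hit:
        return "gain"
    if wt_hit and not mut_hit:
        return "loss"
    return "none"


def _neglog10(p: float) -> float:
    return -math.log10(max(p, 1e-300))


def combine_match_pvalues(p_wt_by_tf: Mapping[str, float],
                          p_mut_by_tf: Mapping[str, float],
                          region_best: tuple[str, float],
                          alpha: float = DEFAULT_ALPHA) -> TFBSScores:
    """Fold per-TF wild-type/mutant best p-values into the three TFBS scores.

    Shared by the built-in scanner and the FIMO-table ingestion path, so a
    precomputed external scan reproduces the scores bit for bit.
    """
    changed: list[tuple[float, str, float, float, int]] = []
    for tf in sorted(p_wt_by_tf):
        p_wt, p_mut = p_wt_by_tf[tf], p_mut_by_tf[tf]
        kind = classify_change(p_wt, p_mut, alpha)
        if kind == "none":
            continue
        diff = _neglog10(p_wt) - _neglog10(p_mut)
        changed.append((abs(diff), tf, p_wt, p_mut, +1 if kind == "gain" else -1))
    if changed:
        _, tf, p_wt, p_mut, sign = max(changed, key=lambda t: (t[0], t[1]))
        diff = _neglog10(p_wt) - _neglog10(p_mut)
        avg = (_neglog10(p_wt) + _neglog10(p_mut)) / 2.0
        return TFBSScores(diff_log_pval=diff, avg_log_pval=avg,
                          gain_or_loss=sign, bound_tf=tf)
    tf, p_best = region_best
    return TFBSScores(diff_log_pval=0.0, avg_log_pval=_neglog10(p_best),
                      gain_or_loss=0, bound_tf=tf)


def tfbs_scores(mutation: Mutation, dhs_region: GenomicInterval,
                pwms: Sequence[PWM], genome: Mapping[str, str],
                alpha: float = DEFAULT_ALPHA) -> TFBSScores:
    """Scan every PWM around a mutation and summarise gain/loss.

    For each PWM only windows overlapping the mutated base are compared
    between the wild-type and mutant sequence.  When no motif changes, the
    best match anywhere in the DHS region (wild-type) supplies the average
    score and the bound TF.
    """
    if not pwms:
        raise ValueError("no PWMs loaded")
    seq = genome[mutation.chrom]
    start, end = dhs_region.start, dhs_region.end
    region_wt = seq[start:end].upper()
    off = mutation.pos - 1 - start
    if not 0 <= off < len(region_wt):
        raise ValueError(f"mutation {mutation.key} outside its DHS region")
    if region_wt[off] != mutation.ref and region_wt[off] != "N":
        logger.warning("reference mismatch at %s: genome has %s, call says %s",
                       mutation.key, region_wt[off], mutation.ref)
    region_mut = region_wt[:off] + mutation.alt + region_wt[off + 1:]

    p_wt_by_tf: dict[str, float] = {}
    p_mut_by_tf: dict[str, float] = {}
    region_best: tuple[str, float] | None = None
    for pwm in pwms:
        L = len(pwm)
        if len(region_wt) < L:
            continue
        lo = max(0, off - L + 1)
        hi = min(len(region_wt), off + L)
        p_wt_by_tf[pwm.tf_id] = scan_best_match(pwm, region_wt[lo:hi]).p_value
        p_mut_by_tf[pwm.tf_id] = scan_best_match(pwm, region_mut[lo:hi]).p_value
        whole = scan_best_match(pwm, region_wt)
        if region_best is None or (whole.p_value, pwm.tf_id) < region_best[::-1]:
            region_best = (pwm.tf_id, whole.p_value)
    if region_best is None:
        raise ValueError(f"DHS region of {mutation.key} shorter than every motif")
    return combine_match_pvalues(p_wt_by_tf, p_mut_by_tf, region_best, alpha)


# ---------------------------------------------------------------------------
# motif file formats


def read_meme_motifs(path: str | Path,
                     background: Sequence[float] | None = None) -> list[PWM]:
    """MEME minimal motif format (``MOTIF`` + letter-probability matrix)."""
    pwms: list[PWM] = []
    tf_id = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if tf_id is not None and rows:
                    pwms.append(PWM(tf_id, np.array(rows), background))
                tf_id = line.split()[1]
                rows = []
                in_matrix = False
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line:
                try:
                    vals = [float(v) for v in line.split()[:4]]
                except ValueError:
                    in_matrix = False
                    continue
                rows.append(vals)
    if tf_id is not None and rows:
        pwms.append(PWM(tf_id, np.array(rows), background))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_meme_motifs(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}\n")
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_transfac_motifs(path: str | Path, pseudocount: float = 0.0,
                         background: Sequence[float] | None = None) -> list[PWM]:
    """TRANSFAC count matrices (ID / P0 header / numbered count rows / //)."""
    pwms: list[PWM] = []
    tf_id = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag in ("ID", "AC", "NA") and tf_id is None and len(parts) > 1:
                tf_id = parts[1]
            elif tag == "//":
                if tf_id and rows:
                    counts = np.array(rows) + pseudocount
                    probs = counts / counts.sum(axis=1, keepdims=True)
                    pwms.append(PWM(tf_id, probs, background))
                tf_id, rows = None, []
            elif tag.isdigit() and len(parts) >= 5:
                rows.append([float(v) for v in parts[1:5]])
    if tf_id and rows:
        counts = np.array(rows) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        pwms.append(PWM(tf_id, probs, background))
    if not pwms:
        raise FormatError(f"{path}: no TRANSFAC matrices found")
    return pwms


FIMO_COLUMNS = ["motif_id", "sequence_name", "start", "stop", "strand",
                "score", "p-value"]


def read_fimo_tsv(path: str | Path) -> pd.DataFrame:
    """FIMO-style match table; one row per motif occurrence."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FIMO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: FIMO table missing columns {missing}")
    return df


def fimo_best_pvalues(fimo: pd.DataFrame, sequence_name: str) -> dict[str, float]:
    """Best (smallest) match p-value per motif for one scanned sequence."""
    sub = fimo[fimo["sequence_name"] == sequence_name]
    return sub.groupby("motif_id")["p-value"].min().to_dict()


def tfbs_scores_from_fimo(fimo: pd.DataFrame, wt_name: str, mut_name: str,
                          region_name: str,
                          alpha: float = DEFAULT_ALPHA) -> TFBSScores:
    """TFBS scores from a precomputed FIMO table instead of the built-in scanner.

    ``wt_name``/``mut_name`` are the sequence names of the mutation-centred
    wild-type and mutant scans, ``region_name`` the whole-DHS wild-type scan.
    """
    p_wt = fimo_best_pvalues(fimo, wt_name)
    p_mut = fimo_best_pvalues(fimo, mut_name)
    tfs = sorted(set(p_wt) | set(p_mut))
    p_wt_full = {tf: p_wt.get(tf, 1.0) for tf in tfs}
    p_mut_full = {tf: p_mut.get(tf, 1.0) for tf in tfs}
    region = fimo_best_pvalues(fimo, region_name)
    if not region:
        raise ValueError(f"no FIMO matches for region sequence {region_name!r}")
    tf_best = min(sorted(region), key=lambda tf: (region[tf], tf))
    return combine_match_pvalues(p_wt_full, p_mut_full,
                                 (tf_best, region[tf_best]), alpha)
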