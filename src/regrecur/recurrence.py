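"""Windowed mutation recurrence and its Poisson significance.

A focal mutation's *raw recurrence* x is the number of cohort mutation
records falling in a small window (w = 5/10/20 bp) centred on it.  Its
*significance* compares x with the local background: the per-bp mutation
rate p estimated in a much larger window (B = 1 kbp .. 1 Mbp), under the
null that mutation counts are Poisson with mean w*p.  Sites with
P(X >= x) below a cutoff form the "true" (recurrent) training class; the
"false" class is a seeded random sample of non-recurrent sites three times
as large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import poisson

from .io_formats import CohortIndex, Mutation

logger = logging.getLogger(__name__)

RAW_WINDOWS = (5, 10, 20)
BACKGROUND_WINDOWS = (1_000, 10_000, 100_000, 1_000_000)
DEFAULT_PVALUE_CUTOFF = 5e-6


def window_bounds(pos: int, w: int) -> tuple[int, int]:
    """1-based inclusive bounds of the w-bp window centred on pos.

    Even windows are left-heavy: the window is [pos - w//2, pos + (w+1)//2 - 1],
    which always contains pos and has exact width w.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    return pos - w // 2, pos + (w + 1) // 2 - 1


@dataclass(frozen=True)
class RecurrenceRecord:
    mutation: Mutation
    w: int
    x: int              # raw recurrence count (includes the focal record)
    B: int              # nominal background window (bp)
    effective_B: int    # after clipping at chromosome ends
    n_bg: int
    p: float            # background rate per bp
    lam: float          # Poisson mean w*p
    p_value: float


def count_raw_recurrence(focal: Mutation, cohort: CohortIndex, w: int) -> int:
    """Cohort mutation records within the w-bp window centred on the focal site.

    Counting is position-based and allele-agnostic, over records from all
    samples; the focal record itself counts when present in the cohort.
    """
    lo, hi = window_bounds(focal.pos, w)
    return cohort.count_in(focal.chrom, max(lo, 1), hi)


def background_rate(focal: Mutation, cohort: CohortIndex,
                    B: int, w: int = 1,
                    exclude_core: bool = False) -> tuple[int, float, int]:
    """Local per-bp mutation rate in the B-bp window centred on the focal site.

    Returns ``(n_bg, p, effective_B)``.  The window is clipped to
    [1, chromosome length] and the rate renormalised by the clipped width.
    With ``exclude_core`` the recurrence window's own records and width are
    removed from the estimate.
    """
    if B <= w:
        raise ValueError(f"background window B={B} must exceed recurrence window w={w}")
    lo, hi = window_bounds(focal.pos, B)
    lo = max(lo, 1)
    clen = cohort.chrom_length(focal.chrom)
    if clen is not None:
        hi = min(hi, clen)
    effective_B = hi - lo + 1
    n_bg = cohort.count_in(focal.chrom, lo, hi)
    width = effective_B
    if exclude_core:
        n_bg -= count_raw_recurrence(focal, cohort, w)
        width -= w
        n_bg = max(n_bg, 0)
    p = n_bg / width if width > 0 else 0.0
    return n_bg, p, effective_B


def recurrence_pvalue(x: int, w: int, p: float) -> float:
    """Upper-tail Poisson probability P(X >= x) with X ~ Poisson(w*p).

    For x <= lambda the library survival function is used.  Deep in the
    upper tail (x > lambda) it is replaced by direct summation of the tail
    series e^-lam * lam^x/x! * (1 + lam/(x+1) + ...), whose positive
    decreasing terms keep full relative precision down to the double
    underflow limit (~1e-300), where the incomplete-gamma route loses
    several digits.
    """
    if x < 0 or w < 1 or p < 0:
        raise ValueError(f"invalid inputs x={x}, w={w}, p={p}")
    if x == 0:
        return 1.0
    lam = w * p
    if lam == 0.0:
        return 0.0
    if x <= lam:
        return float(poisson.sf(x - 1, lam))
    import math

    log_t = -lam + x * math.log(lam) - math.lgamma(x + 1)
    if log_t < -745.0:          # below exp underflow
        return 0.0
    t = math.exp(log_t)
    total = t
    j = 1
    while True:
        t *= lam / (x + j)
        total += t
        if t <= total * 1e-18:
            break
        j += 1
    return min(total, 1.0)


def score_cohort(focal_set: CohortIndex, cohort: CohortIndex,
                 w: int, B: int,
                 exclude_core_from_background: bool = False) -> list[RecurrenceRecord]:
    """One RecurrenceRecord per focal mutation, deterministic in the inputs.

    ``focal_set`` is the candidate cohort (e.g. one cancer type); ``cohort``
    supplies both the recurrence counts and the background rate (typically
    the pan-cancer superset).
    """
    records = []
    for m in focal_set:
        x = count_raw_recurrence(m, cohort, w)
        n_bg, p, eff_B = background_rate(m, cohort, B, w=w,
                                         exclude_core=exclude_core_from_background)
        lam = w * p
        records.append(RecurrenceRecord(
            mutation=m, w=w, x=x, B=B, effective_B=eff_B, n_bg=n_bg, p=p,
            lam=lam, p_value=recurrence_pvalue(x, w, p)))
    return records


@dataclass(frozen=True)
class LabeledSet:
    """True/false training mutation keys with full sampling provenance."""

    true_ids: tuple[str, ...]
    false_ids: tuple[str, ...]
    model: Literal["raw", "significance"]
    params: dict
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.true_ids) & set(self.false_ids)
        if overlap:
            raise ValueError(f"true/false sets overlap: {sorted(overlap)[:5]}")


def build_labeled_set(records: Sequence[RecurrenceRecord],
                      model: Literal["raw", "significance"],
                      threshold: float,
                      ratio: int = 3,
                      seed: int = 0) -> LabeledSet:
    """Construct the recurrent (true) and non-recurrent (false) training sets.

    raw model: true iff x >= threshold.  significance model: true iff
    p_value < threshold.  The false set is a uniform random sample, without
    replacement, of ``ratio`` times the true-set size, drawn from sites with
    raw count exactly 1 whose p-value is above the cutoff.

    The same substitution carried by several samples yields several records
    with identical position-based statistics; labelling is per *site*, so
    such records are collapsed to one before thresholding.
    """
    seen: set[str] = set()
    deduped = []
    for r in records:
        if r.mutation.key not in seen:
            seen.add(r.mutation.key)
            deduped.append(r)
    records = deduped
    if model == "raw":
        true_ids = [r.mutation.key for r in records if r.x >= threshold]
    elif model == "significance":
        true_ids = [r.mutation.key for r in records if r.p_value < threshold]
    else:
        raise ValueError(f"unknown model {model!r}")
    if not true_ids:
        raise ValueError(f"no mutation passes the {model} threshold {threshold}")
    if model == "significance":
        nonrec = [r for r in records if r.x == 1 and r.p_value >= threshold]
    else:
        nonrec = [r for r in records if r.x == 1]
    want = ratio * len(true_ids)
    rng = np.random.default_rng(seed)
    if len(nonrec) < want:
        logger.warning("only %d non-recurrent mutations available for a false set "
                       "of %d; using all", len(nonrec), want)
        false_records = list(nonrec)
    else:
        pick = rng.choice(len(nonrec), size=want, replace=False)
        false_records = [nonrec[i] for i in sorted(pick)]
    params = ({"w": records[0].w, "threshold": threshold} if model == "raw" else
              {"w": records[0].w, "B": records[0].B, "cutoff": threshold})
    return LabeledSet(true_ids=tuple(true_ids),
                      false_ids=tuple(r.mutation.key for r in false_records),
                      model=model, params=params, seed=seed)
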