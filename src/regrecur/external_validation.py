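"""Revalidation of selected mutations against an added, independent cohort.

The idea: if a selection method (raw recurrence, recurrence significance, or
forest vote proportion) truly ranks driver-like sites first, then adding new
cancer samples should *reveal* recurrence at the selected sites — at least
one new-cohort mutation should land inside a small window around them.  The
number of revealed selections, at equal selection size k, compares the
methods on ground that none of them saw during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .io_formats import CohortIndex
from .recurrence import RecurrenceRecord, window_bounds
from .classifier_eval import VoteRecord

Method = Literal["raw", "significance", "forest_votes"]
CHECK_WINDOWS = (10, 100)


@dataclass(frozen=True)
class SelectionSet:
    method: Method
    k: int
    keys: tuple[str, ...]          # ordered best-first
    positions: tuple[tuple[str, int], ...]   # (chrom, pos) per key

    def __post_init__(self) -> None:
        if len(self.keys) != self.k or len(set(self.keys)) != self.k:
            raise ValueError("selection must hold exactly k unique keys")


def _dedupe_records(records: Sequence[RecurrenceRecord]) -> list[RecurrenceRecord]:
    seen: set[str] = set()
    out = []
    for r in records:
        if r.mutation.key not in seen:
            seen.add(r.mutation.key)
            out.append(r)
    return out


def select_top(records: Sequence[RecurrenceRecord] | None,
               votes: Sequence[VoteRecord] | None,
               method: Method, k: int,
               positions: Mapping[str, tuple[str, int]] | None = None) -> SelectionSet:
    """Top-k mutations under one selection method.

    raw: highest recurrence count first; significance: smallest p-value
    first; forest_votes: highest vote proportion first.  Ties always break
    by (chrom, pos) so selections are stable across runs.
    """
    if method in ("raw", "significance"):
        if records is None:
            raise ValueError(f"method {method!r} needs recurrence records")
        recs = _dedupe_records(records)
        if k > len(recs):
            raise ValueError(f"k={k} exceeds {len(recs)} scored mutations")
        if method == "raw":
            key = lambda r: (-r.x, r.mutation.chrom, r.mutation.pos)
        else:
            key = lambda r: (r.p_value, r.mutation.chrom, r.mutation.pos)
        top = sorted(recs, key=key)[:k]
        return SelectionSet(method, k, tuple(r.mutation.key for r in top),
                            tuple((r.mutation.chrom, r.mutation.pos) for r in top))
    if method == "forest_votes":
        if votes is None or positions is None:
            raise ValueError("forest_votes needs vote records and a key->position map")
        uniq: dict[str, VoteRecord] = {}
        for v in votes:
            if v.mutation_key not in uniq or v.vote > uniq[v.mutation_key].vote:
                uniq[v.mutation_key] = v
        if k > len(uniq):
            raise ValueError(f"k={k} exceeds {len(uniq)} voted mutations")
        top = sorted(uniq.values(),
                     key=lambda v: (-v.vote,) + positions[v.mutation_key])[:k]
        return SelectionSet(method, k, tuple(v.mutation_key for v in top),
                            tuple(positions[v.mutation_key] for v in top))
    raise ValueError(f"unknown selection method {method!r}")


@dataclass(frozen=True)
class ValidationRow:
    method: Method
    k: int
    check_window: int
    revealed: int                  # selections with >= 1 new-cohort mutation nearby

    def __post_init__(self) -> None:
        if self.revealed > self.k:
            raise ValueError("revealed count cannot exceed k")


def recheck_recurrence(selection: SelectionSet, new_cohort: CohortIndex,
                       check_window: int,
                       training_samples: Sequence[str] = ()) -> ValidationRow:
    """Count selected sites revealed as recurrent by the added cohort.

    A selection is revealed when at least one new-cohort mutation (any
    allele, any sample) lies inside the check window centred on it.  The new
    cohort must be disjoint from the training samples — overlap would leak
    the training recurrence back into the validation.
    """
    overlap = set(training_samples) & set(new_cohort.samples)
    if overlap:
        raise ValueError(f"validation cohort shares samples with training: "
                         f"{sorted(overlap)[:5]}")
    revealed = 0
    for chrom, pos in selection.positions:
        lo, hi = window_bounds(pos, check_window)
        if new_cohort.count_in(chrom, max(lo, 1), hi) >= 1:
            revealed += 1
    return ValidationRow(selection.method, selection.k, check_window, revealed)


def validation_report(selections: Sequence[SelectionSet],
                      new_cohort: CohortIndex,
                      check_windows: Sequence[int] = CHECK_WINDOWS,
                      training_samples: Sequence[str] = ()) -> list[ValidationRow]:
    return [recheck_recurrence(sel, new_cohort, w, training_samples)
            for sel in selections for w in check_windows]
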