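"""Align features, weak labels and manual labels into rows; balance by quality.

A 1-s feature window takes a (weak or manual) label only when it is fully
contained in a single segment of that kind.  Windows without a manual label
are dropped from the experimental dataset: scoring needs ground truth.

Balancing partitions rows by *weak* label (manual labels do not exist in
deployment and ride along solely for scoring), sorts each class by the
heuristic's quality probability (descending) and keeps at most
``floor(cap_factor * n_min)`` rows per class, where ``n_min`` is the size of
the smallest class and ``cap_factor`` defaults to 1.3 — classic
undersampling at ``cap_factor = 1.0``, except the lowest-quality rows are
discarded first instead of random ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from stepfuse.features import Window, extract_all
from stepfuse.types import (
    ACTIVITY_PRIORITY,
    Activity,
    GroundTruthSegment,
    LabeledRow,
    WeakLabelSegment,
)

CAP_FACTOR = 1.3


class BalanceError(ValueError):
    """Raised when a weak-label class required for balancing is empty."""


@dataclass(frozen=True)
class BalanceSpec:
    """Retention counts of the quality-aware undersampler.

    ``n_i = min(|C_i|, floor(cap_factor * n_min))`` per weak-label class.
    """

    counts: dict[Activity, int]
    cap_factor: float = CAP_FACTOR

    @property
    def n_min(self) -> int:
        return min(self.counts.values())

    @property
    def cap(self) -> int:
        return math.floor(self.cap_factor * self.n_min)

    @property
    def retained(self) -> dict[Activity, int]:
        return {act: min(n, self.cap) for act, n in self.counts.items()}

    @classmethod
    def from_counts(cls, counts: dict[Activity, int], cap_factor: float = CAP_FACTOR) -> "BalanceSpec":
        empty = [a.value for a in ACTIVITY_PRIORITY if counts.get(a, 0) == 0]
        if empty:
            raise BalanceError(f"cannot balance: empty weak-label class(es) {empty}")
        return cls(dict(counts), cap_factor)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-class sample counts of a labeled dataset (manual labels)."""

    counts: dict[Activity, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def hours(self, window_s: float = 1.0) -> dict[Activity, float]:
        return {a: n * window_s / 3600.0 for a, n in self.counts.items()}


def summarize(rows: Sequence[LabeledRow]) -> DatasetSummary:
    counts = {a: 0 for a in ACTIVITY_PRIORITY}
    for r in rows:
        if r.label is not None:
            counts[r.label] += 1
    return DatasetSummary(counts)


def _containing(start: float, end: float, segments, lo_attr="start", hi_attr="end"):
    """The single segment fully containing [start, end), or None."""
    for seg in segments:
        if getattr(seg, lo_attr) <= start + 1e-9 and end <= getattr(seg, hi_attr) + 1e-9:
            return seg
    return None


def align(
    windows: Sequence[Window],
    features: np.ndarray,
    weak: Sequence[WeakLabelSegment],
    truth: Sequence[GroundTruthSegment],
) -> list[LabeledRow]:
    """Join windows+features with weak and manual labels by full containment.

    A window straddling a weak-segment boundary gets no weak label
    (MISSING); a window not fully inside any manual segment is dropped.
    """
    if len(windows) != len(features):
        raise ValueError("windows and feature rows must correspond one-to-one")
    truth_sorted = sorted(truth, key=lambda s: s.start)
    weak_labeled = [s for s in weak if not s.is_missing]
    rows = []
    for win, feat in zip(windows, features):
        ts = _containing(win.start, win.end, truth_sorted)
        if ts is None:
            continue
        ws = _containing(win.start, win.end, weak_labeled)
        if ws is None:
            rows.append(LabeledRow(ts.activity, None, None, feat, win.start))
        else:
            rows.append(LabeledRow(ts.activity, ws.activity, ws.probability, feat, win.start))
    return rows


def balance(rows: Sequence[LabeledRow], cap_factor: float = CAP_FACTOR) -> list[LabeledRow]:
    """Quality-aware undersampling over weak-label classes.

    All rows must carry a weak label; every class must be non-empty.  Within
    each class rows are ranked by probability descending (ties broken by
    earlier window start) and truncated to the :class:`BalanceSpec` count.
    Output preserves class-priority order then rank order, so the operation
    is deterministic and idempotent.
    """
    for r in rows:
        if r.weak_label is None:
            raise ValueError("balance requires every row to carry a weak label")
    groups: dict[Activity, list[LabeledRow]] = {a: [] for a in ACTIVITY_PRIORITY}
    for r in rows:
        groups[r.weak_label].append(r)
    spec = BalanceSpec.from_counts({a: len(g) for a, g in groups.items()}, cap_factor)
    retained = spec.retained
    out: list[LabeledRow] = []
    for act in ACTIVITY_PRIORITY:
        ranked = sorted(groups[act], key=lambda r: (-r.probability, r.window_start))
        out.extend(ranked[: retained[act]])
    return out
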