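"""Shared domain types for sensor streams, segments and labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

NOMINAL_RATE_HZ = 30.0
NOMINAL_DT = 1.0 / NOMINAL_RATE_HZ


class Activity(str, Enum):
    """The five-class activity taxonomy."""

    SITTING = "SITTING"
    WALKING = "WALKING"
    RUNNING = "RUNNING"
    CYCLING = "CYCLING"
    TRANSPORTATION = "TRANSPORTATION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Deterministic priority used to break ties at argmax: earlier wins on equal
#: probability; a later activity wins only on strictly greater probability.
ACTIVITY_PRIORITY: tuple[Activity, ...] = (
    Activity.SITTING,
    Activity.WALKING,
    Activity.RUNNING,
    Activity.CYCLING,
    Activity.TRANSPORTATION,
)

#: Sentinel tags used in files and logs alongside activity names.
MISSING = "MISSING"
UNLABELED = "UNLABELED"
ERROR_TAG = "ERROR"
STOP_TAG = "STOP"


class FormatError(ValueError):
    """Raised when an input file does not follow the declared schema."""


class IntegrityError(ValueError):
    """Raised when parsed values violate a domain invariant."""


@dataclass(frozen=True)
class AccelStream:
    """Uniformly sampled tri-axial acceleration, nominally 30 Hz, units of g.

    All four channels are equal-length 1-D arrays; timestamps are seconds
    from recording start and strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if not (len(t) == len(self.x) == len(self.y) == len(self.z)):
            raise IntegrityError("accelerometer channels have unequal lengths")
        for name in ("t", "x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.isnan(arr).any():
                raise IntegrityError(f"NaN in accelerometer channel {name!r}")
            object.__setattr__(self, name, arr)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise IntegrityError("accelerometer timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass(frozen=True)
class StepEventSeries:
    """Timestamps (seconds) of detected steps, strictly increasing."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if np.isnan(t).any():
            raise IntegrityError("NaN in step timestamps")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise IntegrityError("step timestamps are not strictly increasing")
        object.__setattr__(self, "t", t)

    def __len__(self) -> int:
        return len(self.t)

    def count_in(self, start: float, end: float) -> int:
        """Number of step events with timestamp in [start, end)."""
        return int(np.searchsorted(self.t, end, side="left") - np.searchsorted(self.t, start, side="left"))


@dataclass(frozen=True)
class GpsFix:
    """A time-stamped position with its accuracy estimate (meters, lower = better)."""

    t: float
    lat: float
    lon: float
    accuracy: float

    def __post_init__(self) -> None:
        for name in ("t", "lat", "lon", "accuracy"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise IntegrityError(f"NaN/None in GPS field {name!r}")
        if not -90.0 <= self.lat <= 90.0:
            raise IntegrityError(f"latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise IntegrityError(f"longitude {self.lon} out of [-180, 180]")
        if not self.accuracy > 0:
            raise IntegrityError(f"GPS accuracy must be > 0, got {self.accuracy}")


@dataclass(frozen=True)
class GroundTruthSegment:
    """A manually annotated half-open interval [start, end) with its activity."""

    start: float
    end: float
    activity: Activity

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise IntegrityError(f"segment end {self.end} must exceed start {self.start}")
        if not isinstance(self.activity, Activity):
            object.__setattr__(self, "activity", Activity(self.activity))

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WeakLabelSegment:
    """A heuristic-labeled interval with a quality probability.

    ``activity`` is ``None`` when the heuristic abstains (a MISSING label);
    ``probability`` is present iff a label was assigned.
    """

    start: float
    end: float
    activity: Optional[Activity]
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise IntegrityError(f"segment end {self.end} must exceed start {self.start}")
        if self.activity is not None and not isinstance(self.activity, Activity):
            object.__setattr__(self, "activity", Activity(self.activity))
        if (self.activity is None) != (self.probability is None):
            raise IntegrityError("probability must be present iff a label is assigned")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise IntegrityError(f"probability {self.probability} out of [0, 1]")

    @property
    def is_missing(self) -> bool:
        return self.activity is None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledRow:
    """One dataset row: manual label, weak label, quality and 18 features."""

    label: Optional[Activity]  # None means UNLABELED
    weak_label: Optional[Activity]  # None means MISSING
    probability: Optional[float]
    features: np.ndarray
    window_start: float

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        object.__setattr__(self, "features", f)
        if (self.weak_label is None) != (self.probability is None):
            raise IntegrityError("probability present iff weak_label assigned")


def overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Length of the intersection of two half-open intervals."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def check_disjoint(segments: Sequence) -> None:
    """Assert that time-ordered segments are pairwise disjoint."""
    for prev, cur in zip(segments, segments[1:]):
        if cur.start < prev.end - 1e-9:
            raise IntegrityError(
                f"segments overlap: [{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
            )
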