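"""Weak-label heuristic: cadence windows, merging, GPS speed and fuzzy fusion.

Pipeline, applied to one recording:

1. :func:`compute_spm_windows` — step cadence sampled on 1-minute windows;
2. :func:`merge_windows` — adjacent windows merged while they stay within
   10 steps/min of the running segment mean, so prolonged walking (or
   prolonged near-zero cadence) collapses into one segment;
3. :func:`segment_speed` — duration-weighted mean of consecutive-fix GPS
   speeds within each merged segment, with a weight ``w_gps`` derived from
   fix accuracy;
4. :func:`assign_weak_label` — fuzzy cadence memberships (Gaussian for
   walking/running, trapezoid for sedentary) and trapezoidal speed
   memberships are fused per activity as ``(p_step + w*p_gps) / (1 + w)``;
   the argmax wins if it clears the decision threshold, otherwise the
   segment is left MISSING;
5. :func:`smooth_labels` — strictly consecutive cycling/transportation
   pairs are rewritten to transportation (GPS speed alone cannot separate
   them reliably, e.g. driving in traffic);
6. :func:`label_quality_report` — per-day precision and missing rate
   against a manually annotated ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from stepfuse.types import (
    ACTIVITY_PRIORITY,
    Activity,
    GpsFix,
    GroundTruthSegment,
    StepEventSeries,
    WeakLabelSegment,
    overlap,
)

EARTH_RADIUS_M = 6_371_000.0

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class SpmWindow:
    """A cadence sample: steps/min over a (nominally 60-s) window."""

    start: float
    end: float
    spm: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class MergedSegment:
    """A run of cadence-compatible windows with its GPS speed estimate."""

    start: float
    end: float
    spm: float
    speed: Optional[float] = None  # m/s; None when < 2 usable fixes
    w_gps: float = 0.0

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Trapezoid:
    """Trapezoidal membership with non-decreasing vertices (a, b, c, d).

    0 below ``a``, linear rise on [a, b], plateau 1 on [b, c], linear fall on
    [c, d], 0 above ``d``.  ``c = d = inf`` gives a right-open shoulder.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"trapezoid vertices must be non-decreasing: {self}")

    def __call__(self, x: float) -> float:
        if x < self.a or x > self.d:
            return 0.0
        if self.b <= x <= self.c:
            return 1.0
        if x < self.b:  # rising edge; a == b never reaches here (plateau caught above)
            return (x - self.a) / (self.b - self.a)
        if math.isinf(self.d):
            return 1.0
        return (self.d - x) / (self.d - self.c)


@dataclass(frozen=True)
class Gaussian:
    """Gaussian membership normalized to peak 1 at the mean."""

    mean: float
    sd: float

    def __call__(self, x: float) -> float:
        return math.exp(-0.5 * ((x - self.mean) / self.sd) ** 2)


@dataclass
class FuzzyConfig:
    """Membership models and fusion constants of the labeling heuristic.

    The cadence bands (walking 90-110, running 160-180 steps/min) and the
    speed anchors (~1.4 walking, 3-4 running, 4-8 cycling, >=20 m/s
    transportation) fix the membership centers; standard deviations and
    trapezoid vertices are tool defaults chosen so memberships are ~1 across
    each band and fall below the decision threshold at the ambiguous
    cadences 50 and 130 steps/min.
    """

    walking_cadence: Gaussian = field(default_factory=lambda: Gaussian(100.0, 12.0))
    running_cadence: Gaussian = field(default_factory=lambda: Gaussian(170.0, 12.0))
    sedentary_cadence: Trapezoid = field(default_factory=lambda: Trapezoid(0.0, 0.0, 15.0, 40.0))
    speed: dict[Activity, Trapezoid] = field(
        default_factory=lambda: {
            Activity.SITTING: Trapezoid(0.0, 0.0, 0.2, 0.7),
            Activity.WALKING: Trapezoid(0.6, 1.0, 1.8, 2.6),
            Activity.RUNNING: Trapezoid(2.4, 3.0, 4.0, 5.0),
            Activity.CYCLING: Trapezoid(3.5, 4.0, 8.0, 12.0),
            Activity.TRANSPORTATION: Trapezoid(8.0, 20.0, math.inf, math.inf),
        }
    )
    #: reference GPS accuracy (m): fixes at least this accurate get full weight
    a0: float = 10.0
    #: minimum GPS weight for the GPS-only classes (cycling, transportation)
    w_min: float = 0.3
    #: decision threshold: below it no weak label is emitted
    theta: float = 0.5
    #: merge tolerance in steps/min (strict <)
    merge_spm: float = 10.0

    def to_dict(self) -> dict:
        return {
            "walking_cadence": {"mean": self.walking_cadence.mean, "sd": self.walking_cadence.sd},
            "running_cadence": {"mean": self.running_cadence.mean, "sd": self.running_cadence.sd},
            "sedentary_cadence": [
                self.sedentary_cadence.a,
                self.sedentary_cadence.b,
                self.sedentary_cadence.c,
                self.sedentary_cadence.d,
            ],
            "speed": {
                act.value: [tz.a, tz.b, tz.c, tz.d] for act, tz in self.speed.items()
            },
            "a0": self.a0,
            "w_min": self.w_min,
            "theta": self.theta,
            "merge_spm": self.merge_spm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyConfig":
        kwargs: dict = {}
        if "walking_cadence" in d:
            kwargs["walking_cadence"] = Gaussian(**d["walking_cadence"])
        if "running_cadence" in d:
            kwargs["running_cadence"] = Gaussian(**d["running_cadence"])
        if "sedentary_cadence" in d:
            kwargs["sedentary_cadence"] = Trapezoid(*d["sedentary_cadence"])
        if "speed" in d:
            kwargs["speed"] = {
                Activity(k): Trapezoid(*(math.inf if v == "inf" else v for v in verts))
                for k, verts in d["speed"].items()
            }
        for key in ("a0", "w_min", "theta", "merge_spm"):
            if key in d:
                kwargs[key] = float(d[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Cadence windowing and merging
# ---------------------------------------------------------------------------


def compute_spm_windows(
    steps: StepEventSeries, span: tuple[float, float], window: float = 60.0
) -> list[SpmWindow]:
    """Sample the steps/min rate on 1-minute windows tiling ``span``.

    The trailing partial window is kept (scaled to a per-minute rate) when at
    least half a window long, otherwise discarded.
    """
    start, end = span
    if end - start < window:
        raise ValueError(f"span shorter than one window: {end - start} s")
    out = []
    t = start
    while t + window <= end + 1e-9:
        n = steps.count_in(t, t + window)
        out.append(SpmWindow(t, t + window, n * 60.0 / window))
        t += window
    rem = end - t
    if rem >= window / 2.0:
        n = steps.count_in(t, end)
        out.append(SpmWindow(t, end, n * 60.0 / rem))
    return out


def merge_windows(windows: Sequence[SpmWindow], merge_spm: float = 10.0) -> list[MergedSegment]:
    """Greedy left-to-right merge of cadence-compatible adjacent windows.

    A window joins the current segment when its rate is strictly within
    ``merge_spm`` of the segment's duration-weighted mean (comparing to the
    running mean rather than the last raw window stabilizes long sessions).
    """
    out: list[MergedSegment] = []
    cur_start = cur_end = cur_weight = cur_sum = None
    for w in windows:
        if cur_start is None:
            cur_start, cur_end, cur_weight, cur_sum = w.start, w.end, w.duration, w.spm * w.duration
            continue
        mean = cur_sum / cur_weight
        contiguous = math.isclose(w.start, cur_end, abs_tol=1e-6)
        if contiguous and abs(w.spm - mean) < merge_spm:
            cur_end = w.end
            cur_weight += w.duration
            cur_sum += w.spm * w.duration
        else:
            out.append(MergedSegment(cur_start, cur_end, cur_sum / cur_weight))
            cur_start, cur_end, cur_weight, cur_sum = w.start, w.end, w.duration, w.spm * w.duration
    if cur_start is not None:
        out.append(MergedSegment(cur_start, cur_end, cur_sum / cur_weight))
    return out


# ---------------------------------------------------------------------------
# GPS speed
# ---------------------------------------------------------------------------


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters (Earth radius 6,371,000 m)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def estimate_speed(a: GpsFix, b: GpsFix) -> float:
    """Speed between two consecutive fixes: great-circle distance over Δt."""
    dt = b.t - a.t
    if dt <= 0:
        raise ValueError(f"non-positive time delta between fixes: {dt}")
    return haversine_m(a.lat, a.lon, b.lat, b.lon) / dt


def segment_speed(
    segment: MergedSegment, fixes: Sequence[GpsFix], cfg: FuzzyConfig
) -> tuple[Optional[float], float]:
    """Δt-weighted mean speed over consecutive fixes inside the segment.

    Returns ``(speed, w_gps)`` where ``w_gps`` is the mean over used fix
    pairs of ``min(1, a0 / max(acc_i, acc_j))`` — fixes at least as accurate
    as the reference ``a0`` contribute full weight.  With fewer than two
    fixes in the interval, ``(None, 0.0)``.
    """
    inside = [f for f in fixes if segment.start <= f.t < segment.end]
    if len(inside) < 2:
        return None, 0.0
    speeds, dts, weights = [], [], []
    for f1, f2 in zip(inside, inside[1:]):
        speeds.append(estimate_speed(f1, f2))
        dts.append(f2.t - f1.t)
        weights.append(min(1.0, cfg.a0 / max(f1.accuracy, f2.accuracy)))
    speed = float(np.average(speeds, weights=dts))
    return speed, float(np.mean(weights))


# ---------------------------------------------------------------------------
# Fuzzy memberships and fusion
# ---------------------------------------------------------------------------


def step_membership(spm: float, cfg: FuzzyConfig) -> dict[Activity, float]:
    """Cadence memberships: Gaussian walking/running, trapezoidal sedentary."""
    if spm < 0:
        raise ValueError("steps/min must be >= 0")
    return {
        Activity.SITTING: cfg.sedentary_cadence(spm),
        Activity.WALKING: cfg.walking_cadence(spm),
        Activity.RUNNING: cfg.running_cadence(spm),
    }


def speed_membership(v: float, cfg: FuzzyConfig) -> dict[Activity, float]:
    """Trapezoidal speed membership for every activity."""
    if v < 0:
        raise ValueError("speed must be >= 0")
    return {act: tz(v) for act, tz in cfg.speed.items()}


def combine_probability(p_step: float, p_gps: float, w_gps: float) -> float:
    """Accuracy-weighted fusion of the two source probabilities.

    ``(p_step + w_gps * p_gps) / (1 + w_gps)`` — reduces to ``p_step`` when
    the GPS carries no weight and is a weighted mean otherwise.
    """
    if not 0.0 <= p_step <= 1.0:
        raise ValueError(f"p_step {p_step} out of [0, 1]")
    if not 0.0 <= p_gps <= 1.0:
        raise ValueError(f"p_gps {p_gps} out of [0, 1]")
    if w_gps < 0:
        raise ValueError(f"w_gps {w_gps} must be >= 0")
    return (p_step + w_gps * p_gps) / (1.0 + w_gps)


def assign_weak_label(segment: MergedSegment, cfg: FuzzyConfig) -> WeakLabelSegment:
    """Score every activity for a merged segment and emit the winning label.

    Sitting/walking/running fuse cadence and speed memberships; cycling and
    transportation are detectable from GPS speed alone and become eligible
    only when the GPS weight reaches ``w_min``.  If the best probability is
    below ``theta`` the segment stays MISSING.
    """
    p_step = step_membership(segment.spm, cfg)
    has_speed = segment.speed is not None
    p_gps = speed_membership(segment.speed, cfg) if has_speed else None
    w = segment.w_gps if has_speed else 0.0

    scores: dict[Activity, float] = {}
    for act in (Activity.SITTING, Activity.WALKING, Activity.RUNNING):
        gps_part = p_gps[act] if has_speed else 0.0
        scores[act] = combine_probability(p_step[act], gps_part, w)
    if has_speed and w >= cfg.w_min:
        scores[Activity.CYCLING] = p_gps[Activity.CYCLING]
        scores[Activity.TRANSPORTATION] = p_gps[Activity.TRANSPORTATION]

    best: Optional[Activity] = None
    best_p = -1.0
    for act in ACTIVITY_PRIORITY:  # earlier in priority wins ties
        if act in scores and scores[act] > best_p:
            best, best_p = act, scores[act]
    if best is None or best_p < cfg.theta:
        return WeakLabelSegment(segment.start, segment.end, None, None)
    return WeakLabelSegment(segment.start, segment.end, best, min(1.0, best_p))


def smooth_labels(segments: Sequence[WeakLabelSegment]) -> list[WeakLabelSegment]:
    """Rewrite strictly consecutive cycling/transportation pairs as transportation.

    Left-to-right passes repeated to fixpoint; MISSING gaps are not bridged.
    """
    segs = list(segments)
    changed = True
    while changed:
        changed = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            pair = {a.activity, b.activity}
            if pair == {Activity.CYCLING, Activity.TRANSPORTATION}:
                for j in (i, i + 1):
                    if segs[j].activity is Activity.CYCLING:
                        segs[j] = WeakLabelSegment(
                            segs[j].start, segs[j].end, Activity.TRANSPORTATION, segs[j].probability
                        )
                        changed = True
    return segs


def weak_label_trace(
    steps: StepEventSeries,
    fixes: Sequence[GpsFix],
    span: tuple[float, float],
    cfg: Optional[FuzzyConfig] = None,
) -> list[WeakLabelSegment]:
    """Full heuristic: cadence windows → merge → speed → fuzzy label → smooth."""
    cfg = cfg or FuzzyConfig()
    windows = compute_spm_windows(steps, span)
    merged = merge_windows(windows, cfg.merge_spm)
    labeled = []
    for seg in merged:
        speed, w = segment_speed(seg, fixes, cfg)
        seg = MergedSegment(seg.start, seg.end, seg.spm, speed, w)
        labeled.append(assign_weak_label(seg, cfg))
    return smooth_labels(labeled)


# ---------------------------------------------------------------------------
# Quality reporting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DayQuality:
    """Heuristic quality for one calendar day of recording."""

    day: int
    precision: Optional[float]  # None when no weakly labeled time that day
    missing_rate: float
    labeled_time: float  # manually labeled seconds that day


def label_quality_report(
    weak: Sequence[WeakLabelSegment], truth: Sequence[GroundTruthSegment]
) -> list[DayQuality]:
    """Per-day precision and missing rate of the heuristic vs. ground truth.

    Precision is correctly weak-labeled time over weakly labeled time (both
    restricted to manually labeled time); the missing rate is the manually
    labeled time without a weak label over all manually labeled time.
    """
    if not truth:
        return []
    last = max(s.end for s in truth)
    days = range(int((last - 1e-9) // SECONDS_PER_DAY) + 1)
    out = []
    for day in days:
        d0, d1 = day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY
        labeled = correct = weakly = missing = 0.0
        for ts in truth:
            t0, t1 = max(ts.start, d0), min(ts.end, d1)
            if t1 <= t0:
                continue
            labeled += t1 - t0
            covered = 0.0
            for ws in weak:
                ov = overlap(t0, t1, ws.start, ws.end)
                if ov <= 0:
                    continue
                covered += ov
                if ws.is_missing:
                    missing += ov
                else:
                    weakly += ov
                    if ws.activity is ts.activity:
                        correct += ov
            missing += max(0.0, (t1 - t0) - covered)  # uncovered time counts as missing
        if labeled <= 0:
            continue
        precision = correct / weakly if weakly > 0 else None
        out.append(DayQuality(day, precision, missing / labeled, labeled))
    return out
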