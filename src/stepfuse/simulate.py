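"""Synthetic free-living traces: schedule, accelerometer, steps and GPS.

The generator emulates a single-subject recording: a schedule over the
five activities is drawn from configurable mixture weights, then each
segment emits

* 30-Hz tri-axial acceleration — per-axis baseline (gravity folded into a
  constant offset so the magnitude oscillates around 1 g) plus an
  activity-specific sinusoid at the step frequency plus white noise;
* step events at the segment cadence during walking/running (and sparse
  spurious events during transportation, emulating step-counter false
  positives while riding);
* GPS fixes polled at variable intervals (default 60-180 s), positions
  integrated along a straight per-segment path at the segment speed, with
  accuracy drawn from an indoor distribution while sitting and an outdoor
  one otherwise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from stepfuse.types import AccelStream, Activity, GpsFix, NOMINAL_RATE_HZ, StepEventSeries

_DEG_PER_M_LAT = 1.0 / 111_194.93  # 1 deg latitude at Earth radius 6,371 km


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered (start, end, activity) segments tiling [0, duration)."""

    segments: tuple[tuple[float, float, Activity], ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end, _ in self.segments:
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValueError("schedule segments must tile the duration without gaps")
            if end <= start:
                raise ValueError("schedule segment must have positive duration")
            prev_end = end

    @property
    def duration(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def time_share(self) -> dict[Activity, float]:
        """Fraction of total time spent in each activity."""
        share = {a: 0.0 for a in Activity}
        for start, end, act in self.segments:
            share[act] += end - start
        total = self.duration or 1.0
        return {a: v / total for a, v in share.items()}


@dataclass
class SimulationConfig:
    """Distributions governing the synthetic recording.

    Cadences follow the walking 90-110 / running 160-180 steps-per-minute
    bands; speeds the ~1.4 / 3-4 / 4-8 / >=20 m/s anchors.  GPS accuracy
    defaults (indoor vs outdoor) are tool choices.
    """

    cadence_spm: dict[Activity, tuple[float, float]] = field(
        default_factory=lambda: {
            Activity.WALKING: (100.0, 5.0),
            Activity.RUNNING: (170.0, 5.0),
            # pedaling partially registers on phone step counters; the rate
            # lands in the ambiguous cadence band, so cycling is identified
            # by GPS speed (or left unlabeled when the GPS is unusable)
            Activity.CYCLING: (60.0, 8.0),
        }
    )
    speed_ms: dict[Activity, tuple[float, float]] = field(
        default_factory=lambda: {
            Activity.SITTING: (0.0, 0.0),
            Activity.WALKING: (1.4, 0.2),
            # spread kept below the running/cycling speed-band crossover at 4 m/s
            Activity.RUNNING: (3.5, 0.25),
            Activity.CYCLING: (6.0, 1.0),
            Activity.TRANSPORTATION: (25.0, 5.0),
        }
    )
    gps_poll_bounds: tuple[float, float] = (60.0, 180.0)
    indoor_accuracy: tuple[float, float] = (35.0, 10.0)
    outdoor_accuracy: tuple[float, float] = (8.0, 3.0)
    #: oscillation amplitude (g) of the periodic component, per activity
    oscillation_g: dict[Activity, float] = field(
        default_factory=lambda: {
            Activity.SITTING: 0.0,
            Activity.WALKING: 0.30,
            Activity.RUNNING: 0.60,
            Activity.CYCLING: 0.08,
            Activity.TRANSPORTATION: 0.03,
        }
    )
    noise_g: dict[Activity, float] = field(
        default_factory=lambda: {
            Activity.SITTING: 0.005,
            Activity.WALKING: 0.05,
            Activity.RUNNING: 0.08,
            Activity.CYCLING: 0.06,
            Activity.TRANSPORTATION: 0.02,
        }
    )
    segment_bounds_s: dict[Activity, tuple[float, float]] = field(
        default_factory=lambda: {
            Activity.SITTING: (900.0, 5400.0),
            Activity.WALKING: (300.0, 1800.0),
            Activity.RUNNING: (300.0, 1500.0),
            Activity.CYCLING: (300.0, 1800.0),
            Activity.TRANSPORTATION: (300.0, 1800.0),
        }
    )
    mixture_weights: dict[Activity, float] = field(
        default_factory=lambda: {
            Activity.SITTING: 0.55,
            Activity.WALKING: 0.22,
            Activity.RUNNING: 0.05,
            Activity.CYCLING: 0.06,
            Activity.TRANSPORTATION: 0.12,
        }
    )
    #: spurious step rate during transportation (steps/min), step-counter FP model
    spurious_spm_transport: float = 4.0
    sample_rate_hz: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        lo, hi = self.gps_poll_bounds
        if not (60.0 <= lo <= hi <= 180.0):
            raise ValueError(f"GPS poll bounds must lie within [60, 180] s: {self.gps_poll_bounds}")
        total = sum(self.mixture_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        for act, (mu, sd) in {**self.cadence_spm, **self.speed_ms}.items():
            if sd < 0:
                raise ValueError(f"negative spread for {act}")

    def to_dict(self) -> dict:
        return {
            "cadence_spm": {a.value: list(v) for a, v in self.cadence_spm.items()},
            "speed_ms": {a.value: list(v) for a, v in self.speed_ms.items()},
            "gps_poll_bounds": list(self.gps_poll_bounds),
            "indoor_accuracy": list(self.indoor_accuracy),
            "outdoor_accuracy": list(self.outdoor_accuracy),
            "oscillation_g": {a.value: v for a, v in self.oscillation_g.items()},
            "noise_g": {a.value: v for a, v in self.noise_g.items()},
            "segment_bounds_s": {a.value: list(v) for a, v in self.segment_bounds_s.items()},
            "mixture_weights": {a.value: v for a, v in self.mixture_weights.items()},
            "spurious_spm_transport": self.spurious_spm_transport,
            "sample_rate_hz": self.sample_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs: dict = {}
        act_maps = {
            "cadence_spm": tuple,
            "speed_ms": tuple,
            "oscillation_g": float,
            "noise_g": float,
            "segment_bounds_s": tuple,
            "mixture_weights": float,
        }
        for key, conv in act_maps.items():
            if key in d:
                kwargs[key] = {Activity(a): conv(v) for a, v in d[key].items()}
        for key in ("gps_poll_bounds", "indoor_accuracy", "outdoor_accuracy"):
            if key in d:
                kwargs[key] = tuple(float(v) for v in d[key])
        for key in ("spurious_spm_transport", "sample_rate_hz"):
            if key in d:
                kwargs[key] = float(d[key])
        return cls(**kwargs)


def generate_schedule(config: SimulationConfig, duration: float, seed: int) -> ActivitySchedule:
    """Draw an activity schedule tiling [0, duration).

    Activities are drawn with probability proportional to
    ``weight / mean_segment_duration`` so the *time share* of each class
    converges to its mixture weight; segment lengths are uniform within the
    per-activity bounds (the final segment is truncated at ``duration``).
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    rng = np.random.default_rng(seed)
    acts = list(Activity)
    mean_dur = {a: np.mean(config.segment_bounds_s[a]) for a in acts}
    p = np.array([config.mixture_weights[a] / mean_dur[a] for a in acts])
    p = p / p.sum()
    segments: list[tuple[float, float, Activity]] = []
    t = 0.0
    while t < duration - 1e-9:
        act = acts[rng.choice(len(acts), p=p)]
        lo, hi = config.segment_bounds_s[act]
        end = min(duration, t + rng.uniform(lo, hi))
        segments.append((t, end, act))
        t = end
    return ActivitySchedule(tuple(segments))


def explicit_schedule(blocks: list[tuple[float, Activity]]) -> ActivitySchedule:
    """Build a schedule from (duration, activity) blocks, starting at t = 0."""
    segments = []
    t = 0.0
    for dur, act in blocks:
        segments.append((t, t + dur, act))
        t += dur
    return ActivitySchedule(tuple(segments))


def synth_trace(
    schedule: ActivitySchedule,
    config: SimulationConfig,
    seed: int,
    include_accel: bool = True,
) -> tuple[AccelStream, StepEventSeries, list[GpsFix]]:
    """Render a schedule into accelerometer, step and GPS streams.

    ``include_accel=False`` returns an empty accelerometer stream (step and
    GPS draws are unchanged) — useful for long heuristic-only runs.
    """
    seq = np.random.SeedSequence(seed).spawn(4)
    rng_seg, rng_accel, rng_steps, rng_gps = (np.random.default_rng(s) for s in seq)
    fs = config.sample_rate_hz
    duration = schedule.duration
    n = int(round(duration * fs)) if include_accel else 0
    t = np.arange(n) / fs
    x = np.zeros(n)
    y = np.zeros(n)
    z = np.zeros(n)

    step_times: list[float] = []
    seg_speed: list[float] = []

    for start, end, act in schedule:
        cadence = 0.0
        if act in config.cadence_spm:
            mu, sd = config.cadence_spm[act]
            cadence = max(1.0, rng_seg.normal(mu, sd))
        mu, sd = config.speed_ms[act]
        seg_speed.append(max(0.0, rng_seg.normal(mu, sd)) if sd > 0 else mu)

        if include_accel:
            lo = int(np.ceil(start * fs - 1e-9))
            hi = min(n, int(np.ceil(end * fs - 1e-9)))
            tt = t[lo:hi]
            amp = config.oscillation_g.get(act, 0.0)
            noise = config.noise_g.get(act, 0.01)
            f_step = cadence / 60.0 if cadence > 0 else 1.2  # idle oscillation freq
            phase = rng_accel.uniform(0, 2 * np.pi)
            osc = amp * np.sin(2 * np.pi * f_step * tt + phase)
            # gravity folded into a constant z offset so |a| oscillates around 1 g
            z[lo:hi] = 1.0 + osc + rng_accel.normal(0, noise, hi - lo)
            x[lo:hi] = 0.3 * osc + rng_accel.normal(0, noise, hi - lo)
            y[lo:hi] = rng_accel.normal(0, noise, hi - lo)

        if cadence > 0:  # walking/running step events with timing jitter
            period = 60.0 / cadence
            k = int((end - start) / period)
            times = start + period * (np.arange(k) + 0.5)
            times = times + rng_steps.normal(0, 0.01 * period, k)
            step_times.extend(times[(times >= start) & (times < end)])
        elif act is Activity.TRANSPORTATION and config.spurious_spm_transport > 0:
            rate = config.spurious_spm_transport / 60.0
            n_fp = rng_steps.poisson(rate * (end - start))
            step_times.extend(rng_steps.uniform(start, end, n_fp))

    steps = StepEventSeries(np.sort(np.unique(np.asarray(step_times, dtype=float))))

    fixes = _synth_gps(schedule, config, seg_speed, rng_gps)
    return AccelStream(t, x, y, z), steps, fixes


def _synth_gps(
    schedule: ActivitySchedule,
    config: SimulationConfig,
    seg_speed: list[float],
    rng: np.random.Generator,
) -> list[GpsFix]:
    """Poll positions integrated along straight per-segment paths."""
    if len(schedule) == 0:
        return []
    duration = schedule.duration
    poll_lo, poll_hi = config.gps_poll_bounds
    poll_times = []
    t = rng.uniform(poll_lo, poll_hi) * 0.1  # first fix early in the recording
    while t < duration:
        poll_times.append(t)
        t += rng.uniform(poll_lo, poll_hi)

    bearings = rng.uniform(0, 2 * np.pi, len(schedule))
    # piecewise-linear position (meters east/north of origin) at segment edges
    edge_pos = [(0.0, 0.0)]
    for (start, end, _), speed, brg in zip(schedule, seg_speed, bearings):
        ex, ey = edge_pos[-1]
        d = speed * (end - start)
        edge_pos.append((ex + d * math.sin(brg), ey + d * math.cos(brg)))

    lat0 = 45.0
    fixes = []
    seg_idx = 0
    segs = list(schedule)
    for pt in poll_times:
        while seg_idx + 1 < len(segs) and pt >= segs[seg_idx][1]:
            seg_idx += 1
        start, end, act = segs[seg_idx]
        frac = (pt - start) / (end - start)
        (x0, y0), (x1, y1) = edge_pos[seg_idx], edge_pos[seg_idx + 1]
        px, py = x0 + frac * (x1 - x0), y0 + frac * (y1 - y0)
        mu, sd = config.indoor_accuracy if act is Activity.SITTING else config.outdoor_accuracy
        acc = max(1.0, rng.normal(mu, sd))
        lat = lat0 + py * _DEG_PER_M_LAT
        lon = px * _DEG_PER_M_LAT / math.cos(math.radians(lat0))
        fixes.append(GpsFix(t=float(pt), lat=float(lat), lon=float(lon), accuracy=float(acc)))
    return fixes


def degrade_gps(
    fixes: list[GpsFix], dropout_prob: float, accuracy_inflation: float, seed: int
) -> list[GpsFix]:
    """Drop fixes independently and inflate surviving accuracy estimates."""
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError(f"dropout_prob must be in [0, 1], got {dropout_prob}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fixes)) >= dropout_prob
    return [
        GpsFix(f.t, f.lat, f.lon, f.accuracy * accuracy_inflation)
        for f, k in zip(fixes, keep)
        if k
    ]


def schedule_to_truth(schedule: ActivitySchedule):
    """Ground-truth segments equal to the schedule (perfect annotation)."""
    from stepfuse.types import GroundTruthSegment

    return [GroundTruthSegment(s, e, a) for s, e, a in schedule]


def schedule_to_label_events(schedule: ActivitySchedule) -> list[tuple[float, str]]:
    """A manual label log reproducing the schedule, terminated by STOP."""
    events = [(s, a.value) for s, _, a in schedule]
    if len(schedule):
        events.append((schedule.duration, "STOP"))
    return events
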