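"""CSV readers and writers for sensor streams, label logs and datasets.

All files are UTF-8 CSV with a header row and '.' decimal separator, one
stream per file.  Schemas:

======================  ==========================================
accelerometer           ``t,x,y,z``
step events             ``t``
GPS fixes               ``t,lat,lon,accuracy``
manual label log        ``t,tag`` (tag = activity, ERROR or STOP)
weak labels             ``start,end,activity,probability``
ground-truth segments   ``start,end,activity``
dataset                 ``label,weak_label,f1..f18`` (+ optional
                        ``probability,window_start`` metadata)
======================  ==========================================

Time is seconds from recording start; intervals are half-open [start, end).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from stepfuse.types import (
    AccelStream,
    Activity,
    ERROR_TAG,
    FormatError,
    GpsFix,
    GroundTruthSegment,
    IntegrityError,
    LabeledRow,
    MISSING,
    STOP_TAG,
    StepEventSeries,
    UNLABELED,
    WeakLabelSegment,
)

PathLike = Union[str, Path]

N_FEATURES = 18


def _read_csv(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected header {','.join(columns)}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}, expected header {','.join(columns)}")
    return df


def _reject_nan(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    for c in cols:
        if df[c].isna().any():
            raise IntegrityError(f"{path}: NaN value in column {c!r}")


def read_accel(path: PathLike) -> AccelStream:
    """Read a tri-axial accelerometer stream (``t,x,y,z``)."""
    df = _read_csv(path, ["t", "x", "y", "z"])
    _reject_nan(df, ["t", "x", "y", "z"], path)
    return AccelStream(
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
    )


def write_accel(stream: AccelStream, path: PathLike) -> None:
    pd.DataFrame({"t": stream.t, "x": stream.x, "y": stream.y, "z": stream.z}).to_csv(
        path, index=False
    )


def read_steps(path: PathLike) -> StepEventSeries:
    """Read a step-event stream (single column ``t``)."""
    df = _read_csv(path, ["t"])
    _reject_nan(df, ["t"], path)
    return StepEventSeries(t=df["t"].to_numpy(float))


def write_steps(steps: StepEventSeries, path: PathLike) -> None:
    pd.DataFrame({"t": steps.t}).to_csv(path, index=False)


def read_gps(path: PathLike) -> list[GpsFix]:
    """Read GPS fixes (``t,lat,lon,accuracy``), returned sorted by timestamp."""
    df = _read_csv(path, ["t", "lat", "lon", "accuracy"])
    _reject_nan(df, ["t", "lat", "lon", "accuracy"], path)
    df = df.sort_values("t", kind="stable")
    return [
        GpsFix(t=float(r.t), lat=float(r.lat), lon=float(r.lon), accuracy=float(r.accuracy))
        for r in df.itertuples()
    ]


def write_gps(fixes: Sequence[GpsFix], path: PathLike) -> None:
    pd.DataFrame(
        {
            "t": [f.t for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "accuracy": [f.accuracy for f in fixes],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Manual label log
# ---------------------------------------------------------------------------

_VALID_TAGS = {a.value for a in Activity} | {ERROR_TAG, STOP_TAG}


def read_label_log(path: PathLike, blank_halfwidth: float = 2.0) -> list[GroundTruthSegment]:
    """Parse a manual annotation log into cleaned ground-truth segments.

    The log is a time-ordered sequence of ``(t, tag)`` events where an
    activity stays active until the next event and the log ends with STOP.
    Cleaning applies the annotation-error semantics:

    * the activity segment immediately preceding an ERROR event is dropped
      entirely (the annotator flagged it as mistaken);
    * at every transition between two kept, time-adjacent activity segments,
      ``[transition - blank_halfwidth, transition + blank_halfwidth)`` is
      excluded from both sides (default: a 4-s blanked window);
    * no blanking is applied at recording start or at STOP.
    """
    df = _read_csv(path, ["t", "tag"])
    _reject_nan(df, ["t"], path)
    events = [(float(r.t), str(r.tag).strip()) for r in df.itertuples()]
    return parse_label_events(events, blank_halfwidth=blank_halfwidth)


def parse_label_events(
    events: Sequence[tuple[float, str]], blank_halfwidth: float = 2.0
) -> list[GroundTruthSegment]:
    """Event-list form of :func:`read_label_log` (see there for semantics)."""
    if not events:
        raise FormatError("label log is empty")
    for (t0, _), (t1, _) in zip(events, events[1:]):
        if t1 < t0:
            raise IntegrityError("label log events are not time-ordered")
    if events[-1][1] != STOP_TAG:
        raise FormatError("label log must end with a STOP event")
    for t, tag in events:
        if tag not in _VALID_TAGS:
            raise FormatError(f"unknown label-log tag {tag!r} at t={t}")

    # Build raw segments; ERROR closes and drops the preceding segment.
    raw: list[GroundTruthSegment] = []
    active: Optional[tuple[float, Activity]] = None
    prev_was_error = False
    for t, tag in events:
        if tag == ERROR_TAG:
            if prev_was_error:
                warnings.warn("consecutive ERROR events: the second is ignored", stacklevel=2)
                continue
            active = None  # drop exactly the one segment preceding the error
            prev_was_error = True
            continue
        prev_was_error = False
        if active is not None and t > active[0]:
            raw.append(GroundTruthSegment(active[0], t, active[1]))
        active = None if tag == STOP_TAG else (t, Activity(tag))

    # Blank transitions between kept, time-adjacent segments.
    out: list[GroundTruthSegment] = []
    starts = [s.start for s in raw]
    ends = [s.end for s in raw]
    for i, seg in enumerate(raw):
        start, end = seg.start, seg.end
        if i > 0 and np.isclose(starts[i], ends[i - 1]):
            start += blank_halfwidth
        if i + 1 < len(raw) and np.isclose(ends[i], starts[i + 1]):
            end -= blank_halfwidth
        if end > start:
            out.append(GroundTruthSegment(start, end, seg.activity))
    return out


def write_label_log(events: Sequence[tuple[float, str]], path: PathLike) -> None:
    pd.DataFrame({"t": [t for t, _ in events], "tag": [tag for _, tag in events]}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Segment files (ground truth, weak labels)
# ---------------------------------------------------------------------------


def write_truth(segments: Sequence[GroundTruthSegment], path: PathLike) -> None:
    pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "activity": [s.activity.value for s in segments],
        }
    ).to_csv(path, index=False)


def read_truth(path: PathLike) -> list[GroundTruthSegment]:
    df = _read_csv(path, ["start", "end", "activity"])
    _reject_nan(df, ["start", "end"], path)
    return [
        GroundTruthSegment(float(r.start), float(r.end), Activity(r.activity))
        for r in df.itertuples()
    ]


def write_weak_labels(segments: Sequence[WeakLabelSegment], path: PathLike) -> None:
    """Write weak labels; MISSING rows carry an empty probability field."""
    pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "activity": [MISSING if s.is_missing else s.activity.value for s in segments],
            "probability": [s.probability for s in segments],
        }
    ).to_csv(path, index=False)


def read_weak_labels(path: PathLike) -> list[WeakLabelSegment]:
    df = _read_csv(path, ["start", "end", "activity", "probability"])
    _reject_nan(df, ["start", "end"], path)
    out = []
    for r in df.itertuples():
        if str(r.activity) == MISSING:
            out.append(WeakLabelSegment(float(r.start), float(r.end), None, None))
        else:
            out.append(
                WeakLabelSegment(float(r.start), float(r.end), Activity(r.activity), float(r.probability))
            )
    return out


# ---------------------------------------------------------------------------
# Dataset rows
# ---------------------------------------------------------------------------


def write_dataset(rows: Sequence[LabeledRow], path: PathLike, with_meta: bool = False) -> None:
    """Write labeled rows as ``label,weak_label,f1..fn``.

    With ``with_meta=True`` the quality probability and window start time are
    appended as extra columns so the file round-trips losslessly through
    :func:`read_dataset`.
    """
    dims = {len(r.features) for r in rows}
    if len(dims) > 1:
        raise IntegrityError(f"inconsistent feature dimensionality: {sorted(dims)}")
    n = dims.pop() if dims else N_FEATURES
    data: dict[str, list] = {
        "label": [UNLABELED if r.label is None else r.label.value for r in rows],
        "weak_label": [MISSING if r.weak_label is None else r.weak_label.value for r in rows],
    }
    feats = np.array([r.features for r in rows]).reshape(len(rows), n)
    for j in range(n):
        data[f"f{j + 1}"] = feats[:, j]
    if with_meta:
        data["probability"] = [r.probability for r in rows]
        data["window_start"] = [r.window_start for r in rows]
    pd.DataFrame(data).to_csv(path, index=False)


def read_dataset(path: PathLike) -> list[LabeledRow]:
    df = _read_csv(path, ["label", "weak_label", "f1"])
    fcols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    _reject_nan(df, fcols, path)
    has_meta = "probability" in df.columns and "window_start" in df.columns
    rows = []
    for i, r in enumerate(df.itertuples()):
        label = None if r.label == UNLABELED else Activity(r.label)
        weak = None if r.weak_label == MISSING else Activity(r.weak_label)
        prob: Optional[float] = None
        start = float(getattr(r, "window_start")) if has_meta else float(i)
        if weak is not None:
            if has_meta:
                prob = float(getattr(r, "probability"))
            else:
                prob = 1.0  # quality not stored in the bare schema
        feats = np.array([getattr(r, c) for c in fcols], dtype=float)
        rows.append(LabeledRow(label, weak, prob, feats, start))
    return rows
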