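"""Sliding-window segmentation and the 18-feature vector per 1-s window.

Windows are 1 s (30 samples at 30 Hz) with 50% overlap.  Each window yields,
in this fixed order (the order is part of the dataset file contract):

====  =========================================================
 1-7  acceleration magnitude: mean, variance, min, max, range,
      skewness, excess kurtosis
 8-16 per axis (x, y, z): \\|mean\\|, variance, range
17-18 magnitude spectrum: PSD peak count, dominant-peak
      frequency (Hz)
====  =========================================================

Moments are population moments; zero-variance windows report skewness and
kurtosis of 0 by convention.  The PSD uses the mean-removed 30-point DFT
(rectangular window, one-sided), giving exactly 1-Hz bins over 1-15 Hz with
DC excluded; a peak is a bin strictly greater than both neighbors with power
at least 10% of the maximum bin, and dominant-peak ties break toward the
lower frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stepfuse.types import AccelStream, IntegrityError, NOMINAL_DT

WINDOW_SAMPLES = 30
HOP_SAMPLES = 15
N_FEATURES = 18
PEAK_FLOOR = 0.10  # peak must reach 10% of the strongest bin

FEATURE_NAMES = (
    "mag_mean",
    "mag_var",
    "mag_min",
    "mag_max",
    "mag_range",
    "mag_skew",
    "mag_kurt",
    "x_absmean",
    "x_var",
    "x_range",
    "y_absmean",
    "y_var",
    "y_range",
    "z_absmean",
    "z_var",
    "z_range",
    "psd_peaks",
    "psd_dominant_hz",
)


@dataclass(frozen=True)
class Window:
    """Exactly 30 consecutive tri-axial samples covering [start, start + 1 s)."""

    start: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (WINDOW_SAMPLES,):
                raise IntegrityError(f"window axis {name} must have {WINDOW_SAMPLES} samples")
            object.__setattr__(self, name, arr)

    @property
    def end(self) -> float:
        return self.start + WINDOW_SAMPLES * NOMINAL_DT


def segment(accel: AccelStream, max_gap_factor: float = 2.0) -> list[Window]:
    """Cut a stream into 30-sample windows with 15-sample hop.

    Sample gaps wider than ``max_gap_factor`` times the nominal spacing break
    the tiling so no window straddles a recording gap; trailing partial
    windows are discarded.
    """
    if len(accel) == 0:
        return []
    gap = max_gap_factor * NOMINAL_DT
    breaks = np.flatnonzero(np.diff(accel.t) > gap)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks + 1, [len(accel)]))
    windows = []
    for lo, hi in zip(run_starts, run_ends):
        i = lo
        while i + WINDOW_SAMPLES <= hi:
            sl = slice(i, i + WINDOW_SAMPLES)
            windows.append(Window(float(accel.t[i]), accel.x[sl], accel.y[sl], accel.z[sl]))
            i += HOP_SAMPLES
    return windows


def magnitude(window: Window) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2)."""
    return np.sqrt(window.x**2 + window.y**2 + window.z**2)


def _moments(series: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/variance/skewness/excess-kurtosis; 0-variance -> (m, 0, 0, 0)."""
    m = float(np.mean(series))
    var = float(np.var(series))
    # numerically flat windows (variance at rounding-noise level) count as constant
    if var <= 1e-24 * max(1.0, m * m):
        return m, 0.0, 0.0, 0.0
    centered = series - m
    sd = np.sqrt(var)
    skew = float(np.mean(centered**3) / sd**3)
    kurt = float(np.mean(centered**4) / var**2 - 3.0)
    return m, var, skew, kurt


def psd_features(mag_series: np.ndarray) -> tuple[int, float]:
    """(peak count, dominant-peak frequency in Hz) of a 30-sample magnitude series.

    Flat (zero-power) spectra return (0, 0).
    """
    series = np.asarray(mag_series, dtype=float)
    if series.shape != (WINDOW_SAMPLES,):
        raise IntegrityError(f"PSD input must have {WINDOW_SAMPLES} samples")
    spectrum = np.fft.rfft(series - series.mean())
    power = np.abs(spectrum) ** 2  # bins 0..15 Hz; bin k is exactly k Hz
    power = power[1:]  # drop DC
    pmax = power.max()
    if pmax <= 1e-24:
        return 0, 0.0
    floor = PEAK_FLOOR * pmax
    peaks = 0
    for k in range(len(power)):
        left = power[k - 1] if k > 0 else -np.inf
        right = power[k + 1] if k + 1 < len(power) else -np.inf
        if power[k] > left and power[k] > right and power[k] >= floor:
            peaks += 1
    dominant_hz = float(np.argmax(power) + 1)  # argmax ties break toward lower freq
    return peaks, dominant_hz


def extract(window: Window) -> np.ndarray:
    """The 18-feature vector for one window (see module docstring for order)."""
    axes = (window.x, window.y, window.z)
    if any(np.isnan(a).any() for a in axes):
        raise IntegrityError("NaN in window samples")
    mag = magnitude(window)
    m_mean, m_var, m_skew, m_kurt = _moments(mag)
    m_min, m_max = float(mag.min()), float(mag.max())
    feats = [m_mean, m_var, m_min, m_max, m_max - m_min, m_skew, m_kurt]
    for axis in axes:
        mean = float(axis.mean())
        var = float(np.var(axis))
        if var <= 1e-24 * max(1.0, mean * mean):
            var = 0.0
        feats.extend([abs(mean), var, float(axis.max() - axis.min())])
    peaks, dom = psd_features(mag)
    feats.extend([float(peaks), dom])
    return np.asarray(feats, dtype=float)


def extract_all(windows: list[Window]) -> np.ndarray:
    """Stack feature vectors for a list of windows into an (n, 18) array."""
    if not windows:
        return np.empty((0, N_FEATURES))
    return np.vstack([extract(w) for w in windows])
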