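"""Interbeat-interval cleaning and windowed Poincaré heart-rate-variability metrics.

The processing chain mirrors common practice for wearable photoplethysmography:
robust artifact detection on the raw interbeat intervals (IBIs), linear
interpolation of flagged beats, tiling of the recording into nonoverlapping
5-minute windows, exclusion of windows with too many interpolated beats, and
Poincaré descriptors (SD1, SD2, SDNN) per surviving window.

Conventions
-----------
* ``beat_times`` are the times (seconds) at which each interval *ends*; the
  interval ``ibi_ms[i]`` covers ``(beat_times[i] - ibi_ms[i]/1000,
  beat_times[i])``.
* Windows are half-open ``[start, start + window_s)``, anchored at the first
  beat time of the recording; a beat belongs to the window containing its end
  time; the trailing partial window is discarded.
* Standard deviations inside a window are population SDs (divide by n): with
  consecutive pairs ``(x_i, x_{i+1})``, ``SD1 = SD((x_{i+1} - x_i)/sqrt(2))``
  is the dispersion perpendicular to the identity line of the Poincaré plot,
  ``SD2 = SD((x_{i+1} + x_i)/sqrt(2))`` the dispersion along it, and ``SDNN``
  the plain SD of the intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IBISeries",
    "HRVWindow",
    "ArtifactDetectorParams",
    "poincare_metrics",
    "detect_artifacts",
    "interpolate_artifacts",
    "window_series",
    "filter_windows",
]

FLAG_VALID = 0
FLAG_ARTIFACT = 1
FLAG_INTERPOLATED = 2

_SQRT2 = np.sqrt(2.0)


@dataclass
class IBISeries:
    """A timestamped interbeat-interval stream with per-beat flags."""

    beat_times: np.ndarray  # seconds, strictly increasing
    ibi_ms: np.ndarray  # interval durations, ms, > 0
    flags: np.ndarray = field(default=None)  # FLAG_* codes

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibi_ms = np.asarray(self.ibi_ms, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.ibi_ms.shape, dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.beat_times.ndim != 1 or self.beat_times.shape != self.ibi_ms.shape:
            raise ValueError("beat_times and ibi_ms must be 1-D and equal length")
        if self.flags.shape != self.ibi_ms.shape:
            raise ValueError("flags must align with ibi_ms")
        if len(self.beat_times) and np.any(np.diff(self.beat_times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.beat_times) <= 0)[0]) + 1
            raise ValueError(f"beat_times must be strictly increasing (row {bad})")
        if np.any(self.ibi_ms <= 0):
            raise ValueError("ibi_ms must be positive")

    def __len__(self) -> int:
        return len(self.ibi_ms)


@dataclass
class HRVWindow:
    """One nonoverlapping analysis window of a cleaned IBI stream."""

    start: float
    end: float
    n_beats: int
    n_interpolated: int
    mean_hr: float  # bpm
    sd1: float  # ms
    sd2: float  # ms
    sdnn: float  # ms
    kept: bool = True


@dataclass(frozen=True)
class ArtifactDetectorParams:
    """Settings for the quartile-deviation artifact criterion.

    ``multiplier`` scales the quartile deviation (half the interquartile
    range) of successive IBI differences into the rejection criterion; 3.32
    converts the QD into an estimate of the maximum expected beat difference
    for a Gaussian series.  The QD is computed locally over ``qd_window``
    beats so the criterion tracks the higher nocturnal variability instead
    of rejecting healthy night beats against a daytime scale.
    ``neighborhood`` is the half-width (beats) of the rolling median used as
    the robust local expectation, and ``min_criterion_ms`` is an absolute
    floor absorbing sensor quantization on near-regular stretches.
    """

    multiplier: float = 3.32
    neighborhood: int = 5
    qd_window: int = 501
    min_criterion_ms: float = 5.0
    min_beats: int = 12


def poincare_metrics(ibi_ms: np.ndarray) -> tuple[float, float, float]:
    """Return (sd1, sd2, sdnn) in ms for one window of consecutive IBIs.

    Uses the successive-difference formulation, equivalent to the SD of
    distances from the +45° and −45° lines of the Poincaré plot.  Requires at
    least 3 beats (2 consecutive pairs).
    """
    x = np.asarray(ibi_ms, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("poincare_metrics requires at least 3 beats")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((b - a) / _SQRT2))
    sd2 = float(np.std((b + a) / _SQRT2))
    sdnn = float(np.std(x))
    return sd1, sd2, sdnn


def detect_artifacts(
    series: IBISeries, params: ArtifactDetectorParams | None = None
) -> np.ndarray:
    """Flag beats whose interval deviates from a robust local expectation.

    The robust expectation is a centered rolling median over
    ``2 * neighborhood + 1`` beats; the criterion is ``multiplier`` times the
    quartile deviation of successive beat-to-beat differences in a rolling
    ``qd_window`` around each beat (quartiles are insensitive to the sparse
    artifacts themselves).  A beat is an artifact when its interval differs
    from its expectation by more than the criterion.  Deterministic; returns
    a boolean mask aligned with the series.
    """
    params = params or ArtifactDetectorParams()
    x = series.ibi_ms
    if len(x) < params.min_beats:
        raise ValueError(
            f"need at least {params.min_beats} beats for robust artifact detection, got {len(x)}"
        )
    s = pd.Series(x)
    expect = s.rolling(
        2 * params.neighborhood + 1, center=True, min_periods=2
    ).median().to_numpy()
    d = pd.Series(np.diff(x))
    q75 = d.rolling(params.qd_window, center=True, min_periods=5).quantile(0.75)
    q25 = d.rolling(params.qd_window, center=True, min_periods=5).quantile(0.25)
    qd = ((q75 - q25) / 2.0).to_numpy()
    # align diff-based scale to beats: beat i sees the diffs around it
    qd_beats = np.empty(len(x))
    qd_beats[1:] = qd
    qd_beats[0] = qd[0]
    criterion = np.maximum(params.multiplier * qd_beats, params.min_criterion_ms)
    return np.abs(x - expect) > criterion


def interpolate_artifacts(series: IBISeries, mask: np.ndarray) -> IBISeries:
    """Replace flagged intervals by linear interpolation between valid beats.

    Interpolation is linear in beat index between the nearest unflagged
    neighbours; flagged runs at either edge are filled from the nearest valid
    beat (constant extension).  Replaced beats are flagged ``interpolated``;
    timestamps are left untouched, so the covered time changes by at most one
    beat's duration per artifact run.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.ibi_ms.shape:
        raise ValueError("mask must align with series")
    if not mask.any():
        return series
    if mask.all():
        raise ValueError("cannot interpolate: every beat is flagged")
    idx = np.arange(len(series))
    valid = ~mask
    new_ibi = series.ibi_ms.copy()
    new_ibi[mask] = np.interp(idx[mask], idx[valid], series.ibi_ms[valid])
    new_flags = series.flags.copy()
    new_flags[mask] = FLAG_INTERPOLATED
    return replace(series, ibi_ms=new_ibi, flags=new_flags)


def window_series(
    series: IBISeries, window_s: float = 300.0, min_beats: int = 3
) -> list[HRVWindow]:
    """Tile the recording into nonoverlapping windows and compute metrics.

    Windows start at the first beat time and advance in ``window_s`` steps;
    the trailing partial window is discarded.  Windows with fewer than
    ``min_beats`` beats carry NaN metrics and ``kept=False``.  Mean HR is
    ``60000 / mean(ibi_ms)`` bpm.
    """
    if len(series) == 0:
        return []
    t0 = series.beat_times[0]
    span = series.beat_times[-1] - t0
    n_windows = int(np.floor(span / window_s))
    if n_windows < 1:
        return []
    assign = np.floor((series.beat_times - t0) / window_s).astype(int)
    windows: list[HRVWindow] = []
    for k in range(n_windows):
        in_w = assign == k
        beats = series.ibi_ms[in_w]
        n_interp = int(np.sum(series.flags[in_w] == FLAG_INTERPOLATED))
        if len(beats) >= min_beats:
            sd1, sd2, sdnn = poincare_metrics(beats)
            mean_hr = 60000.0 / float(np.mean(beats))
            ok = True
        else:
            sd1 = sd2 = sdnn = mean_hr = float("nan")
            ok = False
        windows.append(
            HRVWindow(
                start=float(t0 + k * window_s),
                end=float(t0 + (k + 1) * window_s),
                n_beats=int(len(beats)),
                n_interpolated=n_interp,
                mean_hr=mean_hr,
                sd1=sd1,
                sd2=sd2,
                sdnn=sdnn,
                kept=ok,
            )
        )
    return windows


def filter_windows(
    windows: list[HRVWindow], max_interpolated: int = 4
) -> list[HRVWindow]:
    """Set each window's ``kept`` flag from its interpolated-beat count.

    A window survives iff it has at most ``max_interpolated`` interpolated
    IBIs (the exclusion rule removes windows with 5 or more) and its metrics
    are defined.  Returns the same window objects, mutated in place.
    """
    for w in windows:
        w.kept = bool(w.n_interpolated <= max_interpolated and np.isfinite(w.sdnn))
    return windows
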