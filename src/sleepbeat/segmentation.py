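"""Resting classification, sleep-period estimation and the normative HRV transform.

Heart-rate and HRV aggregates are only trustworthy from wearable
photoplethysmography while the wearer is at rest, so 5-minute windows enter
the HRV analysis only when their mean heart rate is below
``0.55 × (220 − age)`` bpm.  Sleep periods are estimated from the joint
signature of low arm motion, zero steps and nocturnal bradycardia, and one
hour on each side of the estimated bed and wake times is discarded as a
wake/sleep transition zone before anything is aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SleepPeriod",
    "NormativeTable",
    "SleepEstimatorParams",
    "NoSleepFoundError",
    "classify_resting",
    "estimate_sleep_period",
    "normative_transform",
]

TRIM_S = 3600.0  # transition exclusion on each side of bed/wake


class NoSleepFoundError(RuntimeError):
    """No contiguous block of the night qualified as sleep."""


@dataclass(frozen=True)
class SleepPeriod:
    """Estimated bed/wake times plus the trimmed analysis bounds (seconds)."""

    bed_time: float
    wake_time: float
    trim_s: float = TRIM_S

    def __post_init__(self) -> None:
        if self.wake_time <= self.bed_time:
            raise ValueError("wake_time must be after bed_time")

    @property
    def analysis_start(self) -> float:
        return self.bed_time + self.trim_s

    @property
    def analysis_end(self) -> float:
        return self.wake_time - self.trim_s

    @property
    def usable(self) -> bool:
        return self.analysis_end > self.analysis_start


def classify_resting(mean_hr, age) -> np.ndarray | bool:
    """True where a window's mean HR is strictly below 0.55 × (220 − age) bpm.

    Vectorized over ``mean_hr``.  The threshold is the standard fraction of
    the age-predicted maximum heart rate used to gate photoplethysmography
    HRV windows.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0) or np.any(age >= 120):
        raise ValueError("age must be in (0, 120)")
    hr = np.asarray(mean_hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("mean_hr must be positive")
    # 0.55 x (220 - age), computed as 11(220 - age)/20 so clinical boundary
    # values (e.g. 110.0 at age 20) are represented exactly
    out = hr < 11.0 * (220.0 - age) / 20.0
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SleepEstimatorParams:
    """Thresholds for the automated sleep-period heuristic.

    Signals are reduced to 1-minute means, then smoothed with a rolling
    median of ``smooth_min`` minutes.  The activity threshold is the
    midpoint between the ``activity_quantiles`` of the day's smoothed
    activity — a valley cut between the resting and active clusters of the
    bimodal activity distribution.  A minute is a sleep candidate when
    smoothed activity is below that threshold, the smoothed step rate is
    zero, and smoothed HR is below the participant-day median.  The longest
    candidate run wins and must last at least ``min_duration_h`` hours.
    """

    smooth_min: int = 10
    activity_quantiles: tuple[float, float] = (0.10, 0.90)
    min_duration_h: float = 3.0
    max_gap_min: int = 20  # brief mid-sleep arousals bridged into the block
    min_density: float = 0.8  # candidate-minute fraction a bridged block must keep


def _minute_means(t: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.floor(t / 60.0).astype(int)
    m0 = m.min()
    sums = np.bincount(m - m0, weights=x)
    cnts = np.bincount(m - m0)
    keep = cnts > 0
    mins = (np.arange(len(sums)) + m0)[keep]
    return mins, sums[keep] / cnts[keep]


def _rolling_median(x: np.ndarray, k: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(k, center=True, min_periods=1).median().to_numpy()


def estimate_sleep_period(
    hr_t: np.ndarray,
    hr: np.ndarray,
    accel_t: np.ndarray,
    accel: np.ndarray,
    steps_t: np.ndarray,
    steps: np.ndarray,
    params: SleepEstimatorParams | None = None,
) -> SleepPeriod:
    """Estimate one night's bed and wake times from 1 Hz HR/motion/steps.

    The streams should cover roughly one evening-to-morning stretch (at
    least 12 h).  Returns the longest contiguous low-activity, zero-step,
    low-HR block, expanded to the enclosing state change; raises
    :class:`NoSleepFoundError` when no block reaches the minimum duration.
    Deterministic.
    """
    params = params or SleepEstimatorParams()
    hr_t = np.asarray(hr_t, dtype=float)
    if hr_t[-1] - hr_t[0] < 12 * 3600:
        raise ValueError("streams must cover at least 12 h around the night")
    mins_hr, hr_m = _minute_means(hr_t, hr)
    mins_ac, ac_m = _minute_means(accel_t, accel)
    mins_st, st_m = _minute_means(steps_t, steps)
    # align on common minutes
    common = np.intersect1d(np.intersect1d(mins_hr, mins_ac), mins_st)
    hr_m = hr_m[np.isin(mins_hr, common)]
    ac_m = ac_m[np.isin(mins_ac, common)]
    st_m = st_m[np.isin(mins_st, common)]
    k = params.smooth_min
    hr_s = _rolling_median(hr_m, k)
    ac_s = _rolling_median(ac_m, k)
    st_s = _rolling_median(st_m, k)
    q_lo, q_hi = np.quantile(ac_s, params.activity_quantiles)
    ac_thr = 0.5 * (q_lo + q_hi)
    hr_thr = np.median(hr_s)
    cand = (ac_s <= ac_thr) & (st_s <= 0) & (hr_s < hr_thr)
    # candidate runs, with brief gaps (mid-sleep arousals) bridged as long as
    # the bridged block stays dominated by candidate minutes
    runs = []
    i = 0
    n = len(cand)
    while i < n:
        if cand[i]:
            j = i
            while j + 1 < n and cand[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= params.max_gap_min:
            cand_minutes = int(cand[merged[-1][0] : run[1] + 1].sum())
            if cand_minutes / (run[1] - merged[-1][0] + 1) >= params.min_density:
                merged[-1][1] = run[1]
                continue
        merged.append(list(run))
    best = max(merged, key=lambda r: r[1] - r[0], default=None)
    if best is None or best[1] - best[0] + 1 < params.min_duration_h * 60:
        got = 0 if best is None else best[1] - best[0] + 1
        raise NoSleepFoundError(
            f"longest resting block {got} min < {params.min_duration_h} h minimum"
        )
    bed = float(common[best[0]]) * 60.0
    wake = float(common[best[1]] + 1) * 60.0
    return SleepPeriod(bed_time=bed, wake_time=wake)


class NormativeTable:
    """Reference means/SDs of HRV metrics by sex, age band and hour band.

    Strata are rows (sex, age_lo, age_hi, hour_lo, hour_hi, metric, mean,
    sd); age bands are half-open ``[age_lo, age_hi)``, hour bands inclusive
    ``hour_lo..hour_hi`` on the 0-23 clock, and ``sex`` may be ``"any"``.
    The published norm tables this emulates are not redistributable, so the
    package ships only an identity table and a builder that derives a table
    from its own synthetic population.
    """

    COLUMNS = ["sex", "age_lo", "age_hi", "hour_lo", "hour_hi", "metric", "mean", "sd"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"normative table missing columns: {missing}")
        if (frame["sd"] <= 0).any():
            raise ValueError("normative table reference SDs must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def identity(cls, metrics=("sd1", "sd2", "sdnn")) -> "NormativeTable":
        """A single all-covering stratum with mean 0 and SD 1 per metric."""
        rows = [
            {"sex": "any", "age_lo": 0, "age_hi": 120, "hour_lo": 0, "hour_hi": 23,
             "metric": m, "mean": 0.0, "sd": 1.0}
            for m in metrics
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_windows(
        cls,
        table: pd.DataFrame,
        metrics=("sd1", "sd2", "sdnn"),
        age_bands=((0, 40), (40, 120)),
        hour_bands=((0, 5), (6, 11), (12, 17), (18, 23)),
    ) -> "NormativeTable":
        """Build a table from a window-level frame with columns
        sex, age, hour and one column per metric (synthetic-population norms)."""
        rows = []
        for sex in sorted(table["sex"].unique()):
            for a_lo, a_hi in age_bands:
                for h_lo, h_hi in hour_bands:
                    sel = table[
                        (table["sex"] == sex)
                        & (table["age"] >= a_lo)
                        & (table["age"] < a_hi)
                        & (table["hour"] >= h_lo)
                        & (table["hour"] <= h_hi)
                    ]
                    for m in metrics:
                        vals = sel[m].dropna()
                        if len(vals) < 2 or vals.std(ddof=1) <= 0:
                            continue
                        rows.append(
                            {"sex": sex, "age_lo": a_lo, "age_hi": a_hi,
                             "hour_lo": h_lo, "hour_hi": h_hi, "metric": m,
                             "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
                        )
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def lookup(self, metric: str, sex: str, age: float, hour: int) -> tuple[float, float]:
        f = self.frame
        hit = f[
            (f["metric"] == metric)
            & ((f["sex"] == sex) | (f["sex"] == "any"))
            & (f["age_lo"] <= age)
            & (f["age_hi"] > age)
            & (f["hour_lo"] <= hour)
            & (f["hour_hi"] >= hour)
        ]
        if hit.empty:
            raise KeyError(
                f"no normative stratum for metric={metric}, sex={sex}, age={age}, hour={hour}"
            )
        row = hit.iloc[0]
        return float(row["mean"]), float(row["sd"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "NormativeTable":
        return cls(pd.read_csv(path))


def normative_transform(
    value: float, metric: str, sex: str, age: float, hour: int, table: NormativeTable
) -> float:
    """Standardize a raw HRV value against its (sex, age, hour) reference stratum."""
    mean, sd = table.lookup(metric, sex, age, hour)
    return (float(value) - mean) / sd
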