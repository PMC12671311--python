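"""Per-participant-day feature construction.

Each participant-day record pairs the waking stretch of one day with the
following night and the sleep-quality rating reported the next morning.
Days are anchored at wake-up: a day runs from one estimated wake time to the
next, with the hour before and after every bed/wake transition excluded.
Window-level heart-rate and Poincaré metrics (from resting, kept windows)
and minute-level motion/step streams are reduced per day-state to five
aggregates — minimum, mean, maximum, and the min/mean and max/mean ratios —
alongside diary variables and binarized static severity covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ibi import HRVWindow
from .segmentation import NormativeTable, SleepPeriod, classify_resting, normative_transform

__all__ = [
    "ParticipantProfile",
    "STATIC_CUTOFFS",
    "split_day",
    "aggregate_day",
    "aggregate_stress",
    "binarize_static",
    "build_daily_table",
]

#: strict > cutoffs separating "light to no disability" from more severe scores
STATIC_CUTOFFS = {"edss": 3.0, "msss": 3.0, "armss": 4.0, "compass": 17.0}

WINDOW_VARS = ("hr", "sd1", "sd2", "sdnn")
AGGREGATES = ("minimum", "mean", "maximum", "minimum_ratio", "maximum_ratio")


@dataclass
class ParticipantProfile:
    """Static covariates for one participant."""

    id: str
    age: float
    sex: str  # "f" / "m"
    group: str  # "MS" / "control"
    ms_type: str = "none"  # none / PMS / RRMS
    edss: float = 0.0
    msss: float = 0.0
    armss: float = 0.0
    compass: float = 0.0
    spinal_cord_affected: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("MS", "control"):
            raise ValueError(f"group must be MS or control, got {self.group!r}")
        if self.group == "control" and self.ms_type != "none":
            raise ValueError("control participants must have ms_type 'none'")
        for name in ("edss", "msss", "armss", "compass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def binarize_static(profile: ParticipantProfile) -> dict[str, bool]:
    """Binary severity flags from the clinical scores.

    Controls have their scores zeroed before the cutoff rule, so every flag
    is False for them.  The rule is strict: a score equal to the cutoff still
    counts as light-to-no disability.
    """
    flags = {}
    for name, cutoff in STATIC_CUTOFFS.items():
        score = getattr(profile, name)
        if profile.group == "control":
            score = 0.0
        key = "ans_dysfunction" if name == "compass" else f"{name}_severe"
        flags[key] = bool(score > cutoff)
    return flags


def split_day(
    windows: Sequence[HRVWindow], sleep_periods: Sequence[SleepPeriod]
) -> pd.DataFrame:
    """Assign kept windows to (day index, state) slots.

    Day ``d`` spans wake ``d-1`` → wake ``d`` (for ``d = 0`` the awake stretch
    starts at the recording's first window).  A window is *awake* of day ``d``
    when fully inside ``[wake_{d-1}+trim, bed_d−trim)`` and *asleep* when
    fully inside the night's trimmed analysis bounds; windows overlapping a
    transition zone belong to neither state.  Returns one row per window with
    columns window_index, day, state (awake/asleep/excluded).
    """
    periods = sorted(sleep_periods, key=lambda p: p.bed_time)
    for a, b in zip(periods, periods[1:]):
        if b.bed_time < a.wake_time:
            raise ValueError("sleep periods overlap")
    rows = []
    t_first = windows[0].start if windows else 0.0
    for i, w in enumerate(windows):
        if not w.kept:
            continue
        day, state = None, "excluded"
        for d, p in enumerate(periods):
            awake_lo = periods[d - 1].wake_time + p.trim_s if d > 0 else t_first
            if awake_lo <= w.start and w.end <= p.bed_time - p.trim_s:
                day, state = d, "awake"
                break
            if p.analysis_start <= w.start and w.end <= p.analysis_end:
                day, state = d, "asleep"
                break
        rows.append({"window_index": i, "day": day, "state": state})
    return pd.DataFrame(rows, columns=["window_index", "day", "state"])


def aggregate_day(values: Iterable[float]) -> dict[str, float]:
    """Five summary aggregates of one day-state's values.

    Returns NaN for every aggregate when no value is present (an explicitly
    missing day, never a silent zero); ratios are NaN when the mean is 0.
    """
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(vals) == 0:
        return {a: float("nan") for a in AGGREGATES}
    mn, mean, mx = float(vals.min()), float(vals.mean()), float(vals.max())
    if mean != 0.0:
        r_min, r_max = mn / mean, mx / mean
    else:
        r_min = r_max = float("nan")
    return {
        "minimum": mn,
        "mean": mean,
        "maximum": mx,
        "minimum_ratio": r_min,
        "maximum_ratio": r_max,
    }


def aggregate_stress(stress_values: Iterable[float]) -> float:
    """Arithmetic mean of a day's 1-10 stress logs; NaN when there are none."""
    vals = list(stress_values)
    for v in vals:
        if not (1 <= v <= 10):
            raise ValueError(f"stress values must lie in 1-10, got {v}")
    return float(np.mean(vals)) if vals else float("nan")


def _feature_name(var: str, agg: str, state: str) -> str:
    if agg == "mean" and var == "motion":
        return f"motion_{state}"  # table naming: "Motion asleep" is the mean
    if agg in ("minimum_ratio", "maximum_ratio"):
        return f"{var}_{agg}_{state}"
    return f"{agg}_{var}_{state}"


def _minute_means(t: np.ndarray, x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        return np.empty(0)
    m = np.floor(t[sel] / 60.0).astype(int)
    m0 = m.min()
    sums = np.bincount(m - m0, weights=x[sel])
    cnts = np.bincount(m - m0)
    return sums[cnts > 0] / cnts[cnts > 0]


def build_daily_table(
    profile: ParticipantProfile,
    windows: Sequence[HRVWindow],
    sleep_periods: Sequence[SleepPeriod],
    accel_t: np.ndarray,
    accel: np.ndarray,
    steps_t: np.ndarray,
    steps: np.ndarray,
    diary: pd.DataFrame,
    stress: pd.DataFrame,
    min_coverage_h: float = 4.0,
    resting_filter_asleep: bool = True,
    normative: NormativeTable | None = None,
) -> pd.DataFrame:
    """One row per participant-day with every model feature.

    ``diary`` needs columns day, sleep_quality, awake_at_night,
    sleep_medication (day = night index); ``stress`` needs timestamp_s and
    stress.  HRV/HR aggregates use kept windows passing the resting rule
    (applied to night windows too unless ``resting_filter_asleep`` is False);
    motion and steps are aggregated from 1-minute means of the raw streams.
    When a ``normative`` table is given, each window's SD1/SD2/SDNN are
    standardized against the participant's (sex, age, hour-of-day) reference
    stratum before aggregation.  Days with under ``min_coverage_h`` hours of
    kept windows in a state are flagged ``low_coverage``.
    """
    assign = split_day(windows, sleep_periods)
    periods = sorted(sleep_periods, key=lambda p: p.bed_time)
    t_first = windows[0].start if windows else 0.0
    accel_t = np.asarray(accel_t, dtype=float)
    accel = np.asarray(accel, dtype=float)
    steps_t = np.asarray(steps_t, dtype=float)
    steps = np.asarray(steps, dtype=float)
    diary = diary.set_index("day") if "day" in diary.columns else diary
    records = []
    for d, p in enumerate(periods):
        awake_lo = periods[d - 1].wake_time + p.trim_s if d > 0 else t_first
        awake_hi = p.bed_time - p.trim_s
        rec: dict[str, float] = {"participant": profile.id, "day": d}
        rec["sleep_duration"] = (p.wake_time - p.bed_time) / 3600.0
        rec["awake_duration"] = (p.bed_time - awake_lo) / 3600.0
        low_cov = False
        for state, (lo, hi) in (
            ("awake", (awake_lo, awake_hi)),
            ("asleep", (p.analysis_start, p.analysis_end)),
        ):
            idx = assign[(assign["day"] == d) & (assign["state"] == state)][
                "window_index"
            ].to_numpy()
            ws = [windows[i] for i in idx]
            if state == "awake" or resting_filter_asleep:
                ws = [w for w in ws if classify_resting(w.mean_hr, profile.age)]
            covered_h = sum(w.end - w.start for w in ws) / 3600.0
            if covered_h < min_coverage_h:
                low_cov = True
            for var in WINDOW_VARS:
                attr = "mean_hr" if var == "hr" else var
                if normative is not None and var != "hr":
                    vals = [
                        normative_transform(
                            getattr(w, attr), var, profile.sex, profile.age,
                            int((w.start % 86400.0) // 3600), normative,
                        )
                        for w in ws
                    ]
                else:
                    vals = [getattr(w, attr) for w in ws]
                aggs = aggregate_day(vals)
                for agg, val in aggs.items():
                    rec[_feature_name(var, agg, state)] = val
            for var, (tt, xx) in (("motion", (accel_t, accel)), ("steps", (steps_t, steps))):
                aggs = aggregate_day(_minute_means(tt, xx, lo, hi))
                for agg, val in aggs.items():
                    rec[_feature_name(var, agg, state)] = val
        rec["low_coverage"] = low_cov
        sel = (stress["timestamp_s"] >= awake_lo) & (stress["timestamp_s"] < p.bed_time)
        rec["mean_stress_awake"] = aggregate_stress(stress.loc[sel, "stress"].tolist())
        if d in diary.index:
            row = diary.loc[d]
            sq = float(row["sleep_quality"])
            if not (1 <= sq <= 5):
                raise ValueError(f"sleep_quality must lie in 1-5, got {sq}")
            rec["sleep_quality"] = sq
            rec["awake_at_night"] = float(row.get("awake_at_night", np.nan))
            rec["sleep_medication"] = float(row.get("sleep_medication", np.nan))
        else:
            rec["sleep_quality"] = float("nan")
            rec["awake_at_night"] = float("nan")
            rec["sleep_medication"] = float("nan")
        records.append(rec)
    table = pd.DataFrame(records)
    for key, val in binarize_static(profile).items():
        table[key] = val
    table["group"] = profile.group
    return table
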