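"""Synthetic wearable cohorts with known ground truth.

The generator emulates the statistical structure a two-week wearable sleep
study produces — circadian heart rate with nocturnal bradycardia, elevated
nocturnal beat-to-beat variability, missed-beat/ectopic IBI artifacts, the
sleep/wake activity contrast, stress logs, and 1-5 morning ratings driven by
a known logistic effect vector over the derived features — so every
downstream stage can be tested against truth.

Two sampling levels are provided:

* :func:`simulate_cohort` draws full beat-level IBI streams plus 1 Hz heart
  rate, accelerometer magnitude and step streams.  Intended for small
  cohorts (a handful of participant-days) when exercising the IBI cleaning
  and sleep-segmentation stages end-to-end.
* :func:`simulate_feature_cohort` draws the per-participant-day aggregate
  feature table directly from the same participant-level distributions,
  skipping the streams.  Intended for cohort-scale modeling studies
  (e.g. 60 participants x 14 days) where beat-level detail is irrelevant.

Both levels share the response model: features are z-scored within
participant, a latent score is the configured linear combination plus
logistic noise, the high/low label is its sign, and the 1-5 rating is a
monotone discretization of the latent anchored at the participant's
baseline, so that binarizing ratings at the personal mean approximately
recovers the labels.

IBI model: intervals follow ``60000 / HR(t)`` with an AR(1) slow component
plus white respiratory-like beat noise; both noise scales are multiplied by
the configured nocturnal HRV gain while asleep.  Artifacts are missed beats
(two intervals merged) and ectopics (one interval split), the two classes
robust beat detectors target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import ParticipantProfile
from .ibi import IBISeries
from .segmentation import SleepPeriod

__all__ = [
    "SimConfig",
    "CohortDataset",
    "DEFAULT_EFFECT_VECTOR",
    "MS_ONLY_EFFECTS",
    "FEATURE_COLUMNS",
    "simulate_cohort",
    "simulate_feature_cohort",
    "simulate_responses",
]

DAY_S = 86400.0

#: default effect vector on the normalized log-odds scale: the within-person
#: effects reported for the joint night-and-day sleep-quality models.
DEFAULT_EFFECT_VECTOR: dict[str, float] = {
    "sleep_duration": 0.47,
    "awake_at_night": -0.58,
    "motion_asleep": -0.29,
    "mean_sd1_asleep": 0.30,
    "minimum_sd2_asleep": -0.18,
    "mean_sd2_asleep": -0.47,
    "maximum_sd2_asleep": 0.08,
    "maximum_sdnn_asleep": 0.51,
    "sdnn_maximum_ratio_asleep": -0.54,
    "hr_minimum_ratio_awake": 0.16,
    "mean_stress_awake": -0.14,
}

#: default group-specific add-on: the nocturnal minimum-HR effect attributed
#: to the patient group only (zero for controls), sized like the swing the
#: group-wise night models show between the two groups.
MS_ONLY_EFFECTS: dict[str, float] = {"minimum_hr_asleep": 0.45}

# population mean, between-participant SD, within-participant (day-to-day) SD
_FEATURE_LEVELS: dict[str, tuple[float, float, float]] = {
    "sleep_duration": (7.7, 0.6, 0.8),  # h
    "awake_duration": (15.5, 0.7, 0.9),  # h
    "motion_asleep": (0.08, 0.02, 0.03),  # accel magnitude, g
    "minimum_hr_asleep": (52.0, 5.0, 3.0),  # bpm
    "mean_sd1_asleep": (38.0, 8.0, 6.0),  # ms
    "maximum_sd1_asleep": (70.0, 12.0, 10.0),
    "minimum_sd2_asleep": (35.0, 8.0, 6.0),
    "mean_sd2_asleep": (62.0, 10.0, 8.0),
    "maximum_sd2_asleep": (110.0, 18.0, 15.0),
    "maximum_sdnn_asleep": (95.0, 15.0, 12.0),
    "sdnn_maximum_ratio_asleep": (1.8, 0.2, 0.25),
    "minimum_sd1_awake": (12.0, 3.0, 2.5),
    "hr_minimum_ratio_awake": (0.72, 0.05, 0.05),
    "mean_hr_awake": (78.0, 6.0, 3.0),
    "maximum_hr_awake": (120.0, 10.0, 8.0),
    "minimum_hr_awake": (58.0, 5.0, 3.0),
    "mean_sdnn_awake": (45.0, 9.0, 7.0),
    "steps_awake": (8000.0, 2500.0, 2000.0),
}

FEATURE_COLUMNS: list[str] = list(_FEATURE_LEVELS) + ["awake_at_night", "mean_stress_awake"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the emulated study design: ~60 participants (roughly
    two-thirds patients), two weeks of nights, a 3.72 mean rating with a
    −0.4-point deficit for participants with autonomic dysfunction, bed
    around 23:00 and wake around 07:00, a 15 bpm nocturnal HR dip, 1.5x
    nocturnal HRV gain, and a 0.5% per-beat artifact rate.
    """

    n_participants: int = 60
    n_days: int = 14
    fraction_ms: float = 53 / 77
    age_range: tuple[float, float] = (18.0, 65.0)
    sex_ratio: float = 48 / 77  # fraction female
    true_bed_time: tuple[float, float] = (23.0 * 3600, 45.0 * 60)  # mean s-of-day, SD s
    true_wake_time: tuple[float, float] = (7.0 * 3600, 45.0 * 60)
    hr_day_mean: float = 75.0  # bpm
    hr_night_dip: float = 15.0  # bpm
    hrv_night_gain: float = 1.5
    artifact_rate: float = 0.005
    stress_level: tuple[float, float] = (4.0, 1.5)  # participant mean, day-to-day SD
    stress_between_sd: float = 1.5
    effect_vector: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_VECTOR)
    )
    ms_only_effects: dict[str, float] = field(
        default_factory=lambda: dict(MS_ONLY_EFFECTS)
    )
    noise_sd: float = 1.0  # scale of the latent logistic noise
    baseline_rating: float = 3.72
    person_rating_sd: float = 0.45
    severity_effect_points: float = -0.4  # rating deficit with ANS dysfunction
    # IBI micro-structure
    ibi_ar_coef: float = 0.8
    ibi_ar_sd_ms: float = 15.0
    ibi_white_sd_ms: float = 25.0
    transition_min: float = 20.0  # bed/wake ramp width, minutes
    bathroom_bout_prob: float = 0.3  # per night
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("SimConfig.n_participants must be >= 2")
        if self.n_days < 2:
            raise ValueError("SimConfig.n_days must be >= 2")
        for name in ("fraction_ms", "sex_ratio", "bathroom_bout_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"SimConfig.{name} must lie in [0, 1]")
        if not (0 <= self.artifact_rate < 0.5):
            raise ValueError("SimConfig.artifact_rate must lie in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValueError("SimConfig.noise_sd must be positive")
        for name in ("hr_day_mean", "hrv_night_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        for field_name in ("effect_vector", "ms_only_effects"):
            for key in getattr(self, field_name):
                if key not in FEATURE_COLUMNS:
                    raise ValueError(
                        f"SimConfig.{field_name} key {key!r} is not a generated "
                        f"feature; valid names: {sorted(FEATURE_COLUMNS)}"
                    )


@dataclass
class CohortDataset:
    """A simulated cohort with ground truth for every pipeline stage."""

    config: SimConfig
    participants: list[ParticipantProfile]
    streams: dict[str, dict[str, object]]  # pid -> ibi/hr_t/hr/accel_t/accel/...
    diary: pd.DataFrame  # participant, day, sleep_quality, awake_at_night, sleep_medication
    stress: pd.DataFrame  # participant, timestamp_s, stress
    truth: dict  # sleep_periods, artifacts, effect_vector, features, labels


def _simulate_profiles(config: SimConfig, rng: np.random.Generator):
    n = config.n_participants
    n_ms = max(1, min(n - 1, round(config.fraction_ms * n)))
    is_ms = np.zeros(n, dtype=bool)
    is_ms[rng.permutation(n)[:n_ms]] = True
    profiles = []
    for i in range(n):
        age = float(rng.uniform(*config.age_range))
        sex = "f" if rng.random() < config.sex_ratio else "m"
        if is_ms[i]:
            edss = float(np.round(np.clip(rng.gamma(2.0, 1.2), 0, 8) * 2) / 2)
            msss = float(np.clip(edss + rng.normal(0, 1.0), 0, 10))
            armss = float(np.clip(edss + rng.normal(0.5, 1.2), 0, 10))
            # calibrated so ~45% of patients exceed the dysfunction cutoff 17,
            # the rate the emulated cohort reports (24 of 53)
            compass = float(np.clip(rng.gamma(2.2, 8.5), 0, 70))
            profiles.append(
                ParticipantProfile(
                    id=f"p{i:03d}", age=age, sex=sex, group="MS",
                    ms_type="PMS" if rng.random() < 9 / 53 else "RRMS",
                    edss=edss, msss=msss, armss=armss, compass=compass,
                    spinal_cord_affected=bool(rng.random() < 24 / 53),
                )
            )
        else:
            profiles.append(
                ParticipantProfile(id=f"p{i:03d}", age=age, sex=sex, group="control")
            )
    return profiles


def _rating_map_calibration(
    config: SimConfig, rating_scale: float = 0.5
) -> tuple[float, float]:
    """(baseline anchor, attenuation slope) of the clip/round rating map.

    The 1-5 discretization is not mean-preserving: clipping pulls the
    observed mean toward the scale centre and compresses baseline contrasts
    (a shift near the ceiling partly disappears into it).  The generator
    therefore solves for the pre-discretization anchor whose *observed*
    mean equals ``baseline_rating``, and divides configured rating
    contrasts by the local slope so they reappear at full size in the
    observed ratings — honoring the contract that generator marginals match
    the config.  Deterministic quadrature over baseline and latent laws.
    """
    from scipy.stats import norm

    q = np.linspace(0.001, 0.999, 201)
    var_effects = sum(v**2 for v in config.effect_vector.values())
    latent_sd = np.sqrt(var_effects + (np.pi**2 / 3) * config.noise_sd**2)
    z = norm.ppf(q)[:, None] * latent_sd
    u = norm.ppf(q)[None, :] * config.person_rating_sd

    def mean_rating(anchor):
        return np.clip(np.round(anchor + u + rating_scale * z), 1, 5).mean()

    anchor = config.baseline_rating
    for _ in range(25):  # contraction: |1 - slope| < 1
        anchor += config.baseline_rating - mean_rating(anchor)
    delta = 0.25
    slope = (mean_rating(anchor + delta) - mean_rating(anchor - delta)) / (2 * delta)
    return float(anchor), float(max(slope, 0.2))


def _participant_baselines(
    profiles: list[ParticipantProfile], config: SimConfig, rng: np.random.Generator
) -> pd.Series:
    """Baseline 1-5 rating level per participant (severity deficit included)."""
    anchor, slope = _rating_map_calibration(config)
    shift = config.severity_effect_points / slope
    base = {}
    for p in profiles:
        b = anchor + rng.normal(0, config.person_rating_sd)
        if p.group == "MS" and p.compass > 17:
            b += shift
        base[p.id] = b
    return pd.Series(base)


def simulate_feature_cohort(
    config: SimConfig | None = None,
) -> tuple[list[ParticipantProfile], pd.DataFrame, dict]:
    """Draw the per-participant-day feature table directly (no streams).

    Returns (profiles, table, truth).  The table has one row per
    participant-day with the aggregate feature columns, the 1-5
    ``sleep_quality`` rating, and a ``group`` column; ``truth`` holds the
    effect vector actually applied per group, the latent scores and the
    binary labels.  Deterministic given ``config.seed``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = _simulate_profiles(config, rng)
    rows = []
    for p in profiles:
        mu = {
            c: m + rng.normal(0, bs)
            for c, (m, bs, _) in _FEATURE_LEVELS.items()
        }
        q_awake = rng.beta(2, 4)  # participant's propensity to wake at night
        stress_mu = np.clip(
            config.stress_level[0] + rng.normal(0, config.stress_between_sd), 1, 10
        )
        for d in range(config.n_days):
            rec = {"participant": p.id, "day": d, "group": p.group}
            for c, (m, _, ws) in _FEATURE_LEVELS.items():
                rec[c] = mu[c] + rng.normal(0, ws)
            rec["awake_at_night"] = float(rng.random() < q_awake)
            rec["mean_stress_awake"] = float(
                np.clip(stress_mu + rng.normal(0, config.stress_level[1]), 1, 10)
            )
            rows.append(rec)
    table = pd.DataFrame(rows)
    baselines = _participant_baselines(profiles, config, rng)
    group_of = {p.id: p.group for p in profiles}
    effect_by_row = table["participant"].map(group_of)
    normed = _normalize_within(table, FEATURE_COLUMNS)
    labels, ratings, latent = simulate_responses(
        normed,
        config.effect_vector,
        noise_sd=config.noise_sd,
        seed=int(rng.integers(2**31)),
        participant_baselines=baselines,
        extra_effects={"MS": config.ms_only_effects},
        row_groups=effect_by_row,
    )
    table["sleep_quality"] = ratings
    truth = {
        "effect_vector": dict(config.effect_vector),
        "ms_only_effects": dict(config.ms_only_effects),
        "labels": labels,
        "latent": latent,
        "baselines": baselines,
    }
    return profiles, table, truth


def _normalize_within(table: pd.DataFrame, columns) -> pd.DataFrame:
    out = table[["participant"]].copy()
    g = table.groupby("participant")
    for c in columns:
        mu = table["participant"].map(g[c].mean())
        sd = table["participant"].map(g[c].std(ddof=1))
        z = (table[c] - mu) / sd
        out[c] = z.where(np.isfinite(z), 0.0)
    return out


def simulate_responses(
    features: pd.DataFrame,
    effect_vector: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
    participant_baselines: pd.Series | None = None,
    rating_scale: float = 0.5,
    extra_effects: dict[str, dict[str, float]] | None = None,
    row_groups: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw binary labels and 1-5 ratings from a logistic model on features.

    ``features`` must be a per-participant normalized table containing every
    key of ``effect_vector`` (unknown names raise, listing the valid ones).
    The latent score is ``X @ beta`` plus logistic noise of scale
    ``noise_sd``; the label is its sign and the rating is
    ``clip(round(baseline + rating_scale * latent), 1, 5)``, a monotone
    discretization anchored at each participant's baseline so that
    binarizing ratings at the personal mean approximately recovers the
    labels.  ``extra_effects`` adds group-specific coefficients for the rows
    whose ``row_groups`` entry matches.  Returns (labels, ratings, latent).
    """
    unknown = [k for k in effect_vector if k not in features.columns]
    if unknown:
        valid = sorted(c for c in features.columns if c != "participant")
        raise ValueError(f"unknown effect_vector features {unknown}; valid names: {valid}")
    rng = np.random.default_rng(seed)
    n = len(features)
    lin = np.zeros(n)
    for name, beta in effect_vector.items():
        lin += beta * np.nan_to_num(features[name].to_numpy(dtype=float))
    if extra_effects:
        if row_groups is None:
            raise ValueError("extra_effects requires row_groups")
        grp = np.asarray(row_groups)
        for gname, effects in extra_effects.items():
            unknown = [k for k in effects if k not in features.columns]
            if unknown:
                raise ValueError(f"unknown extra_effects features {unknown}")
            sel = grp == gname
            for name, beta in effects.items():
                lin[sel] += beta * np.nan_to_num(
                    features[name].to_numpy(dtype=float)[sel]
                )
    latent = lin + rng.logistic(0.0, noise_sd, size=n)
    labels = (latent > 0).astype(int)
    if participant_baselines is None:
        base = np.full(n, 3.72)
    else:
        base = features["participant"].map(participant_baselines).to_numpy(dtype=float)
    ratings = np.clip(np.round(base + rating_scale * latent), 1, 5).astype(int)
    return labels, ratings, latent


# --------------------------------------------------------------------------
# stream-level simulation


def _smooth_sleep_indicator(t: np.ndarray, periods: list[SleepPeriod], ramp_s: float):
    """1 while asleep, 0 awake, with logistic ramps at each transition."""
    s = np.zeros_like(t)
    for p in periods:
        s += 1.0 / (1.0 + np.exp(-(t - p.bed_time) / ramp_s)) - 1.0 / (
            1.0 + np.exp(-(t - p.wake_time) / ramp_s)
        )
    return np.clip(s, 0.0, 1.0)


def _ar1(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov_sd = sd * np.sqrt(1 - coef**2)
    e = rng.normal(0, innov_sd, size=n)
    out = np.empty(n)
    out[0] = rng.normal(0, sd)
    c = coef
    # vectorized AR(1) via filtering would pull in scipy.signal; the loop is
    # fine at the stream sizes this level is meant for
    prev = out[0]
    for i in range(1, n):
        prev = c * prev + e[i]
        out[i] = prev
    return out


def _inject_artifacts(
    ibi_ms: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a beat sequence with missed beats and ectopics.

    Returns (corrupted ibi array, boolean truth mask over the corrupted
    array marking affected intervals).  Positions are kept at least three
    beats apart so events do not interact.
    """
    n = len(ibi_ms)
    if rate == 0 or n < 10:
        return ibi_ms.copy(), np.zeros(n, dtype=bool)
    n_events = rng.binomial(n, rate)
    pos = np.sort(rng.choice(np.arange(2, n - 2), size=min(n_events, (n - 4) // 3),
                             replace=False))
    keep = np.ones(len(pos), dtype=bool)
    keep[1:] = np.diff(pos) >= 3
    pos = pos[keep]
    kinds = rng.random(len(pos)) < 0.5  # True -> missed beat, False -> ectopic
    out: list[float] = []
    mask: list[bool] = []
    i = 0
    ptr = 0
    while i < n:
        if ptr < len(pos) and i == pos[ptr]:
            if kinds[ptr] and i + 1 < n:
                out.append(ibi_ms[i] + ibi_ms[i + 1])  # missed beat: merged
                mask.append(True)
                i += 2
            else:
                u = rng.uniform(0.3, 0.7)  # ectopic: split interval
                out.extend([ibi_ms[i] * u, ibi_ms[i] * (1 - u)])
                mask.extend([True, True])
                i += 1
            ptr += 1
        else:
            out.append(ibi_ms[i])
            mask.append(False)
            i += 1
    return np.asarray(out), np.asarray(mask, dtype=bool)


def simulate_cohort(config: SimConfig | None = None) -> CohortDataset:
    """Simulate full streams for every participant-day.

    Streams run from noon of day 0 to two hours past the last wake-up at
    1 Hz (HR, accelerometer magnitude, steps) plus the beat-level IBI
    stream.  Deterministic given ``config.seed``; intended for small
    cohorts — the beat streams are ~100k beats per participant-day.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = _simulate_profiles(config, rng)
    ramp_s = config.transition_min * 60.0 / 4.0
    streams: dict[str, dict[str, object]] = {}
    truth_periods: dict[str, list[SleepPeriod]] = {}
    truth_artifacts: dict[str, np.ndarray] = {}
    truth_rows = []
    stress_rows = []
    for p in profiles:
        hr_person = config.hr_day_mean + rng.normal(0, 4.0)
        dip_person = config.hr_night_dip * np.exp(rng.normal(0, 0.08))
        bed_mu = rng.normal(config.true_bed_time[0], config.true_bed_time[1] / 2)
        wake_mu = rng.normal(config.true_wake_time[0], config.true_wake_time[1] / 2)
        stress_mu = float(np.clip(
            config.stress_level[0] + rng.normal(0, config.stress_between_sd), 1, 10))
        periods = []
        night_gain = []
        night_motion = []
        for d in range(config.n_days):
            bed = d * DAY_S + bed_mu + rng.normal(0, config.true_bed_time[1] / 2)
            wake = (d + 1) * DAY_S + wake_mu + rng.normal(0, config.true_wake_time[1] / 2)
            periods.append(SleepPeriod(bed_time=bed, wake_time=wake))
            night_gain.append(config.hrv_night_gain * np.exp(rng.normal(0, 0.10)))
            night_motion.append(0.08 * np.exp(rng.normal(0, 0.35)))
        t0 = DAY_S / 2.0
        t_end = periods[-1].wake_time + 2 * 3600.0
        t = np.arange(t0, t_end, 1.0)
        sleep_ind = _smooth_sleep_indicator(t, periods, ramp_s)
        hr_slow = _ar1(len(t) // 600 + 2, 0.9, 2.0, rng)
        hr = (
            hr_person
            - dip_person * sleep_ind
            + np.repeat(hr_slow, 600)[: len(t)]
            + rng.normal(0, 1.0, size=len(t))
        )
        hr = np.clip(hr, 35, 190)
        # accelerometer magnitude and steps
        awake_level = 0.55 * np.exp(rng.normal(0, 0.1))
        night_level = np.full_like(t, 0.08)
        for d, p_d in enumerate(periods):
            inside = (t >= p_d.bed_time) & (t < p_d.wake_time)
            night_level[inside] = night_motion[d]
        accel = (
            (1 - sleep_ind) * awake_level * rng.gamma(2.0, 0.5, size=len(t))
            + sleep_ind * night_level * rng.gamma(2.0, 0.5, size=len(t))
        )
        steps = np.zeros(len(t))
        walk_minutes = rng.random(len(t) // 60 + 1) < 0.15
        steps_rate = np.repeat(walk_minutes, 60)[: len(t)] * rng.uniform(
            1.0, 2.0, size=len(t)
        )
        steps = np.where(sleep_ind < 0.5, np.round(steps_rate), 0.0)
        for d, p_d in enumerate(periods):
            if rng.random() < config.bathroom_bout_prob:
                start = rng.uniform(p_d.analysis_start, p_d.analysis_end - 300)
                sel = (t >= start) & (t < start + rng.uniform(120, 300))
                accel[sel] += 0.4
                steps[sel] = np.round(rng.uniform(0.5, 1.5, size=sel.sum()))
        # IBI stream: integrate HR to get smooth beat times, then add noise
        phase = np.cumsum(hr / 60.0)
        n_beats = int(phase[-1]) - 1
        beat_idx = np.arange(1, n_beats + 1)
        smooth_times = t0 + np.interp(beat_idx, phase, np.arange(len(t), dtype=float))
        base_ibi = np.diff(smooth_times) * 1000.0
        gain_at_beat = np.ones(len(base_ibi))
        for d, p_d in enumerate(periods):
            inside = (smooth_times[1:] >= p_d.bed_time) & (
                smooth_times[1:] < p_d.wake_time
            )
            gain_at_beat[inside] = night_gain[d]
        ar = _ar1(len(base_ibi), config.ibi_ar_coef, config.ibi_ar_sd_ms, rng)
        white = rng.normal(0, config.ibi_white_sd_ms, size=len(base_ibi))
        ibi = np.clip(base_ibi + gain_at_beat * (ar + white), 250.0, 2500.0)
        ibi_corrupt, art_mask = _inject_artifacts(ibi, config.artifact_rate, rng)
        beat_times = t0 + np.cumsum(ibi_corrupt) / 1000.0
        series = IBISeries(beat_times=beat_times, ibi_ms=ibi_corrupt)
        streams[p.id] = {
            "ibi": series,
            "hr_t": t, "hr": hr,
            "accel_t": t, "accel": accel,
            "steps_t": t, "steps": steps,
        }
        truth_periods[p.id] = periods
        truth_artifacts[p.id] = np.flatnonzero(art_mask)
        # truth daily features from the realized per-night parameters
        sd1_base = np.sqrt(
            config.ibi_white_sd_ms**2
            + config.ibi_ar_sd_ms**2 * (1 - config.ibi_ar_coef)
        )
        sdnn_base = np.sqrt(config.ibi_white_sd_ms**2 + config.ibi_ar_sd_ms**2)
        for d, p_d in enumerate(periods):
            awake_lo = periods[d - 1].wake_time if d > 0 else t0
            n_logs = max(1, rng.poisson(3))
            log_times = np.sort(rng.uniform(awake_lo, p_d.bed_time, size=n_logs))
            vals = np.clip(
                np.round(stress_mu + rng.normal(0, config.stress_level[1], n_logs)),
                1, 10,
            )
            for lt, lv in zip(log_times, vals):
                stress_rows.append(
                    {"participant": p.id, "timestamp_s": float(lt), "stress": float(lv)}
                )
            truth_rows.append(
                {
                    "participant": p.id,
                    "day": d,
                    "group": p.group,
                    "sleep_duration": (p_d.wake_time - p_d.bed_time) / 3600.0,
                    "awake_duration": (p_d.bed_time - awake_lo) / 3600.0,
                    "motion_asleep": night_motion[d],
                    "minimum_hr_asleep": hr_person - dip_person + rng.normal(0, 1.5),
                    "mean_sd1_asleep": sd1_base * night_gain[d],
                    "mean_sd2_asleep": sdnn_base * night_gain[d] * 1.3,
                    "maximum_sd2_asleep": sdnn_base * night_gain[d] * 1.8,
                    "maximum_sdnn_asleep": sdnn_base * night_gain[d] * 1.5,
                    "sdnn_maximum_ratio_asleep": 1.5 + rng.normal(0, 0.1),
                    "minimum_sd2_asleep": sdnn_base * night_gain[d] * 0.8,
                    "maximum_sd1_asleep": sd1_base * night_gain[d] * 1.6,
                    "minimum_sd1_awake": sd1_base * 0.5,
                    "hr_minimum_ratio_awake": 0.75 + rng.normal(0, 0.04),
                    "mean_stress_awake": float(np.mean(vals)),
                    "awake_at_night": float(rng.random() < 0.3),
                }
            )
    truth_table = pd.DataFrame(truth_rows)
    baselines = _participant_baselines(profiles, config, rng)
    normed = _normalize_within(
        truth_table,
        sorted(set(config.effect_vector) | set(config.ms_only_effects)),
    )
    labels, ratings, latent = simulate_responses(
        normed,
        config.effect_vector,
        noise_sd=config.noise_sd,
        seed=int(rng.integers(2**31)),
        participant_baselines=baselines,
        extra_effects={"MS": config.ms_only_effects},
        row_groups=truth_table["participant"].map(
            {p.id: p.group for p in profiles}
        ),
    )
    diary = truth_table[["participant", "day", "awake_at_night"]].copy()
    diary["sleep_quality"] = ratings
    diary["sleep_medication"] = (
        rng.random(len(diary)) < 0.05
    ).astype(float)
    truth = {
        "sleep_periods": truth_periods,
        "artifacts": truth_artifacts,
        "effect_vector": dict(config.effect_vector),
        "features": truth_table,
        "labels": labels,
        "latent": latent,
    }
    return CohortDataset(
        config=config,
        participants=profiles,
        streams=streams,
        diary=diary,
        stress=pd.DataFrame(stress_rows, columns=["participant", "timestamp_s", "stress"]),
        truth=truth,
    )
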