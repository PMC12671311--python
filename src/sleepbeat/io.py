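"""CSV interchange, pipeline configuration and the end-to-end orchestration.

All interchange files are plain CSV: per-participant stream files
(``ibi.csv``: timestamp_s, ibi_ms; ``hr.csv``: timestamp_s, hr_bpm;
``accel.csv``: timestamp_s, magnitude; ``steps.csv``: timestamp_s, steps),
diary and stress logs, a participant table, and the stage outputs (feature
table, model coefficient tables, evaluation report, subgroup report).  A
truth sidecar JSON and a manifest (config hash, seed) accompany simulated
cohorts.  Timestamps are seconds from the cohort's local midnight of day 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, ibi, modeling, segmentation, stats
from .features import ParticipantProfile
from .ibi import IBISeries
from .simulate import DAY_S, CohortDataset, SimConfig, simulate_cohort

logger = logging.getLogger("sleepbeat")

__all__ = [
    "PipelineConfig",
    "read_ibi_csv",
    "write_ibi_csv",
    "read_stream_csv",
    "write_stream_csv",
    "read_participants_csv",
    "write_participants_csv",
    "write_cohort",
    "read_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Every tunable constant of the processing chain, with study defaults."""

    window_s: float = 300.0
    artifact_multiplier: float = 3.32
    artifact_neighborhood: int = 5
    resting_coefficient: float = 0.55
    hr_ceiling: float = 220.0
    trim_hours: float = 1.0
    max_interpolated: int = 4
    static_cutoffs: dict = field(default_factory=lambda: dict(features.STATIC_CUTOFFS))
    penalty: float = modeling.DEFAULT_ALPHA
    selection_tolerance: float = 0.01
    n_splits: int = 50
    test_fraction: float = 0.20
    min_coverage_h: float = 4.0
    seed: int = 0
    scope: str = "both"

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.trim_hours < 0:
            raise ValueError("trim_hours must be non-negative")
        if self.scope not in ("both", "night", "day"):
            raise ValueError("scope must be both, night or day")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _validated_frame(path, required: list[str], time_col: str | None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if time_col is not None:
        t = frame[time_col].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            # offending data row is bad[0] + 1; +2 more for header and 1-basing
            raise ValueError(
                f"{path}: non-monotone {time_col} at row {int(bad[0]) + 3}"
            )
    return frame


def read_ibi_csv(path) -> IBISeries:
    frame = _validated_frame(path, ["timestamp_s", "ibi_ms"], "timestamp_s")
    flags = frame["flag"].to_numpy() if "flag" in frame.columns else None
    return IBISeries(
        beat_times=frame["timestamp_s"].to_numpy(),
        ibi_ms=frame["ibi_ms"].to_numpy(),
        flags=flags,
    )


def write_ibi_csv(series: IBISeries, path) -> None:
    pd.DataFrame(
        {"timestamp_s": series.beat_times, "ibi_ms": series.ibi_ms, "flag": series.flags}
    ).to_csv(path, index=False)


def read_stream_csv(path, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    frame = _validated_frame(path, ["timestamp_s", value_col], "timestamp_s")
    return frame["timestamp_s"].to_numpy(), frame[value_col].to_numpy()


def write_stream_csv(t, x, value_col: str, path) -> None:
    pd.DataFrame({"timestamp_s": t, value_col: x}).to_csv(path, index=False)


_PARTICIPANT_COLS = [
    "id", "age", "sex", "group", "ms_type", "edss", "msss", "armss", "compass",
    "spinal_cord",
]


def write_participants_csv(profiles: list[ParticipantProfile], path) -> None:
    rows = [
        {
            "id": p.id, "age": p.age, "sex": p.sex, "group": p.group,
            "ms_type": p.ms_type, "edss": p.edss, "msss": p.msss,
            "armss": p.armss, "compass": p.compass,
            "spinal_cord": int(p.spinal_cord_affected),
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_PARTICIPANT_COLS).to_csv(path, index=False)


def read_participants_csv(path) -> list[ParticipantProfile]:
    frame = _validated_frame(path, _PARTICIPANT_COLS, None)
    return [
        ParticipantProfile(
            id=str(r["id"]), age=float(r["age"]), sex=str(r["sex"]),
            group=str(r["group"]), ms_type=str(r["ms_type"]),
            edss=float(r["edss"]), msss=float(r["msss"]), armss=float(r["armss"]),
            compass=float(r["compass"]), spinal_cord_affected=bool(r["spinal_cord"]),
        )
        for _, r in frame.iterrows()
    ]


def write_cohort(dataset: CohortDataset, outdir) -> None:
    """Write a simulated cohort in the pipeline's own CSV dialects + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_participants_csv(dataset.participants, outdir / "participants.csv")
    dataset.diary.to_csv(outdir / "diary.csv", index=False)
    dataset.stress.to_csv(outdir / "stress.csv", index=False)
    for pid, s in dataset.streams.items():
        pdir = outdir / pid
        pdir.mkdir(exist_ok=True)
        write_ibi_csv(s["ibi"], pdir / "ibi.csv")
        write_stream_csv(s["hr_t"], s["hr"], "hr_bpm", pdir / "hr.csv")
        write_stream_csv(s["accel_t"], s["accel"], "magnitude", pdir / "accel.csv")
        write_stream_csv(s["steps_t"], s["steps"], "steps", pdir / "steps.csv")
    truth = {
        "sleep_periods": {
            pid: [[p.bed_time, p.wake_time] for p in periods]
            for pid, periods in dataset.truth["sleep_periods"].items()
        },
        "artifacts": {
            pid: np.asarray(v).tolist() for pid, v in dataset.truth["artifacts"].items()
        },
        "effect_vector": dataset.truth["effect_vector"],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(indir) -> tuple[list[ParticipantProfile], dict, pd.DataFrame, pd.DataFrame]:
    """Read back a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    profiles = read_participants_csv(indir / "participants.csv")
    diary = pd.read_csv(indir / "diary.csv")
    stress = pd.read_csv(indir / "stress.csv")
    streams = {}
    for p in profiles:
        pdir = indir / p.id
        streams[p.id] = {
            "ibi": read_ibi_csv(pdir / "ibi.csv"),
        }
        for name, col in (("hr", "hr_bpm"), ("accel", "magnitude"), ("steps", "steps")):
            t, x = read_stream_csv(pdir / f"{name}.csv", col)
            streams[p.id][f"{name}_t"] = t
            streams[p.id][name] = x
    return profiles, streams, diary, stress


def process_participant(
    profile: ParticipantProfile,
    stream: dict,
    diary: pd.DataFrame,
    stress: pd.DataFrame,
    config: PipelineConfig,
    n_days: int,
) -> pd.DataFrame:
    """Run one participant through cleaning, segmentation and feature building."""
    series: IBISeries = stream["ibi"]
    det = ibi.ArtifactDetectorParams(
        multiplier=config.artifact_multiplier,
        neighborhood=config.artifact_neighborhood,
    )
    mask = ibi.detect_artifacts(series, det)
    clean = ibi.interpolate_artifacts(series, mask)
    windows = ibi.filter_windows(
        ibi.window_series(clean, window_s=config.window_s),
        max_interpolated=config.max_interpolated,
    )
    periods = []
    for d in range(n_days):
        lo = d * DAY_S + DAY_S / 2
        hi = (d + 1) * DAY_S + DAY_S / 2
        sel = (stream["hr_t"] >= lo) & (stream["hr_t"] < hi)
        if sel.sum() < 12 * 3600:
            logger.warning("participant %s day %d: insufficient coverage", profile.id, d)
            continue
        try:
            period = segmentation.estimate_sleep_period(
                stream["hr_t"][sel], stream["hr"][sel],
                stream["accel_t"][sel], stream["accel"][sel],
                stream["steps_t"][sel], stream["steps"][sel],
            )
        except segmentation.NoSleepFoundError as exc:
            logger.warning("participant %s day %d: %s", profile.id, d, exc)
            continue
        period = segmentation.SleepPeriod(
            period.bed_time, period.wake_time, trim_s=config.trim_hours * 3600.0
        )
        if not period.usable:
            logger.warning(
                "participant %s day %d: night too short after trimming", profile.id, d
            )
            continue
        periods.append(period)
    if not periods:
        return pd.DataFrame()
    return features.build_daily_table(
        profile, windows, periods,
        stream["accel_t"], stream["accel"], stream["steps_t"], stream["steps"],
        diary=diary[diary["participant"] == profile.id],
        stress=stress[stress["participant"] == profile.id],
        min_coverage_h=config.min_coverage_h,
    )


def run_pipeline(
    pipeline_config: PipelineConfig | None = None,
    sim_config: SimConfig | None = None,
    outdir=None,
    dataset: CohortDataset | None = None,
):
    """Simulate (or accept) a cohort and run every stage end to end.

    Returns a dict with the daily feature table, model fits, evaluation
    report and subgroup report; when ``outdir`` is given the outputs and a
    manifest (config hash + seed) are written as CSV/JSON.  Deterministic
    given the seeds in the configs.
    """
    config = pipeline_config or PipelineConfig()
    config.validate()
    if dataset is None:
        sim_config = sim_config or SimConfig(n_participants=6, n_days=4)
        dataset = simulate_cohort(sim_config)
    tables = []
    for profile in dataset.participants:
        tab = process_participant(
            profile, dataset.streams[profile.id], dataset.diary, dataset.stress,
            config, dataset.config.n_days,
        )
        if len(tab):
            tables.append(tab)
    daily = pd.concat(tables, ignore_index=True)
    model_cols = [
        c for c in daily.columns
        if c not in ("participant", "day", "group", "low_coverage", "sleep_quality")
        and not c.endswith("_severe") and c != "ans_dysfunction"
        and daily[c].dtype.kind in "fi"
    ]
    usable = daily[~daily["low_coverage"].astype(bool)].reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normed = modeling.normalize_per_participant(
            usable, model_cols + ["sleep_quality"]
        )
    data = normed.data.dropna(subset=["sleep_quality"]).reset_index(drop=True)
    y = modeling.binarize_sleep_quality(data["sleep_quality"])
    feat_cols = [
        c for c in model_cols if data[c].notna().mean() > 0.8
    ]
    data = data.dropna(subset=feat_cols).reset_index(drop=True)
    y = modeling.binarize_sleep_quality(data["sleep_quality"])
    fits = modeling.fit_model_family(
        data, y, feat_cols, scope=config.scope, family="M1",
        penalty=config.penalty, selection_tolerance=config.selection_tolerance,
    )
    split_tab = data[["participant"]].copy()
    split_tab["label"] = y
    plan = evaluation.make_balanced_splits(
        split_tab, n_splits=config.n_splits, test_fraction=config.test_fraction,
        seed=config.seed,
    )
    scoped = modeling.scope_columns(feat_cols, config.scope)
    report = evaluation.evaluate_model(
        lambda: modeling.L1LogisticModel(alpha=config.penalty),
        data[scoped], y, data["participant"], plan,
    )
    specs = default_subgroup_specs()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        groups = stats.subgroup_report(daily, dataset.participants, specs)
    outputs = {
        "daily": daily,
        "fits": fits,
        "evaluation": report,
        "subgroups": groups,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        daily.to_csv(outdir / "daily_features.csv", index=False)
        fit_rows = [
            {"model": f.model_id, "group": f.group, "feature": k,
             "coefficient": v, "p": f.pvalues.get(k, float("nan"))}
            for f in fits for k, v in f.coefficients.items()
        ]
        pd.DataFrame(fit_rows, columns=["model", "group", "feature", "coefficient", "p"]
                     ).to_csv(outdir / "model_fits.csv", index=False)
        per = report.per_split.copy()
        agg = {"split": "aggregate", **report.aggregate}
        pd.concat([per, pd.DataFrame([agg])], ignore_index=True).to_csv(
            outdir / "evaluation.csv", index=False
        )
        groups.to_csv(outdir / "subgroup_report.csv", index=False)
        manifest = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "sim_seed": dataset.config.seed,
            "n_participants": len(dataset.participants),
            "n_days": dataset.config.n_days,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outputs


def default_subgroup_specs() -> list[stats.SubgroupSpec]:
    """The study-table subgroup contrasts over sleep-quality scores."""
    return [
        stats.SubgroupSpec("sex", "female", "male", lambda p: p.sex == "m"),
        stats.SubgroupSpec("disease_status", "no MS", "MS", lambda p: p.group == "MS"),
        stats.SubgroupSpec(
            "ans_dysfunction_all", "no ANS dysfunction", "ANS dysfunction",
            lambda p: p.compass > 17 and p.group == "MS",
        ),
        stats.SubgroupSpec(
            "ans_dysfunction_ms", "no ANS dysfunction (MS)", "ANS dysfunction",
            lambda p: p.compass > 17 and p.group == "MS", scope="MS-only",
        ),
        stats.SubgroupSpec(
            "edss_all", "EDSS <= 3", "EDSS > 3",
            lambda p: p.group == "MS" and p.edss > 3,
        ),
        stats.SubgroupSpec(
            "edss_ms", "EDSS <= 3 (MS)", "EDSS > 3",
            lambda p: p.group == "MS" and p.edss > 3, scope="MS-only",
        ),
        stats.SubgroupSpec(
            "spinal_cord_all", "spinal cord unaffected", "spinal cord affected",
            lambda p: p.spinal_cord_affected,
        ),
    ]
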