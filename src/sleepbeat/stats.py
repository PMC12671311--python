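"""Subgroup comparisons, correlation analyses and the design-stage sample size.

Subgroup contrasts of self-reported sleep quality follow the study-table
protocol: participant-level mean scores first (repeated nights of one person
are not independent), then group mean (SD) and a two-sided rank-based test
for a mean shift between the two groups.  The test is the independent-samples
Mann-Whitney U; p-values come from exact enumeration of labelings for small
samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil, comb, sqrt
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import ParticipantProfile

__all__ = [
    "SubgroupSpec",
    "rank_sum_test",
    "subgroup_report",
    "correlation_matrix",
    "sample_size_for_proportion",
]

EXACT_MAX_N = 20  # exact enumeration up to this combined sample size


@dataclass(frozen=True)
class SubgroupSpec:
    """A two-group contrast over participant profiles."""

    name: str
    group1_label: str
    group2_label: str
    predicate: Callable[[ParticipantProfile], bool]  # True -> group 2
    scope: str = "all"  # "all" or "MS-only"


def _u_statistic(g1: np.ndarray, g2: np.ndarray) -> float:
    """Mann-Whitney U for group 1 via midranks (ties get half credit)."""
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(g1)].sum()
    return float(r1 - len(g1) * (len(g1) + 1) / 2.0)


def rank_sum_test(values_g1, values_g2) -> tuple[float, float]:
    """Two-sided independent-samples rank test for a shift between groups.

    Returns (U, p).  For combined n <= 20 the p-value enumerates all
    C(n, n1) assignments of the pooled values to the two groups and counts
    those whose U deviates from its null mean at least as much as observed
    (tie-safe and exact).  For larger samples the tie-corrected normal
    approximation with continuity correction is used.
    """
    g1 = np.asarray(values_g1, dtype=float)
    g2 = np.asarray(values_g2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    u_obs = _u_statistic(g1, g2)
    mu = n1 * n2 / 2.0
    if n <= EXACT_MAX_N:
        pooled = np.concatenate([g1, g2])
        dev_obs = abs(u_obs - mu)
        hits = 0
        for idx in combinations(range(n), n1):
            take = np.zeros(n, dtype=bool)
            take[list(idx)] = True
            u = _u_statistic(pooled[take], pooled[~take])
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / comb(n, n1)
    # tie-corrected normal approximation
    pooled = np.concatenate([g1, g2])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(sigma2)
    z = max(z, 0.0)
    return u_obs, float(2 * sps.norm.sf(z))


def subgroup_report(
    daily_table: pd.DataFrame,
    profiles: list[ParticipantProfile],
    specs: list[SubgroupSpec],
    response_col: str = "sleep_quality",
    id_col: str = "participant",
) -> pd.DataFrame:
    """Group means/SDs and rank-test p-values for each subgroup contrast.

    Sleep-quality scores are averaged per participant before anything else.
    Specs scoped "MS-only" restrict group 1 to MS participants.  Contrasts
    with an empty side are skipped with a warning.
    """
    per_participant = (
        daily_table.dropna(subset=[response_col])
        .groupby(id_col)[response_col]
        .mean()
    )
    by_id = {p.id: p for p in profiles}
    rows = []
    for spec in specs:
        g1, g2 = [], []
        for pid, score in per_participant.items():
            prof = by_id.get(pid)
            if prof is None:
                continue
            if spec.predicate(prof):
                g2.append(score)
            else:
                if spec.scope == "MS-only" and prof.group != "MS":
                    continue
                g1.append(score)
        if not g1 or not g2:
            warnings.warn(f"subgroup spec {spec.name!r} skipped: empty group")
            continue
        u, p = rank_sum_test(g1, g2)
        rows.append(
            {
                "spec": spec.name,
                "scope": spec.scope,
                "group1": spec.group1_label,
                "n1": len(g1),
                "mean1": float(np.mean(g1)),
                "sd1": float(np.std(g1, ddof=1)) if len(g1) > 1 else float("nan"),
                "group2": spec.group2_label,
                "n2": len(g2),
                "mean2": float(np.mean(g2)),
                "sd2": float(np.std(g2, ddof=1)) if len(g2) > 1 else float("nan"),
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, columns: list[str], group_col: str | None = None
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Pairwise Pearson r and two-sided p per group, pairwise-complete.

    Returns ``{group: (r_frame, p_frame)}``; with ``group_col=None`` a single
    entry keyed "all".  Cells with fewer than 3 paired observations are NaN.
    """
    groups = {"all": table} if group_col is None else dict(tuple(table.groupby(group_col)))
    out = {}
    for gname, sub in groups.items():
        k = len(columns)
        r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
        p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
        for i, a in enumerate(columns):
            for j in range(i + 1, k):
                b = columns[j]
                pair = sub[[a, b]].dropna()
                if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                    rv, pv = float("nan"), float("nan")
                else:
                    res = sps.pearsonr(pair[a], pair[b])
                    rv, pv = float(res.statistic), float(res.pvalue)
                r.iloc[i, j] = r.iloc[j, i] = rv
                p.iloc[i, j] = p.iloc[j, i] = pv
        out[str(gname)] = (r, p)
    return out


def sample_size_for_proportion(p: float, halfwidth: float, confidence: float) -> int:
    """Smallest n whose normal-approximation CI half-width meets the target.

    Solves ``z * sqrt(p(1-p)/n) <= halfwidth`` with
    ``z = Phi^{-1}((1+confidence)/2)``; e.g. estimating an 85% rate to
    +/-10 percentage points at 95% confidence needs n = 49.
    """
    if not (0 < p < 1):
        raise ValueError("p must lie strictly between 0 and 1")
    if not (0 < halfwidth < 1):
        raise ValueError("halfwidth must lie strictly between 0 and 1")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie strictly between 0 and 1")
    if halfwidth >= min(p, 1 - p):
        warnings.warn("CI half-width exceeds the smaller tail of p")
    z = sps.norm.ppf((1 + confidence) / 2.0)
    n = z**2 * p * (1 - p) / halfwidth**2
    return int(ceil(n - 1e-9))
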