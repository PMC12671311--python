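"""Balanced subject-held-out evaluation of sleep-quality classifiers.

Generalization is measured on repeated splits that hold out 20% of the
*participants* (never individual nights of a training participant), with the
held-out nights downsampled to exactly equal counts of high- and low-quality
sleep, so that chance accuracy is 50% by construction.  Fifty such splits
are drawn by default; accuracy, precision and recall use a 0.5 probability
cutoff with high-quality sleep as the positive class, and AUC is the
probability that a random positive night outscores a random negative one
(ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["SplitPlan", "EvalReport", "auc", "make_balanced_splits", "evaluate_model"]


@dataclass
class SplitPlan:
    """Realized balanced subject-held-out splits."""

    n_splits: int
    test_fraction: float
    seed: int
    test_participants: list[np.ndarray] = field(default_factory=list)
    test_rows: list[np.ndarray] = field(default_factory=list)  # balanced row indices


@dataclass
class EvalReport:
    """Per-split and aggregate classification metrics (percent, AUC in [0,1])."""

    per_split: pd.DataFrame  # columns split, accuracy, precision, recall, auc
    cutoff: float = 0.5

    @property
    def aggregate(self) -> dict[str, float]:
        cols = ["accuracy", "precision", "recall", "auc"]
        return {c: float(self.per_split[c].mean()) for c in cols}


def auc(scores, labels) -> float:
    """Pairwise-concordance AUC: P(random positive outscores random negative).

    Ties count one half.  Computed via the rank-sum identity, which equals
    the explicit count over all positive x negative pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_balanced_splits(
    table: pd.DataFrame,
    n_splits: int = 50,
    test_fraction: float = 0.20,
    seed: int = 0,
    label_col: str = "label",
    id_col: str = "participant",
    max_retries: int = 100,
) -> SplitPlan:
    """Draw repeated perfectly balanced subject-held-out test sets.

    Each split samples ``ceil(test_fraction x n_participants)`` participants
    without replacement; among their rows the majority class is downsampled
    (without replacement) to match the minority, giving exactly equal class
    counts.  Splits whose held-out rows are single-class are redrawn, up to
    ``max_retries`` times each.
    """
    rng = np.random.default_rng(seed)
    pids = np.asarray(sorted(table[id_col].unique()))
    n_test = ceil(test_fraction * len(pids))
    plan = SplitPlan(n_splits=n_splits, test_fraction=test_fraction, seed=seed)
    labels = table[label_col].to_numpy()
    row_pid = table[id_col].to_numpy()
    for _ in range(n_splits):
        for attempt in range(max_retries + 1):
            test_ids = rng.choice(pids, size=n_test, replace=False)
            mask = np.isin(row_pid, test_ids)
            rows = np.flatnonzero(mask)
            pos = rows[labels[rows] == 1]
            neg = rows[labels[rows] == 0]
            if len(pos) and len(neg):
                break
        else:
            raise RuntimeError("could not draw a two-class held-out set")
        k = min(len(pos), len(neg))
        pos = rng.choice(pos, size=k, replace=False) if len(pos) > k else pos
        neg = rng.choice(neg, size=k, replace=False) if len(neg) > k else neg
        plan.test_participants.append(np.sort(test_ids))
        plan.test_rows.append(np.sort(np.concatenate([pos, neg])))
    return plan


def evaluate_model(
    model_factory,
    X: pd.DataFrame,
    y: np.ndarray,
    participants,
    plan: SplitPlan,
    cutoff: float = 0.5,
) -> EvalReport:
    """Fit and score a plug-in classifier over a realized split plan.

    ``model_factory()`` must return an object with ``fit(X, y)`` and
    ``predict_probability(X)``.  For each split the model is fit on every
    row of the non-held-out participants and scored on the balanced held-out
    rows; accuracy/precision/recall are percentages at the cutoff and the
    aggregate row is the mean over splits.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=int)
    pid = np.asarray(participants)
    rows = []
    for s, (test_ids, test_rows) in enumerate(
        zip(plan.test_participants, plan.test_rows)
    ):
        train = np.flatnonzero(~np.isin(pid, test_ids))
        model = model_factory()
        model.fit(Xv[train], yv[train])
        p = np.asarray(model.predict_probability(Xv[test_rows]), dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("plug-in model returned probabilities outside [0, 1]")
        yt = yv[test_rows]
        pred = (p > cutoff).astype(int)
        tp = int(np.sum((pred == 1) & (yt == 1)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        acc = 100.0 * np.mean(pred == yt)
        prec = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
        rec = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
        rows.append(
            {"split": s, "accuracy": acc, "precision": prec, "recall": rec,
             "auc": auc(p, yt)}
        )
    return EvalReport(per_split=pd.DataFrame(rows), cutoff=cutoff)
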