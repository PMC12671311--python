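"""Within-person normalization and L1-penalized logistic sleep-quality models.

The response of interest is *relative* sleep quality: every feature and the
1-5 morning rating are z-scored against the participant's own two-week mean
and SD, so models explain why a person slept better or worse than their own
average, not differences between people.  Because the normalized rating is
far from normal (it takes at most five values per person), modeling is done
in the binary setting: a night is "high quality" when the normalized rating
is strictly positive.

Model family
------------
* M1.x — features selected and the model fit on all participants jointly;
* M2.x — M1's feature sets, refit separately per group (MS / control);
* M3.x — selection *and* fit per group;

with x indexing the input scope: .1 night and day, .2 night only, .3 day
only.  Each fit combines greedy forward selection (grouped-CV AUC), an L1
penalty that zeroes weak coefficients, and an unpenalized refit on the
surviving features for coefficients and Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold

import statsmodels.api as sm

__all__ = [
    "NormalizedMatrix",
    "ModelFit",
    "L1LogisticModel",
    "normalize_per_participant",
    "binarize_sleep_quality",
    "check_response_normality",
    "fit_l1_logistic",
    "sequential_feature_selection",
    "fit_model_family",
    "scope_columns",
    "DEFAULT_ALPHA",
]

#: default per-observation L1 penalty weight (sklearn C = 1 / (alpha * n));
#: scaling per observation makes fits invariant to duplicating the data set.
DEFAULT_ALPHA = 0.05

NIGHT_EXTRAS = ("sleep_duration", "awake_at_night", "sleep_medication")
DAY_EXTRAS = ("awake_duration",)


@dataclass
class NormalizedMatrix:
    """Participant-day feature matrix z-scored within participant."""

    data: pd.DataFrame  # normalized columns + 'participant'
    means: pd.DataFrame  # per-participant column means
    sds: pd.DataFrame  # per-participant column sample SDs
    dropped: dict[str, list[str]] = field(default_factory=dict)  # participant -> cols

    def denormalize(self) -> pd.DataFrame:
        out = self.data.copy()
        for pid, grp in out.groupby("participant"):
            for col in self.means.columns:
                out.loc[grp.index, col] = (
                    grp[col] * self.sds.loc[pid, col] + self.means.loc[pid, col]
                )
        return out


@dataclass
class ModelFit:
    """One fitted sleep-quality model with its reporting metadata."""

    model_id: str
    scope: str  # both / night / day
    group: str  # all / MS / control
    selected: list[str]
    coefficients: dict[str, float]  # log-odds per within-person SD (refit)
    pvalues: dict[str, float]
    penalty: float
    l1_coefficients: dict[str, float] = field(default_factory=dict)
    separation_warning: bool = False
    cutoff: float = 0.5
    notes: str = (
        "p-values from an unpenalized refit on the L1-surviving features; "
        "no post-selection correction applied"
    )

    def significant(self, p_threshold: float = 0.10) -> dict[str, float]:
        """Coefficients reported at the table convention P < .10."""
        return {
            k: v for k, v in self.coefficients.items()
            if k != "const" and self.pvalues.get(k, 1.0) < p_threshold
        }


def normalize_per_participant(
    table: pd.DataFrame,
    columns: list[str],
    id_col: str = "participant",
    min_days: int = 2,
) -> NormalizedMatrix:
    """Z-score each column within participant (sample SD, n−1 denominator).

    Participants with fewer than ``min_days`` rows are dropped entirely
    (with a warning).  Constant columns (SD = 0) are recorded in ``dropped``
    for that participant and their normalized cells set to 0 — the value
    never deviates from the participant's own mean, so its within-person
    deviation is exactly zero (the column carries no within-person signal
    for them).  Cells that are missing in the input stay NaN.
    """
    keep_rows = []
    for pid, grp in table.groupby(id_col):
        if len(grp) >= min_days:
            keep_rows.append(grp)
        else:
            warnings.warn(f"participant {pid} dropped: fewer than {min_days} days")
    if not keep_rows:
        raise ValueError("no participant has enough days to normalize")
    tab = pd.concat(keep_rows)
    data = tab[[id_col]].copy()
    means = tab.groupby(id_col)[columns].mean()
    sds = tab.groupby(id_col)[columns].std(ddof=1)
    dropped: dict[str, list[str]] = {}
    for col in columns:
        mu = tab[id_col].map(means[col])
        sd = tab[id_col].map(sds[col])
        z = (tab[col] - mu) / sd
        constant = (sd == 0) & tab[col].notna()
        z[constant] = 0.0
        data[col] = z
    for pid in means.index:
        bad = [c for c in columns if not np.isfinite(sds.loc[pid, c]) or sds.loc[pid, c] == 0]
        if bad:
            dropped[str(pid)] = bad
    data = data.rename(columns={id_col: "participant"})
    return NormalizedMatrix(data=data, means=means, sds=sds, dropped=dropped)


def binarize_sleep_quality(normalized_response: pd.Series | np.ndarray) -> np.ndarray:
    """High (1) iff the night beat the participant's own average, strictly.

    A normalized response of exactly 0 counts as low: "better than the
    personal average" is a strict comparison.
    """
    z = np.asarray(normalized_response, dtype=float)
    return (z > 0).astype(int)


def check_response_normality(normalized_response) -> tuple[float, float]:
    """Shapiro–Wilk W and p for the normalized response.

    The discrete 1-5 rating scale makes the normalized response fail this
    test at any realistic sample size, which is the documented reason the
    pipeline models the binary high/low outcome instead of a linear fit.
    Constant input raises (the statistic is undefined).
    """
    z = np.asarray(normalized_response, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(z) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(z)
    return float(res.statistic), float(res.pvalue)


class L1LogisticModel:
    """L1-penalized logistic classifier satisfying the plug-in contract.

    ``alpha`` is the per-observation penalty weight; the sklearn ``C`` is
    derived as ``1 / (alpha * n)`` at fit time.  Deterministic (liblinear).
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA):
        self.alpha = alpha
        self._est: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "L1LogisticModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present to fit")
        C = 1.0 / (self.alpha * len(y))
        self._est = LogisticRegression(
            penalty="l1", C=C, solver="liblinear", tol=1e-8,
            intercept_scaling=100.0, max_iter=2000,
        )
        self._est.fit(X, y)
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("model not fitted")
        return self._est.predict_proba(np.asarray(X, dtype=float))[:, 1]

    @property
    def coef_(self) -> np.ndarray:
        return self._est.coef_[0]


def fit_l1_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    penalty: float = DEFAULT_ALPHA,
    clusters: np.ndarray | None = None,
) -> "ModelFit":
    """L1 fit for selection plus an unpenalized refit for inference.

    Features whose L1 coefficient is exactly zero are dropped; coefficients
    and Wald p-values come from a plain logistic refit on the survivors.
    When ``clusters`` (participant ids) is given, the refit uses
    cluster-robust standard errors — repeated nights of one participant are
    not independent, and naive Wald p-values overstate significance.
    Perfect separation in the refit is flagged, not silenced.
    """
    cols = list(X.columns)
    yv = np.asarray(y, dtype=int)
    if len(np.unique(yv)) < 2:
        raise ValueError("need both classes present to fit")
    if X.isna().any().any():
        raise ValueError("missing cells in model matrix")
    model = L1LogisticModel(alpha=penalty).fit(X.to_numpy(), yv)
    surviving = [c for c, b in zip(cols, model.coef_) if b != 0.0]
    l1_coefs = {c: float(b) for c, b in zip(cols, model.coef_) if b != 0.0}
    coefs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    separation = False
    if surviving:
        exog = sm.add_constant(X[surviving].to_numpy(), has_constant="add")
        fit_kw = {"disp": 0, "maxiter": 200}
        if clusters is not None:
            fit_kw.update(
                cov_type="cluster", cov_kwds={"groups": np.asarray(clusters)}
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(yv, exog).fit(**fit_kw)
                if not res.mle_retvals.get("converged", True):
                    separation = True
            except Exception:
                separation = True
                res = sm.Logit(yv, exog).fit_regularized(alpha=1e-6, disp=0)
        names = ["const"] + surviving
        for name, b, p in zip(names, res.params, res.pvalues):
            coefs[name] = float(b)
            pvals[name] = float(p) if np.isfinite(p) else 1.0
    return ModelFit(
        model_id="", scope="", group="", selected=surviving,
        coefficients=coefs, pvalues=pvals, penalty=penalty,
        l1_coefficients=l1_coefs, separation_warning=separation,
    )


def _grouped_cv_auc(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, alpha: float, n_folds: int
) -> float:
    from .evaluation import auc  # local import to avoid a cycle

    n_folds = min(n_folds, len(np.unique(groups)))
    cv = GroupKFold(n_splits=n_folds)
    scores = []
    for tr, te in cv.split(X, y, groups):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        m = L1LogisticModel(alpha=alpha).fit(X[tr], y[tr])
        scores.append(auc(m.predict_probability(X[te]), y[te]))
    return float(np.mean(scores)) if scores else 0.5


def choose_penalty_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    grid: tuple[float, ...] = (0.2, 0.1, 0.05, 0.02, 0.01, 0.005),
    n_folds: int = 5,
) -> float:
    """Per-observation penalty weight minimizing grouped-CV deviance.

    Intended for prediction-oriented fits (model comparison on held-out
    participants); the sparse explanatory models keep the fixed default,
    which shrinks harder than the prediction optimum.  Ties prefer the
    stronger penalty.
    """
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    Xv = np.asarray(X, dtype=float)
    n_folds = min(n_folds, len(np.unique(groups)))
    cv = GroupKFold(n_splits=n_folds)
    best_alpha, best_dev = None, np.inf
    for alpha in sorted(grid, reverse=True):
        dev = 0.0
        for tr, te in cv.split(Xv, y, groups):
            if len(np.unique(y[tr])) < 2:
                continue
            m = L1LogisticModel(alpha=alpha).fit(Xv[tr], y[tr])
            p = np.clip(m.predict_probability(Xv[te]), 1e-12, 1 - 1e-12)
            dev += -2.0 * np.sum(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        if dev < best_dev - 1e-9:
            best_alpha, best_dev = alpha, dev
    return float(best_alpha)


def sequential_feature_selection(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    candidates: list[str] | None = None,
    tolerance: float = 0.01,
    n_folds: int = 5,
    penalty: float = DEFAULT_ALPHA,
    max_features: int | None = None,
) -> list[str]:
    """Greedy forward selection maximizing participant-grouped CV AUC.

    At each step the candidate giving the largest cross-validated AUC is
    added; selection stops when the best addition improves the AUC by no
    more than ``tolerance``.  AUC ties between candidates are broken
    lexicographically by feature name.  Deterministic.
    """
    candidates = list(candidates if candidates is not None else X.columns)
    if not candidates:
        raise ValueError("empty candidate feature set")
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    selected: list[str] = []
    current_auc = 0.5  # chance level of the empty model
    while candidates and (max_features is None or len(selected) < max_features):
        best_feat, best_auc = None, -np.inf
        for feat in sorted(candidates):
            cols = selected + [feat]
            score = _grouped_cv_auc(
                X[cols].to_numpy(), y, groups, penalty, n_folds
            )
            if score > best_auc + 1e-12:
                best_feat, best_auc = feat, score
        if best_auc <= current_auc + tolerance:
            break
        selected.append(best_feat)
        candidates.remove(best_feat)
        current_auc = best_auc
    return selected


def scope_columns(columns: list[str], scope: str) -> list[str]:
    """Filter feature names by input scope (both / night / day).

    Night features are everything measured while asleep plus sleep duration
    and the night diary flags; day features are everything measured awake
    plus the time spent awake before bed.
    """
    if scope == "both":
        return [c for c in columns if c in scope_columns(columns, "night")
                or c in scope_columns(columns, "day")]
    if scope == "night":
        return [c for c in columns if c.endswith("_asleep") or c in NIGHT_EXTRAS]
    if scope == "day":
        return [c for c in columns if c.endswith("_awake") or c in DAY_EXTRAS]
    raise ValueError(f"unknown scope {scope!r}")


_SCOPE_SUFFIX = {"both": "1", "night": "2", "day": "3"}


def fit_model_family(
    data: pd.DataFrame,
    y: np.ndarray,
    feature_columns: list[str],
    scope: str,
    family: str,
    group_labels: pd.Series | None = None,
    penalty: float = DEFAULT_ALPHA,
    selection: str = "l1",
    selection_tolerance: float = 0.01,
    n_folds: int = 5,
    min_group_participants: int = 4,
) -> list[ModelFit]:
    """Fit one member scope of the M1/M2/M3 model families.

    ``family``:
      * ``"M1"`` — features selected and the model fit on all rows jointly;
      * ``"M2"`` — M1's joint selection, but per-group refits;
      * ``"M3"`` — selection and fit per group.

    With the default ``selection="l1"`` the penalty itself is the selector:
    features whose L1 coefficient shrinks to zero are removed and the rest
    refit unpenalized for inference.  ``selection="sequential"`` prepends
    greedy forward selection by grouped-CV AUC before the L1 stage.

    ``data`` must contain 'participant' plus the feature columns (already
    normalized within participant); rows with missing values in the scoped
    columns are dropped.  Returns one :class:`ModelFit` per group.
    """
    if family not in ("M1", "M2", "M3"):
        raise ValueError(f"unknown family {family!r}")
    if selection not in ("l1", "sequential"):
        raise ValueError(f"unknown selection mode {selection!r}")
    cols = scope_columns(feature_columns, scope)
    if not cols:
        raise ValueError(f"no features in scope {scope!r}")
    sub = data[["participant"] + cols].copy()
    sub["__y"] = np.asarray(y, dtype=int)
    if group_labels is not None:
        sub["__g"] = np.asarray(group_labels)
    sub = sub.dropna(subset=cols)
    mid = f"{family}.{_SCOPE_SUFFIX[scope]}"

    def _candidates(frame: pd.DataFrame) -> list[str]:
        if selection == "l1":
            return cols
        return sequential_feature_selection(
            frame[cols], frame["__y"].to_numpy(), frame["participant"].to_numpy(),
            candidates=cols, tolerance=selection_tolerance,
            n_folds=n_folds, penalty=penalty,
        )

    def _fit(frame: pd.DataFrame, candidates: list[str], group: str) -> ModelFit:
        if not candidates:
            return ModelFit(model_id=mid, scope=scope, group=group, selected=[],
                            coefficients={}, pvalues={}, penalty=penalty)
        fit = fit_l1_logistic(
            frame[candidates], frame["__y"].to_numpy(), penalty,
            clusters=frame["participant"].to_numpy(),
        )
        fit.model_id, fit.scope, fit.group = mid, scope, group
        return fit

    if family == "M1":
        return [_fit(sub, _candidates(sub), "all")]

    if group_labels is None:
        raise ValueError(f"family {family} needs group labels")
    fits = []
    if family == "M2":
        joint = _fit(sub, _candidates(sub), "all").selected
    for grp in ("MS", "control"):
        frame = sub[sub["__g"] == grp]
        if frame["participant"].nunique() < min_group_participants:
            raise ValueError(
                f"group {grp} has too few participants "
                f"({frame['participant'].nunique()} < {min_group_participants})"
            )
        candidates = joint if family == "M2" else _candidates(frame)
        fits.append(_fit(frame, candidates, grp))
    return fits
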