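"""Balanced subject-held-out evaluation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepbeat.evaluation import auc, evaluate_model, make_balanced_splits


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_chance(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            n = 30
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        if labels.sum() in (0, 25):
            labels[0] = 1 - labels[0]
        base = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(base, abs=1e-12)
        assert auc(2 * scores - 7, labels) == pytest.approx(base, abs=1e-12)


def cohort_table(rng, n_participants=60, days=10):
    return pd.DataFrame(
        {
            "participant": np.repeat([f"p{i:02d}" for i in range(n_participants)], days),
            "label": rng.integers(0, 2, n_participants * days),
        }
    )


class TestMakeBalancedSplits:
    def test_split_sizes_and_balance(self, rng):
        table = cohort_table(rng)
        plan = make_balanced_splits(table, n_splits=50, seed=3)
        assert len(plan.test_rows) == 50
        labels = table["label"].to_numpy()
        for ids, rows in zip(plan.test_participants, plan.test_rows):
            assert len(ids) == 12  # ceil(0.2 * 60)
            held = labels[rows]
            assert held.sum() * 2 == len(held)  # perfectly balanced

    def test_ceiling_participant_count(self, rng):
        table = cohort_table(rng, n_participants=11)
        plan = make_balanced_splits(table, n_splits=5, seed=0)
        assert all(len(ids) == 3 for ids in plan.test_participants)  # ceil(2.2)

    def test_no_participant_in_both_train_and_test(self, rng):
        table = cohort_table(rng)
        plan = make_balanced_splits(table, n_splits=50, seed=11)
        pids = table["participant"].to_numpy()
        for ids, rows in zip(plan.test_participants, plan.test_rows):
            train_pids = set(pids) - set(ids)
            assert set(pids[rows]) <= set(ids)
            assert not (set(pids[rows]) & train_pids)

    def test_seeded_determinism(self, rng):
        table = cohort_table(rng)
        a = make_balanced_splits(table, n_splits=10, seed=7)
        b = make_balanced_splits(table, n_splits=10, seed=7)
        for ra, rb in zip(a.test_rows, b.test_rows):
            assert np.array_equal(ra, rb)

    def test_single_class_cohort_errors(self, rng):
        table = cohort_table(rng)
        table["label"] = 1
        with pytest.raises(RuntimeError):
            make_balanced_splits(table, n_splits=2, seed=0, max_retries=3)


class _OracleModel:
    """Scores equal the true labels (fed via closure)."""

    def __init__(self, labels):
        self._labels = labels

    def fit(self, X, y):
        return self

    def predict_probability(self, X):
        return self._labels(X)


class TestEvaluateModel:
    def _setup(self, rng):
        table = cohort_table(rng)
        X = table[["label"]].astype(float) * 0.8 + 0.1  # scores encode labels
        plan = make_balanced_splits(table, n_splits=20, seed=5)
        return table, X, plan

    def test_oracle_model_is_perfect(self, rng):
        table, X, plan = self._setup(rng)
        model = _OracleModel(lambda X: X[:, 0])
        report = evaluate_model(
            lambda: model, X, table["label"], table["participant"], plan
        )
        agg = report.aggregate
        assert agg["accuracy"] == 100.0
        assert agg["auc"] == 1.0

    def test_constant_scorer_is_chance(self, rng):
        table, X, plan = self._setup(rng)
        model = _OracleModel(lambda X: np.full(len(X), 0.5))
        report = evaluate_model(
            lambda: model, X, table["label"], table["participant"], plan
        )
        agg = report.aggregate
        assert agg["accuracy"] == 50.0  # balanced sets, all predicted negative
        assert agg["auc"] == 0.5

    def test_aggregate_equals_mean_of_splits(self, rng):
        table, X, plan = self._setup(rng)
        model = _OracleModel(lambda X: X[:, 0])
        report = evaluate_model(
            lambda: model, X, table["label"], table["participant"], plan
        )
        for col, val in report.aggregate.items():
            assert val == pytest.approx(report.per_split[col].mean(), abs=1e-12)

    def test_probability_contract_enforced(self, rng):
        table, X, plan = self._setup(rng)
        model = _OracleModel(lambda X: np.full(len(X), 1.7))
        with pytest.raises(ValueError, match="probabilities"):
            evaluate_model(lambda: model, X, table["label"], table["participant"], plan)

    def test_fitted_model_tracks_bayes_auc(self):
        """A logistic fit on the default synthetic cohort reaches the
        generator's analytic ranking ceiling to within 0.05."""
        import warnings

        from scipy.special import expit

        from sleepbeat import modeling
        from sleepbeat.simulate import (
            DEFAULT_EFFECT_VECTOR,
            MS_ONLY_EFFECTS,
            FEATURE_COLUMNS,
            SimConfig,
            simulate_feature_cohort,
        )

        profiles, table, truth = simulate_feature_cohort(SimConfig(seed=77))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normed = modeling.normalize_per_participant(
                table, FEATURE_COLUMNS + ["sleep_quality"]
            )
        data = normed.data
        # evaluate against the generator's exact labels: this isolates the
        # evaluation machinery from the extra diary-discretization channel
        y = truth["labels"]
        split_tab = data[["participant"]].copy()
        split_tab["label"] = y
        plan = make_balanced_splits(split_tab, n_splits=50, seed=77)
        cols = modeling.scope_columns(FEATURE_COLUMNS, "both")
        X = data[cols].fillna(0.0)
        # prediction context: penalty chosen by participant-grouped CV
        alpha = modeling.choose_penalty_cv(X, y, data["participant"].to_numpy())
        report = evaluate_model(
            lambda: modeling.L1LogisticModel(alpha=alpha),
            X, y, data["participant"], plan,
        )
        # Bayes AUC from the generator's latent-score law: s ~ N(0, sigma^2),
        # P(y=1|s) = expit(s); deterministic large-sample evaluation.  The
        # n-1 z-score denominator leaves marginal feature variance (d-1)/d.
        frac_ms = np.mean([p.group == "MS" for p in profiles])
        var_common = sum(v**2 for v in DEFAULT_EFFECT_VECTOR.values())
        var_ms = var_common + sum(v**2 for v in MS_ONLY_EFFECTS.values())
        d = 14
        sigma = np.sqrt(
            (frac_ms * var_ms + (1 - frac_ms) * var_common) * (d - 1) / d
        )
        oracle_rng = np.random.default_rng(123456)
        s = oracle_rng.normal(0.0, sigma, 400_000)
        y_oracle = (oracle_rng.random(len(s)) < expit(s)).astype(int)
        bayes = auc(s, y_oracle)
        assert report.aggregate["auc"] == pytest.approx(bayes, abs=0.05)
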