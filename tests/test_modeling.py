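"""Normalization, binarization and penalized-model tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sleepbeat.modeling import (
    DEFAULT_ALPHA,
    binarize_sleep_quality,
    check_response_normality,
    fit_l1_logistic,
    fit_model_family,
    normalize_per_participant,
    scope_columns,
    sequential_feature_selection,
)


def toy_table():
    return pd.DataFrame(
        {
            "participant": ["a"] * 3 + ["b"] * 3,
            "x": [3.0, 4.0, 5.0, 10.0, 10.0, 10.0],
            "y": [1.0, 2.0, 4.0, 0.0, 5.0, 10.0],
        }
    )


class TestNormalizePerParticipant:
    def test_three_point_example(self):
        out = normalize_per_participant(toy_table(), ["x"])
        a = out.data[out.data["participant"] == "a"]["x"].to_numpy()
        assert a == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_recorded_and_zero_deviation(self):
        out = normalize_per_participant(toy_table(), ["x"])
        assert out.dropped == {"b": ["x"]}
        b = out.data[out.data["participant"] == "b"]["x"].to_numpy()
        assert b == pytest.approx([0.0, 0.0, 0.0])

    def test_within_participant_moments(self, rng):
        table = pd.DataFrame(
            {
                "participant": np.repeat([f"p{i}" for i in range(5)], 14),
                "v": rng.normal(50, 9, 70),
            }
        )
        out = normalize_per_participant(table, ["v"])
        for _, grp in out.data.groupby("participant"):
            assert grp["v"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["v"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_denormalize_round_trip(self, rng):
        table = pd.DataFrame(
            {
                "participant": np.repeat(["a", "b", "c"], 10),
                "u": rng.normal(10, 3, 30),
                "v": rng.uniform(0, 1, 30),
            }
        )
        out = normalize_per_participant(table, ["u", "v"])
        back = out.denormalize()
        assert np.allclose(back[["u", "v"]].to_numpy(), table[["u", "v"]].to_numpy(), atol=1e-12)

    def test_too_few_days_drops_participant(self):
        table = pd.DataFrame({"participant": ["a", "a", "b"], "x": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="b"):
            out = normalize_per_participant(table, ["x"])
        assert set(out.data["participant"]) == {"a"}


class TestBinarizeSleepQuality:
    def test_sign_rule_with_strict_tie(self):
        z = np.array([0.3, -0.2, 0.0, 2.0])
        assert list(binarize_sleep_quality(z)) == [1, 0, 0, 1]

    def test_counts_match_sign_counts(self, rng):
        z = rng.normal(0, 1, 500)
        y = binarize_sleep_quality(z)
        assert y.sum() == int((z > 0).sum())


class TestCheckResponseNormality:
    def test_normal_draws_usually_pass(self):
        passes = 0
        for seed in range(20):
            z = np.random.default_rng(seed).normal(0, 1, 500)
            _, p = check_response_normality(z)
            passes += p > 0.05
        assert passes >= 18

    def test_discrete_response_fails_hard(self, rng):
        ratings = rng.integers(1, 6, size=500).astype(float)
        z = (ratings - ratings.mean()) / ratings.std(ddof=1)
        _, p = check_response_normality(z)
        assert p < 1e-3

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            check_response_normality([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            check_response_normality([1.0, 2.0])


def simulate_logistic(rng, n, betas):
    X = rng.normal(0, 1, size=(n, len(betas)))
    y = (rng.random(n) < expit(X @ np.asarray(betas))).astype(int)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(len(betas))]), y


class TestFitL1Logistic:
    def test_null_model_shrinks_everything(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = simulate_logistic(rng, 800, [0.0] * 10)
            fit = fit_l1_logistic(X, y)
            hits += len(fit.selected) == 0
        assert hits >= 18

    def test_recovers_single_strong_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, y = simulate_logistic(rng, 800, [1.5] + [0.0] * 10)
            fit = fit_l1_logistic(X, y)
            hits += "f0" in fit.selected and fit.coefficients["f0"] > 0
        assert hits >= 19

    def test_duplication_invariance(self, rng):
        X, y = simulate_logistic(rng, 300, [1.0, -0.5, 0.0])
        fit1 = fit_l1_logistic(X, y)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        fit2 = fit_l1_logistic(X2, y2)
        assert fit1.selected == fit2.selected
        for k in fit1.l1_coefficients:
            assert fit1.l1_coefficients[k] == pytest.approx(
                fit2.l1_coefficients[k], abs=1e-5
            )

    def test_single_class_rejected(self, rng):
        X, _ = simulate_logistic(rng, 50, [0.0])
        with pytest.raises(ValueError):
            fit_l1_logistic(X, np.ones(50, dtype=int))

    def test_penalty_monotonicity(self, rng):
        X, y = simulate_logistic(rng, 500, [1.0, 0.7, -0.5, 0.3, 0.0, 0.0])
        counts = [
            len(fit_l1_logistic(X, y, penalty=a).selected)
            for a in (0.01, 0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_separation_flagged_not_silenced(self):
        X = pd.DataFrame({"f0": np.r_[np.full(20, -2.0), np.full(20, 2.0)]})
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        fit = fit_l1_logistic(X, y, penalty=0.001)
        assert fit.separation_warning
        assert "f0" in fit.coefficients


class TestSequentialFeatureSelection:
    def _grouped(self, rng, n_participants=30, days=10, betas=(1.5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)):
        n = n_participants * days
        X, y = simulate_logistic(rng, n, list(betas))
        groups = np.repeat(np.arange(n_participants), days)
        return X, y, groups

    def test_informative_feature_selected_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y, groups = self._grouped(rng)
            sel = sequential_feature_selection(X, y, groups)
            hits += bool(sel) and sel[0] == "f0"
        assert hits >= 9

    def test_all_noise_selects_nothing_useful(self):
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            X, y, groups = self._grouped(rng, n_participants=50, days=16, betas=(0,) * 8)
            sel = sequential_feature_selection(X, y, groups)
            if sel:
                from sleepbeat.modeling import _grouped_cv_auc

                score = _grouped_cv_auc(
                    X[sel].to_numpy(), y, groups, DEFAULT_ALPHA, 5
                )
                assert score <= 0.55
            assert len(sel) <= 1

    def test_column_order_invariance(self, rng):
        X, y, groups = self._grouped(rng, betas=(1.2, -0.8, 0, 0, 0))
        sel1 = sequential_feature_selection(X, y, groups)
        shuffled = X[list(X.columns[::-1])]
        sel2 = sequential_feature_selection(shuffled, y, groups)
        assert sel1 == sel2

    def test_empty_candidates_rejected(self, rng):
        X, y, groups = self._grouped(rng)
        with pytest.raises(ValueError):
            sequential_feature_selection(X, y, groups, candidates=[])


class TestScopeColumns:
    COLS = [
        "mean_sd1_asleep", "minimum_hr_awake", "sleep_duration", "awake_at_night",
        "mean_stress_awake", "awake_duration", "sleep_medication", "motion_asleep",
    ]

    def test_night_scope(self):
        night = scope_columns(self.COLS, "night")
        assert "mean_sd1_asleep" in night and "sleep_duration" in night
        assert "minimum_hr_awake" not in night and "mean_stress_awake" not in night

    def test_day_scope_excludes_night_columns(self):
        day = scope_columns(self.COLS, "day")
        assert set(day) == {"minimum_hr_awake", "mean_stress_awake", "awake_duration"}

    def test_both_is_union(self):
        both = scope_columns(self.COLS, "both")
        assert set(both) == set(self.COLS)


class TestFitModelFamily:
    def test_day_scope_fits_contain_no_night_features(self, feature_cohort):
        from sleepbeat.simulate import FEATURE_COLUMNS

        profiles, table, truth = feature_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normed = normalize_per_participant(table, FEATURE_COLUMNS + ["sleep_quality"])
        data = normed.data
        y = binarize_sleep_quality(data["sleep_quality"])
        fits = fit_model_family(data, y, FEATURE_COLUMNS, "day", "M1")
        for f in fits:
            for feat in f.selected:
                assert feat.endswith("_awake") or feat == "awake_duration"

    def test_m2_candidates_come_from_joint_selection(self, feature_cohort):
        from sleepbeat.simulate import FEATURE_COLUMNS

        profiles, table, truth = feature_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normed = normalize_per_participant(table, FEATURE_COLUMNS + ["sleep_quality"])
        data = normed.data
        y = binarize_sleep_quality(data["sleep_quality"])
        m1 = fit_model_family(data, y, FEATURE_COLUMNS, "night", "M1")[0]
        m2 = fit_model_family(
            data, y, FEATURE_COLUMNS, "night", "M2", group_labels=table["group"]
        )
        assert {f.group for f in m2} == {"MS", "control"}
        for f in m2:
            assert set(f.selected) <= set(m1.selected)

    def test_sign_stability_across_m1_m2_refits(self, feature_cohort):
        """Homogeneous true effects keep their sign in every group refit."""
        from sleepbeat.simulate import DEFAULT_EFFECT_VECTOR, FEATURE_COLUMNS

        profiles, table, truth = feature_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normed = normalize_per_participant(table, FEATURE_COLUMNS + ["sleep_quality"])
        data = normed.data
        y = binarize_sleep_quality(data["sleep_quality"])
        m1 = fit_model_family(data, y, FEATURE_COLUMNS, "both", "M1")[0]
        m2 = fit_model_family(
            data, y, FEATURE_COLUMNS, "both", "M2", group_labels=table["group"]
        )
        strong = {k for k, v in DEFAULT_EFFECT_VECTOR.items() if abs(v) >= 0.4}
        for f in m2:
            for feat in strong & set(f.selected) & set(m1.selected):
                if f.pvalues.get(feat, 1.0) < 0.10:
                    assert np.sign(f.coefficients[feat]) == np.sign(
                        m1.coefficients[feat]
                    )

    def test_small_group_rejected(self, rng):
        data = pd.DataFrame(
            {
                "participant": np.repeat(["a", "b"], 10),
                "f_asleep": rng.normal(size=20),
            }
        )
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="too few"):
            fit_model_family(
                data, y, ["f_asleep"], "night", "M3",
                group_labels=pd.Series(["MS"] * 10 + ["control"] * 10),
            )
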