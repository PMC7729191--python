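import numpy as np
import pandas as pd
import pytest

import facekin as fk
from facekin.models import (
    ArousalRegression,
    added_variable_data,
    fit_between_group,
    fit_single_predictor,
    fit_within_group,
    flag_outliers,
    refit_excluding,
    specificity_models,
    summarize_ratings,
    zscore,
)

from conftest import standardized_design


def ratings_frame(rows):
    return pd.DataFrame(
        rows, columns=["rater_id", "group", "clip_id", "arousal", "valence"]
    )


class TestSummarizeRatings:
    def test_means_and_counts(self):
        recs = ratings_frame(
            [("r1", "NT", "c1", 40, 50), ("r2", "NT", "c1", 60, 70),
             ("r3", "NT", "c2", 30, 30), ("r1", "ASD", "c1", 90, 90)]
        )
        out = summarize_ratings(recs, "NT")
        assert out.loc["c1", "mean_arousal"] == 50
        assert out.loc["c1", "n_raters"] == 2
        assert out.loc["c2", "n_raters"] == 1

    def test_unrated_clip_absent(self):
        recs = ratings_frame([("r1", "NT", "c1", 40, 50)])
        assert "c2" not in summarize_ratings(recs, "NT").index

    def test_missing_group_rejected(self):
        recs = ratings_frame([("r1", "NT", "c1", 40, 50)])
        with pytest.raises(ValueError, match="HAT"):
            summarize_ratings(recs, "HAT")


class TestZscore:
    def test_hand_case(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_moments(self, rng):
        z = zscore(rng.normal(5, 3, 100))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(zscore(7 * x + 3), zscore(x), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestArousalRegression:
    def test_noiseless_fit_recovers_coefficients(self, rng):
        x = rng.normal(size=40)
        y = 10 + 2 * x
        est = ArousalRegression(zscore_x=False)
        est.fit(pd.DataFrame({"x1": x}), y)
        assert est.intercept_ == pytest.approx(10.0)
        assert est.coef_[0] == pytest.approx(2.0)
        assert est.fit_.r_squared == pytest.approx(1.0)

    def test_ols_matches_normal_equations(self, rng):
        """Independent oracle: brute-force normal-equations solve."""
        for _ in range(10):
            X = rng.normal(size=(25, 3))
            y = rng.normal(size=25)
            est = ArousalRegression(zscore_x=False).fit(pd.DataFrame(X), y)
            A = np.column_stack([np.ones(25), X])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            np.testing.assert_allclose(
                np.concatenate([[est.intercept_], est.coef_]), beta, atol=1e-10
            )
            # hat diagonal from the explicit projection matrix
            H = A @ np.linalg.inv(A.T @ A) @ A.T
            np.testing.assert_allclose(
                est.fit_.hat_values.to_numpy(), np.diag(H), atol=1e-10
            )

    def test_intercept_of_zscored_model_is_mean_response(self, rng):
        X = pd.DataFrame({"a": rng.normal(5, 2, 30), "b": rng.normal(1, 3, 30)})
        y = rng.normal(50, 10, 30)
        est = ArousalRegression().fit(X, y)
        assert est.intercept_ == pytest.approx(float(np.mean(y)))

    def test_simple_standardized_slope_equals_pearson_r(self, rng):
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(size=60)
        est = ArousalRegression().fit(pd.DataFrame({"x": x}), y)
        r = np.corrcoef(x, y)[0, 1]
        assert est.fit_.std_params["x"] == pytest.approx(r)
        assert est.fit_.r_squared == pytest.approx(r**2)

    def test_standardized_variant_matches_refit(self, rng):
        """Scaling the fit equals literally refitting on the z-scored response."""
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(50, 20, 40))
        plain = ArousalRegression().fit(X, y).fit_
        std = ArousalRegression(zscore_y=True).fit(X, y).fit_
        np.testing.assert_allclose(plain.std_params, std.params, atol=1e-12)
        np.testing.assert_allclose(plain.std_conf_int, std.conf_int, atol=1e-12)
        assert plain.r_squared == pytest.approx(std.r_squared)

    def test_r2_from_correlated_standardized_construct(self):
        X, y, r2 = standardized_design(80, r=0.51, b1=0.28, b2=0.12)
        fit = ArousalRegression().fit(X, y).fit_
        assert fit.std_params["dist_neutral_mean"] == pytest.approx(0.28)
        assert fit.std_params["speed_mean"] == pytest.approx(0.12)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert round(fit.r_squared, 2) == 0.13

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            ArousalRegression(zscore_x=False).fit(X, rng.normal(size=30))

    def test_mean_hat_is_k_over_n(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        fit = ArousalRegression().fit(X, rng.normal(size=80)).fit_
        assert fit.hat_values.mean() == pytest.approx(3 / 80)
        assert fit.hat_values.sum() == pytest.approx(3.0)
        assert ((fit.hat_values > 0) & (fit.hat_values <= 1)).all()

    def test_predict_on_training_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = 3 + X["a"] - 2 * X["b"]
        est = ArousalRegression().fit(X, y)
        np.testing.assert_allclose(est.predict(X), y, atol=1e-10)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = ArousalRegression(ci_level=0.9)
        assert clone(est).get_params()["ci_level"] == 0.9


class TestGroupFits:
    def _features(self, rng, n=40):
        return pd.DataFrame(
            {
                "dist_neutral_mean": rng.uniform(0.01, 0.1, n),
                "speed_mean": rng.uniform(0.001, 0.01, n),
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="clip_id"),
        )

    def _summary(self, features, arousal):
        return pd.DataFrame(
            {
                "mean_arousal": arousal,
                "mean_valence": np.full(len(features), 50.0),
                "n_raters": np.full(len(features), 5),
            },
            index=features.index,
        )

    def test_identical_groups_give_zero_difference_model(self, rng):
        features = self._features(rng)
        arousal = rng.uniform(30, 70, len(features))
        s = self._summary(features, arousal)
        fit = fit_between_group(features, s, s)
        np.testing.assert_allclose(fit.params, 0.0, atol=1e-12)

    def test_constant_offset_recovered_exactly(self, rng):
        features = self._features(rng)
        arousal = rng.uniform(30, 70, len(features))
        s_nt = self._summary(features, arousal)
        s_asd = self._summary(features, arousal - 4.29)
        fit = fit_between_group(features, s_nt, s_asd)
        assert fit.params["const"] == pytest.approx(4.29, abs=1e-10)
        assert abs(fit.params["dist_neutral_mean"]) < 1e-10
        assert abs(fit.params["speed_mean"]) < 1e-10

    def test_null_difference_ci_coverage(self, rng):
        """With no true group slope difference, slope CIs cover 0 in >=90%."""
        features = self._features(rng, n=60)
        covered = 0
        for i in range(100):
            arousal = rng.uniform(30, 70, 60)
            s_nt = self._summary(features, arousal + rng.normal(0, 5, 60))
            s_asd = self._summary(features, arousal + rng.normal(0, 5, 60))
            fit = fit_between_group(features, s_nt, s_asd)
            lo, hi = fit.conf_int.loc["dist_neutral_mean"]
            covered += int(lo <= 0 <= hi)
        assert covered >= 90

    def test_single_predictor_r2_is_squared_std_slope(self, rng):
        features = self._features(rng)
        s = self._summary(
            features, 40 + 100 * features["dist_neutral_mean"]
            + rng.normal(0, 3, len(features))
        )
        fit = fit_single_predictor(features, s, "NT", "dist_neutral_mean")
        assert fit.r_squared == pytest.approx(
            float(fit.std_params["dist_neutral_mean"]) ** 2
        )

    @pytest.mark.parametrize("slope,r2_2dp", [(0.34, 0.12), (0.26, 0.07)])
    def test_single_predictor_r2_constructs(self, slope, r2_2dp):
        X, y, _ = standardized_design(80, r=0.0, b1=slope, b2=0.0)
        features = X
        s = pd.DataFrame(
            {"mean_arousal": y, "mean_valence": 50.0, "n_raters": 5},
            index=X.index,
        )
        fit = fit_single_predictor(features, s, "NT", "dist_neutral_mean")
        assert fit.std_params["dist_neutral_mean"] == pytest.approx(slope)
        assert round(fit.r_squared, 2) == r2_2dp


class TestOutliersAndDiagnostics:
    def _features(self, rng, n=30):
        return pd.DataFrame(
            {
                "dist_neutral_mean": rng.normal(0.05, 0.01, n),
                "speed_mean": rng.normal(0.005, 0.001, n),
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="clip_id"),
        )

    def test_homogeneous_data_not_flagged(self, rng):
        report = flag_outliers(self._features(rng))
        assert report.flagged == []

    def test_extreme_point_flagged(self, rng):
        features = self._features(rng)
        x = features["dist_neutral_mean"].copy()
        others = x.drop("c0")
        features.loc["c0", "dist_neutral_mean"] = (
            others.mean() + 10 * others.std(ddof=1)
        )
        report = flag_outliers(features)
        assert report.flagged == ["c0"]
        assert report.loo_z["c0"] > 4

    def test_infinite_threshold_flags_nothing(self, rng):
        features = self._features(rng)
        features.loc["c0", "dist_neutral_mean"] = 10.0
        assert flag_outliers(features, threshold=np.inf).flagged == []

    def test_loo_z_matches_naive_computation(self, rng):
        features = self._features(rng, n=12)
        report = flag_outliers(features)
        x = features["dist_neutral_mean"]
        for cid in features.index:
            rest = x.drop(cid)
            expected = abs(x[cid] - rest.mean()) / rest.std(ddof=1)
            assert report.loo_z[cid] == pytest.approx(expected, rel=1e-9)

    def test_refit_with_empty_flag_set_identical(self, rng):
        features = self._features(rng)
        y = pd.Series(
            rng.normal(50, 10, len(features)), index=features.index,
            name="mean_arousal",
        )
        report = flag_outliers(features)
        base = fit_within_group(
            features,
            pd.DataFrame({"mean_arousal": y, "mean_valence": 50.0, "n_raters": 3}),
            "NT",
        )
        refit = refit_excluding(features, y, report)
        np.testing.assert_allclose(refit.params, base.params, atol=1e-12)

    def test_removing_low_outlier_below_trend_steepens_slope(self, rng):
        """A high-leverage point sitting under the trend drags the slope down;
        excluding it must increase the estimate."""
        n = 30
        x = np.linspace(0, 1, n)
        y = 10 * x + rng.normal(0, 0.3, n)
        features = pd.DataFrame(
            {"dist_neutral_mean": x, "speed_mean": rng.normal(size=n)},
            index=[f"c{i}" for i in range(n)],
        )
        features.loc["c29", "dist_neutral_mean"] = 3.0   # far right ...
        y[29] = 5.0                                       # ... far below trend
        ys = pd.Series(y, index=features.index)
        report = flag_outliers(features)
        assert "c29" in report.flagged
        full = refit_excluding(
            features, ys, flag_outliers(features, threshold=np.inf)
        )
        reduced = refit_excluding(features, ys, report)
        assert (
            reduced.params["dist_neutral_mean"]
            > full.params["dist_neutral_mean"]
        )
        assert reduced.df_resid == full.df_resid - len(report.flagged)

    def test_added_variable_slope_equals_full_model_coefficient(self, rng):
        """Frisch-Waugh: the added-variable slope reproduces the coefficient."""
        for r in (0.0, 0.51):
            X, y, _ = standardized_design(60, r=r, b1=0.4, b2=0.2, seed=7)
            fit = ArousalRegression().fit(X, y).fit_
            for pred in X.columns:
                av = added_variable_data(fit, pred)
                slope = np.polyfit(av["x_partial"], av["y_partial"], 1)[0]
                assert slope == pytest.approx(
                    float(fit.params[pred]), abs=1e-10
                )

    def test_added_variable_orthogonal_predictors(self):
        X, y, _ = standardized_design(50, r=0.0, b1=0.4, b2=0.2, seed=9)
        fit = ArousalRegression().fit(X, y).fit_
        av = added_variable_data(fit, "dist_neutral_mean")
        np.testing.assert_allclose(
            av["x_partial"],
            X["dist_neutral_mean"] - X["dist_neutral_mean"].mean(),
            atol=1e-10,
        )

    def test_added_variable_needs_two_predictors(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        fit = ArousalRegression().fit(X, rng.normal(size=20)).fit_
        with pytest.raises(ValueError):
            added_variable_data(fit, "a")


class TestSpecificity:
    def test_valence_copy_of_arousal_gives_identical_fits(self, rng):
        features = pd.DataFrame(
            {
                "dist_neutral_mean": rng.uniform(0.01, 0.1, 30),
                "speed_mean": rng.uniform(0.001, 0.01, 30),
            },
            index=[f"c{i}" for i in range(30)],
        )
        arous = rng.uniform(30, 70, 30)
        s = pd.DataFrame(
            {"mean_arousal": arous, "mean_valence": arous, "n_raters": 4},
            index=features.index,
        )
        val = specificity_models(features, {"NT": s})["valence_NT"]
        aro = fit_within_group(features, s, "NT")
        np.testing.assert_allclose(val.params, aro.params, atol=1e-12)

    def test_independent_valence_cis_cover_zero(self, small_study):
        """Valence is generated independently of the kinematics, so its slope
        CIs should cover zero."""
        summ = {
            g: summarize_ratings(small_study.ratings, g) for g in ("NT", "ASD")
        }
        fits = specificity_models(small_study.features, summ)
        covered = 0
        total = 0
        for fit in fits.values():
            for term in ("dist_neutral_mean", "speed_mean"):
                lo, hi = fit.conf_int.loc[term]
                covered += int(lo <= 0 <= hi)
                total += 1
        assert covered >= total - 1

    def test_empty_summaries_rejected(self, rng):
        with pytest.raises(ValueError):
            specificity_models(pd.DataFrame(), {})
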