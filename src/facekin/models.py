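"""Rating summarization and the arousal / valence regression models.

Per-clip mean ratings (per group) are regressed on the z-scored kinematic
predictors with ordinary least squares:

    Arousal_G = b0_G + b1_G * Distance + b2_G * Speed + e          (within group)
    Arousal_NT - Arousal_ASD = b0 + b1 * Distance + b2 * Speed + e (between groups)

Predictors are z-scored over the analysis clip set; the standardized variant
additionally z-scores the response, so standardized slopes are the usual
fully-standardized coefficients.  Confidence intervals are t-based.  Leverage
(hat) diagnostics, a leave-one-out outlier rule on the distance predictor,
outlier re-fits and added-variable (partial-residual) data support the model
criticism around high-leverage clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_PREDICTORS = ("dist_neutral_mean", "speed_mean")


def summarize_ratings(records: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-clip mean arousal/valence for one group.

    Clips without any rating in the group are simply absent: assignment of
    raters to clips is random (missing completely at random), so per-clip
    means remain unbiased.
    """
    if len(records) == 0:
        raise ValueError("no rating records")
    sub = records[records["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no ratings for group {group!r}")
    out = sub.groupby("clip_id").agg(
        mean_arousal=("arousal", "mean"),
        mean_valence=("valence", "mean"),
        n_raters=("arousal", "size"),
    )
    out.attrs["group"] = group
    return out


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined for zero-variance input")
    return (arr - arr.mean()) / sd


@dataclass
class RegressionFit:
    """One fitted OLS model with the quantities the report tables need."""

    label: str
    params: pd.Series
    conf_int: pd.DataFrame            # columns: low, high
    pvalues: pd.Series
    bse: pd.Series
    std_params: pd.Series             # fully standardized coefficients
    std_conf_int: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    resid_se: float
    df_resid: int
    f_statistic: float
    f_pvalue: float
    nobs: int
    hat_values: pd.Series
    residuals: pd.Series
    design: pd.DataFrame = field(repr=False)   # z-scored predictors, no const
    response: pd.Series = field(repr=False)

    @property
    def predictors(self) -> list[str]:
        return list(self.design.columns)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, CI, p and standardized analogues."""
        return pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": self.conf_int["low"],
                "ci_high": self.conf_int["high"],
                "p_value": self.pvalues,
                "std_estimate": self.std_params,
                "std_ci_low": self.std_conf_int["low"],
                "std_ci_high": self.std_conf_int["high"],
            }
        )

    def summary_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": {
                term: {
                    "estimate": float(self.params[term]),
                    "ci": [
                        float(self.conf_int.loc[term, "low"]),
                        float(self.conf_int.loc[term, "high"]),
                    ],
                    "p_value": float(self.pvalues[term]),
                    "std_estimate": float(self.std_params[term]),
                }
                for term in self.params.index
            },
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "resid_se": self.resid_se,
            "df_resid": self.df_resid,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "nobs": self.nobs,
        }


class ArousalRegression(BaseEstimator, RegressorMixin):
    """Sklearn-style OLS with the inference the rating analysis reports.

    Parameters
    ----------
    predictors : sequence of str or None
        Columns of X to use (all columns when None).
    zscore_x : bool
        Standardize predictors over the fitted clip set (default True, the
        tables' "[Z-score]" convention); the scaling is reused in predict.
    zscore_y : bool
        Additionally standardize the response (the "standardized" model
        columns).
    ci_level : float
        Two-sided confidence level for the t-based intervals.

    Fitted attributes include ``coef_``, ``intercept_``, ``conf_int_``,
    ``pvalues_``, ``r_squared_``, ``adj_r_squared_``, ``hat_values_`` and the
    full :class:`RegressionFit` under ``fit_``.
    """

    def __init__(
        self,
        predictors=None,
        zscore_x: bool = True,
        zscore_y: bool = False,
        ci_level: float = 0.95,
        label: str = "ols",
    ):
        self.predictors = predictors
        self.zscore_x = zscore_x
        self.zscore_y = zscore_y
        self.ci_level = ci_level
        self.label = label

    def _design(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=float),
                columns=[f"x{i}" for i in range(np.asarray(X).shape[1])],
            )
        if self.predictors is not None:
            missing = [p for p in self.predictors if p not in X.columns]
            if missing:
                raise ValueError(f"missing predictor column(s) {missing}")
            X = X[list(self.predictors)]
        return X.astype(float)

    def fit(self, X, y):
        X = self._design(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
        n, k = X.shape
        if n < k + 2:
            raise ValueError(f"need at least {k + 2} observations, got {n}")
        self.x_mean_ = X.mean()
        self.x_sd_ = X.std(ddof=1)
        if self.zscore_x:
            if (self.x_sd_ == 0).any():
                dead = list(self.x_sd_.index[self.x_sd_ == 0])
                raise ValueError(f"zero-variance predictor(s) {dead}")
            Xz = (X - self.x_mean_) / self.x_sd_
        else:
            Xz = X
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std(ddof=1))
        if self.zscore_y:
            if self.y_sd_ == 0:
                raise ValueError("zero-variance response")
            yt = (y - self.y_mean_) / self.y_sd_
        else:
            yt = y

        design = sm.add_constant(Xz, has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise ValueError("rank-deficient design matrix")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(yt, design).fit()
        # a constant response makes R^2/F undefined; report NaN, not -inf
        r_squared = float(res.rsquared)
        if not np.isfinite(r_squared):
            r_squared = float("nan")
        alpha = 1 - self.ci_level
        ci = res.conf_int(alpha=alpha)
        ci.columns = ["low", "high"]

        # fully standardized coefficients: the estimates of the model with the
        # response additionally z-scored (slopes in SDs of y per SD of x, the
        # intercept re-centered); a linear rescaling of the same fit
        if self.zscore_y:
            std_params = res.params.copy()
            std_ci = ci.copy()
        else:
            y_sd = self.y_sd_ if self.y_sd_ > 0 else 1.0
            x_sd = (
                pd.Series(1.0, index=Xz.columns)
                if self.zscore_x
                else self.x_sd_
            )
            scale = pd.concat([pd.Series({"const": 1.0}), x_sd]) / y_sd
            shift = pd.Series(0.0, index=res.params.index)
            x_bar = 0.0 if self.zscore_x else float(
                (res.params.drop("const") * X.mean()).sum()
            )
            shift["const"] = (self.y_mean_ - x_bar) / y_sd
            std_params = res.params * scale - shift
            std_ci = ci.mul(scale, axis=0).sub(shift, axis=0)

        influence_hat = pd.Series(
            res.get_influence().hat_matrix_diag, index=Xz.index
        )
        self.results_ = res
        self.coef_ = res.params.drop("const").to_numpy()
        self.intercept_ = float(res.params["const"])
        self.conf_int_ = ci
        self.pvalues_ = res.pvalues
        self.r_squared_ = r_squared
        self.adj_r_squared_ = (
            float(res.rsquared_adj) if np.isfinite(res.rsquared_adj)
            else float("nan")
        )
        self.hat_values_ = influence_hat
        self.fit_ = RegressionFit(
            label=self.label,
            params=res.params,
            conf_int=ci,
            pvalues=res.pvalues,
            bse=res.bse,
            std_params=std_params,
            std_conf_int=std_ci,
            r_squared=r_squared,
            adj_r_squared=float(res.rsquared_adj)
            if np.isfinite(res.rsquared_adj) else float("nan"),
            resid_se=float(np.sqrt(res.mse_resid)),
            df_resid=int(res.df_resid),
            f_statistic=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            nobs=int(res.nobs),
            hat_values=influence_hat,
            residuals=pd.Series(res.resid, index=Xz.index),
            design=Xz,
            response=yt,
        )
        return self

    def predict(self, X):
        if not hasattr(self, "results_"):
            raise ValueError("ArousalRegression is not fitted")
        X = self._design(X)
        Xz = (X - self.x_mean_) / self.x_sd_ if self.zscore_x else X
        design = sm.add_constant(Xz, has_constant="add")
        # with zscore_y the predictions stay on the standardized scale
        return np.asarray(self.results_.predict(design))


def _join(features: pd.DataFrame, response: pd.Series) -> pd.DataFrame:
    df = features.join(response.rename("y"), how="inner")
    if df.isna().to_numpy().any():
        raise ValueError("missing values after joining features and ratings")
    return df


def _fit(
    features: pd.DataFrame,
    response: pd.Series,
    predictors,
    label: str,
    ci_level: float = 0.95,
) -> RegressionFit:
    df = _join(features[list(predictors)], response)
    est = ArousalRegression(
        predictors=list(predictors), ci_level=ci_level, label=label
    )
    est.fit(df[list(predictors)], df["y"])
    return est.fit_


def fit_within_group(
    features: pd.DataFrame,
    summaries: pd.DataFrame,
    group: str,
    predictors=DEFAULT_PREDICTORS,
    response: str = "mean_arousal",
    ci_level: float = 0.95,
) -> RegressionFit:
    """One group's ratings regressed on the z-scored kinematic predictors."""
    return _fit(
        features,
        summaries[response],
        predictors,
        label=f"{response}~{'+'.join(predictors)}|{group}",
        ci_level=ci_level,
    )


def fit_between_group(
    features: pd.DataFrame,
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    response: str = "mean_arousal",
    ci_level: float = 0.95,
    label: str = "difference",
) -> RegressionFit:
    """Difference of the two groups' per-clip means regressed on predictors.

    A nonzero intercept indicates a mean rating offset between the groups;
    nonzero slopes would indicate group differences in how the kinematic
    measures relate to the ratings.
    """
    diff = (summaries_a[response] - summaries_b[response]).dropna()
    if len(diff) == 0:
        raise ValueError("no clips rated in both groups")
    return _fit(features, diff, predictors, label=label, ci_level=ci_level)


def fit_single_predictor(
    features: pd.DataFrame,
    summaries: pd.DataFrame,
    group: str,
    predictor: str,
    response: str = "mean_arousal",
    ci_level: float = 0.95,
) -> RegressionFit:
    """Within-group model with a single predictor."""
    return fit_within_group(
        features, summaries, group, (predictor,), response, ci_level
    )


def hat_values(fit: RegressionFit) -> pd.Series:
    """Leverage of each observation: diagonal of the OLS hat matrix.

    Values lie in (0, 1] and average to (number of coefficients) / n.
    """
    return fit.hat_values


@dataclass
class OutlierReport:
    """Observations flagged by the leave-one-out distance rule."""

    predictor: str
    threshold: float
    loo_z: pd.Series                  # |x_i - mean_{-i}| / sd_{-i}
    flagged: list
    hat_values: pd.Series | None = None


def flag_outliers(
    features: pd.DataFrame,
    predictor: str = "dist_neutral_mean",
    threshold: float = 4.0,
    fit: RegressionFit | None = None,
) -> OutlierReport:
    """Flag clips extreme on one predictor by a leave-one-out z-distance.

    Observation i is flagged when its distance from the mean of the remaining
    observations exceeds ``threshold`` of their standard deviations.  The
    reference clips were singled out visually in an added-variable plot, so
    the numeric rule (default 4 SD) is a configurable approximation.
    """
    x = features[predictor].astype(float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    total, total_sq = x.sum(), (x**2).sum()
    loo_mean = (total - x) / (n - 1)
    loo_var = (total_sq - x**2 - (n - 1) * loo_mean**2) / (n - 2)
    loo_sd = np.sqrt(loo_var.clip(lower=0))
    z = (x - loo_mean).abs() / loo_sd
    flagged = list(x.index[z > threshold])
    hats = None
    if fit is not None:
        hats = fit.hat_values.reindex(x.index)
    return OutlierReport(predictor, threshold, z, flagged, hats)


def refit_excluding(
    features: pd.DataFrame,
    response: pd.Series,
    report: OutlierReport,
    predictors=DEFAULT_PREDICTORS,
    ci_level: float = 0.95,
    label: str = "refit",
) -> RegressionFit:
    """Re-fit the model with the flagged clips removed."""
    keep = [i for i in features.index if i not in set(report.flagged)]
    if len(keep) < len(predictors) + 2:
        raise ValueError("too few observations remain after exclusion")
    return _fit(
        features.loc[keep],
        response.loc[[i for i in response.index if i in set(keep)]],
        predictors,
        label=label,
        ci_level=ci_level,
    )


def added_variable_data(fit: RegressionFit, predictor: str) -> pd.DataFrame:
    """Partial-residual pairs for one predictor of a multi-predictor fit.

    Regress the response and the predictor on all *other* predictors (with
    intercept); the OLS slope through the resulting residual pairs equals the
    predictor's coefficient in the full model (Frisch-Waugh).
    """
    if len(fit.predictors) < 2:
        raise ValueError("added-variable data needs at least two predictors")
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} is not in the fitted model")
    others = [p for p in fit.predictors if p != predictor]
    Z = sm.add_constant(fit.design[others], has_constant="add")
    y_res = sm.OLS(fit.response, Z).fit().resid
    x_res = sm.OLS(fit.design[predictor], Z).fit().resid
    return pd.DataFrame(
        {"x_partial": x_res, "y_partial": y_res}, index=fit.design.index
    )


def specificity_models(
    features: pd.DataFrame,
    summaries_by_group: dict[str, pd.DataFrame],
    predictors=DEFAULT_PREDICTORS,
    ci_level: float = 0.95,
) -> dict[str, RegressionFit]:
    """The arousal models repeated with valence as the response.

    With predictors specific to arousal, none of the valence coefficients
    should be distinguishable from zero.
    """
    if not summaries_by_group:
        raise ValueError("no group summaries supplied")
    fits: dict[str, RegressionFit] = {}
    for group, summ in summaries_by_group.items():
        fits[f"valence_{group}"] = fit_within_group(
            features, summ, group, predictors, "mean_valence", ci_level
        )
    groups = list(summaries_by_group)
    if len(groups) >= 2:
        a, b = groups[0], groups[1]
        fits[f"valence_{a}-{b}"] = fit_between_group(
            features,
            summaries_by_group[a],
            summaries_by_group[b],
            predictors,
            "mean_valence",
            ci_level,
            label=f"valence {a}-{b}",
        )
    return fits
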