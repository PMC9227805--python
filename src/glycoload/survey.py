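"""Survey-weighted estimation under stratified cluster sampling.

Point estimates are weighted least squares; variances use first-stage
with-replacement Taylor linearization: per-observation score contributions
``z_i = w_i x_i e_i`` are summed to PSU totals, and within each sampling
stratum h with n_h PSUs the variance of the estimated total is

    V = Σ_h  n_h/(n_h − 1) Σ_c (z_hc − z̄_h)(z_hc − z̄_h)'

which sandwiches to ``cov(β̂) = (X'WX)⁻¹ V (X'WX)⁻¹``. No finite-population
correction is applied (school sampling fractions unknown). Inference uses a
t reference with the design degrees of freedom, df = #PSUs − #strata. The
same linearization drives survey means and their confidence intervals, so
descriptive and regression output share one variance engine.

Robust SEs are invariant to rescaling all weights by a positive constant;
with equal weights, a single stratum and one unit per PSU the point
estimates collapse to ordinary least squares. Both facts are exercised in
the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateStandardizationError,
    LonelyPSUError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

METRICS = ["dgi", "av_gi", "dgl", "av_gl"]
DEFAULT_COVARIATES = ["female", "age_years", "maturation"]  # + PA category dummies


@dataclass
class RegressionResult:
    marker: str
    metric: str
    stratum_group: str
    beta: float
    se: float
    p_value: float
    n_used: int
    df: int


def standardize(values, weights=None) -> np.ndarray:
    """Weighted z-scores: weighted mean 0, weighted SD 1.

    The SD uses the population convention (divide by the sum of weights).
    Constant input raises :class:`DegenerateStandardizationError`.
    Idempotent: standardizing a standardized column is the identity.
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if x.shape != w.shape:
        raise ValueError("values and weights must have the same shape")
    mean = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - mean) ** 2, weights=w))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateStandardizationError(f"constant or non-finite input (sd={sd})")
    return (x - mean) / sd


def _taylor_cov(
    scores: np.ndarray,
    stratum: np.ndarray,
    psu: np.ndarray,
    lonely_psu: str = "error",
) -> tuple[np.ndarray, int, int]:
    """Taylor-linearized covariance of a vector of estimated totals.

    ``scores`` is n×k; returns ``(V, n_psu, n_strata)`` after any lonely-PSU
    merging. ``lonely_psu``: ``"error"`` raises; ``"merge"`` folds each
    single-PSU stratum into the adjacent stratum in sorted label order.
    """
    df = pd.DataFrame(scores)
    df["_stratum"] = np.asarray(stratum).astype(str)
    df["_psu"] = np.asarray(psu).astype(str)

    totals = df.groupby(["_stratum", "_psu"], sort=True).sum()
    counts = totals.groupby(level="_stratum").size()
    lonely = counts.index[counts < 2].tolist()
    if lonely:
        if lonely_psu == "merge":
            order = counts.index.tolist()
            mapping = {}
            for s in lonely:
                i = order.index(s)
                neighbours = [t for t in (order[i - 1 :: -1] if i else []) if t not in lonely]
                if not neighbours:
                    neighbours = [t for t in order[i + 1 :] if t not in lonely]
                if not neighbours:
                    raise LonelyPSUError(lonely)
                mapping[s] = neighbours[0]
            logger.warning("merging lonely strata into neighbours: %s", mapping)
            new_stratum = pd.Series(np.asarray(stratum).astype(str)).replace(mapping).to_numpy()
            return _taylor_cov(scores, new_stratum, psu, lonely_psu="error")
        raise LonelyPSUError(lonely)

    k = scores.shape[1]
    V = np.zeros((k, k))
    n_psu = 0
    for _, t in totals.groupby(level="_stratum"):
        z = t.to_numpy(dtype=float)
        n_h = z.shape[0]
        n_psu += n_h
        dev = z - z.mean(axis=0)
        V += (n_h / (n_h - 1)) * dev.T @ dev
    return V, n_psu, int(counts.size)


@dataclass
class SurveyOLSResult:
    """Weighted least-squares fit with design-based (Taylor) covariance."""

    params: pd.Series
    cov: pd.DataFrame
    df: int
    n_obs: int
    n_psu: int
    n_strata: int

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def t_values(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def p_values(self) -> pd.Series:
        t = self.t_values.to_numpy(dtype=float)
        p = np.where(
            np.isfinite(t), 2 * stats.t.sf(np.abs(t), self.df), np.where(np.isnan(t), np.nan, 0.0)
        )
        return pd.Series(p, index=self.params.index)


def weighted_ols(
    y,
    X: pd.DataFrame,
    stratum,
    psu,
    weight,
    lonely_psu: str = "error",
) -> SurveyOLSResult:
    """Survey-weighted linear regression with cluster-robust (Taylor) variance.

    ``X`` must include any intercept column explicitly. Rank deficiency
    raises :class:`SingularDesignError` naming the collinear columns.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("sampling weights must be positive")
    n, k = Xv.shape

    Xs = Xv * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xs)
    if rank < k:
        # pivoted QR flags the columns beyond the numerical rank
        _, _, piv = _qr_pivot(Xs)
        bad = [X.columns[j] for j in sorted(piv[rank:])]
        raise SingularDesignError(bad)

    XtWX = Xv.T @ (w[:, None] * Xv)
    XtWy = Xv.T @ (w * yv)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yv - Xv @ beta

    scores = w[:, None] * Xv * resid[:, None]
    V, n_psu, n_strata = _taylor_cov(scores, stratum, psu, lonely_psu=lonely_psu)
    A_inv = np.linalg.inv(XtWX)
    cov = A_inv @ V @ A_inv
    cols = list(X.columns)
    return SurveyOLSResult(
        params=pd.Series(beta, index=cols),
        cov=pd.DataFrame(cov, index=cols, columns=cols),
        df=n_psu - n_strata,
        n_obs=n,
        n_psu=n_psu,
        n_strata=n_strata,
    )


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    return qr(A, mode="economic", pivoting=True)


def survey_mean(y, stratum, psu, weight, lonely_psu: str = "error") -> dict:
    """Design-based mean with Taylor-linearized SE and 95% t confidence interval."""
    yv = np.asarray(y, dtype=float)
    w = np.asarray(weight, dtype=float)
    keep = ~np.isnan(yv)
    yv, w = yv[keep], w[keep]
    stratum = np.asarray(stratum)[keep]
    psu = np.asarray(psu)[keep]
    if yv.size == 0:
        return {"mean": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0}
    wsum = w.sum()
    mean = float(np.sum(w * yv) / wsum)
    scores = (w * (yv - mean) / wsum)[:, None]
    V, n_psu, n_strata = _taylor_cov(scores, stratum, psu, lonely_psu=lonely_psu)
    se = float(np.sqrt(V[0, 0]))
    df = n_psu - n_strata
    tcrit = stats.t.ppf(0.975, df) if df > 0 else np.nan
    return {
        "mean": mean,
        "se": se,
        "ci_low": mean - tcrit * se,
        "ci_high": mean + tcrit * se,
        "n": int(yv.size),
    }


# ---------------------------------------------------------------------------
# model grid


def _model_frame(
    students: pd.DataFrame, metrics_df: pd.DataFrame
) -> pd.DataFrame:
    df = students.merge(metrics_df, on="student_id", how="inner", validate="one_to_one")
    return df


def fit_marker_model(
    df: pd.DataFrame,
    marker: str,
    metric: str,
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    lonely_psu: str = "error",
    metric_z: Optional[str] = None,
) -> tuple[RegressionResult, SurveyOLSResult]:
    """Fit one marker ~ z(metric) + covariates model on a prepared subset.

    Listwise-deletes rows missing the marker, metric or any covariate, then
    standardizes the metric within the fitted subset (weighted moments)
    unless ``metric_z`` names a pre-standardized column. The standardized
    column's weighted mean/SD are asserted on every fit.
    """
    needed = [marker, metric, "stratum", "psu", "weight", "pa_category", *covariates]
    sub = df.dropna(subset=[c for c in needed if c in df.columns]).copy()
    sub = sub[sub["pa_category"].notna()]

    w = sub["weight"].to_numpy(dtype=float)
    if metric_z is None:
        z = standardize(sub[metric].to_numpy(), w)
    else:
        z = sub[metric_z].to_numpy(dtype=float)
    zm = np.average(z, weights=w)
    zs = np.sqrt(np.average((z - zm) ** 2, weights=w))
    if metric_z is None:
        assert abs(zm) < 1e-8 and abs(zs - 1) < 1e-8, "metric standardization violated"

    X = pd.DataFrame({"const": 1.0, f"z_{metric}": z}, index=sub.index)
    for c in covariates:
        X[c] = sub[c].astype(float)
    for cat in ["insufficiently_active", "active"]:  # baseline: inactive
        X[f"pa_{cat}"] = (sub["pa_category"] == cat).astype(float)

    fit = weighted_ols(
        sub[marker].to_numpy(dtype=float),
        X,
        sub["stratum"].to_numpy(),
        sub["psu"].to_numpy(),
        w,
        lonely_psu=lonely_psu,
    )
    name = f"z_{metric}"
    res = RegressionResult(
        marker=marker,
        metric=metric,
        stratum_group=str(sub["weight_stratum"].iloc[0]) if "weight_stratum" in sub else "all",
        beta=float(fit.params[name]),
        se=float(fit.se[name]),
        p_value=float(fit.p_values[name]),
        n_used=fit.n_obs,
        df=fit.df,
    )
    return res, fit


def fit_model_grid(
    students: pd.DataFrame,
    metrics_df: pd.DataFrame,
    markers: Sequence[str] = ("hba1c", "insulin", "homa_ir"),
    metrics: Sequence[str] = tuple(METRICS),
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    standardization_scope: str = "within_stratum",
    lonely_psu: str = "error",
) -> pd.DataFrame:
    """Fit the full marker × metric × weight-stratum grid.

    4 metrics × 3 markers × 2 strata = 24 models when both strata are
    populated; an empty stratum is logged and its rows are absent. Each model
    standardizes its metric within the fitted subset by default
    (``standardization_scope="within_stratum"``); ``"whole_sample"``
    standardizes once across both strata before splitting.
    """
    if standardization_scope not in {"within_stratum", "whole_sample"}:
        raise ValueError(f"unknown standardization scope {standardization_scope!r}")
    df = _model_frame(students, metrics_df)

    zcols = {}
    if standardization_scope == "whole_sample":
        for m in metrics:
            ok = df[m].notna()
            zname = f"_z_whole_{m}"
            df[zname] = np.nan
            df.loc[ok, zname] = standardize(
                df.loc[ok, m].to_numpy(), df.loc[ok, "weight"].to_numpy()
            )
            zcols[m] = zname

    rows = []
    for group in ["NW", "OW"]:
        sub = df[df["weight_stratum"] == group]
        if sub.empty:
            logger.warning("weight stratum %s is empty; its 12 models are absent", group)
            continue
        for marker, metric in itertools.product(markers, metrics):
            res, _ = fit_marker_model(
                sub,
                marker,
                metric,
                covariates=covariates,
                lonely_psu=lonely_psu,
                metric_z=zcols.get(metric),
            )
            rows.append(
                {
                    "stratum_group": group,
                    "marker": marker,
                    "metric": metric,
                    "beta": res.beta,
                    "se": res.se,
                    "p_value": res.p_value,
                    "n_used": res.n_used,
                    "df": res.df,
                }
            )
    return pd.DataFrame(
        rows, columns=["stratum_group", "marker", "metric", "beta", "se", "p_value", "n_used", "df"]
    )
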