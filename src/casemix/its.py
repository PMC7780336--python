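"""Single-group interrupted time-series (ITS) estimation.

Segmented regression of a monthly CMI series around a policy interruption:

    Y_t = b0 + b1*T_t + b2*X_t + b3*(T_t - T_I)*X_t + sum_m g_m*M_mt + e_t

where T_t is the month index (1 for the first series month, calendar
spacing), X_t indicates months on/after the interruption (intervention
month + behavioural lag), T_I is the index of the first post-interruption
month (so b2 is the level change *at* that month), and M_mt are 11
calendar-month indicators (January reference) adjusting for seasonality.

Coefficients are ordinary least squares; inference uses the Newey-West
heteroskedasticity- and autocorrelation-consistent (HAC) sandwich
covariance with Bartlett-kernel weights w_j = 1 - j/(L+1) up to a bandwidth
L.  The bandwidth defaults to 1 and escalates automatically when the
Cumby-Huizinga residual-autocorrelation test rejects at a higher order.
Relative (percentage) changes are reported against the starting level b0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ItsConfig",
    "ItsFit",
    "AutocorrTestResult",
    "EstimationError",
    "fit",
    "newey_covariance",
    "cumby_huizinga",
    "lag_sensitivity",
]

BASE_TERMS = ["level_start", "trend_pre", "level_change", "trend_change"]


class EstimationError(ValueError):
    """Design is rank-deficient, too short, or otherwise unusable."""


@dataclass(frozen=True)
class ItsConfig:
    intervention_month: str = "2014-08"
    lag_months: int = 2
    seasonal: bool = True
    hac_lag: int | None = None  # None -> 1, with autocorrelation-driven escalation
    hac_lag_max: int = 6
    autocorr_orders: tuple = tuple(range(1, 13))
    ci_level: float = 0.95
    alpha: float = 0.05
    #: scale the HAC covariance by n/(n-k), the usual small-sample
    #: degrees-of-freedom correction of Newey OLS implementations
    df_correction: bool = True

    def __post_init__(self):
        if not 0 <= self.lag_months <= 4:
            raise EstimationError("lag_months must lie in 0..4")
        if not 0.0 < self.ci_level < 1.0:
            raise EstimationError("ci_level must lie in (0,1)")

    @property
    def interruption_month(self) -> pd.Period:
        return pd.Period(self.intervention_month, "M") + self.lag_months


@dataclass
class AutocorrTestResult:
    """Test statistics for zero residual autocorrelation at lags 1..q.

    ``form`` is ``"f"`` (small-sample F version, default) or ``"chi2"``
    (asymptotic chi-square on q degrees of freedom).
    """

    lags_tested: list
    statistic: list
    p_value: list
    form: str = "f"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"order": self.lags_tested, "statistic": self.statistic, "p_value": self.p_value}
        )

    def min_p(self) -> float:
        return float(min(self.p_value))


@dataclass
class ItsFit:
    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    cov: pd.DataFrame
    residuals: pd.Series  # indexed by month
    fitted: pd.Series
    relative: dict
    n: int
    df_resid: int
    hac_lag: int
    config: ItsConfig
    design: pd.DataFrame = field(repr=False, default=None)
    y: pd.Series = field(repr=False, default=None)

    @property
    def beta(self) -> pd.Series:
        """The four segmented-regression coefficients (b0, b1, b2, b3)."""
        return self.params[BASE_TERMS]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "hac_se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_values,
            }
        )

    def relative_summary(self) -> pd.Series:
        return pd.Series(self.relative)


def _build_design(months: pd.PeriodIndex, config: ItsConfig) -> pd.DataFrame:
    start = months.min()
    t = np.array([(m - start).n for m in months], dtype=float) + 1.0
    interruption = config.interruption_month
    x = (months >= interruption).astype(float)
    t_i = float((interruption - start).n + 1)
    cols = {
        "level_start": np.ones(len(months)),
        "trend_pre": t,
        "level_change": x,
        "trend_change": (t - t_i) * x,
    }
    if config.seasonal:
        cal = months.month
        if len(np.unique(cal)) < 12:
            raise EstimationError("seasonal adjustment needs all 12 calendar months in the series")
        for m in range(2, 13):
            cols[f"month_{m:02d}"] = (cal == m).astype(float)
    return pd.DataFrame(cols, index=months)


def fit(series: pd.DataFrame, config: ItsConfig = ItsConfig()) -> ItsFit:
    """Estimate the segmented regression on a monthly CMI series.

    ``series`` is a DataFrame with ``month`` (Period or parseable) and
    ``cmi`` columns (as produced by :func:`casemix.cmi.monthly_cmi`).
    Missing months (NaN) are dropped listwise; the time index keeps
    calendar spacing.  Requires >= 24 usable points with >= 6 on each side
    of the interruption.
    """
    months = pd.PeriodIndex(series["month"], freq="M")
    y = pd.Series(np.asarray(series["cmi"], dtype=float), index=months)
    y = y.dropna()
    if y.index.has_duplicates:
        raise EstimationError("duplicate months in series")
    months = pd.PeriodIndex(y.index, freq="M")

    interruption = config.interruption_month
    n_pre = int((months < interruption).sum())
    n_post = int((months >= interruption).sum())
    if len(y) < 24 or n_pre < 6 or n_post < 6:
        raise EstimationError(
            f"need >=24 points with >=6 each side of {interruption}; "
            f"have {len(y)} ({n_pre} pre, {n_post} post)"
        )

    X = _build_design(months, config)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        raise EstimationError(f"rank-deficient design (rank {rank} < {Xv.shape[1]} columns)")

    beta, *_ = np.linalg.lstsq(Xv, y.to_numpy(), rcond=None)
    fitted = Xv @ beta
    resid = y.to_numpy() - fitted
    n, k = Xv.shape

    # HAC bandwidth: fixed if given, else default 1 with escalation when the
    # Cumby-Huizinga test finds residual autocorrelation at a higher order.
    if config.hac_lag is not None:
        hac_lag = int(config.hac_lag)
    else:
        hac_lag = 1
        orders = [q for q in config.autocorr_orders if q <= config.hac_lag_max and q < n - k]
        if orders:
            probe = cumby_huizinga_raw(Xv, resid, orders)
            rejecting = [q for q, p in zip(probe.lags_tested, probe.p_value) if p < config.alpha]
            if rejecting:
                hac_lag = max(rejecting)
    if hac_lag >= n:
        raise EstimationError(f"hac_lag {hac_lag} must be < n = {n}")

    cov = newey_covariance(Xv, resid, hac_lag)
    df_resid = n - k
    if config.df_correction:
        cov = cov * (n / df_resid)
    # clip away the tiny negative diagonal entries a numerically perfect fit
    # can leave behind
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tcrit = stats.t.ppf(0.5 + config.ci_level / 2.0, df_resid)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)

    names = list(X.columns)
    params = pd.Series(beta, index=names)
    b0, b1, b2, b3 = (params[t] for t in BASE_TERMS)
    relative = {
        "level_pct": 100.0 * b2 / b0,
        "pre_trend_pct": 100.0 * b1 / b0,
        "post_trend_pct": 100.0 * (b1 + b3) / b0,
        "trend_change_pct": 100.0 * b3 / b0,
    }
    return ItsFit(
        params=params,
        se=pd.Series(se, index=names),
        ci_low=pd.Series(beta - tcrit * se, index=names),
        ci_high=pd.Series(beta + tcrit * se, index=names),
        p_values=pd.Series(pvals, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        residuals=pd.Series(resid, index=months),
        fitted=pd.Series(fitted, index=months),
        relative=relative,
        n=n,
        df_resid=df_resid,
        hac_lag=hac_lag,
        config=config,
        design=X,
        y=y,
    )


def newey_covariance(design: np.ndarray, residuals: np.ndarray, hac_lag: int) -> np.ndarray:
    """Newey-West HAC coefficient covariance.

    (X'X)^-1 Omega (X'X)^-1 with Bartlett weights w_j = 1 - j/(L+1) on the
    residual autocovariance terms up to lag L.  With L = 0 this is exactly
    the White heteroskedasticity-robust (HC0) covariance.  No small-sample
    correction is applied.
    """
    X = np.asarray(design, dtype=float)
    u = X * np.asarray(residuals, dtype=float)[:, None]
    n = X.shape[0]
    if hac_lag < 0 or hac_lag >= n:
        raise EstimationError(f"hac_lag must lie in [0, n); got {hac_lag} with n = {n}")
    omega = u.T @ u
    for j in range(1, hac_lag + 1):
        w = 1.0 - j / (hac_lag + 1.0)
        gamma = u[j:].T @ u[:-j]
        omega += w * (gamma + gamma.T)
    xtx_inv = np.linalg.inv(X.T @ X)
    return xtx_inv @ omega @ xtx_inv


def cumby_huizinga_raw(
    design: np.ndarray, residuals: np.ndarray, lags, form: str = "f"
) -> AutocorrTestResult:
    """Test zero residual autocorrelation at lags 1..q for each order q.

    Operational score form of the general Cumby-Huizinga (1992) test for a
    regression with strictly exogenous regressors (the ITS design is
    deterministic): the residuals are regressed on the original design plus
    q lagged residuals (zero-padded); re-including the design columns is
    exactly what accounts for the estimated coefficients.  ``form="chi2"``
    is the asymptotic statistic n*R^2 ~ chi2(q); the default ``form="f"``
    is the small-sample F version (q, n-k-q degrees of freedom), which
    holds its nominal size better at the 72-month series lengths this
    package targets.
    """
    if form not in ("f", "chi2"):
        raise EstimationError(f"unknown test form {form!r}")
    X = np.asarray(design, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, k = len(e), X.shape[1]
    stats_, pvals, orders = [], [], []
    for q in lags:
        q = int(q)
        if q < 1:
            raise EstimationError("autocorrelation order must be >= 1")
        if q >= n:
            raise EstimationError(f"autocorrelation order {q} must be < n = {n}")
        tss = float(((e - e.mean()) ** 2).sum())
        if tss / n < np.finfo(float).eps:
            # numerically perfect fit: no residual signal to test
            r2 = 0.0
        else:
            Z = np.zeros((n, q))
            for j in range(1, q + 1):
                Z[j:, j - 1] = e[:-j]
            A = np.hstack([X, Z])
            coef, *_ = np.linalg.lstsq(A, e, rcond=None)
            u = e - A @ coef
            r2 = 1.0 - float((u**2).sum()) / tss
        if form == "chi2":
            stat = n * r2
            p = float(stats.chi2.sf(stat, q))
        else:
            df2 = n - k - q
            if df2 <= 0:
                raise EstimationError(f"order {q} leaves no residual degrees of freedom")
            stat = (r2 / q) / ((1.0 - r2) / df2) if r2 < 1.0 else np.inf
            p = float(stats.f.sf(stat, q, df2))
        stats_.append(stat)
        pvals.append(p)
        orders.append(q)
    return AutocorrTestResult(lags_tested=orders, statistic=stats_, p_value=pvals, form=form)


def cumby_huizinga(fit_result: ItsFit, lags=None, form: str = "f") -> AutocorrTestResult:
    """Residual autocorrelation test for a fitted ITS model."""
    k = fit_result.design.shape[1]
    if lags is None:
        lags = [q for q in fit_result.config.autocorr_orders if q < fit_result.n - k]
    return cumby_huizinga_raw(
        fit_result.design.to_numpy(), fit_result.residuals.to_numpy(), lags, form=form
    )


def lag_sensitivity(series: pd.DataFrame, config: ItsConfig = ItsConfig(), lags=range(0, 5)) -> pd.DataFrame:
    """Refit with each behavioural lag; summarize the impact coefficients.

    One row per lag with the interruption month, level- and trend-change
    estimates, HAC confidence bounds, p-values, and sign flags used to judge
    sign stability across lags.
    """
    from dataclasses import replace

    rows = []
    for lag in lags:
        cfg = replace(config, lag_months=int(lag))
        f = fit(series, cfg)
        rows.append(
            {
                "lag_months": int(lag),
                "interruption_month": cfg.interruption_month,
                "level_change": f.params["level_change"],
                "level_ci_low": f.ci_low["level_change"],
                "level_ci_high": f.ci_high["level_change"],
                "level_p": f.p_values["level_change"],
                "level_sign": int(np.sign(f.params["level_change"])),
                "trend_change": f.params["trend_change"],
                "trend_ci_low": f.ci_low["trend_change"],
                "trend_ci_high": f.ci_high["trend_change"],
                "trend_p": f.p_values["trend_change"],
                "trend_sign": int(np.sign(f.params["trend_change"])),
                "hac_lag": f.hac_lag,
            }
        )
    return pd.DataFrame(rows)
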