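"""Segmented regression, HAC covariance and autocorrelation testing."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.stats.sandwich_covariance as sw
from statsmodels.stats.diagnostic import acorr_breusch_godfrey

from casemix import its
from casemix.its import EstimationError, ItsConfig, cumby_huizinga_raw, newey_covariance


def build_series(beta, months=None, config=None, seasonal_effects=None, noise=None):
    """Noiseless (or noisy) series from segmented-regression coefficients."""
    config = config or ItsConfig(seasonal=False)
    if months is None:
        months = pd.period_range("2011-01", "2016-12", freq="M")
    t = np.array([(m - months[0]).n for m in months], dtype=float) + 1.0
    interruption = config.interruption_month
    x = (months >= interruption).astype(float)
    t_i = (interruption - months[0]).n + 1
    b0, b1, b2, b3 = beta
    y = b0 + b1 * t + b2 * x + b3 * (t - t_i) * x
    if seasonal_effects:
        y = y + np.array([seasonal_effects.get(m.month, 0.0) for m in months])
    if noise is not None:
        y = y + noise
    return pd.DataFrame({"month": months, "cmi": y})


BETA = (0.975, -0.001, 0.022, 0.002)


def test_noiseless_series_recovered_to_machine_precision():
    series = build_series(BETA)
    fit = its.fit(series, ItsConfig(seasonal=False))
    assert np.abs(fit.beta.to_numpy() - np.array(BETA)).max() < 1e-10
    assert fit.relative["level_pct"] == pytest.approx(100 * 0.022 / 0.975)
    assert fit.relative["trend_change_pct"] == pytest.approx(100 * 0.002 / 0.975)
    assert fit.relative["post_trend_pct"] == pytest.approx(100 * 0.001 / 0.975)


def test_seasonal_signal_does_not_bias_segmented_coefficients():
    effects = {m: 0.02 * np.sin(2 * np.pi * m / 12) for m in range(2, 13)}
    series = build_series(BETA, seasonal_effects=effects)
    fit = its.fit(series, ItsConfig(seasonal=True))
    assert np.abs(fit.beta.to_numpy() - np.array(BETA)).max() < 1e-10
    for m, eff in effects.items():
        assert fit.params[f"month_{m:02d}"] == pytest.approx(eff, abs=1e-10)


def test_flat_series_yields_zero_changes():
    series = build_series((1.234, 0.0, 0.0, 0.0))
    fit = its.fit(series, ItsConfig(seasonal=False))
    assert fit.params["level_start"] == pytest.approx(1.234)
    assert np.abs(fit.beta.to_numpy()[1:]).max() < 1e-12


def test_missing_months_dropped_with_calendar_spacing():
    series = build_series(BETA)
    series.loc[series.index[10], "cmi"] = np.nan
    series.loc[series.index[50], "cmi"] = np.nan
    fit = its.fit(series, ItsConfig(seasonal=False))
    assert fit.n == 70
    assert np.abs(fit.beta.to_numpy() - np.array(BETA)).max() < 1e-10


def test_preconditions_enforced():
    short = build_series(BETA, months=pd.period_range("2014-01", "2015-06", freq="M"))
    with pytest.raises(EstimationError):
        its.fit(short, ItsConfig(seasonal=False))
    # seasonal dummies need all 12 calendar months
    few = build_series(BETA, months=pd.period_range("2013-10", "2015-09", freq="M"))
    few_ok = its.fit(few, ItsConfig(seasonal=False))
    assert few_ok.n == 24
    with pytest.raises(EstimationError):
        its.ItsConfig(lag_months=7)


def test_ci_brackets_point_estimates(medical_series):
    fit = its.fit(medical_series, ItsConfig())
    assert (fit.ci_low <= fit.params).all() and (fit.params <= fit.ci_high).all()
    assert fit.cov.shape == (15, 15)


def test_newey_matches_brute_force_double_sum():
    rng = np.random.default_rng(1)
    for n, lag in ((5, 0), (5, 2), (8, 3), (10, 4)):
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float), rng.normal(size=n)])
        y = rng.normal(size=n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        e = y - X @ beta
        mine = newey_covariance(X, e, lag)
        # independent oracle: explicit double sum over all (t, s) pairs
        u = X * e[:, None]
        omega = np.zeros((X.shape[1], X.shape[1]))
        for t in range(n):
            for s in range(n):
                j = abs(t - s)
                w = 1.0 - j / (lag + 1.0) if j <= lag else 0.0
                omega += w * np.outer(u[t], u[s])
        xtx_inv = np.linalg.inv(X.T @ X)
        oracle = xtx_inv @ omega @ xtx_inv
        assert np.abs(mine - oracle).max() < 1e-12
        assert np.abs(mine - mine.T).max() < 1e-15
        assert (np.diag(mine) >= 0).all()


def test_newey_lag_zero_equals_hc0_and_statsmodels():
    rng = np.random.default_rng(2)
    n = 40
    X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    y = 1.0 + 0.1 * np.arange(n) + rng.normal(size=n) * (1 + np.arange(n) / n)
    res = sm.OLS(y, X).fit()
    mine0 = newey_covariance(X, res.resid, 0)
    u = X * res.resid[:, None]
    hc0 = np.linalg.inv(X.T @ X) @ (u.T @ u) @ np.linalg.inv(X.T @ X)
    assert np.abs(mine0 - hc0).max() == 0.0
    for lag in (0, 1, 5):
        smc = sw.cov_hac(res, nlags=lag, use_correction=False)
        assert np.abs(newey_covariance(X, res.resid, lag) - smc).max() < 1e-12


def test_newey_rejects_bad_bandwidth():
    X = np.ones((5, 1))
    with pytest.raises(EstimationError):
        newey_covariance(X, np.zeros(5), 5)


def test_autocorr_chi2_form_matches_breusch_godfrey():
    rng = np.random.default_rng(3)
    n = 72
    X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    y = 1.0 + 0.01 * np.arange(n) + rng.normal(size=n) * 0.1
    res = sm.OLS(y, X).fit()
    for q in (1, 3, 6):
        mine = cumby_huizinga_raw(X, res.resid, [q], form="chi2")
        bg_stat, bg_p, *_ = acorr_breusch_godfrey(res, nlags=q)
        assert mine.statistic[0] == pytest.approx(bg_stat, rel=1e-9)
        assert mine.p_value[0] == pytest.approx(bg_p, rel=1e-9)


def test_autocorr_p_monotone_in_statistic():
    rng = np.random.default_rng(4)
    n = 60
    X = np.ones((n, 1))
    results = []
    for scale in (0.0, 0.4, 0.9):
        e = rng.normal(size=n)
        e = e + scale * np.roll(e, 1)
        r = cumby_huizinga_raw(X, e - e.mean(), [1])
        results.append((r.statistic[0], r.p_value[0]))
    results.sort()
    stats_sorted, ps = zip(*results)
    assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))


def test_autocorr_order_bounds():
    X = np.ones((10, 1))
    e = np.arange(10, dtype=float)
    with pytest.raises(EstimationError):
        cumby_huizinga_raw(X, e, [10])
    with pytest.raises(EstimationError):
        cumby_huizinga_raw(X, e, [0])


def test_hac_bandwidth_escalates_under_strong_autocorrelation():
    months = pd.period_range("2011-01", "2016-12", freq="M")
    rng = np.random.default_rng(5)
    e = np.zeros(73)
    innov = rng.normal(size=73) * 0.01
    for i in range(1, 73):
        e[i] = 0.8 * e[i - 1] + innov[i]
    series = build_series(BETA, noise=e[1:])
    fit = its.fit(series, ItsConfig(seasonal=False))
    assert fit.hac_lag > 1
    fixed = its.fit(series, ItsConfig(seasonal=False, hac_lag=1))
    assert fixed.hac_lag == 1


def test_lag_sensitivity_table():
    series = build_series(BETA)
    table = its.lag_sensitivity(series, ItsConfig(seasonal=False), lags=range(0, 5))
    assert len(table) == 5
    assert (table["trend_sign"] == 1).all()
    assert (table["level_sign"] == 1).all()
    lag2 = table[table["lag_months"] == 2].iloc[0]
    assert lag2["interruption_month"] == pd.Period("2014-10", "M")
    empty = its.lag_sensitivity(series, ItsConfig(seasonal=False), lags=[])
    assert empty.empty
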