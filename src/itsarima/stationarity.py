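"""Differencing, transformations, correlograms and unit-root testing.

These are the exploratory steps of the Box–Jenkins workflow: make the
series stationary (log transform for unstable variance, regular and
seasonal differencing for trend and seasonality) and read AR/MA structure
off the ACF/PACF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .timeseries import TimeSeries

__all__ = [
    "CorrelogramResult", "difference", "log_transform", "acf", "pacf",
    "adf_test", "AdfResult",
]


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample (partial) autocorrelations with a white-noise band.

    ``ci_bound`` is the +-1.96/sqrt(n) half-width: under the white-noise
    null roughly 95% of sample correlations at positive lags fall inside
    the band, so bars crossing it flag significant autocorrelation.
    """

    lags: np.ndarray
    values: np.ndarray
    ci_bound: float
    n: int
    kind: str = "acf"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag": self.lags,
            "value": self.values,
            "ci_bound": np.full(self.lags.size, self.ci_bound),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def difference(series: TimeSeries, lag: int = 1, times: int = 1) -> TimeSeries:
    """Apply ``(1 - B^lag)`` to the series ``times`` times.

    Lag-1 differencing removes trend; lag-s differencing removes stable
    seasonality. Each pass loses ``lag`` observations off the front, so
    the output has length ``n - lag*times`` and its start advances.
    """
    if lag < 1 or times < 1:
        raise ValueError("lag and times must be >= 1")
    need = lag * times + 1
    if series.n < need:
        raise ValueError(
            f"insufficient observations for differencing: need at least {need}, "
            f"have {series.n}"
        )
    vals = series.values
    for _ in range(times):
        vals = vals[lag:] - vals[:-lag]
    out = series.with_values(vals, drop_front=lag * times)
    object.__setattr__(out, "_diff_lags", series._diff_lags + (lag,) * times)
    return out


def log_transform(series: TimeSeries) -> TimeSeries:
    """Natural log of the series, for variance that grows with the level.

    The transform is recorded on the result so downstream effect
    estimates can be reported multiplicatively on the original scale.
    """
    if np.any(series.values <= 0):
        raise ValueError("log transform requires strictly positive series")
    out = series.with_values(np.log(series.values))
    object.__setattr__(out, "transform", "log")
    return out


def _sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    # biased estimator: lag-0 sum of squares in the denominator, which
    # keeps the sequence positive semidefinite (needed by Durbin-Levinson)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("series has zero variance; ACF undefined")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(x[k:] @ x[:-k]) / denom
    return r


def acf(series: TimeSeries, max_lag: int) -> CorrelogramResult:
    """Sample autocorrelation function r_k for lags 0..max_lag."""
    n = series.n
    if max_lag >= n:
        raise ValueError(f"max_lag must be < series length ({n})")
    r = _sample_acf(series.values, max_lag)
    return CorrelogramResult(np.arange(max_lag + 1), r,
                             ci_bound=1.96 / np.sqrt(n), n=n, kind="acf")


def _durbin_levinson(r: np.ndarray) -> np.ndarray:
    """Partial autocorrelations phi_kk from autocorrelations r_0..r_K."""
    K = r.size - 1
    pacf_vals = np.zeros(K + 1)
    pacf_vals[0] = 1.0
    phi_prev = np.zeros(0)
    for k in range(1, K + 1):
        if k == 1:
            phi_kk = r[1]
            phi_prev = np.array([phi_kk])
        else:
            num = r[k] - phi_prev @ r[k - 1:0:-1]
            den = 1.0 - phi_prev @ r[1:k]
            phi_kk = num / den
            phi_new = np.empty(k)
            phi_new[:-1] = phi_prev - phi_kk * phi_prev[::-1]
            phi_new[-1] = phi_kk
            phi_prev = phi_new
        pacf_vals[k] = phi_kk
    return pacf_vals


def pacf(series: TimeSeries, max_lag: int) -> CorrelogramResult:
    """Partial autocorrelations via the Durbin–Levinson recursion.

    phi_kk is the correlation between Y_t and Y_{t-k} after removing what
    lags 1..k-1 already explain; for an AR(p) process it cuts off after
    lag p.
    """
    n = series.n
    if max_lag >= n:
        raise ValueError(f"max_lag must be < series length ({n})")
    r = _sample_acf(series.values, max_lag)
    vals = _durbin_levinson(r)
    return CorrelogramResult(np.arange(max_lag + 1), vals,
                             ci_bound=1.96 / np.sqrt(n), n=n, kind="pacf")


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    p_value: float
    reject_unit_root: bool
    used_lag: int
    regression: str


def adf_test(series: TimeSeries, max_lag=None, regression: str = "c",
             alpha: float = 0.05) -> AdfResult:
    """Augmented Dickey–Fuller unit-root test.

    The null hypothesis is a unit root (the series needs differencing);
    rejection at ``alpha`` indicates stationarity. The regression includes
    a constant by default ("c"); pass "ct" to add a linear trend. The
    augmentation lag is chosen by AIC when ``max_lag`` is None.
    """
    x = series.values
    if np.ptp(x) == 0:
        raise ValueError("constant series: unit-root regression is degenerate")
    min_n = 10 + (max_lag or 0)
    if series.n < min_n:
        raise ValueError(f"series too short for ADF test: need >= {min_n} observations")
    if max_lag is None:
        stat, pval, used_lag, *_ = adfuller(x, regression=regression, autolag="AIC")
    else:
        stat, pval, used_lag, *_ = adfuller(x, maxlag=int(max_lag),
                                            regression=regression, autolag=None)
    return AdfResult(float(stat), float(pval), bool(pval < alpha),
                     int(used_lag), regression)
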