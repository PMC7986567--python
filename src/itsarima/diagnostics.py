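"""Residual white-noise diagnostics.

A well specified model leaves residuals indistinguishable from white
noise.  The Ljung–Box portmanteau statistic aggregates the squared
residual autocorrelations over the first L lags,

    Q = n (n + 2) sum_{k=1..L} r_k^2 / (n - k),

and is compared to chi-square with L - fitdf degrees of freedom, where
fitdf counts the ARMA coefficients (p + q + P + Q) spent fitting — the
constant and sigma^2 are not counted, following the dominant convention
(R's Box.test and the forecast package).  Failing to reject means the
model has captured the autocorrelation structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sarima import FittedModel
from .stationarity import CorrelogramResult, acf
from .timeseries import TimeSeries

__all__ = ["ljung_box", "LjungBoxResult", "residual_report", "ResidualReport"]


@dataclass(frozen=True)
class LjungBoxResult:
    statistic: float
    df: int
    p_value: float
    lags: int
    fitdf: int


def ljung_box(residuals: TimeSeries, lags: int, fitdf: int = 0) -> LjungBoxResult:
    """Ljung–Box test that residual autocorrelations 1..lags are jointly zero."""
    n = residuals.n
    if lags >= n:
        raise ValueError(f"lags must be < number of residuals ({n})")
    if lags <= fitdf:
        raise ValueError(
            "degrees of freedom must be positive: lags must exceed fitdf "
            f"(got lags={lags}, fitdf={fitdf})")
    r = acf(residuals, max_lag=lags).values[1:]
    k = np.arange(1, lags + 1)
    Q = float(n * (n + 2) * np.sum(r ** 2 / (n - k)))
    df = lags - fitdf
    p = float(stats.chi2.sf(Q, df))
    return LjungBoxResult(statistic=Q, df=df, p_value=p, lags=lags, fitdf=fitdf)


@dataclass
class ResidualReport:
    mean: float
    variance: float
    acf: CorrelogramResult
    ljung_box: LjungBoxResult
    jarque_bera: float
    jarque_bera_p: float
    white_noise: bool             # verdict at alpha = 0.05
    normal: bool
    lags: int

    def to_dict(self) -> dict:
        return {
            "residual_mean": self.mean,
            "residual_variance": self.variance,
            "ljung_box": {"Q": self.ljung_box.statistic,
                          "df": self.ljung_box.df,
                          "p_value": self.ljung_box.p_value,
                          "lags": self.ljung_box.lags,
                          "fitdf": self.ljung_box.fitdf},
            "jarque_bera": {"statistic": self.jarque_bera,
                            "p_value": self.jarque_bera_p},
            "white_noise": self.white_noise,
            "normal_residuals": self.normal,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def residual_report(model: FittedModel, lags: int | None = None,
                    alpha: float = 0.05) -> ResidualReport:
    """Full residual check: ACF, Ljung–Box, normality, and a verdict.

    The verdict is "white noise" when the Ljung–Box p-value exceeds
    ``alpha`` — i.e. the null of no residual autocorrelation is not
    rejected and the chosen model is considered an adequate fit.
    Default lags = min(24, n/2), which puts 24 lags on a 4-year monthly
    series.
    """
    resid = model.residuals
    n = resid.n
    if lags is None:
        lags = min(24, n // 2)
    fitdf = model.order.n_arma
    if lags <= fitdf:
        lags = fitdf + 1
    lb = ljung_box(resid, lags=lags, fitdf=fitdf)
    r = acf(resid, max_lag=min(lags, n - 1))
    jb_stat, jb_p = stats.jarque_bera(resid.values)
    return ResidualReport(
        mean=float(resid.values.mean()),
        variance=float(resid.values.var()),
        acf=r, ljung_box=lb,
        jarque_bera=float(jb_stat), jarque_bera_p=float(jb_p),
        white_noise=bool(lb.p_value > alpha),
        normal=bool(jb_p > alpha),
        lags=lags,
    )
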