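"""Counterfactual series and intervention-effect summaries.

The fitted model separates the outcome into an undisturbed process and
the intervention impact.  The *counterfactual* is the model-implied
prediction with every intervention regressor set to zero — what the
series would have looked like had the intervention not happened.  The
pointwise effect at post-onset horizon k is the sum over interventions
of their transfer-function responses (step: omega_0 at every k; ramp:
(k+1) omega_0; pulse with decay: omega_0 delta^k), with delta-method
confidence intervals from the coefficient covariance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interventions import TransferParams, theoretical_response
from .sarima import FittedModel, forecast as _forecast
from .timeseries import TimeSeries

__all__ = ["counterfactual", "effect_at", "effect_summary", "EffectSummary"]


def counterfactual(model: FittedModel, mode: str = "adjust") -> TimeSeries:
    """Predicted outcome with the interventions switched off.

    ``mode="adjust"`` (default) zeroes the intervention regressors in the
    fitted model: before onset the counterfactual equals the fitted
    (one-step prediction) values; afterwards it is the fitted value minus
    the estimated impact.  ``mode="forecast"`` instead re-forecasts
    dynamically from the last pre-onset observation with the regressors
    held at zero (a sensitivity variant).
    """
    if not model.interventions:
        raise ValueError("model was fitted without interventions; "
                         "there is no counterfactual to compute")
    series = model.series
    loss = model.order.diff_loss
    if mode == "adjust":
        impact = model.impact_series()[loss:]
        vals = model.fitted_level - impact
        idx = series.index[loss:] if series.index is not None else None
        return TimeSeries(vals, period=series.period, index=idx,
                          label="counterfactual")
    if mode == "forecast":
        t0 = min(series.position_of(sp.onset) + sp.delay
                 for sp in model.interventions)
        pre = TimeSeries(series.values[:t0], period=series.period,
                         index=series.index[:t0] if series.index is not None
                         else None)
        from .sarima import fit as _fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre_model = _fit(pre, model.order,
                             include_constant=model.include_constant)
        fc = _forecast(pre_model, horizon=series.n - t0,
                       future_interventions="zero")
        vals = np.r_[pre_model.fitted_level, fc.mean]
        idx = series.index[model.order.diff_loss:] if series.index is not None \
            else None
        return TimeSeries(vals, period=series.period, index=idx,
                          label="counterfactual (dynamic forecast)")
    raise ValueError("mode must be 'adjust' or 'forecast'")


def _effect_and_gradient(model: FittedModel, k: int):
    """Total effect at horizon k and its gradient in coefficient space."""
    total = 0.0
    grad = np.zeros(model.coef_cov.shape[0])
    for j, spec in enumerate(model.interventions):
        params = model.transfer_params(j)
        total += theoretical_response(spec.shape, params, k)
        om_idx, de_idx = model.intervention_coef_indices(j)
        # analytic in omega (response is linear in omega_0); numeric in delta
        unit = TransferParams(np.ones(1), params.delta)
        grad[om_idx[0]] += theoretical_response(spec.shape, unit, k)
        for pos, di in enumerate(de_idx):
            h = 1e-6
            dplus = params.delta.copy(); dplus[pos] += h
            dminus = params.delta.copy(); dminus[pos] -= h
            rp = theoretical_response(spec.shape,
                                      TransferParams(params.omega, dplus), k)
            rm = theoretical_response(spec.shape,
                                      TransferParams(params.omega, dminus), k)
            grad[di] += (rp - rm) / (2 * h)
    return total, grad


def effect_at(model: FittedModel, k: int, flag_beyond: bool = True):
    """Pointwise intervention effect k periods after onset, with 95% CI.

    k = 0 is the onset period itself.  Negative values mean the outcome
    is below its counterfactual.  Horizons beyond the observed series are
    computed but flagged: findings are only considered valid within the
    study period.
    """
    if k < 0:
        raise ValueError("horizon k must be >= 0")
    if not model.interventions:
        raise ValueError("model has no interventions")
    est, grad = _effect_and_gradient(model, k)
    var = float(grad @ model.coef_cov @ grad)
    se = np.sqrt(max(var, 0.0))
    t0 = min(model.series.position_of(sp.onset) + sp.delay
             for sp in model.interventions)
    if flag_beyond and t0 + k >= model.series.n:
        warnings.warn(
            f"horizon k={k} extends beyond the study period; the estimate "
            "is an extrapolation and should be interpreted with caution",
            stacklevel=2)
    return float(est), (float(est - 1.96 * se), float(est + 1.96 * se))


@dataclass
class EffectSummary:
    """Pointwise and cumulative effects per post-onset horizon."""

    table: pd.DataFrame           # horizon, date, effect, lo, hi, cumulative...
    observed: TimeSeries
    counterfactual: TimeSeries

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"effects": self.table.to_dict(orient="records")}, indent=2,
            default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot_table(self) -> pd.DataFrame:
        """Observed vs counterfactual, ready for plotting."""
        cf = self.counterfactual
        dates = ([str(p) for p in cf.index] if cf.index is not None
                 else list(range(cf.n)))
        offset = self.observed.n - cf.n
        return pd.DataFrame({
            "date": dates,
            "observed": self.observed.values[offset:],
            "counterfactual": cf.values,
        })


def effect_summary(model: FittedModel, horizons: int | None = None,
                   mode: str = "adjust") -> EffectSummary:
    """Effect table over post-onset horizons observed in the study period.

    The cumulative column is the running sum of pointwise effects (with a
    delta-method CI on the sum); on a log-transformed outcome the effects
    are additionally reported as percent change.
    """
    if not model.interventions:
        raise ValueError("model has no interventions")
    series = model.series
    t0 = min(series.position_of(sp.onset) + sp.delay
             for sp in model.interventions)
    if horizons is None:
        horizons = series.n - t0
    rows = []
    cum, cum_grad = 0.0, np.zeros(model.coef_cov.shape[0])
    log_scale = series.transform == "log"
    for k in range(horizons):
        est, grad = _effect_and_gradient(model, k)
        se = np.sqrt(max(float(grad @ model.coef_cov @ grad), 0.0))
        cum += est
        cum_grad = cum_grad + grad
        cum_se = np.sqrt(max(float(cum_grad @ model.coef_cov @ cum_grad), 0.0))
        row = {
            "horizon": k,
            "date": str(series.period_at(t0 + k)),
            "effect": est, "lo95": est - 1.96 * se, "hi95": est + 1.96 * se,
            "cumulative": cum,
            "cumulative_lo95": cum - 1.96 * cum_se,
            "cumulative_hi95": cum + 1.96 * cum_se,
        }
        if log_scale:
            # effects on the log scale are multiplicative on the original
            row["pct_change"] = 100 * (np.exp(est) - 1)
            row["pct_lo95"] = 100 * (np.exp(est - 1.96 * se) - 1)
            row["pct_hi95"] = 100 * (np.exp(est + 1.96 * se) - 1)
        rows.append(row)
    return EffectSummary(table=pd.DataFrame(rows), observed=series,
                         counterfactual=counterfactual(model, mode=mode))
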