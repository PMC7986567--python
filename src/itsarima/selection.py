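"""Automatic order selection, differencing recommendation, delay search.

The order search is a constrained stepwise walk over (p, q, P, Q): start
from a handful of seed models, repeatedly evaluate every neighbour that
changes one order by +-1 (within caps, 5/5/2/2 by default), move to the
best model by the chosen information criterion, stop at a local minimum.
Degrees of differencing d and D are fixed by the user or recommended
from unit-root tests and the strength of the seasonal autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sarima import ArimaOrder, ConvergenceError, FittedModel, fit
from .stationarity import acf, adf_test, difference
from .timeseries import TimeSeries

__all__ = ["auto_search", "choose_differencing", "delay_search",
           "SearchResult", "DifferencingAdvice"]


@dataclass
class SearchResult:
    best_order: ArimaOrder
    best_model: FittedModel
    trace: pd.DataFrame           # order, criterion value, converged flag
    criterion: str

    def trace_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)


def _seed_orders(d: int, D: int, s: int):
    if s > 1:
        seeds = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
    else:
        seeds = [(2, 2, 0, 0), (0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0)]
    return [ArimaOrder(p, d, q, P, D, Q, s) for p, q, P, Q in seeds]


def _neighbours(o: ArimaOrder, caps) -> list:
    out = []
    for attr in ("p", "q", "P", "Q"):
        for delta in (-1, +1):
            vals = {k: getattr(o, k) for k in ("p", "d", "q", "P", "D", "Q", "s")}
            vals[attr] += delta
            if vals[attr] < 0 or vals[attr] > caps[attr]:
                continue
            if o.s == 1 and attr in ("P", "Q"):
                continue
            out.append(ArimaOrder(**vals))
    return out


def _param_count(o: ArimaOrder) -> int:
    return o.p + o.q + o.P + o.Q


def auto_search(series: TimeSeries, d: Optional[int] = None,
                D: Optional[int] = None, interventions: Sequence = (),
                criterion: str = "aicc", max_p: int = 5, max_q: int = 5,
                max_P: int = 2, max_Q: int = 2,
                include_constant: Optional[bool] = None) -> SearchResult:
    """Stepwise information-criterion search for the best SARIMA order.

    ``d``/``D`` default to the :func:`choose_differencing` recommendation.
    Candidates that fail to converge (or hit the stationarity boundary so
    hard the likelihood is unusable) are skipped but logged in the trace.
    Ties break toward fewer parameters, then lower q, then lower p — the
    most parsimonious adequate model.
    """
    criterion = criterion.lower()
    if criterion not in ("aic", "aicc", "bic"):
        raise ValueError("criterion must be one of aic, aicc, bic")
    if d is None or D is None:
        advice = choose_differencing(series)
        d = advice.d if d is None else d
        D = advice.D if D is None else D
    s = series.period if D or series.period > 1 else series.period
    caps = {"p": max_p, "q": max_q, "P": max_P if s > 1 else 0,
            "Q": max_Q if s > 1 else 0}

    evaluated: dict = {}
    rows = []

    def crit_of(o: ArimaOrder):
        key = (o.p, o.d, o.q, o.P, o.D, o.Q)
        if key in evaluated:
            return evaluated[key]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit(series, o, interventions,
                            include_constant=include_constant)
            value = model.criterion(criterion)
            ok = True
        except (ValueError, ConvergenceError, np.linalg.LinAlgError) as exc:
            model, value, ok = None, np.inf, False
            rows.append({"order": str(o), "criterion": np.nan,
                         "converged": False, "note": str(exc)[:80]})
            evaluated[key] = (value, model)
            return evaluated[key]
        rows.append({"order": str(o), "criterion": value,
                     "converged": ok, "note": ""})
        evaluated[key] = (value, model)
        return evaluated[key]

    def better(o_new, c_new, o_best, c_best):
        if c_new < c_best - 1e-10:
            return True
        if abs(c_new - c_best) <= 1e-10:   # tie: parsimony wins
            tn = (_param_count(o_new), o_new.q, o_new.p)
            tb = (_param_count(o_best), o_best.q, o_best.p)
            return tn < tb
        return False

    current, current_c = None, np.inf
    for o in _seed_orders(d, D, series.period):
        if o.p > caps["p"] or o.q > caps["q"] or o.P > caps["P"] or o.Q > caps["Q"]:
            continue
        c, model = crit_of(o)
        if model is not None and better(o, c, current, current_c):
            current, current_c = o, c
    if current is None:
        raise ConvergenceError(
            "no seed model converged; search trace: "
            + "; ".join(r["order"] for r in rows))

    while True:
        moved = False
        for o in _neighbours(current, caps):
            c, model = crit_of(o)
            if model is not None and better(o, c, current, current_c):
                current, current_c, moved = o, c, True
        if not moved:
            break

    best_model = evaluated[(current.p, current.d, current.q,
                            current.P, current.D, current.Q)][1]
    return SearchResult(best_order=current, best_model=best_model,
                        trace=pd.DataFrame(rows), criterion=criterion)


@dataclass
class DifferencingAdvice:
    d: int
    D: int
    rationale: str


def choose_differencing(series: TimeSeries, alpha: float = 0.05,
                        max_d: int = 2) -> DifferencingAdvice:
    """Recommend (d, D) from the data; advisory, user values override.

    D: after removing a linear trend, a seasonal-lag autocorrelation
    beyond the white-noise band indicates seasonality worth a seasonal
    difference.  d: repeated unit-root (ADF) testing on the (seasonally)
    differenced series, adding regular differences while the unit root
    is not rejected (capped at 2).  Because the ADF test has little power
    in short series and over-differencing is the costlier mistake (it
    plants a non-invertible moving-average root), escalating beyond d=1
    requires the test to show essentially no evidence of stationarity
    (p > 0.5), not merely p > alpha.
    """
    s = series.period
    notes = []
    D = 0
    if s > 1:
        if series.n < 2 * s + 10:
            notes.append(f"series too short (n={series.n}) to assess "
                         f"seasonality at period {s}; assuming D=0")
        else:
            # remove the trend by a first difference (robust to stochastic
            # trends, which OLS detrending leaves behind), then look for a
            # significant seasonal-lag autocorrelation
            detr = difference(series, lag=1)
            r = acf(detr, max_lag=s)
            if abs(r.values[s]) > r.ci_bound:
                D = 1
                notes.append(
                    f"detrended ACF at lag {s} = {r.values[s]:.2f} exceeds "
                    f"the +-{r.ci_bound:.2f} band: seasonal difference D=1")
            else:
                notes.append(
                    f"no significant seasonal autocorrelation at lag {s}: D=0")
    work = difference(series, lag=s, times=1) if D else series
    d = 0
    while d <= max_d:
        try:
            res = adf_test(work)
        except ValueError as exc:
            notes.append(f"ADF unavailable ({exc}); stopping at d={d}")
            break
        threshold = alpha if d == 0 else 0.5
        if res.p_value < threshold:
            notes.append(f"ADF finds no remaining unit root after d={d} "
                         f"(p={res.p_value:.3f})")
            break
        if d == max_d:
            notes.append(f"unit root still not rejected at d={max_d}; "
                         "consider a transformation")
            break
        work = difference(work, lag=1, times=1)
        d += 1
        notes.append(f"ADF fails to reject a unit root (p={res.p_value:.3f}); "
                     f"taking a regular difference (d={d})")
    return DifferencingAdvice(d=d, D=D, rationale=" | ".join(notes))


def delay_search(series: TimeSeries, order: ArimaOrder,
                 interventions: Sequence, window: int,
                 criterion: str = "aicc") -> tuple:
    """Refit with every candidate onset delay in 0..window; pick the best.

    All interventions are shifted together (one common delay).  Returns
    (best_delay, best_model, comparison table with window+1 rows).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    base_pos = min(series.position_of(sp.onset) for sp in interventions)
    post_len = series.n - base_pos
    if window >= post_len:
        raise ValueError(
            f"delay window {window} exceeds the post-intervention length "
            f"{post_len}")
    rows, fits = [], {}
    for delay in range(window + 1):
        shifted = [sp.with_delay(sp.delay + delay) for sp in interventions]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit(series, order, shifted)
            value = model.criterion(criterion)
        except (ValueError, ConvergenceError):
            model, value = None, np.inf
        rows.append({"delay": delay, "criterion": value,
                     "converged": model is not None})
        fits[delay] = model
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    if ok.empty:
        raise ConvergenceError("no delay candidate converged")
    best_delay = int(ok.loc[ok.criterion.idxmin(), "delay"])
    return best_delay, fits[best_delay], table
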