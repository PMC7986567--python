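"""Seasonal ARIMA estimation with intervention regressors.

The model for an outcome Y_t with intervention inputs is

    phi(B) Phi(B^s) (1-B)^d (1-B^s)^D [ Y_t - sum_j f_j(B) X_jt ] =
        c + theta(B) Theta(B^s) eps_t,        eps_t ~ N(0, sigma^2)

where each f_j(B) = omega_j(B)/delta_j(B) is a rational transfer function
acting on an intervention indicator X_jt.  Estimation is exact Gaussian
maximum likelihood: the regressors are differenced identically to the
outcome, the ARMA likelihood is evaluated by the innovations (Kalman)
decomposition with stationary initialisation, and the regression
coefficients and innovation variance are profiled out, leaving a
low-dimensional optimisation over the ARMA coefficients (and any transfer
denominators delta), parameterised through partial autocorrelations so
stationarity/invertibility hold throughout.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _statespace as ss
from .interventions import InterventionSpec, TransferParams, apply_transfer, indicator
from .timeseries import TimeSeries

__all__ = ["ArimaOrder", "FittedModel", "Forecast", "fit", "forecast",
           "simulate_from", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimiser fails from every start."""


@dataclass(frozen=True)
class ArimaOrder:
    """(p, d, q) x (P, D, Q)_s model orders."""

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 1

    def __post_init__(self):
        vals = (self.p, self.d, self.q, self.P, self.D, self.Q, self.s)
        if any(int(v) != v or v < 0 for v in vals):
            raise ValueError("all order components must be non-negative integers")
        if self.s < 1:
            raise ValueError("seasonal period s must be >= 1")
        if self.d + self.D > 3:
            raise ValueError("total differencing d + D above 3 is not supported "
                             "(third-order differencing is already rare)")
        if self.s == 1 and (self.P or self.D or self.Q):
            raise ValueError("seasonal terms require a seasonal period s > 1")

    @property
    def n_arma(self) -> int:
        return self.p + self.q + self.P + self.Q

    @property
    def diff_loss(self) -> int:
        return self.d + self.D * self.s

    @classmethod
    def parse(cls, text: str, s: Optional[int] = None) -> "ArimaOrder":
        """Parse '(2,1,0)(0,1,1)12' or '2,1,0' (with s for seasonal part)."""
        nums = [int(tok) for tok in re.findall(r"-?\d+", text)]
        if len(nums) == 3:
            return cls(*nums, s=s or 1)
        if len(nums) == 6:
            return cls(*nums, s=s or 1)
        if len(nums) == 7:
            return cls(*nums[:6], s=nums[6])
        raise ValueError(f"cannot parse ARIMA order from {text!r}")

    def __str__(self):
        if self.s > 1:
            return (f"({self.p},{self.d},{self.q})"
                    f"({self.P},{self.D},{self.Q})[{self.s}]")
        return f"({self.p},{self.d},{self.q})"


@dataclass(frozen=True)
class Forecast:
    mean: np.ndarray
    se: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    index: Optional[object] = None

    def to_frame(self) -> pd.DataFrame:
        dates = [str(p) for p in self.index] if self.index is not None \
            else list(range(self.mean.size))
        return pd.DataFrame({"date": dates, "forecast": self.mean,
                             "se": self.se, "lo95": self.lo, "hi95": self.hi})


def _difference(values: np.ndarray, d: int, D: int, s: int) -> np.ndarray:
    v = values
    for _ in range(d):
        v = v[1:] - v[:-1]
    for _ in range(D):
        v = v[s:] - v[:-s]
    return v


def _integrate(w: np.ndarray, d: int, D: int, s: int) -> np.ndarray:
    v = w.copy()
    for _ in range(D):
        out = v.copy()
        for t in range(s, v.size):
            out[t] += out[t - s]
        v = out
    for _ in range(d):
        v = np.cumsum(v)
    return v


def _impact_columns(series: TimeSeries, spec: InterventionSpec,
                    delta: np.ndarray) -> np.ndarray:
    """Level-scale regressor columns (one per omega lag) for one spec."""
    x = indicator(series, spec).values
    if spec.r > 0:
        x = apply_transfer(series.with_values(x),
                           TransferParams(np.array([1.0]), delta)).values
    cols = [x]
    for lag in range(1, spec.h + 1):
        shifted = np.zeros_like(x)
        shifted[lag:] = x[:-lag]
        cols.append(shifted)
    return np.column_stack(cols)


@dataclass
class FittedModel:
    """A maximum-likelihood SARIMA fit with intervention regressors."""

    order: ArimaOrder
    series: TimeSeries
    interventions: tuple
    phi: np.ndarray
    theta: np.ndarray
    seasonal_phi: np.ndarray
    seasonal_theta: np.ndarray
    beta: np.ndarray              # [mu?] + omegas, in coef_names order
    deltas: list                  # per intervention, np.ndarray (possibly empty)
    include_constant: bool
    sigma2: float
    loglik: float
    n_effective: int
    coef_names: list
    coef_cov: np.ndarray          # covariance of [beta, arma, deltas]
    residuals: TimeSeries = None
    fitted_level: np.ndarray = None
    converged: bool = True
    optimizer_message: str = ""
    _beta_slices: dict = field(default_factory=dict)

    # ------------------------------------------------------------- metrics
    @property
    def k_params(self) -> int:
        return (self.beta.size + self.order.n_arma
                + sum(d.size for d in self.deltas) + 1)  # + sigma^2

    @property
    def aic(self) -> float:
        return -2 * self.loglik + 2 * self.k_params

    @property
    def bic(self) -> float:
        return -2 * self.loglik + self.k_params * np.log(self.n_effective)

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.n_effective
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2 * k * (k + 1) / (n - k - 1)

    def criterion(self, name: str) -> float:
        return {"aic": self.aic, "aicc": self.aicc, "bic": self.bic}[name.lower()]

    @property
    def mean(self) -> float:
        """Process mean mu of the (differenced) outcome, 0 if no constant."""
        return float(self.beta[0]) if self.include_constant else 0.0

    @property
    def const(self) -> float:
        """Constant c of the recursion form: c = mu * phi_full(1)."""
        return self.mean * float(np.sum(self._apoly()))

    def _apoly(self):
        return ss.ar_poly(self.phi, self.seasonal_phi, self.order.s)

    def _bpoly(self):
        return ss.ma_poly(self.theta, self.seasonal_theta, self.order.s)

    # -------------------------------------------------- coefficient access
    def coef_table(self) -> pd.DataFrame:
        est = self._coef_vector()
        se = np.sqrt(np.clip(np.diag(self.coef_cov), 0, None))
        return pd.DataFrame({
            "coef": est, "se": se,
            "lo95": est - 1.96 * se, "hi95": est + 1.96 * se,
        }, index=self.coef_names)

    def _coef_vector(self) -> np.ndarray:
        return np.concatenate([
            self.beta, self.phi, self.theta, self.seasonal_phi,
            self.seasonal_theta,
            np.concatenate(self.deltas) if self.deltas and
            any(d.size for d in self.deltas) else np.zeros(0),
        ])

    def transfer_params(self, j: int) -> TransferParams:
        """Estimated (omega, delta) of the j-th intervention."""
        sl = self._beta_slices[f"iv{j}"]
        return TransferParams(self.beta[sl], self.deltas[j])

    def intervention_coef_indices(self, j: int):
        """Indices of the j-th intervention's omega (and delta) in coef_cov."""
        sl = self._beta_slices[f"iv{j}"]
        om_idx = list(range(sl.start, sl.stop))
        ndelta_before = sum(self.deltas[i].size for i in range(j))
        base = self.beta.size + self.order.n_arma
        de_idx = list(range(base + ndelta_before,
                            base + ndelta_before + self.deltas[j].size))
        return om_idx, de_idx

    def impact_series(self, horizon_extra: int = 0) -> np.ndarray:
        """Estimated total intervention impact on the level scale."""
        base = self.series
        if horizon_extra:
            ext = np.r_[base.values, np.zeros(horizon_extra)]
            if base.index is not None:
                idx = pd.period_range(base.index[0],
                                      periods=base.n + horizon_extra,
                                      freq=base.index.freq)
            else:
                idx = None
            base = TimeSeries(ext, period=base.period, index=idx)
        total = np.zeros(base.n)
        for j, spec in enumerate(self.interventions):
            cols = _impact_columns(base, spec, self.deltas[j])
            total += cols @ self.beta[self._beta_slices[f"iv{j}"]]
        return total

    # ------------------------------------------------------------- exports
    def summary(self) -> str:
        lines = [f"SARIMA {self.order}  n_eff={self.n_effective}  "
                 f"loglik={self.loglik:.3f}",
                 f"sigma^2={self.sigma2:.6g}  AIC={self.aic:.2f}  "
                 f"AICc={self.aicc:.2f}  BIC={self.bic:.2f}"]
        lines.append(self.coef_table().to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tab = self.coef_table()
        return {
            "order": str(self.order),
            "n_effective": int(self.n_effective),
            "loglik": float(self.loglik),
            "sigma2": float(self.sigma2),
            "aic": float(self.aic), "aicc": float(self.aicc),
            "bic": float(self.bic),
            "k_params": int(self.k_params),
            "coefficients": {
                name: {"estimate": float(tab.loc[name, "coef"]),
                       "se": float(tab.loc[name, "se"]),
                       "lo95": float(tab.loc[name, "lo95"]),
                       "hi95": float(tab.loc[name, "hi95"])}
                for name in tab.index
            },
            "interventions": [sp.describe() for sp in self.interventions],
            "converged": bool(self.converged),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------- fitting
def _build_design(series: TimeSeries, order: ArimaOrder,
                  interventions: Sequence[InterventionSpec],
                  deltas: Sequence[np.ndarray], include_constant: bool):
    """Differenced outcome and regressor matrix (constant appended last-differenced)."""
    w = _difference(series.values, order.d, order.D, order.s)
    cols, names, slices = [], [], {}
    if include_constant:
        cols.append(np.ones(w.size))
        names.append("const")
    for j, spec in enumerate(interventions):
        level_cols = _impact_columns(series, spec, deltas[j])
        dcols = np.column_stack([
            _difference(level_cols[:, i], order.d, order.D, order.s)
            for i in range(level_cols.shape[1])
        ])
        start = sum(c.shape[1] if c.ndim == 2 else 1 for c in cols)
        slices[f"iv{j}"] = slice(start, start + dcols.shape[1])
        cols.append(dcols)
        tag = spec.label or f"{spec.shape}{j}"
        names.extend([f"{tag}.omega{i}" for i in range(dcols.shape[1])])
    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols]) \
        if cols else np.zeros((w.size, 0))
    return w, X, names, slices


def _unpack_z(z, order: ArimaOrder, r_sizes):
    i = 0
    phi = ss.unconstrained_to_ar(z[i:i + order.p]); i += order.p
    theta = ss.unconstrained_to_ma(z[i:i + order.q]); i += order.q
    sphi = ss.unconstrained_to_ar(z[i:i + order.P]); i += order.P
    stheta = ss.unconstrained_to_ma(z[i:i + order.Q]); i += order.Q
    deltas = []
    for rj in r_sizes:
        deltas.append(np.tanh(z[i:i + rj])); i += rj
    return phi, theta, sphi, stheta, deltas


def fit(series: TimeSeries, order: ArimaOrder,
        interventions: Sequence[InterventionSpec] = (),
        include_constant: Optional[bool] = None,
        maxiter: int = 500, n_restarts: int = 5,
        restart_seed: int = 0) -> FittedModel:
    """Fit a SARIMA(+interventions) model by exact maximum likelihood.

    The constant is included by default only when d = D = 0 (a constant
    under differencing would imply a deterministic polynomial trend);
    pass ``include_constant`` to override.  Reported coefficients are on
    the original outcome scale; standard errors come from the inverse
    observed information (numerical Hessian).
    """
    if isinstance(order, tuple):
        order = ArimaOrder(*order)
    if include_constant is None:
        include_constant = (order.d + order.D == 0)
    interventions = tuple(interventions)
    r_sizes = [spec.r for spec in interventions]
    n_eff = series.n - order.diff_loss
    k_free = (int(include_constant) + sum(sp.h + 1 for sp in interventions)
              + order.n_arma + sum(r_sizes) + 1)
    if n_eff < k_free + 2:
        raise ValueError(
            f"insufficient data: {n_eff} effective observations after "
            f"differencing but {k_free} free parameters (need >= {k_free + 2}, "
            f"short by {k_free + 2 - n_eff})"
        )

    def neg_loglik(z):
        phi, theta, sphi, stheta, deltas = _unpack_z(z, order, r_sizes)
        ap = ss.ar_poly(phi, sphi, order.s)
        bp = ss.ma_poly(theta, stheta, order.s)
        w, X, _, _ = _build_design(series, order, interventions, deltas,
                                   include_constant)
        try:
            ll, *_ = ss.profile_gls_loglik(ap, bp, w, X)
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    nz = order.n_arma + sum(r_sizes)
    rng = np.random.default_rng(restart_seed)
    best = None
    z0 = np.zeros(nz)
    for attempt in range(n_restarts + 1):
        if nz == 0:
            best = type("R", (), {"x": z0, "success": True,
                                  "message": "no ARMA parameters"})()
            break
        res = minimize(neg_loglik, z0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        z0 = rng.normal(0, 0.4, nz)
    if best is None or not np.isfinite(
            best.fun if hasattr(best, "fun") else 0.0):
        raise ConvergenceError(
            f"SARIMA optimisation failed: {getattr(best, 'message', 'no result')}"
        )
    converged = bool(getattr(best, "success", True))
    if not converged:
        warnings.warn(f"optimizer did not report convergence: {best.message}",
                      stacklevel=2)

    phi, theta, sphi, stheta, deltas = _unpack_z(best.x, order, r_sizes)
    # boundary warning: near-unit partials signal a (near) non-invertible optimum
    if nz and np.any(np.abs(np.tanh(best.x)) > 0.998):
        warnings.warn("estimate lies near the stationarity/invertibility "
                      "boundary; standard errors may be unreliable",
                      stacklevel=2)
    ap = ss.ar_poly(phi, sphi, order.s)
    bp = ss.ma_poly(theta, stheta, order.s)
    w, X, names, slices = _build_design(series, order, interventions, deltas,
                                        include_constant)
    ll, beta, sigma2, resid = ss.profile_gls_loglik(ap, bp, w, X)

    # one-step innovations on the differenced scale -> fitted levels
    z_resid = w - (X @ beta if X.size else 0.0)
    V, F = ss.kalman_innovations(ap, bp, z_resid[:, None])
    u = V[:, 0]
    fitted_level = series.values[order.diff_loss:] - u

    cov = _observed_information_cov(series, order, interventions,
                                    include_constant, beta, phi, theta,
                                    sphi, stheta, deltas, sigma2)

    resid_idx = series.index[order.diff_loss:] if series.index is not None else None
    resid_ts = TimeSeries(resid, period=series.period, index=resid_idx,
                          label="residuals")
    delta_names = []
    for j, spec in enumerate(interventions):
        tag = spec.label or f"{spec.shape}{j}"
        delta_names += [f"{tag}.delta{i+1}" for i in range(deltas[j].size)]
    return FittedModel(
        order=order, series=series, interventions=interventions,
        phi=phi, theta=theta, seasonal_phi=sphi, seasonal_theta=stheta,
        beta=beta, deltas=deltas, include_constant=include_constant,
        sigma2=sigma2, loglik=ll, n_effective=w.size,
        coef_names=(names + [f"ar{i+1}" for i in range(order.p)]
                    + [f"ma{i+1}" for i in range(order.q)]
                    + [f"sar{i+1}" for i in range(order.P)]
                    + [f"sma{i+1}" for i in range(order.Q)] + delta_names),
        coef_cov=cov, residuals=resid_ts, fitted_level=fitted_level,
        converged=converged,
        optimizer_message=str(getattr(best, "message", "")),
        _beta_slices=slices,
    )


def _observed_information_cov(series, order, interventions, include_constant,
                              beta, phi, theta, sphi, stheta, deltas, sigma2):
    """Inverse numerical Hessian of -loglik over all natural coefficients."""
    r_sizes = [d.size for d in deltas]
    flat_delta = np.concatenate(deltas) if sum(r_sizes) else np.zeros(0)
    pi0 = np.concatenate([beta, phi, theta, sphi, stheta, flat_delta,
                          [np.log(sigma2)]])
    nb = beta.size

    def split(pi):
        i = nb
        ph = pi[i:i + order.p]; i += order.p
        th = pi[i:i + order.q]; i += order.q
        sp = pi[i:i + order.P]; i += order.P
        st = pi[i:i + order.Q]; i += order.Q
        ds, j = [], i
        for rj in r_sizes:
            ds.append(pi[j:j + rj]); j += rj
        return pi[:nb], ph, th, sp, st, ds, np.exp(pi[j])

    def nll(pi):
        b, ph, th, sp, st, ds, s2 = split(pi)
        ap = ss.ar_poly(ph, sp, order.s)
        bp = ss.ma_poly(th, st, order.s)
        if not (ss.poly_stable(ap, tol=1e-12) and ss.poly_stable(bp, tol=1e-12)):
            return np.inf
        w, X, _, _ = _build_design(series, order, interventions, ds,
                                   include_constant)
        return -ss.loglik_given_all(ap, bp, w, X, b, s2)

    npar = pi0.size
    H = np.zeros((npar, npar))
    step = 1e-4 * np.maximum(1.0, np.abs(pi0))
    f0 = nll(pi0)
    # shrink any step that would cross the stationarity/invertibility
    # boundary (where the likelihood is undefined)
    for i in range(npar):
        ei = np.zeros(npar); ei[i] = 1.0
        while step[i] > 1e-10 and not (
                np.isfinite(nll(pi0 + step[i] * ei))
                and np.isfinite(nll(pi0 - step[i] * ei))):
            step[i] *= 0.2
    # central second differences
    for i in range(npar):
        ei = np.zeros(npar); ei[i] = step[i]
        fpp = nll(pi0 + ei); fmm = nll(pi0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / step[i] ** 2
        for j in range(i + 1, npar):
            ej = np.zeros(npar); ej[j] = step[j]
            fpq = nll(pi0 + ei + ej); fmq = nll(pi0 - ei + ej)
            fpm = nll(pi0 + ei - ej); fm2 = nll(pi0 - ei - ej)
            hij = (fpq - fmq - fpm + fm2) / (4 * step[i] * step[j])
            # a cross step may still cross the boundary; drop that term
            H[i, j] = H[j, i] = hij if np.isfinite(hij) else 0.0
    if not np.all(np.isfinite(H)):
        warnings.warn("Hessian not finite at the optimum; SEs unavailable",
                      stacklevel=2)
        return np.full((npar - 1, npar - 1), np.nan)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(H)
    if np.any(np.diag(cov_full) < 0):
        cov_full = np.linalg.pinv(H)
    return cov_full[:-1, :-1]   # drop log-sigma2 row/col


# --------------------------------------------------------------- forecast
def forecast(model: FittedModel, horizon: int,
             future_interventions: str | np.ndarray = "extend") -> Forecast:
    """Minimum-MSE forecasts with 95% prediction intervals.

    ``future_interventions`` controls the post-sample impact path:
    "extend" continues every fitted intervention per its shape, "zero"
    switches them all off (counterfactual continuation), or pass an array
    of length ``horizon`` with the total impact to add.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    order = model.order
    y = model.series.values
    impact_in = model.impact_series() if model.interventions else np.zeros(y.size)
    if isinstance(future_interventions, str):
        if future_interventions == "extend":
            impact_fut = (model.impact_series(horizon_extra=horizon)[y.size:]
                          if model.interventions else np.zeros(horizon))
        elif future_interventions == "zero":
            impact_fut = np.zeros(horizon)
        else:
            raise ValueError("future_interventions must be 'extend', 'zero' "
                             "or an array")
    else:
        impact_fut = np.asarray(future_interventions, float)
        if impact_fut.size != horizon:
            raise ValueError(
                f"future intervention path has length {impact_fut.size}, "
                f"expected {horizon}: supply a value for every future period"
            )

    N = y - impact_in                       # outcome net of interventions
    ap, bp = model._apoly(), model._bpoly()
    g = ss.poly_mul(ap, ss.diff_poly(order.d, order.D, order.s))
    cstar = model.mean * float(np.sum(ap))

    # innovations history for the MA part
    w = _difference(y, order.d, order.D, order.s)
    _, X, _, _ = _build_design(model.series, order, model.interventions,
                               model.deltas, model.include_constant)
    z = w - (X @ model.beta if X.size else 0.0)
    V, _ = ss.kalman_innovations(ap, bp, z[:, None])
    e_hist = V[:, 0]

    b = bp
    hist = list(N)
    e = list(np.r_[np.zeros(order.diff_loss), e_hist])
    mean = np.empty(horizon)
    for hstep in range(1, horizon + 1):
        t = len(hist)
        acc = cstar
        for i in range(1, g.size):
            if t - i >= 0:
                acc -= g[i] * hist[t - i]
        for l in range(hstep, b.size):
            acc += b[l] * e[t - l]
        hist.append(acc)
        mean[hstep - 1] = acc

    psi = ss.psi_weights(g, bp, horizon)
    var = model.sigma2 * np.cumsum(psi ** 2)
    se = np.sqrt(var)
    mean = mean + impact_fut
    if model.series.index is not None:
        idx = pd.period_range(model.series.index[-1] + 1, periods=horizon,
                              freq=model.series.index.freq)
    else:
        idx = None
    return Forecast(mean=mean, se=se, lo=mean - 1.96 * se,
                    hi=mean + 1.96 * se, index=idx)


# --------------------------------------------------------------- simulate
def simulate_from(model_or_order, n: int, seed: int,
                  phi=(), theta=(), sphi=(), stheta=(),
                  const: float = 0.0, sigma: float = 1.0) -> TimeSeries:
    """Simulate a SARIMA realisation (no intervention impact).

    Pass a :class:`FittedModel` to simulate from its estimates, or an
    :class:`ArimaOrder` with explicit parameters.  A burn-in of at least
    10 x (p + q + s) draws is discarded before integrating the d regular
    and D seasonal differences; output is deterministic given ``seed``.
    """
    if isinstance(model_or_order, FittedModel):
        m = model_or_order
        return simulate_from(m.order, n, seed, phi=m.phi, theta=m.theta,
                             sphi=m.seasonal_phi, stheta=m.seasonal_theta,
                             const=m.const, sigma=np.sqrt(m.sigma2))
    order = model_or_order
    if isinstance(order, tuple):
        order = ArimaOrder(*order)
    ap = ss.ar_poly(np.asarray(phi, float), np.asarray(sphi, float), order.s)
    bp = ss.ma_poly(np.asarray(theta, float), np.asarray(stheta, float), order.s)
    if not ss.poly_stable(ap):
        raise ValueError("unstable AR parameters: simulation would explode")
    if not ss.poly_stable(bp):
        raise ValueError("non-invertible MA parameters")
    a = -ap[1:]
    bcoef = bp[1:]
    burn = 10 * (ap.size - 1 + bp.size - 1 + order.s) + 50
    n_diff = n - order.diff_loss
    if n_diff < 1:
        raise ValueError("n too small for the requested differencing orders")
    total = burn + n_diff
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, total)
    wsim = np.zeros(total)
    for t in range(total):
        acc = const + eps[t]
        for i in range(1, min(t, a.size) + 1):
            acc += a[i - 1] * wsim[t - i]
        for jj in range(1, min(t, bcoef.size) + 1):
            acc += bcoef[jj - 1] * eps[t - jj]
        wsim[t] = acc
    w = wsim[burn:]
    level = _integrate(np.r_[np.zeros(order.diff_loss), w],
                       order.d, order.D, order.s)
    return TimeSeries(level[:n], period=order.s, label="simulated")
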