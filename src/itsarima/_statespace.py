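"""Numerical internals: polynomial algebra, Kalman filtering, whitening.

The exact Gaussian likelihood of a (seasonal) ARMA process is evaluated
through the innovations decomposition.  Two equivalent routes are used:

* a Harvey companion-form state space with the stationary initial
  covariance (general ARMA); the covariance recursion is data-independent
  so the gains are computed once and applied to the outcome and every
  regressor column simultaneously (which also yields exact GLS for the
  regression part);
* a direct whitening for pure-AR models (Cholesky of the stationary
  covariance of the first p observations, then the AR recursion), which
  is much faster inside simulation loops.

All routines work with lag polynomials stored as coefficient vectors
``[1, g_1, ..., g_k]`` meaning ``1 + g_1 B + ... + g_k B^k``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_discrete_lyapunov, solve_triangular

_STEADY_TOL = 1e-12


# ----------------------------------------------------------- polynomials
def poly_mul(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return np.convolve(np.asarray(p1, float), np.asarray(p2, float))


def ar_poly(phi: np.ndarray, sphi: np.ndarray, s: int) -> np.ndarray:
    """(1 - phi_1 B - ...)(1 - Phi_1 B^s - ...) as [1, g_1, ...]."""
    p = np.r_[1.0, -np.asarray(phi, float)]
    if np.size(sphi):
        ps = np.zeros(s * len(sphi) + 1)
        ps[0] = 1.0
        ps[s::s] = -np.asarray(sphi, float)
        p = poly_mul(p, ps)
    return p


def ma_poly(theta: np.ndarray, stheta: np.ndarray, s: int) -> np.ndarray:
    """(1 + theta_1 B + ...)(1 + Theta_1 B^s + ...) as [1, b_1, ...]."""
    p = np.r_[1.0, np.asarray(theta, float)]
    if np.size(stheta):
        ps = np.zeros(s * len(stheta) + 1)
        ps[0] = 1.0
        ps[s::s] = np.asarray(stheta, float)
        p = poly_mul(p, ps)
    return p


def diff_poly(d: int, D: int, s: int) -> np.ndarray:
    p = np.array([1.0])
    for _ in range(d):
        p = poly_mul(p, [1.0, -1.0])
    for _ in range(D):
        ps = np.zeros(s + 1)
        ps[0], ps[s] = 1.0, -1.0
        p = poly_mul(p, ps)
    return p


def poly_stable(poly: np.ndarray, tol: float = 1e-8) -> bool:
    """True when every root of the lag polynomial lies outside the unit circle."""
    poly = np.trim_zeros(np.asarray(poly, float), "b")
    if poly.size <= 1:
        return True
    roots = np.roots(poly[::-1])  # np.roots wants highest power first
    return bool(np.all(np.abs(roots) > 1.0 + tol))


# ------------------------------------------- stationarity reparameterisation
def pacf_to_ar(partials: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations in (-1,1) to a stationary AR vector.

    Durbin-Levinson in reverse: any vector of partials maps one-to-one
    onto the stationary region, which lets the optimiser roam an
    unconstrained space (via tanh) without ever leaving it.
    """
    partials = np.asarray(partials, float)
    phi = np.zeros(0)
    for k, r in enumerate(partials, start=1):
        new = np.empty(k)
        new[:-1] = phi - r * phi[::-1]
        new[-1] = r
        phi = new
    return phi


def unconstrained_to_ar(z: np.ndarray) -> np.ndarray:
    return pacf_to_ar(np.tanh(np.asarray(z, float)))


def unconstrained_to_ma(z: np.ndarray) -> np.ndarray:
    # invertible MA poly 1 + b_1 B + ... <=> stationary AR with a sign flip
    return -pacf_to_ar(np.tanh(np.asarray(z, float)))


# --------------------------------------------------------------- state space
def harvey_matrices(apoly: np.ndarray, bpoly: np.ndarray):
    """Companion transition matrix T and shock loading R for an ARMA model.

    apoly, bpoly are the full (seasonal-expanded) lag polynomials; the
    observed value is the first state element.
    """
    a = -np.asarray(apoly, float)[1:]   # w_t = sum a_i w_{t-i} + ...
    b = np.asarray(bpoly, float)[1:]
    m = max(a.size, b.size + 1)
    T = np.zeros((m, m))
    T[: a.size, 0] = a
    for i in range(m - 1):
        T[i, i + 1] = 1.0
    R = np.zeros(m)
    R[0] = 1.0
    R[1 : b.size + 1] = b
    return T, R


def stationary_state_cov(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    return solve_discrete_lyapunov(T, np.outer(R, R))


def kalman_gains(apoly: np.ndarray, bpoly: np.ndarray, n: int):
    """Innovation variances F_t and gains K_t (unit shock variance).

    The covariance recursion does not involve the data, so it is run once
    per parameter value; after it reaches steady state the remaining
    entries are filled with the limiting gain.
    """
    T, R = harvey_matrices(apoly, bpoly)
    m = T.shape[0]
    P = stationary_state_cov(T, R)
    RR = np.outer(R, R)
    F = np.empty(n)
    K = np.empty((n, m))
    steady_at = n
    for t in range(n):
        Ft = P[0, 0]
        Kt = T @ P[:, 0] / Ft
        F[t] = Ft
        K[t] = Kt
        Pn = T @ P @ T.T + RR - np.outer(Kt, Kt) * Ft
        if np.max(np.abs(Pn - P)) < _STEADY_TOL:
            steady_at = t + 1
            P = Pn
            break
        P = Pn
    if steady_at < n:
        F[steady_at:] = F[steady_at - 1]
        K[steady_at:] = K[steady_at - 1]
    return T, F, K


def kalman_innovations(apoly: np.ndarray, bpoly: np.ndarray, Z: np.ndarray):
    """One-step innovations of each column of Z under the ARMA model.

    Returns (V, F): V[t, j] is the innovation of column j at time t and F
    the innovation variance profile (common to all columns, sigma^2 = 1).
    """
    Z = np.atleast_2d(np.asarray(Z, float).T).T  # (n, c)
    n, c = Z.shape
    m_ar = np.trim_zeros(apoly, "b").size - 1
    m_ma = np.trim_zeros(bpoly, "b").size - 1
    if m_ar == 0 and m_ma == 0:
        return Z.copy(), np.ones(n)
    T, F, K = kalman_gains(apoly, bpoly, n)
    m = T.shape[0]
    A = np.zeros((m, c))
    V = np.empty((n, c))
    for t in range(n):
        v = Z[t] - A[0]
        V[t] = v
        A = T @ A + np.outer(K[t], v)
    return V, F


def ar_whiten(apoly: np.ndarray, Z: np.ndarray):
    """Exact whitening for a pure AR model (no MA part).

    The first p observations are decorrelated with the Cholesky factor of
    their stationary covariance; the rest via the AR recursion (unit
    innovation variance).  Returns (E, logdet) with loglik contribution
    -logdet/2 relative to unit innovation variances.
    """
    Z = np.atleast_2d(np.asarray(Z, float).T).T
    n, _ = Z.shape
    a = -np.asarray(apoly, float)[1:]
    p = a.size
    if p == 0:
        return Z.copy(), 0.0
    # lag-state companion (w_t, ..., w_{t-p+1}): its stationary covariance
    # is exactly the Toeplitz matrix Gamma(|i-j|) of the AR process
    T = np.zeros((p, p))
    T[0, :] = a
    T[1:, :-1] = np.eye(p - 1)
    R = np.zeros(p)
    R[0] = 1.0
    G = stationary_state_cov(T, R)
    L = cholesky(G, lower=True)
    E = np.empty_like(Z)
    head = min(p, n)
    E[:head] = solve_triangular(L[:head, :head], Z[:head], lower=True)
    if n > p:
        tail = Z[p:].copy()
        for i in range(1, p + 1):
            tail -= a[i - 1] * Z[p - i : n - i]
        E[p:] = tail
    logdet = 2.0 * float(np.sum(np.log(np.diag(L[:head, :head]))))
    return E, logdet


def whiten(apoly: np.ndarray, bpoly: np.ndarray, Z: np.ndarray):
    """Innovations scaled to unit variance plus the log-det term.

    loglik(z; sigma^2) = -n/2 log(2 pi sigma^2) - logdet/2 - e'e/(2 sigma^2)
    for each whitened column e.
    """
    if np.trim_zeros(bpoly, "b").size - 1 == 0:
        return ar_whiten(apoly, Z)
    V, F = kalman_innovations(apoly, bpoly, Z)
    sq = np.sqrt(F)
    return V / sq[:, None], float(np.sum(np.log(F)))


def profile_gls_loglik(apoly, bpoly, w, X):
    """Concentrated loglik with the regression and variance profiled out.

    Returns (loglik, beta, sigma2, resid) where resid are the whitened
    innovations of w - X beta (amplitude sigma, unit variance profile).
    """
    n = w.size
    cols = [w[:, None]]
    if X is not None and X.size:
        cols.append(X)
    E, logdet = whiten(apoly, bpoly, np.hstack(cols))
    if not np.all(np.isfinite(E)):
        raise np.linalg.LinAlgError("whitening produced non-finite values")
    ew = E[:, 0]
    if E.shape[1] > 1:
        EX = E[:, 1:]
        beta, *_ = np.linalg.lstsq(EX, ew, rcond=None)
        resid = ew - EX @ beta
    else:
        beta = np.zeros(0)
        resid = ew
    ssr = float(resid @ resid)
    sigma2 = max(ssr / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi) + 1.0 + np.log(sigma2)) - 0.5 * logdet
    return loglik, beta, sigma2, resid


def loglik_given_all(apoly, bpoly, w, X, beta, sigma2):
    """Non-concentrated exact loglik at explicit (beta, sigma2)."""
    z = w - (X @ beta if (X is not None and X.size) else 0.0)
    E, logdet = whiten(apoly, bpoly, z[:, None])
    e = E[:, 0]
    n = w.size
    return float(-0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * logdet
                 - 0.5 * float(e @ e) / sigma2)


def psi_weights(pipoly: np.ndarray, bpoly: np.ndarray, h: int) -> np.ndarray:
    """MA(infinity) weights of theta(B)/pi(B) up to lag h-1."""
    g = np.asarray(pipoly, float)
    b = np.asarray(bpoly, float)
    psi = np.zeros(h)
    for j in range(h):
        acc = b[j] if j < b.size else 0.0
        for i in range(1, min(j, g.size - 1) + 1):
            acc -= g[i] * psi[j - i]
        psi[j] = acc
    return psi
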