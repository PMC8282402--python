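"""ARIMA(p, d, q) conditional mean model with Gaussian quasi-MLE.

The estimator maximizes the conditional (CSS-style) Gaussian likelihood
of the ARMA recursion on the d-times differenced series, with zero
pre-sample values. For the 6000-sample one-minute segments this pipeline
targets, conditional and exact likelihoods coincide asymptotically.

Stationarity of the AR polynomial and invertibility of the MA polynomial
are enforced by optimizing in partial-autocorrelation space (the
Levinson-Durbin bijection between coefficient vectors and vectors in
(-1, 1)^k), so the outer optimizer is unconstrained.

The mean of the differenced series is removed before fitting and added
back when producing one-step fitted values; the ARMA recursion itself
carries no intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from ._kernels import arma_residuals, arma_simulate

_LOG_2PI = float(np.log(2.0 * np.pi))
_PACF_CLIP = 0.98


@dataclass(frozen=True)
class ArimaOrders:
    p: int
    d: int
    q: int

    def __post_init__(self):
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be nonnegative")
        if self.d > 2:
            raise ValueError(f"differencing order d must be <= 2, got {self.d}")

    @property
    def n_params(self) -> int:
        # AR + MA coefficients + the innovation variance
        return self.p + self.q + 1


@dataclass
class ArimaFit:
    orders: ArimaOrders
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    innovation_variance: float
    residuals: np.ndarray          # one per differenced observation
    loglik: float
    mean_diff: float               # mean of the differenced series, re-added in fitted values
    converged: bool
    n_params: int

    def to_dict(self) -> dict:
        return {
            "model": "ARIMA",
            "orders": {"p": self.orders.p, "d": self.orders.d, "q": self.orders.q},
            "ar_coeffs": [float(v) for v in self.ar_coeffs],
            "ma_coeffs": [float(v) for v in self.ma_coeffs],
            "innovation_variance": float(self.innovation_variance),
            "mean_diff": float(self.mean_diff),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0


def difference(x: Sequence[float], d: int) -> np.ndarray:
    """Apply (1 - L) d times; output loses d leading samples."""
    x = np.asarray(x, dtype=float)
    if d < 0 or d > 2:
        raise ValueError(f"d must be in {{0, 1, 2}}, got {d}")
    if x.size <= d:
        raise ValueError(f"series of length {x.size} too short for d={d}")
    return np.diff(x, n=d) if d > 0 else x.copy()


def integrate(dx: Sequence[float], d: int, initial_values: Sequence[float]) -> np.ndarray:
    """Exact inverse of :func:`difference`: rebuild x from its d-th differences.

    ``initial_values`` are the first d samples of the original series.
    """
    dx = np.asarray(dx, dtype=float)
    init = np.asarray(initial_values, dtype=float)
    if d < 0 or d > 2:
        raise ValueError(f"d must be in {{0, 1, 2}}, got {d}")
    if init.size != d:
        raise ValueError(f"expected {d} initial values, got {init.size}")
    if d == 0:
        return dx.copy()
    out = dx
    for k in range(d, 0, -1):
        # first value at level k-1 is the (k-1)-th difference of the initial samples
        head = difference(init, k - 1)[0]
        out = np.concatenate([[head], out]).cumsum()
    return out


def pacf_to_coef(r: np.ndarray) -> np.ndarray:
    """Levinson-Durbin map from partial autocorrelations to AR coefficients."""
    a = np.zeros(0)
    for rk in r:
        a = np.concatenate([a - rk * a[::-1], [rk]])
    return a


def coef_to_pacf(a: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pacf_to_coef`; clips to the stationary region when needed."""
    a = np.asarray(a, dtype=float).copy()
    k = a.size
    r = np.zeros(k)
    for i in range(k - 1, -1, -1):
        rk = float(np.clip(a[i], -_PACF_CLIP, _PACF_CLIP))
        r[i] = rk
        if i > 0:
            head = a[:i]
            denom = 1.0 - rk * rk
            a = (head + rk * head[::-1]) / denom
    return r


def arima_loglik(params: dict, x: Sequence[float], orders: ArimaOrders) -> dict:
    """Conditional Gaussian log-likelihood of an ARMA parameter set.

    ``x`` must already be differenced d times. Residuals follow the
    recursion with zero pre-sample values; the likelihood sums Gaussian
    log-densities over t > max(p, q). An explosive recursion yields
    ``loglik = -inf`` rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    ar = np.asarray(params.get("ar_coeffs", []), dtype=float)
    ma = np.asarray(params.get("ma_coeffs", []), dtype=float)
    s2 = float(params["innovation_variance"])
    if s2 <= 0:
        raise ValueError("innovation_variance must be positive")
    if ar.size != orders.p or ma.size != orders.q:
        raise ValueError("coefficient lengths disagree with orders")
    eps = arma_residuals(x, ar, ma)
    m = max(orders.p, orders.q)
    # an explosive MA recursion blows the residuals up; flag, don't raise
    if not np.all(np.isfinite(eps)) or np.max(np.abs(eps)) > 1e100:
        return {"loglik": -np.inf, "residuals": eps}
    tail = eps[m:]
    ll = -0.5 * tail.size * (_LOG_2PI + np.log(s2)) - float(tail @ tail) / (2.0 * s2)
    return {"loglik": float(ll), "residuals": eps}


def _concentrated_negloglik(u: np.ndarray, wc: np.ndarray, p: int, q: int) -> float:
    ar = pacf_to_coef(np.tanh(u[:p]))
    ma = -pacf_to_coef(np.tanh(u[p:]))
    eps = arma_residuals(wc, ar, ma)
    if not np.all(np.isfinite(eps)):
        return 1e12
    m = max(p, q)
    tail = eps[m:]
    s2 = float(tail @ tail) / tail.size
    if not np.isfinite(s2) or s2 <= 0:
        return 1e12
    return 0.5 * tail.size * (_LOG_2PI + np.log(s2) + 1.0)


def _hannan_rissanen_start(wc: np.ndarray, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Long-AR residual regression giving starting AR/MA coefficients."""
    n = wc.size
    h = int(min(max(20, 2 * (p + q)), max(p + q + 1, n // 4)))
    # stage 1: long AR to approximate the innovations
    if h > 0 and n > 2 * h:
        rows = n - h
        lagmat = np.column_stack([wc[h - k - 1 : h - k - 1 + rows] for k in range(h)])
        phi, *_ = np.linalg.lstsq(lagmat, wc[h:], rcond=None)
        ehat = np.zeros(n)
        ehat[h:] = wc[h:] - lagmat @ phi
    else:
        ehat = wc.copy()
    # stage 2: regress w_t on its own lags and innovation lags
    m = max(p, q)
    rows = n - m
    cols = []
    for k in range(p):
        cols.append(wc[m - k - 1 : m - k - 1 + rows])
    for k in range(q):
        cols.append(ehat[m - k - 1 : m - k - 1 + rows])
    if not cols:
        return np.zeros(0), np.zeros(0)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, wc[m:], rcond=None)
    return coef[:p], coef[p:]


def fit_arima(x: Sequence[float], orders: ArimaOrders,
              options: FitOptions = FitOptions()) -> ArimaFit:
    """Quasi-MLE fit of an ARIMA(p, d, q) model to a raw series."""
    x = np.asarray(x, dtype=float)
    if x.size < 10 * orders.n_params + orders.d:
        raise ValueError(
            f"series of length {x.size} too short for ARIMA({orders.p},{orders.d},{orders.q}); "
            f"need at least {10 * orders.n_params + orders.d}"
        )
    w = difference(x, orders.d)
    mu = float(np.mean(w))
    wc = w - mu
    p, q = orders.p, orders.q
    m = max(p, q)

    converged = True
    if p + q == 0:
        ar = np.zeros(0)
        ma = np.zeros(0)
    else:
        ar0, ma0 = _hannan_rissanen_start(wc, p, q)
        u0 = np.concatenate([
            np.arctanh(coef_to_pacf(ar0)),
            np.arctanh(coef_to_pacf(-ma0)),
        ])
        u0 = np.clip(u0, -3.0, 3.0)
        res = optimize.minimize(
            _concentrated_negloglik, u0, args=(wc, p, q), method="L-BFGS-B",
            options={"maxiter": options.max_iter, "ftol": options.tol, "gtol": 1e-10},
        )
        polish = optimize.minimize(
            _concentrated_negloglik, res.x, args=(wc, p, q), method="Nelder-Mead",
            options={"maxiter": options.max_iter * (p + q), "xatol": 1e-9,
                     "fatol": options.tol},
        )
        best = polish if polish.fun < res.fun else res
        converged = bool(best.success or res.success)
        ar = pacf_to_coef(np.tanh(best.x[:p]))
        ma = -pacf_to_coef(np.tanh(best.x[p:]))

    eps = arma_residuals(wc, ar, ma)
    tail = eps[m:]
    s2 = float(tail @ tail) / tail.size
    ll = -0.5 * tail.size * (_LOG_2PI + np.log(s2)) - float(tail @ tail) / (2.0 * s2)
    return ArimaFit(
        orders=orders, ar_coeffs=ar, ma_coeffs=ma, innovation_variance=s2,
        residuals=eps, loglik=float(ll), mean_diff=mu, converged=converged,
        n_params=orders.n_params,
    )


def filter_arima(x: Sequence[float], orders: ArimaOrders, ar: Sequence[float],
                 ma: Sequence[float], mean_diff: Optional[float] = None) -> ArimaFit:
    """Apply fixed ARIMA parameters to a new series (no estimation).

    Used to evaluate a model estimated on training segments against
    held-out segments: residuals and likelihood are recomputed on ``x``
    but the coefficients stay as given. When ``mean_diff`` is None the
    mean of the differenced ``x`` is used.
    """
    x = np.asarray(x, dtype=float)
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    if ar.size != orders.p or ma.size != orders.q:
        raise ValueError("coefficient lengths disagree with orders")
    w = difference(x, orders.d)
    mu = float(np.mean(w)) if mean_diff is None else float(mean_diff)
    eps = arma_residuals(w - mu, ar, ma)
    m = max(orders.p, orders.q)
    tail = eps[m:]
    s2 = float(tail @ tail) / tail.size
    ll = -0.5 * tail.size * (_LOG_2PI + np.log(s2)) - float(tail @ tail) / (2.0 * s2)
    return ArimaFit(orders=orders, ar_coeffs=ar, ma_coeffs=ma, innovation_variance=s2,
                    residuals=eps, loglik=float(ll), mean_diff=mu, converged=True,
                    n_params=orders.n_params)


def arima_fitted(fit: ArimaFit, x_original: Sequence[float]) -> np.ndarray:
    """One-step-ahead conditional means on the original amplitude scale.

    ``fitted_t = x_t - eps_t`` through the integration relation; the first
    ``d + max(p, q)`` positions copy the observation (no prediction there),
    so every segment yields a full-length fitted vector.
    """
    x = np.asarray(x_original, dtype=float)
    d = fit.orders.d
    if x.size - d != fit.residuals.size:
        raise ValueError("x_original length does not match the fitted residuals")
    fitted = x.copy()
    head = d + max(fit.orders.p, fit.orders.q)
    idx = np.arange(head, x.size)
    fitted[idx] = x[idx] - fit.residuals[idx - d]
    return fitted


def simulate_arima(orders: ArimaOrders, ar: Sequence[float], ma: Sequence[float],
                   sigma2: float, n: int, seed: int, burn_in: int = 500,
                   initial_values: Optional[Sequence[float]] = None) -> np.ndarray:
    """Generate an ARIMA path with Gaussian innovations (ground-truth tool)."""
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    if ar.size != orders.p or ma.size != orders.q:
        raise ValueError("coefficient lengths disagree with orders")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=n - orders.d + burn_in)
    w = arma_simulate(eps, ar, ma)[burn_in:]
    init = np.zeros(orders.d) if initial_values is None else np.asarray(initial_values, float)
    return integrate(w, orders.d, init)
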