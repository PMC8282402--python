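"""Conditional-variance models: ARCH, GARCH, GJR-GARCH, EGARCH.

All four families share the observation equation ``y_t = sigma_t Z_t``
with ``Z_t ~ N(0, 1)`` and differ in the recursion driving ``sigma_t^2``:

* ARCH(q):   sigma2_t = alpha0 + sum_i alpha_i y_{t-i}^2
* GARCH(p,q): adds  sum_j beta_j sigma2_{t-j}
* GJR(p,q):  adds   sum_i gamma_i 1[y_{t-i} < 0] y_{t-i}^2  (leverage)
* EGARCH(p,q): log sigma2_t = alpha0
      + sum_i [ theta_i Z_{t-i} + lam_i (|Z_{t-i}| - E|Z|) ]
      + sum_j beta_j log sigma2_{t-j},        E|Z| = sqrt(2/pi)

Naming convention: ``alpha`` are shock loadings and ``beta`` persistence
coefficients in every family. For EGARCH the shock side splits into a
sign part (theta) and a magnitude part (lam), one pair per shock lag —
the identifiable form of Nelson's g(Z) = theta Z + lam (|Z| - E|Z|).
EGARCH coefficients carry no sign restrictions; only the persistence sum
is kept inside (-1, 1) so log-variance is stationary.

Estimation is Gaussian quasi-MLE with the standard conventions:
pre-sample variance set to the sample variance of the input, pre-sample
shocks zero, likelihood summed over t > max(p, q).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from ._kernels import (
    SQRT_2_OVER_PI,
    egarch_simulate,
    egarch_variance_path,
    garch_simulate,
    garch_variance_path,
    gaussian_loglik_terms,
)

FAMILIES = ("ARCH", "GARCH", "GJR", "EGARCH")

_LOG_2PI = float(np.log(2.0 * np.pi))
_BIG = 1e12


@dataclass(frozen=True)
class VolatilityOrders:
    family: str
    p: int  # variance (persistence) lags
    q: int  # shock lags

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.q < 1:
            raise ValueError("q (shock lags) must be >= 1")
        if self.p < 0:
            raise ValueError("p (variance lags) must be >= 0")
        if self.family == "ARCH" and self.p != 0:
            raise ValueError("ARCH has no variance lags; use p=0")

    @property
    def n_params(self) -> int:
        if self.family == "EGARCH":
            return 1 + 2 * self.q + self.p          # alpha0, (theta, lam) per lag, beta
        if self.family == "GJR":
            return 1 + 2 * self.q + self.p          # alpha0, (alpha, gamma) per lag, beta
        return 1 + self.q + self.p                  # alpha0, alpha, beta

    @property
    def max_lag(self) -> int:
        return max(self.p, self.q)


def _as_vec(v, length, name) -> np.ndarray:
    if v is None:
        return np.zeros(length)
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1 and length > 1:
        raise ValueError(f"{name} must have length {length}")
    if arr.size != length:
        raise ValueError(f"{name} must have length {length}, got {arr.size}")
    return arr


@dataclass(frozen=True)
class VolatilityParams:
    """Coefficient set; unused fields for a family may be left None."""

    alpha0: float
    alpha: Optional[Sequence[float]] = None   # shock loadings (ARCH/GARCH/GJR)
    beta: Optional[Sequence[float]] = None    # persistence
    gamma: Optional[Sequence[float]] = None   # GJR asymmetry
    theta: Optional[Sequence[float]] = None   # EGARCH sign coefficients
    lam: Optional[Sequence[float]] = None     # EGARCH magnitude coefficients

    def validated(self, orders: VolatilityOrders) -> "VolatilityParams":
        """Return a canonical copy with vectors shaped for ``orders``."""
        p, q = orders.p, orders.q
        beta = _as_vec(self.beta, p, "beta")
        if orders.family == "EGARCH":
            out = VolatilityParams(
                alpha0=float(self.alpha0),
                alpha=np.zeros(0),
                beta=beta,
                gamma=np.zeros(0),
                theta=_as_vec(self.theta, q, "theta"),
                lam=_as_vec(self.lam, q, "lam"),
            )
            if abs(np.sum(beta)) >= 1.0:
                raise ValueError("EGARCH persistence |sum(beta)| must be < 1")
            return out
        alpha = _as_vec(self.alpha, q, "alpha")
        gamma = _as_vec(self.gamma, q, "gamma")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if np.any(alpha < 0) or np.any(beta < 0):
            raise ValueError("alpha and beta must be nonnegative")
        if orders.family == "GJR" and np.any(alpha + gamma < 0):
            raise ValueError("GJR requires alpha_i + gamma_i >= 0")
        if orders.family != "GJR" and np.any(gamma != 0):
            raise ValueError(f"gamma is only meaningful for GJR, not {orders.family}")
        return VolatilityParams(
            alpha0=float(self.alpha0), alpha=alpha, beta=beta, gamma=gamma,
            theta=None, lam=None,
        )

    def persistence(self, orders: VolatilityOrders) -> float:
        v = self.validated(orders)
        if orders.family == "EGARCH":
            return float(np.sum(v.beta))
        return float(np.sum(v.alpha) + np.sum(v.beta) + 0.5 * np.sum(v.gamma))

    def to_dict(self, orders: VolatilityOrders) -> dict:
        v = self.validated(orders)
        out = {"alpha0": float(v.alpha0), "beta": [float(b) for b in v.beta]}
        if orders.family == "EGARCH":
            out["theta"] = [float(t) for t in v.theta]
            out["lam"] = [float(t) for t in v.lam]
        else:
            out["alpha"] = [float(a) for a in v.alpha]
            if orders.family == "GJR":
                out["gamma"] = [float(g) for g in v.gamma]
        return out


@dataclass
class VolatilityFit:
    orders: VolatilityOrders
    params: VolatilityParams
    sigma2_path: np.ndarray
    std_residuals: np.ndarray
    loglik: float
    n_params: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.orders.family,
            "orders": {"p": self.orders.p, "q": self.orders.q},
            "params": self.params.to_dict(self.orders),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class VolFitOptions:
    max_iter: int = 2000
    tol: float = 1e-9
    seed: int = 0


def egarch_g(z: float, theta: float, lam: float) -> float:
    """Nelson's news-impact function g(z) = theta z + lam (|z| - E|Z|)."""
    return theta * z + lam * (abs(z) - SQRT_2_OVER_PI)


def variance_path(y: Sequence[float], orders: VolatilityOrders,
                  params: VolatilityParams,
                  sigma2_init: Optional[float] = None) -> np.ndarray:
    """Conditional variance sequence for given parameters.

    The first max(p, q) variances equal ``sigma2_init`` (default: the
    sample variance of ``y``); the recursion runs from there with
    pre-sample shocks treated as zero. Raises ``ValueError`` when the
    recursion produces a nonpositive or nonfinite variance (the
    likelihood treats that case as -inf instead).
    """
    sigma2, ok = _raw_variance_path(np.asarray(y, dtype=float), orders,
                                    params.validated(orders), sigma2_init)
    if not ok:
        raise ValueError("invalid variance path (nonpositive or nonfinite sigma^2)")
    return sigma2


def _raw_variance_path(y, orders, v, sigma2_init=None):
    init = float(np.var(y)) if sigma2_init is None else float(sigma2_init)
    if init <= 0:
        init = 1e-12
    if orders.family == "EGARCH":
        return egarch_variance_path(y, v.alpha0, np.asarray(v.theta, float),
                                    np.asarray(v.lam, float), np.asarray(v.beta, float),
                                    float(np.log(init)))
    return garch_variance_path(y, v.alpha0, np.asarray(v.alpha, float),
                               np.asarray(v.gamma, float), np.asarray(v.beta, float),
                               init, orders.family == "GJR")


def volatility_loglik(y: Sequence[float], orders: VolatilityOrders,
                      params: VolatilityParams) -> float:
    """Gaussian quasi-log-likelihood over t > max(p, q); -inf for invalid paths."""
    y = np.asarray(y, dtype=float)
    try:
        v = params.validated(orders)
    except ValueError:
        return -np.inf
    sigma2, ok = _raw_variance_path(y, orders, v)
    if not ok:
        return -np.inf
    return float(gaussian_loglik_terms(y, sigma2, orders.max_lag))


# ---------------------------------------------------------------------------
# estimation: unconstrained transform <-> constrained parameter vector
# ---------------------------------------------------------------------------

def _pack_start(orders: VolatilityOrders, y: np.ndarray,
                persistent: bool = True) -> np.ndarray:
    """Starting point in the unconstrained space.

    Two starts are used by the fitter: a persistent one (the typical
    volatile-data solution) and a low-persistence one. On data with no
    ARCH effect the likelihood is flat along the alpha ~ 0 ridge and a
    persistent start would strand beta at its starting value.
    """
    v = float(np.var(y))
    p, q = orders.p, orders.q
    if orders.family == "EGARCH":
        beta_tot = (0.9 if persistent else 0.1) if p else 0.0
        u = [np.log(max(v, 1e-12)) * (1.0 - beta_tot)]
        u += [0.0] * q                      # theta
        u += [(0.1 if persistent else 0.02) / q] * q   # lam
        u += [np.arctanh(beta_tot / p / 0.9995)] * p if p else []
        return np.asarray(u)
    a_tot = 0.10 if persistent else 0.03
    b_tot = ((0.80 if persistent else 0.10) if p else 0.0)
    u = [np.log(max(v * (1 - a_tot - b_tot), 1e-12))]
    u += [np.log(a_tot / q)] * q
    if orders.family == "GJR":
        u += [0.02 / q] * q                 # gamma, raw
    u += [np.log(b_tot / p)] * p if p else []
    return np.asarray(u)


def _unpack(u: np.ndarray, orders: VolatilityOrders) -> VolatilityParams:
    p, q = orders.p, orders.q
    if orders.family == "EGARCH":
        alpha0 = u[0]
        theta = u[1 : 1 + q]
        lam = u[1 + q : 1 + 2 * q]
        beta = np.tanh(u[1 + 2 * q :]) * (0.9995 / max(p, 1))
        return VolatilityParams(alpha0=float(alpha0), theta=theta, lam=lam, beta=beta)
    alpha0 = np.exp(u[0])
    alpha = np.exp(u[1 : 1 + q])
    k = 1 + q
    gamma = None
    if orders.family == "GJR":
        gamma = u[k : k + q]
        k += q
    beta = np.exp(u[k :])
    return VolatilityParams(alpha0=float(alpha0), alpha=alpha, beta=beta, gamma=gamma)


def _negloglik_u(u: np.ndarray, y: np.ndarray, orders: VolatilityOrders) -> float:
    params = _unpack(u, orders)
    try:
        v = params.validated(orders)
    except ValueError:
        return _BIG
    if orders.family != "EGARCH" and params.persistence(orders) >= 0.9995:
        return _BIG
    sigma2, ok = _raw_variance_path(y, orders, v)
    if not ok:
        return _BIG
    ll = gaussian_loglik_terms(y, sigma2, orders.max_lag)
    if not np.isfinite(ll):
        return _BIG
    return -float(ll)


def _parsimony_sweep(y: np.ndarray, orders: VolatilityOrders,
                     params: VolatilityParams, f_best: float) -> VolatilityParams:
    """Collapse the no-ARCH likelihood ridge toward the parsimonious end.

    When the data carry no ARCH effect the quasi-likelihood is exactly flat
    along alpha -> 0 with alpha0 = var(y) (1 - sum beta): the optimizer's
    stopping point on that ridge is arbitrary. Among parameter vectors whose
    likelihood is indistinguishable from the optimum, report the least
    persistent one; for informative data any shrinkage costs far more than
    the tolerance and the fit is left untouched.
    """
    v = float(np.var(y))
    tol = 1e-4 * (1.0 + abs(f_best))
    chosen = params
    for s in (0.0, 0.25, 0.5):
        if orders.family == "EGARCH":
            cand = VolatilityParams(
                alpha0=float(np.log(max(v, 1e-300))) * (1.0 - s * np.sum(params.beta)),
                theta=np.asarray(params.theta) * s, lam=np.asarray(params.lam) * s,
                beta=np.asarray(params.beta) * s)
        else:
            pers = s * params.persistence(orders)
            cand = VolatilityParams(
                alpha0=max(v * (1.0 - pers), 1e-300),
                alpha=np.asarray(params.alpha) * s, beta=np.asarray(params.beta) * s,
                gamma=np.asarray(params.gamma) * s if orders.family == "GJR" else None)
        try:
            f = -volatility_loglik(y, orders, cand)
        except ValueError:
            continue
        if f <= f_best + tol:
            chosen = cand.validated(orders)
            break
    return chosen


def fit_volatility(y: Sequence[float], orders: VolatilityOrders,
                   options: VolFitOptions = VolFitOptions()) -> VolatilityFit:
    """Constrained Gaussian quasi-MLE for any of the four families."""
    y = np.asarray(y, dtype=float)
    if y.size < 10 * orders.n_params:
        raise ValueError(
            f"series of length {y.size} too short for {orders.family}"
            f"({orders.p},{orders.q}); need at least {10 * orders.n_params}"
        )
    candidates = []
    for persistent in (True, False):
        u0 = _pack_start(orders, y, persistent=persistent)
        nm = optimize.minimize(
            _negloglik_u, u0, args=(y, orders), method="Nelder-Mead",
            options={"maxiter": options.max_iter * u0.size,
                     "maxfev": options.max_iter * u0.size,
                     "xatol": 1e-8, "fatol": options.tol},
        )
        lb = optimize.minimize(
            _negloglik_u, nm.x, args=(y, orders), method="L-BFGS-B",
            bounds=[(-25.0, 25.0)] * u0.size,
            options={"maxiter": options.max_iter, "ftol": options.tol},
        )
        res = lb if lb.fun <= nm.fun else nm
        pers = abs(_unpack(res.x, orders).persistence(orders))
        candidates.append((res, pers, bool(res.success or nm.success)))
    # strictly better likelihood wins; on a near-tie (flat no-ARCH ridge)
    # prefer the less persistent, identifiable solution
    (res_a, pers_a, ok_a), (res_b, pers_b, ok_b) = candidates
    tie = abs(res_a.fun - res_b.fun) <= 1e-4 * (1.0 + abs(res_a.fun))
    if (tie and pers_b < pers_a) or (not tie and res_b.fun < res_a.fun):
        best, converged = res_b, ok_b
    else:
        best, converged = res_a, ok_a
    params = _unpack(best.x, orders).validated(orders)
    params = _parsimony_sweep(y, orders, params, float(best.fun))
    sigma2, ok = _raw_variance_path(y, orders, params)
    if not ok:
        raise RuntimeError("optimizer returned an invalid variance path")
    ll = float(gaussian_loglik_terms(y, sigma2, orders.max_lag))
    return VolatilityFit(
        orders=orders, params=params, sigma2_path=sigma2,
        std_residuals=y / np.sqrt(sigma2), loglik=ll,
        n_params=orders.n_params, converged=converged,
    )


def simulate_volatility(orders: VolatilityOrders, params: VolatilityParams,
                        n: int, seed: int, burn_in: int = 500) -> dict:
    """Generate y_t = sigma_t Z_t from the recursion; burn-in discarded."""
    v = params.validated(orders)
    pers = params.persistence(orders)
    if orders.family == "EGARCH":
        if abs(pers) >= 1.0:
            raise ValueError(f"explosive EGARCH persistence {pers}")
        log_init = v.alpha0 / (1.0 - pers)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n + burn_in)
        y, sigma2 = egarch_simulate(z, v.alpha0, np.asarray(v.theta, float),
                                    np.asarray(v.lam, float), np.asarray(v.beta, float),
                                    float(log_init))
    else:
        if pers >= 1.0:
            raise ValueError(f"explosive persistence {pers} (needs sum < 1)")
        denom = 1.0 - pers
        init = v.alpha0 / denom if denom > 0 else float(np.nan)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n + burn_in)
        y, sigma2 = garch_simulate(z, v.alpha0, np.asarray(v.alpha, float),
                                   np.asarray(v.gamma, float), np.asarray(v.beta, float),
                                   float(init), orders.family == "GJR")
    return {"y": y[burn_in:], "sigma2": sigma2[burn_in:]}
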