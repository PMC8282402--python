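"""The composite conditional mean + conditional variance model.

An ARIMA(p, d, q) process captures the linear, nonstationary-in-mean
structure of an ECG segment; the heteroskedasticity left in its
innovations is modeled by a GARCH-family recursion (EGARCH by default).
Fitting proceeds in stages:

1. quasi-MLE of the ARIMA mean model;
2. quasi-MLE of the volatility model on the ARIMA innovations;
3. (default) joint refinement — mean and variance parameters are
   re-estimated together by maximizing the heteroskedastic Gaussian
   likelihood  sum_t -1/2 [log 2pi + log sigma2_t + eps_t^2 / sigma2_t],
   started from the two-stage solution.

Stage 3 is what differentiates the composite's conditional mean from
plain ARIMA: weighting innovations by their conditional variance is a
GLS-style re-estimation that is statistically more efficient when the
innovations really are heteroskedastic. The refined solution never has a
lower joint likelihood than the two-stage one (the two-stage iterate is
kept if the optimizer fails to improve on it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from ._kernels import arma_residuals, gaussian_loglik_terms
from .arima import (
    ArimaFit,
    ArimaOrders,
    FitOptions,
    arima_fitted,
    coef_to_pacf,
    difference,
    fit_arima,
    pacf_to_coef,
)
from .garch import (
    VolatilityFit,
    VolatilityOrders,
    VolatilityParams,
    VolFitOptions,
    _raw_variance_path,
    _unpack,
    fit_volatility,
)

_BIG = 1e12


@dataclass
class CompositeFit:
    arima: ArimaFit
    volatility: VolatilityFit
    joint_loglik: float
    fitted: np.ndarray
    n_params: int
    mode: str                      # "two-stage" or "joint"
    refined: bool                  # joint refinement improved on the two-stage start

    def to_dict(self) -> dict:
        return {
            "model": f"ARIMA-{self.volatility.orders.family}",
            "mode": self.mode,
            "arima": self.arima.to_dict(),
            "volatility": self.volatility.to_dict(),
            "joint_loglik": float(self.joint_loglik),
            "n_params": int(self.n_params),
            "refined": bool(self.refined),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _joint_burn(arima_orders: ArimaOrders, vol_orders: VolatilityOrders) -> int:
    return max(max(arima_orders.p, arima_orders.q), vol_orders.max_lag)


def _joint_negloglik(u, wc, arima_orders, vol_orders, burn):
    p, q = arima_orders.p, arima_orders.q
    ar = pacf_to_coef(np.tanh(u[:p]))
    ma = -pacf_to_coef(np.tanh(u[p : p + q]))
    eps = arma_residuals(wc, ar, ma)
    if not np.all(np.isfinite(eps)):
        return _BIG
    params = _unpack(u[p + q :], vol_orders)
    try:
        v = params.validated(vol_orders)
    except ValueError:
        return _BIG
    if vol_orders.family != "EGARCH" and params.persistence(vol_orders) >= 0.9995:
        return _BIG
    sigma2, ok = _raw_variance_path(eps, vol_orders, v)
    if not ok:
        return _BIG
    ll = gaussian_loglik_terms(eps, sigma2, burn)
    return -float(ll) if np.isfinite(ll) else _BIG


def _vol_params_to_u(params: VolatilityParams, orders: VolatilityOrders) -> np.ndarray:
    """Inverse of garch._unpack for a validated parameter set."""
    v = params.validated(orders)
    p, q = orders.p, orders.q
    if orders.family == "EGARCH":
        scale = 0.9995 / max(p, 1)
        b = np.arctanh(np.clip(np.asarray(v.beta) / scale, -0.999999, 0.999999))
        return np.concatenate([[v.alpha0], v.theta, v.lam, b])
    u = [np.log(max(v.alpha0, 1e-300))]
    u += list(np.log(np.maximum(v.alpha, 1e-300)))
    if orders.family == "GJR":
        u += list(v.gamma)
    u += list(np.log(np.maximum(v.beta, 1e-300)))
    return np.asarray(u)


def fit_composite(
    x: Sequence[float],
    arima_orders: ArimaOrders,
    vol_orders: VolatilityOrders,
    options: FitOptions = FitOptions(),
    vol_options: VolFitOptions = VolFitOptions(),
    mode: str = "joint",
) -> CompositeFit:
    """Fit the composite model; ``mode`` selects two-stage or joint refinement."""
    if mode not in ("two-stage", "joint"):
        raise ValueError(f"mode must be 'two-stage' or 'joint', got {mode!r}")
    x = np.asarray(x, dtype=float)
    stage1 = fit_arima(x, arima_orders, options)
    stage2 = fit_volatility(stage1.residuals, vol_orders, vol_options)

    w = difference(x, arima_orders.d)
    mu = stage1.mean_diff
    wc = w - mu
    burn = _joint_burn(arima_orders, vol_orders)
    p, q = arima_orders.p, arima_orders.q

    u_mean = np.concatenate([
        np.arctanh(coef_to_pacf(stage1.ar_coeffs)),
        np.arctanh(coef_to_pacf(-stage1.ma_coeffs)),
    ])
    u0 = np.concatenate([u_mean, _vol_params_to_u(stage2.params, vol_orders)])
    f0 = _joint_negloglik(u0, wc, arima_orders, vol_orders, burn)

    refined = False
    u_best, f_best = u0, f0
    if mode == "joint" and np.isfinite(f0):
        res = optimize.minimize(
            _joint_negloglik, u0, args=(wc, arima_orders, vol_orders, burn),
            method="Nelder-Mead",
            options={"maxiter": 400 * u0.size, "maxfev": 400 * u0.size,
                     "xatol": 1e-8, "fatol": 1e-9},
        )
        if np.isfinite(res.fun) and res.fun < f0:
            u_best, f_best = res.x, res.fun
            refined = True

    ar = pacf_to_coef(np.tanh(u_best[:p]))
    ma = -pacf_to_coef(np.tanh(u_best[p : p + q]))
    eps = arma_residuals(wc, ar, ma)
    vol_params = _unpack(u_best[p + q :], vol_orders).validated(vol_orders)
    sigma2, ok = _raw_variance_path(eps, vol_orders, vol_params)
    if not ok:  # fall back to the two-stage solution
        ar, ma = stage1.ar_coeffs, stage1.ma_coeffs
        eps = stage1.residuals
        vol_params = stage2.params
        sigma2 = stage2.sigma2_path
        f_best, refined = f0, False

    m = max(p, q)
    tail = eps[m:]
    refined_arima = ArimaFit(
        orders=arima_orders, ar_coeffs=ar, ma_coeffs=ma,
        innovation_variance=float(tail @ tail) / tail.size,
        residuals=eps,
        loglik=stage1.loglik if not refined else float(
            -0.5 * tail.size * (np.log(2 * np.pi) + np.log(float(tail @ tail) / tail.size))
            - 0.5 * tail.size
        ),
        mean_diff=mu, converged=stage1.converged, n_params=arima_orders.n_params,
    )
    refined_vol = VolatilityFit(
        orders=vol_orders, params=vol_params, sigma2_path=sigma2,
        std_residuals=eps / np.sqrt(sigma2),
        loglik=float(gaussian_loglik_terms(eps, sigma2, vol_orders.max_lag)),
        n_params=vol_orders.n_params, converged=stage2.converged,
    )
    fitted = arima_fitted(refined_arima, x)
    return CompositeFit(
        arima=refined_arima, volatility=refined_vol,
        joint_loglik=float(-f_best), fitted=fitted,
        n_params=arima_orders.n_params - 1 + vol_orders.n_params,
        mode=mode, refined=refined,
    )


def composite_fitted(fit: CompositeFit, x: Sequence[float]) -> np.ndarray:
    """One-step conditional means on the original scale (same rules as ARIMA)."""
    return arima_fitted(fit.arima, x)


def volatility_only_fitted(fit: VolatilityFit, head_values: Optional[Sequence[float]] = None
                           ) -> np.ndarray:
    """Conditional-mean "prediction" of a pure volatility model.

    ``y_t = sigma_t Z_t`` has zero conditional mean, so the prediction is
    identically zero at every predicted index. When ``head_values`` is
    given, the first max(p, q) positions copy those observations — the
    same convention as the mean models, keeping metric vectors aligned.
    The sigma_t path lives on the fit itself for plotting +/- envelopes.
    """
    n = fit.sigma2_path.size
    out = np.zeros(n)
    if head_values is not None:
        head = fit.orders.max_lag
        out[:head] = np.asarray(head_values, dtype=float)[:head]
    return out
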