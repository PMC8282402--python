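"""Compiled inner loops for the sequential time-series recursions.

Every model in the package reduces to a strictly sequential recursion
(ARMA innovations, GARCH/EGARCH conditional variance); these cannot be
vectorized, so they are JIT-compiled. The wrappers in the public modules
do all validation — functions here assume clean float64 arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))


@njit(cache=False)
def arma_residuals(w, ar, ma):
    """Innovations of the conditional ARMA recursion with zero pre-sample values.

    eps_t = w_t - sum_k ar_k w_{t-k} - sum_k ma_k eps_{t-k}
    """
    n = w.shape[0]
    p = ar.shape[0]
    q = ma.shape[0]
    eps = np.empty(n)
    for t in range(n):
        acc = w[t]
        for k in range(p):
            j = t - k - 1
            if j >= 0:
                acc -= ar[k] * w[j]
        for k in range(q):
            j = t - k - 1
            if j >= 0:
                acc -= ma[k] * eps[j]
        eps[t] = acc
    return eps


@njit(cache=False)
def arma_simulate(eps, ar, ma):
    """Generate w from given innovations: the inverse of arma_residuals."""
    n = eps.shape[0]
    p = ar.shape[0]
    q = ma.shape[0]
    w = np.empty(n)
    for t in range(n):
        acc = eps[t]
        for k in range(p):
            j = t - k - 1
            if j >= 0:
                acc += ar[k] * w[j]
        for k in range(q):
            j = t - k - 1
            if j >= 0:
                acc += ma[k] * eps[j]
        w[t] = acc
    return w


@njit(cache=False)
def garch_variance_path(y, alpha0, alpha, gamma, beta, sigma2_init, use_gjr):
    """sigma2_t = alpha0 + sum_i (alpha_i + gamma_i 1[y<0]) y_{t-i}^2 + sum_j beta_j sigma2_{t-j}.

    The first max(p, q) variances are pinned to sigma2_init; the recursion
    runs from there with pre-sample squared shocks treated as 0.
    Returns (sigma2, ok); ok = False when any sigma2_t is nonpositive/nonfinite.
    """
    n = y.shape[0]
    q = alpha.shape[0]
    p = beta.shape[0]
    m = max(p, q)
    sigma2 = np.empty(n)
    ok = True
    for t in range(min(m, n)):
        sigma2[t] = sigma2_init
    for t in range(m, n):
        acc = alpha0
        for i in range(q):
            j = t - i - 1
            if j >= 0:
                s = alpha[i]
                if use_gjr and y[j] < 0.0:
                    s += gamma[i]
                acc += s * y[j] * y[j]
        for i in range(p):
            j = t - i - 1
            if j >= 0:
                acc += beta[i] * sigma2[j]
            else:
                acc += beta[i] * sigma2_init
        sigma2[t] = acc
        if not (acc > 0.0) or not np.isfinite(acc):
            ok = False
            break
    return sigma2, ok


@njit(cache=False)
def egarch_variance_path(y, alpha0, theta, lam, beta, log_sigma2_init):
    """log sigma2_t = alpha0 + sum_i [theta_i Z_{t-i} + lam_i (|Z_{t-i}| - E|Z|)] + sum_j beta_j log sigma2_{t-j}.

    Z_t = y_t / sigma_t computed along the recursion; the first max(p, q)
    log-variances are pinned to log_sigma2_init, pre-sample g-terms are 0.
    Returns (sigma2, ok).
    """
    n = y.shape[0]
    q = theta.shape[0]
    p = beta.shape[0]
    m = max(p, q)
    sigma2 = np.empty(n)
    z = np.zeros(n)
    ok = True
    for t in range(min(m, n)):
        sigma2[t] = np.exp(log_sigma2_init)
        z[t] = y[t] / np.sqrt(sigma2[t])
    for t in range(m, n):
        acc = alpha0
        for i in range(q):
            j = t - i - 1
            if j >= 0:
                zj = z[j]
                acc += theta[i] * zj + lam[i] * (abs(zj) - SQRT_2_OVER_PI)
        for i in range(p):
            j = t - i - 1
            if j >= 0:
                acc += beta[i] * np.log(sigma2[j])
            else:
                acc += beta[i] * log_sigma2_init
        if acc > 50.0 or acc < -50.0 or not np.isfinite(acc):
            ok = False
            break
        s2 = np.exp(acc)
        sigma2[t] = s2
        z[t] = y[t] / np.sqrt(s2)
    return sigma2, ok


@njit(cache=False)
def garch_simulate(zstream, alpha0, alpha, gamma, beta, sigma2_init, use_gjr):
    """Run the GARCH/GJR recursion generatively: y_t = sigma_t Z_t."""
    n = zstream.shape[0]
    q = alpha.shape[0]
    p = beta.shape[0]
    y = np.empty(n)
    sigma2 = np.empty(n)
    for t in range(n):
        acc = alpha0
        for i in range(q):
            j = t - i - 1
            if j >= 0:
                s = alpha[i]
                if use_gjr and y[j] < 0.0:
                    s += gamma[i]
                acc += s * y[j] * y[j]
            else:
                acc += alpha[i] * sigma2_init
                if use_gjr:
                    acc += 0.5 * gamma[i] * sigma2_init
        for i in range(p):
            j = t - i - 1
            if j >= 0:
                acc += beta[i] * sigma2[j]
            else:
                acc += beta[i] * sigma2_init
        sigma2[t] = acc
        y[t] = np.sqrt(acc) * zstream[t]
    return y, sigma2


@njit(cache=False)
def egarch_simulate(zstream, alpha0, theta, lam, beta, log_sigma2_init):
    """Run the EGARCH recursion generatively with the given N(0,1) stream."""
    n = zstream.shape[0]
    q = theta.shape[0]
    p = beta.shape[0]
    y = np.empty(n)
    sigma2 = np.empty(n)
    for t in range(n):
        acc = alpha0
        for i in range(q):
            j = t - i - 1
            if j >= 0:
                zj = zstream[j]
                acc += theta[i] * zj + lam[i] * (abs(zj) - SQRT_2_OVER_PI)
        for i in range(p):
            j = t - i - 1
            if j >= 0:
                acc += beta[i] * np.log(sigma2[j])
            else:
                acc += beta[i] * log_sigma2_init
        sigma2[t] = np.exp(acc)
        y[t] = np.sqrt(sigma2[t]) * zstream[t]
    return y, sigma2


@njit(cache=False)
def gaussian_loglik_terms(y, sigma2, burn):
    """sum over t >= burn of -0.5 (log 2pi + log sigma2_t + y_t^2 / sigma2_t)."""
    n = y.shape[0]
    acc = 0.0
    log2pi = np.log(2.0 * np.pi)
    for t in range(burn, n):
        acc += -0.5 * (log2pi + np.log(sigma2[t]) + y[t] * y[t] / sigma2[t])
    return acc
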