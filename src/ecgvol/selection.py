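"""Order selection by normalized information criteria and error metrics.

The criteria are used in their per-observation normalized form,

    AIC: c_n(k) = 2 k / n        - 2 log L / n
    BIC: c_n(k) = k log(n) / n   - 2 log L / n

which for a fixed segment length ranks models identically to the
classical (unnormalized) versions. BIC drives order selection: every
candidate on a grid is fitted, and the converged candidate with the
smallest criterion wins, ties broken by fewer parameters and then by
lexicographically smaller orders.

Model adequacy is reported through MSE, RMSE, MAE and MAPE between
observed and one-step-predicted amplitudes, per segment and aggregated
(mean and sample std) per label group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arima import ArimaOrders, FitOptions, fit_arima
from .garch import VolatilityOrders, VolFitOptions, fit_volatility

logger = logging.getLogger(__name__)

CRITERIA = ("AIC", "BIC")


@dataclass(frozen=True)
class CriterionValue:
    criterion: str
    k: int
    n: int
    loglik: float
    value: float


@dataclass
class SelectionResult:
    grid: list            # (orders, CriterionValue | None, converged: bool)
    chosen: object        # ArimaOrders or VolatilityOrders
    criterion: str

    @property
    def chosen_value(self) -> float:
        for orders, cv, ok in self.grid:
            if ok and orders == self.chosen:
                return cv.value
        raise LookupError("chosen orders not in grid")


def information_criterion(criterion: str, k: int, n: int, loglik: float) -> CriterionValue:
    """Normalized AIC/BIC value (smaller is better)."""
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    if n < 2:
        raise ValueError("n must be >= 2")
    if k < 1:
        raise ValueError("k must be >= 1")
    penalty = 2.0 * k / n if criterion == "AIC" else k * np.log(n) / n
    return CriterionValue(criterion=criterion, k=k, n=n, loglik=float(loglik),
                          value=float(penalty - 2.0 * loglik / n))


def _orders_sort_key(orders) -> tuple:
    if isinstance(orders, ArimaOrders):
        return (orders.p, orders.d, orders.q)
    return (orders.p, orders.q)


def select_orders(x: Sequence[float], candidate_grid: Sequence, model_kind: str,
                  criterion: str = "BIC",
                  options: Optional[object] = None) -> SelectionResult:
    """Fit every candidate order on ``x`` and return the criterion argmin.

    ``model_kind`` is "arima" for mean models or one of "arch", "garch",
    "gjr", "egarch" for volatility models. Non-converged candidates are
    excluded from the argmin (logged), but remain in the grid report.
    """
    candidates = list(candidate_grid)
    if not candidates:
        raise ValueError("candidate grid is empty")
    x = np.asarray(x, dtype=float)
    grid = []
    best = None
    for orders in candidates:
        try:
            if model_kind == "arima":
                fit = fit_arima(x, orders, options or FitOptions())
                n = fit.residuals.size - max(orders.p, orders.q)
            else:
                fit = fit_volatility(x, orders, options or VolFitOptions())
                n = x.size - orders.max_lag
            cv = information_criterion(criterion, fit.n_params, n, fit.loglik)
            grid.append((orders, cv, fit.converged))
            if not fit.converged:
                logger.info("candidate %s did not converge; excluded", orders)
                continue
            key = (cv.value, cv.k, _orders_sort_key(orders))
            if best is None or key < best[0]:
                best = (key, orders)
        except Exception as exc:  # noqa: BLE001 - per-candidate failures are data
            logger.info("candidate %s failed: %s", orders, exc)
            grid.append((orders, None, False))
    if best is None:
        failures = [(str(o), "failed" if cv is None else "not converged")
                    for o, cv, ok in grid]
        raise RuntimeError(f"no candidate converged: {failures}")
    return SelectionResult(grid=grid, chosen=best[1], criterion=criterion)


def rank_by_loglik(fits: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Stable descending ranking of (name, loglik) pairs."""
    items = [(name, float(ll)) for name, ll in fits]
    if not items:
        raise ValueError("need at least one fit to rank")
    return sorted(items, key=lambda t: -t[1])


def error_metrics(observed: Sequence[float], predicted: Sequence[float],
                  mape_mode: str = "exclude") -> dict:
    """MSE, RMSE, MAE and MAPE between observed and predicted amplitudes.

    MAPE divides by |observed|; ECG amplitudes cross zero, so by default
    zero-observation indices are excluded and counted. ``mape_mode="naive"``
    keeps them (yielding inf), for strict fidelity with implementations
    that do not guard the division.
    """
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.size != xhat.size:
        raise ValueError("observed and predicted lengths differ")
    if x.size == 0:
        raise ValueError("need at least one sample")
    err = x - xhat
    mse = float(np.mean(err**2))
    out = {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.mean(np.abs(err))),
    }
    nonzero = x != 0.0
    if mape_mode == "naive":
        with np.errstate(divide="ignore", invalid="ignore"):
            out["MAPE"] = float(np.mean(np.abs(err) / np.abs(x)) * 100.0)
        out["n_mape_excluded"] = 0
    elif mape_mode == "exclude":
        if not np.any(nonzero):
            out["MAPE"] = None
            out["n_mape_excluded"] = int(x.size)
            out["mape_note"] = "all observed values are zero; MAPE undefined"
        else:
            with np.errstate(over="ignore"):
                out["MAPE"] = float(
                    np.mean(np.abs(err[nonzero]) / np.abs(x[nonzero])) * 100.0
                )
            out["n_mape_excluded"] = int(np.sum(~nonzero))
    else:
        raise ValueError(f"mape_mode must be 'exclude' or 'naive', got {mape_mode!r}")
    return out


METRIC_NAMES = ("MSE", "RMSE", "MAE", "MAPE")


def aggregate_metrics(per_segment: pd.DataFrame,
                      group_by: Sequence[str] = ("model", "label")) -> pd.DataFrame:
    """Mean and sample std (ddof=1; 0 for singleton groups) per metric and group.

    ``per_segment`` needs the grouping columns plus the four metric
    columns; the result mirrors the Ave/Std table layout.
    """
    required = set(group_by) | set(METRIC_NAMES)
    missing = required - set(per_segment.columns)
    if missing:
        raise ValueError(f"per-segment table lacks columns {sorted(missing)}")
    if per_segment.empty:
        raise ValueError("per-segment table is empty")
    rows = []
    for keys, grp in per_segment.groupby(list(group_by), dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_by, keys))
        row["n_segments"] = len(grp)
        for metric in METRIC_NAMES:
            vals = grp[metric].astype(float).dropna()
            if vals.empty:
                logger.info("group %s has no finite %s values; omitted", keys, metric)
                row[f"{metric}_ave"] = np.nan
                row[f"{metric}_std"] = np.nan
                continue
            row[f"{metric}_ave"] = float(vals.mean())
            row[f"{metric}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
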