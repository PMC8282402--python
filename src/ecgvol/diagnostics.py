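"""Heteroskedasticity diagnostics for ECG segments.

Before a GARCH-family model is worth fitting, a segment should actually
show volatility structure. The battery here mirrors the standard
screening sequence: fourth-moment summaries (a kurtosis above the
Gaussian value of 3 flags heavy tails), Engle's ARCH-LM test on squared
residuals, a Wilcoxon signed-rank comparison between the segment and a
series simulated from the fitted volatility model, and histogram/ECDF
distribution summaries with a Kolmogorov-Smirnov distance standing in
for the visual check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import Segment


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    threshold: Optional[float]
    p_value: Optional[float]
    decision: int           # 1 = null rejected
    alpha: float
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    std: float
    skewness: float
    kurtosis: float

    def to_dict(self) -> dict:
        return asdict(self)


def moments(x: Sequence[float]) -> MomentSummary:
    """Population-moment mean/std/skewness/kurtosis (no small-sample correction).

    Kurtosis is the raw fourth standardized moment: 3 for a Gaussian,
    > 3 for heavy tails, and >= 1 for any nondegenerate sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for moment summaries")
    mu = float(np.mean(x))
    c = x - mu
    m2 = float(np.mean(c**2))
    if m2 <= 0:
        raise ValueError("moments undefined for a constant sequence")
    return MomentSummary(
        mean=mu,
        std=float(np.sqrt(m2)),
        skewness=float(np.mean(c**3) / m2**1.5),
        kurtosis=float(np.mean(c**4) / m2**2),
    )


def engle_arch_test(residuals: Sequence[float], lags: int = 1,
                    alpha: float = 0.05) -> TestResult:
    """Engle's LM test for ARCH effects.

    Squared demeaned residuals are regressed on a constant and their
    first ``lags`` lags; the statistic n_eff * R^2 is asymptotically
    chi-square with ``lags`` degrees of freedom under the no-ARCH null.
    """
    r = np.asarray(residuals, dtype=float)
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if r.size < lags + 10:
        raise ValueError(f"series of length {r.size} too short for {lags} lags")
    s = (r - r.mean()) ** 2
    y = s[lags:]
    n_eff = y.size
    design = np.column_stack(
        [np.ones(n_eff)] + [s[lags - k - 1 : lags - k - 1 + n_eff] for k in range(lags)]
    )
    sst = float(np.sum((y - y.mean()) ** 2))
    threshold = float(stats.chi2.ppf(1.0 - alpha, df=lags))
    if sst <= 0:
        return TestResult(name="engle_arch", statistic=0.0, threshold=threshold,
                          p_value=1.0, decision=0, alpha=alpha,
                          note="degenerate auxiliary regression (constant squares)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    ssr = float(np.sum((y - design @ coef) ** 2))
    r2 = 1.0 - ssr / sst
    lm = n_eff * r2
    p = float(stats.chi2.sf(lm, df=lags))
    return TestResult(name="engle_arch", statistic=float(lm), threshold=threshold,
                      p_value=p, decision=int(lm > threshold), alpha=alpha)


def _wilcoxon_core(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, int, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    _, counts = np.unique(np.abs(d), return_counts=True)
    tieadj = float(np.sum(counts.astype(float) ** 3 - counts)) / 2.0
    var = (n * (n + 1) * (2 * n + 1) - tieadj) / 24.0
    z = (w - n * (n + 1) / 4.0) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return w, float(z), p, n, tieadj


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         alpha: float = 0.05) -> TestResult:
    """Paired Wilcoxon signed-rank test, normal approximation with tie adjustment.

    W is the sum of ranks of the positive differences among the midranked
    |x - y|; zero differences are dropped. The z statistic uses the
    tie-corrected null variance (n(n+1)(2n+1) - tieadj)/24 with
    tieadj = sum over tied groups of (t^3 - t)/2.
    """
    w, z, p, n, tieadj = _wilcoxon_core(x, y)
    return TestResult(name="wilcoxon_signed_rank", statistic=w, threshold=None,
                      p_value=p, decision=int(p < alpha), alpha=alpha,
                      note=f"z={z:.10g}, n={n}, tieadj={tieadj:g}")


def wilcoxon_z(x: Sequence[float], y: Sequence[float]) -> float:
    """The z statistic underlying :func:`wilcoxon_signed_rank` (for cross-checks)."""
    return _wilcoxon_core(x, y)[1]


def distribution_compare(x: Sequence[float], y: Sequence[float], bins: int = 50) -> dict:
    """Histogram/ECDF comparison of two samples on shared bin edges.

    The Gaussian reference density uses x's sample mean and std; the
    ks_distance (max ECDF gap) quantifies what the histogram and CDF
    overlays show visually.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    hist_x, _ = np.histogram(x, bins=edges, density=True)
    hist_y, _ = np.histogram(y, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gauss = stats.norm.pdf(centers, loc=x.mean(), scale=x.std())

    pooled = np.concatenate([x, y])
    pooled.sort()
    ecdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    ecdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    ks = float(np.max(np.abs(ecdf_x - ecdf_y)))
    return {
        "bin_edges": edges, "histogram_x": hist_x, "histogram_y": hist_y,
        "gaussian_reference": gauss, "ecdf_x": ecdf_x, "ecdf_y": ecdf_y,
        "ks_distance": ks,
    }


def run_battery(segment: Segment, garch_reference: Optional[Sequence[float]] = None,
                lags: int = 1, alpha: float = 0.05, bins: int = 50) -> dict:
    """Consolidated per-segment heteroskedasticity report.

    When ``garch_reference`` (an equal-length series simulated from the
    fitted GARCH-family model) is supplied, the report also includes the
    Wilcoxon comparison, paired by sample index, and the distribution
    summary against that reference.
    """
    x = segment.samples
    report = {
        "record_id": segment.record_id,
        "index": int(segment.index),
        "label": segment.label,
        "moments": moments(x).to_dict(),
        "engle": engle_arch_test(x - np.mean(x), lags=lags, alpha=alpha).to_dict(),
    }
    if garch_reference is not None:
        ref = np.asarray(garch_reference, dtype=float)
        if ref.size != x.size:
            raise ValueError("garch_reference must match the segment length")
        report["wilcoxon"] = wilcoxon_signed_rank(x, ref, alpha=alpha).to_dict()
        comp = distribution_compare(x, ref, bins=bins)
        report["ks_distance"] = comp["ks_distance"]
    return report


def battery_to_json(report: dict, **kwargs) -> str:
    return json.dumps(report, **kwargs)


def battery_from_json(text: str) -> dict:
    return json.loads(text)
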