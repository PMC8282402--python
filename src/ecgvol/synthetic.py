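"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: composite
ARIMA-EGARCH processes (for parameter-recovery studies) and ECG-like
surrogate segments — a quasi-periodic spike-train baseline of
Gaussian-bump "beats" plus composite heteroskedastic noise. The
surrogate makes no claim of physiological fidelity; it carries the
statistical structure the diagnostics target: heavy tails, volatility
clustering, nonstationarity in mean. Regime defaults live in
``regimes.yaml``; the apnea-like regime has stronger volatility
persistence and shock loading than the normal-like one, and the
homoskedastic control zeroes all dynamics for calibration experiments.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from ._kernels import arma_simulate, egarch_simulate
from .arima import integrate
from .garch import VolatilityOrders, VolatilityParams
from .io import Segment, write_csv_signal, read_csv_signal

REGIMES = ("apnea_like", "normal_like", "homoskedastic_control")


def load_regime_defaults() -> dict:
    """Parameter sets for the built-in regimes (from the packaged YAML)."""
    text = resources.files("ecgvol").joinpath("regimes.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ScenarioSpec:
    regime: str
    n_segments: int = 20
    segment_length: int = 6000
    sampling_rate: float = 100.0
    seed: int = 0
    mean_params: Optional[dict] = None   # {"d": int, "ar": [...], "ma": [...]}
    vol_params: Optional[dict] = None    # {"alpha0", "theta", "lam", "beta"}
    beats: Optional[dict] = "default"    # None disables the spike train

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.n_segments < 1 or self.segment_length < 16:
            raise ValueError("need n_segments >= 1 and segment_length >= 16")

    def resolved(self) -> dict:
        """Regime defaults overridden by any explicitly given parameters."""
        base = load_regime_defaults()[self.regime]
        out = {
            "label": base["label"],
            "mean": dict(base["mean"]) if self.mean_params is None else dict(self.mean_params),
            "egarch": dict(base["egarch"]) if self.vol_params is None else dict(self.vol_params),
            "beats": base["beats"] if self.beats == "default" else self.beats,
        }
        eg = out["egarch"]
        if abs(sum(eg["beta"])) >= 1.0:
            raise ValueError("EGARCH persistence must satisfy |sum(beta)| < 1")
        return out


def simulate_composite(mean_params: dict, vol_params: dict, n: int, seed: int,
                       burn_in: int = 500) -> dict:
    """Composite draw: EGARCH innovations feed the ARMA recursion, then integrate.

    Returns ``{"x", "sigma2", "truth"}`` where ``truth`` records every
    generating parameter and the seed. ``sigma2`` is the conditional
    variance of the innovations, aligned with the differenced series.
    """
    ar = np.asarray(mean_params.get("ar", []), dtype=float)
    ma = np.asarray(mean_params.get("ma", []), dtype=float)
    d = int(mean_params.get("d", 0))
    eg = {k: np.atleast_1d(np.asarray(v, dtype=float)) if k != "alpha0" else float(v)
          for k, v in vol_params.items()}
    orders = VolatilityOrders("EGARCH", p=len(eg["beta"]), q=len(eg["theta"]))
    params = VolatilityParams(alpha0=eg["alpha0"], theta=eg["theta"], lam=eg["lam"],
                              beta=eg["beta"]).validated(orders)
    pers = float(np.sum(params.beta))
    if abs(pers) >= 1.0:
        raise ValueError(f"explosive EGARCH persistence {pers}")
    if ar.size:
        # char. polynomial z^p - a_1 z^{p-1} - ... - a_p: roots must be inside the unit disc
        roots = np.roots(np.concatenate([[1.0], -ar]))
        if np.any(np.abs(roots) >= 1.0):
            raise ValueError("explosive AR coefficients")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n - d + burn_in)
    log_init = params.alpha0 / (1.0 - pers)
    eps, sigma2 = egarch_simulate(z, params.alpha0, np.asarray(params.theta, float),
                                  np.asarray(params.lam, float),
                                  np.asarray(params.beta, float), float(log_init))
    w = arma_simulate(eps, ar, ma)
    w, sigma2 = w[burn_in:], sigma2[burn_in:]
    x = integrate(w, d, np.zeros(d))
    truth = {
        "mean": {"ar": ar.tolist(), "ma": ma.tolist(), "d": d},
        "egarch": {"alpha0": params.alpha0,
                   "theta": np.asarray(params.theta).tolist(),
                   "lam": np.asarray(params.lam).tolist(),
                   "beta": np.asarray(params.beta).tolist()},
        "seed": int(seed), "burn_in": int(burn_in), "n": int(n),
    }
    return {"x": x, "sigma2": sigma2, "truth": truth}


def _beat_train(n: int, rate: float, beats: dict, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic Gaussian bumps at ~1 Hz with jittered intervals."""
    t = np.arange(n) / rate
    duration = n / rate
    period = 1.0 / beats["rate_hz"]
    jitter = beats.get("jitter_s", 0.0)
    amp = beats["amplitude_mv"]
    width = beats["width_s"]
    out = np.zeros(n)
    center = float(rng.uniform(0, period))
    while center < duration:
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        center += period + float(rng.normal(0.0, jitter))
    return out


def make_ecg_like(spec: ScenarioSpec) -> tuple[list[Segment], dict]:
    """Generate labeled surrogate segments plus a truth manifest."""
    cfg = spec.resolved()
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * spec.n_segments)
    # keep derived seeds below 2**31 so they round-trip through JSON readers
    seeds = (seeds % np.uint32(2**31)).astype(np.int64)
    segments = []
    seg_records = []
    for i in range(spec.n_segments):
        noise_seed = int(seeds[2 * i])
        beat_seed = int(seeds[2 * i + 1])
        sim = simulate_composite(cfg["mean"], cfg["egarch"], spec.segment_length,
                                 seed=noise_seed)
        samples = sim["x"]
        if cfg["beats"] is not None:
            beat_rng = np.random.default_rng(beat_seed)
            samples = samples + _beat_train(spec.segment_length, spec.sampling_rate,
                                            cfg["beats"], beat_rng)
        segments.append(Segment(samples=samples, sampling_rate=spec.sampling_rate,
                                label=cfg["label"], record_id=spec.regime, index=i))
        seg_records.append({"index": i, "noise_seed": noise_seed,
                            "beat_seed": beat_seed, "file": f"{spec.regime}_{i:04d}.csv"})
    manifest = {
        "regime": spec.regime,
        "label": cfg["label"],
        "n_segments": spec.n_segments,
        "segment_length": spec.segment_length,
        "sampling_rate": spec.sampling_rate,
        "seed": int(spec.seed),
        "truth": {"mean": cfg["mean"], "egarch": cfg["egarch"], "beats": cfg["beats"]},
        "segments": seg_records,
    }
    return segments, manifest


def write_fixture_set(segments: Sequence[Segment], manifest: dict, out_dir) -> list[Path]:
    """One CSV per segment plus a manifest.json; read-back is exact."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for seg, rec in zip(segments, manifest["segments"]):
        paths.append(write_csv_signal(out_dir / rec["file"], seg))
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    paths.append(mpath)
    return paths


def read_fixture_set(directory) -> tuple[list[Segment], dict]:
    """Inverse of :func:`write_fixture_set`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    segments = []
    for rec in manifest["segments"]:
        sig = read_csv_signal(directory / rec["file"])
        segments.append(Segment(samples=sig.samples, sampling_rate=sig.sampling_rate,
                                label=manifest["label"], record_id=manifest["regime"],
                                index=rec["index"]))
    return segments, manifest
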