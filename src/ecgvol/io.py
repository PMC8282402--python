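"""Signals, one-minute segments, and the train/evaluation split.

The pipeline operates on single-lead ECG amplitude series cut into
non-overlapping one-minute windows (6000 samples at the 100 Hz used by
the Apnea-ECG recordings). Each window carries an apnea/normal/unknown
label; model orders are estimated on a random half of the segments and
the fit is evaluated on the rest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

VALID_LABELS = ("apnea", "normal", "unknown")

CSV_RATE_KEY = "sampling_rate_hz"


@dataclass(frozen=True)
class Signal:
    """A raw single-channel recording in physical units."""

    samples: np.ndarray
    sampling_rate: float
    record_id: str = "unnamed"

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.size == 0:
            raise ValueError("signal has no samples")
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite amplitude at sample {bad}")


@dataclass(frozen=True)
class Segment:
    """One analysis window (one minute by default) of a recording."""

    samples: np.ndarray
    sampling_rate: float
    label: str = "unknown"
    record_id: str = "unnamed"
    index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if self.index < 0:
            raise ValueError("segment index must be nonnegative")

    @property
    def key(self) -> tuple[str, int]:
        return (self.record_id, self.index)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/evaluation partition of segment keys."""

    train_ids: frozenset
    eval_ids: frozenset
    seed: int

    def __post_init__(self):
        if self.train_ids & self.eval_ids:
            raise ValueError("train and eval sets overlap")


def segment_signal(
    signal: Signal,
    window_seconds: float = 60.0,
    labels: Optional[Sequence[str]] = None,
) -> list[Segment]:
    """Cut a signal into consecutive non-overlapping windows.

    Windows are half-open ``[i*W, (i+1)*W)`` in sample coordinates; a
    trailing partial window is dropped. ``labels`` (one per window) are
    assigned positionally; missing trailing labels default to "unknown".
    """
    w_float = window_seconds * signal.sampling_rate
    window = int(round(w_float))
    if window <= 0 or abs(w_float - window) > 1e-9:
        raise ValueError(
            f"window of {window_seconds} s is not a whole number of samples "
            f"at {signal.sampling_rate} Hz"
        )
    n_windows = signal.samples.size // window
    segments = []
    for i in range(n_windows):
        if labels is not None and i < len(labels):
            label = labels[i]
        else:
            label = "unknown"
        segments.append(
            Segment(
                samples=signal.samples[i * window : (i + 1) * window].copy(),
                sampling_rate=signal.sampling_rate,
                label=label,
                record_id=signal.record_id,
                index=i,
            )
        )
    return segments


def split_segments(
    segments: Sequence[Segment], fraction: float = 0.5, seed: int = 0
) -> SplitPlan:
    """Random train/eval partition with ``round-half-up(fraction * n)`` on the train side."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to split")
    keys = [s.key for s in segments]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (record_id, index) keys among segments")
    n_train = int(np.floor(fraction * len(keys) + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    train = frozenset(keys[i] for i in order[:n_train])
    evaluation = frozenset(keys[i] for i in order[n_train:])
    return SplitPlan(train_ids=train, eval_ids=evaluation, seed=seed)


def read_csv_signal(path, sampling_rate_override: Optional[float] = None) -> Signal:
    """Read the package's plain-text signal dialect.

    First line ``# sampling_rate_hz=<value>`` (optional when an override is
    given), then one amplitude per line.
    """
    path = Path(path)
    rate = sampling_rate_override
    samples = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}: blank amplitude at row {lineno}")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith(CSV_RATE_KEY):
                    _, _, val = body.partition("=")
                    rate = float(val)
                continue
            try:
                value = float(line)
            except ValueError:
                raise ValueError(f"{path}: non-numeric amplitude {line!r} at row {lineno}") from None
            if not np.isfinite(value):
                raise ValueError(f"{path}: non-finite amplitude at row {lineno}")
            samples.append(value)
    if rate is None:
        raise ValueError(f"{path}: no '# {CSV_RATE_KEY}=' header and no override given")
    return Signal(samples=np.asarray(samples), sampling_rate=rate, record_id=path.stem)


def write_csv_signal(path, signal_or_segment) -> Path:
    """Write samples in the dialect read_csv_signal understands (full precision)."""
    path = Path(path)
    obj = signal_or_segment
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {CSV_RATE_KEY}={float(obj.sampling_rate)!r}\n")
        for v in np.asarray(obj.samples, dtype=float):
            fh.write(f"{float(v)!r}\n")
    return path
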