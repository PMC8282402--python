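"""Minimal WFDB (PhysioNet) record support.

Reads the standard ``.hea``/``.dat`` pair for signal formats 16
(little-endian int16) and 212 (packed 12-bit pairs, the Apnea-ECG
format), converts to physical units via the header gain/baseline, and
decodes MIT-format annotation files into per-minute apnea/normal labels
(annotation symbols 'A' -> apnea, 'N' -> normal, the Apnea-ECG
convention). Only what the segmentation pipeline needs is implemented;
matching writers exist so round trips can be exercised without any
download. WFDB input is optional — the CSV dialect in :mod:`ecgvol.io`
is the primary interface.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .io import Signal

# Standard MIT annotation code -> symbol table (the slice this module needs).
_ANN_SYMBOLS = {
    0: " ", 1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J",
    8: "A", 9: "S", 10: "E", 11: "j", 12: "/", 13: "Q",
}
_ANN_CODES = {v: k for k, v in _ANN_SYMBOLS.items()}

_PSEUDO_SKIP, _PSEUDO_NUM, _PSEUDO_SUB, _PSEUDO_CHN, _PSEUDO_AUX = 59, 60, 61, 62, 63


def _parse_gain_field(field: str) -> tuple[float, Optional[int]]:
    """Parse '200(1024)/mV'-style gain specs -> (gain, baseline or None)."""
    spec = field.split("/")[0]
    baseline = None
    if "(" in spec:
        spec, _, rest = spec.partition("(")
        baseline = int(rest.rstrip(")"))
    gain = float(spec) if spec else 0.0
    if gain == 0.0:
        gain = 200.0  # WFDB default for an unspecified gain
    return gain, baseline


def read_wfdb_record(header_path, annotation_ext: Optional[str] = "apn"):
    """Read a WFDB record; returns ``(Signal, labels_or_None)``.

    The first signal channel is used when several are present. Per-minute
    labels come from ``<record>.<annotation_ext>`` when that file exists;
    minutes past the last annotation stay "unknown".
    """
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ValueError(f"{header_path}: empty WFDB header")
    head = lines[0].split()
    if len(head) < 3:
        raise ValueError(f"{header_path}: malformed record line {lines[0]!r}")
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3]) if len(head) > 3 else None
    if n_sig < 1 or len(lines) < 1 + n_sig:
        raise ValueError(f"{header_path}: header describes {n_sig} signals but lists fewer")

    sig_lines = [ln.split() for ln in lines[1 : 1 + n_sig]]
    dat_name = sig_lines[0][0]
    fmt = sig_lines[0][1].split("x")[0].split(":")[0].split("+")[0]
    gain, baseline = _parse_gain_field(sig_lines[0][2]) if len(sig_lines[0]) > 2 else (200.0, None)
    adc_zero = int(sig_lines[0][4]) if len(sig_lines[0]) > 4 else 0
    if baseline is None:
        baseline = adc_zero

    raw = (header_path.parent / dat_name).read_bytes()
    if fmt == "16":
        digital = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        digital = digital[: (digital.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    elif fmt == "212":
        digital = _decode_212(raw)
        if n_sig > 1:
            digital = digital[: (digital.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    else:
        raise ValueError(f"{header_path}: unsupported WFDB signal format {fmt!r}")
    if n_samples is not None:
        digital = digital[:n_samples]

    physical = (digital - baseline) / gain
    signal = Signal(samples=physical, sampling_rate=fs, record_id=record_name)

    labels = None
    if annotation_ext:
        ann_path = header_path.with_suffix("." + annotation_ext)
        if ann_path.exists():
            ann = read_wfdb_annotations(ann_path)
            n_minutes = int(signal.samples.size // round(60 * fs))
            labels = ["unknown"] * n_minutes
            for sample, symbol in ann:
                minute = int(sample // round(60 * fs))
                if minute < n_minutes:
                    if symbol == "A":
                        labels[minute] = "apnea"
                    elif symbol == "N":
                        labels[minute] = "normal"
    return signal, labels


def _decode_212(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int64)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * b.shape[0], dtype=np.int64)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out


def read_wfdb_annotations(path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file -> [(sample, symbol), ...]."""
    raw = Path(path).read_bytes()
    out = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        b0, b1 = raw[i], raw[i + 1]
        i += 2
        code = b1 >> 2
        delta = ((b1 & 0x03) << 8) | b0
        if code == 0 and delta == 0:
            break  # EOF marker
        if code == _PSEUDO_SKIP:
            jump = int.from_bytes(raw[i : i + 4], "little", signed=True)
            # stored word-swapped: high pair first
            jump = ((jump & 0xFFFF) << 16) | ((jump >> 16) & 0xFFFF)
            if jump & 0x80000000:
                jump -= 1 << 32
            t += jump
            i += 4
            continue
        if code == _PSEUDO_AUX:
            i += delta + (delta & 1)
            continue
        if code in (_PSEUDO_NUM, _PSEUDO_SUB, _PSEUDO_CHN):
            continue
        t += delta
        out.append((t, _ANN_SYMBOLS.get(code, "?")))
    return out


def write_wfdb_record(directory, record_id: str, signal: Signal, gain: float = 200.0,
                      baseline: int = 0) -> Path:
    """Write a format-16 .hea/.dat pair (test fixtures and interop exports)."""
    directory = Path(directory)
    digital = np.rint(signal.samples * gain + baseline).astype("<i2")
    (directory / f"{record_id}.dat").write_bytes(digital.tobytes())
    rate = signal.sampling_rate
    rate_str = f"{int(rate)}" if float(rate).is_integer() else f"{rate}"
    header = (
        f"{record_id} 1 {rate_str} {digital.size}\n"
        f"{record_id}.dat 16 {gain:g}({baseline})/mV 16 0 {int(digital[0])} 0 0 ECG\n"
    )
    path = directory / f"{record_id}.hea"
    path.write_text(header, encoding="utf-8")
    return path


def write_wfdb_annotations(path, annotations: list[tuple[int, str]]) -> Path:
    """Write MIT-format annotations ([(sample, symbol), ...], sorted by sample)."""
    path = Path(path)
    buf = bytearray()
    t_prev = 0
    for sample, symbol in sorted(annotations):
        code = _ANN_CODES.get(symbol)
        if code is None:
            raise ValueError(f"unsupported annotation symbol {symbol!r}")
        delta = sample - t_prev
        while delta > 1023:
            # SKIP pseudo-annotation carries a 32-bit word-swapped jump
            buf += bytes([0, _PSEUDO_SKIP << 2])
            jump = delta
            swapped = ((jump >> 16) & 0xFFFF) | ((jump & 0xFFFF) << 16)
            buf += int(swapped).to_bytes(4, "little")
            delta = 0
        buf += bytes([delta & 0xFF, (code << 2) | ((delta >> 8) & 0x03)])
        t_prev = sample
    buf += bytes([0, 0])
    path.write_bytes(bytes(buf))
    return path
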