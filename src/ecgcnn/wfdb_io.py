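"""Minimal WFDB record and annotation I/O.

Supports the subset of the WFDB conventions needed to read beat-annotated
ECG records: text headers (``.hea``), signal formats 16 (little-endian
int16, interleaved) and 212 (packed 12-bit pairs, the format of the
classic arrhythmia recordings), and MIT-format annotation files
(``.atr``).  Writers for format 16 and annotations exist so tests can
round-trip fixtures without external downloads.

This is deliberately not a full WFDB implementation (no multi-segment
records, no per-signal files, no calibration) — for anything beyond beat
extraction use the ``wfdb`` package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Header",
    "read_header",
    "read_record",
    "read_annotations",
    "write_record",
    "write_annotations",
    "ANNOTATION_CODES",
]

# MIT annotation code <-> display symbol, for the codes this package maps.
ANNOTATION_CODES = {
    1: "N",    # normal
    2: "L",    # left bundle branch block
    3: "R",    # right bundle branch block
    4: "a",    # aberrated atrial premature
    5: "V",    # premature ventricular contraction
    6: "F",    # fusion
    8: "A",    # atrial premature
    9: "S",    # supraventricular premature
    12: "/",   # paced
    13: "Q",   # unclassifiable
    38: "f",   # fusion of paced and normal
}
_SYMBOL_TO_CODE = {s: c for c, s in ANNOTATION_CODES.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class Header:
    name: str
    n_signals: int
    fs: float
    n_samples: int
    formats: list[int]
    gains: list[float]


def read_header(path: str | Path) -> Header:
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_signals = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    formats, gains = [], []
    for ln in lines[1 : 1 + n_signals]:
        fields = ln.split()
        fmt = int(fields[1].split("x")[0].split(":")[0].split("+")[0])
        gain = 200.0
        if len(fields) > 2:
            gain_tok = fields[2].split("(")[0].split("/")[0]
            if gain_tok:
                gain = float(gain_tok) or 200.0
        formats.append(fmt)
        gains.append(gain)
    return Header(name, n_signals, fs, n_samples, formats, gains)


def _decode_212(raw: np.ndarray, n_values: int) -> np.ndarray:
    # 2 samples packed into 3 bytes; 12-bit two's complement.
    raw = raw[: (len(raw) // 3) * 3].reshape(-1, 3).astype(np.int64)
    first = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    second = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    out = np.empty(raw.shape[0] * 2, dtype=np.int64)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def read_record(record_path: str | Path) -> tuple[np.ndarray, float]:
    """Read ``<record>.hea`` + ``<record>.dat``; returns ((n, nsig) ints, fs).

    All signals must share one format (16 or 212) and live in one ``.dat``
    file, which covers the single-file records this package targets.
    """
    record_path = Path(record_path)
    hdr = read_header(record_path.with_suffix(".hea"))
    if len(set(hdr.formats)) != 1:
        raise OSError(f"mixed signal formats {hdr.formats} are not supported")
    fmt = hdr.formats[0]
    raw = np.frombuffer(record_path.with_suffix(".dat").read_bytes(), dtype=np.uint8)
    n_values = hdr.n_samples * hdr.n_signals if hdr.n_samples else None
    if fmt == 16:
        flat = raw.view("<i2").astype(np.int64)
        flat = flat[:n_values] if n_values else flat
    elif fmt == 212:
        if n_values is None:
            n_values = (len(raw) // 3) * 2
        flat = _decode_212(raw, n_values)
    else:
        raise OSError(f"signal format {fmt} is not supported (only 16 and 212)")
    n_frames = len(flat) // hdr.n_signals
    return flat[: n_frames * hdr.n_signals].reshape(n_frames, hdr.n_signals), hdr.fs


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read a MIT-format annotation file: [(sample, symbol), ...] in order.

    Handles the SKIP/NUM/SUB/CHN/AUX pseudo-annotations; unknown type
    codes are returned with symbol ``"?"``.
    """
    data = Path(path).read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(data):
                raise OSError("truncated SKIP annotation")
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            val = (high << 16) | low
            if val >= 1 << 31:
                val -= 1 << 32
            pending_skip += val
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        time += interval + pending_skip
        pending_skip = 0
        out.append((time, ANNOTATION_CODES.get(code, "?")))
    return out


def write_record(
    directory: str | Path,
    name: str,
    signal: np.ndarray,
    fs: float = 360.0,
    gain: float = 200.0,
) -> Path:
    """Write ``name.hea`` + ``name.dat`` in format 16. ``signal`` is (n, nsig)
    integer ADC units."""
    directory = Path(directory)
    sig = np.asarray(signal)
    if sig.ndim == 1:
        sig = sig[:, None]
    n, nsig = sig.shape
    flat = sig.astype("<i2").ravel()
    (directory / f"{name}.dat").write_bytes(flat.tobytes())
    lines = [f"{name} {nsig} {fs:g} {n}"]
    for ch in range(nsig):
        lines.append(f"{name}.dat 16 {gain:g} 16 0 {int(sig[0, ch])} 0 0 ch{ch}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / name


def write_annotations(path: str | Path, annotations: list[tuple[int, str]]) -> None:
    """Write a MIT-format annotation file from [(sample, symbol), ...]."""
    buf = bytearray()
    prev = 0
    for sample, symbol in sorted(annotations):
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        while delta > 0x3FF:  # long gap -> SKIP pseudo-annotation
            buf += bytes([0, _SKIP << 2])
            buf += bytes([(delta >> 16) & 0xFF, (delta >> 24) & 0xFF,
                          delta & 0xFF, (delta >> 8) & 0xFF])
            delta = 0
        word = (code << 10) | delta
        buf += bytes([word & 0xFF, word >> 8])
        prev = sample
    buf += bytes([0, 0])  # EOF
    Path(path).write_bytes(bytes(buf))
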