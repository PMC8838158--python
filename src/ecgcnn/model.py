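"""Floating-point reference implementation of the 297-parameter beat classifier.

The network is fixed: two 3x(1x7) convolutional layers with a 1x1
channel-collapsing convolution between them, 1x2 and 1x3 row-wise max
pooling, and two dense layers (6->21->6), with no bias terms anywhere.
Shape chain for one beat::

    2x24 -> 3@2x18 -> 3@2x9 -> 1@2x9 -> 3@2x3 -> 3@2x1 -> 6 -> 21 -> 6

This module is the golden model that the hardware datapath simulator in
:mod:`ecgcnn.datapath` must reproduce after quantization.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "BeatClass",
    "ModelWeights",
    "InvalidShapeError",
    "conv_rowwise",
    "conv_1x1",
    "relu",
    "maxpool_row",
    "dense",
    "forward",
    "count_parameters",
    "preprocess_beat",
    "as_input_tensor",
    "WEIGHT_FORMAT_VERSION",
]

WEIGHT_FORMAT_VERSION = 1

#: Expected per-layer scalar parameter counts for the fixed architecture.
EXPECTED_COUNTS = {"conv1": 21, "conv2": 3, "conv3": 21, "fc1": 126, "fc2": 126}
TOTAL_PARAMETERS = 297

INPUT_ROWS = 2
INPUT_COLS = 24
WINDOW_SAMPLES = INPUT_ROWS * INPUT_COLS  # 48-sample beat window
SAMPLES_BEFORE_R = 23                     # window covers R-23 .. R+24
N_CLASSES = 6


class InvalidShapeError(ValueError):
    """Raised when a tensor does not match the fixed architecture's shapes."""


class BeatClass(enum.IntEnum):
    """The six annotated beat types, in their fixed output-node order."""

    NORMAL = 0  # N
    LBBB = 1    # L
    RBBB = 2    # R
    PVC = 3     # V
    APB = 4     # A
    PACED = 5   # /

    @property
    def code(self) -> str:
        return _CLASS_CODES[self.value]

    @classmethod
    def from_code(cls, code: str) -> "BeatClass":
        try:
            return cls(_CLASS_CODES.index(code))
        except ValueError:
            raise ValueError(f"unknown beat class code {code!r}") from None


_CLASS_CODES = ("N", "L", "R", "V", "A", "/")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidShapeError(msg)


@dataclass
class ModelWeights:
    """All 297 trainable coefficients, grouped by layer. No biases.

    ``conv1``/``conv3`` are (3, 7) kernel stacks, ``conv2`` the 3-vector of
    the 1x1 channel-collapsing convolution, ``fc1`` (6, 21) and ``fc2``
    (21, 6) dense matrices.
    """

    conv1: np.ndarray
    conv2: np.ndarray
    conv3: np.ndarray
    fc1: np.ndarray
    fc2: np.ndarray

    _SHAPES = {
        "conv1": (3, 7),
        "conv2": (3,),
        "conv3": (3, 7),
        "fc1": (6, 21),
        "fc2": (21, 6),
    }

    def __post_init__(self) -> None:
        for name, shape in self._SHAPES.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            _require(arr.shape == shape, f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    def groups(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._SHAPES}

    @classmethod
    def zeros(cls) -> "ModelWeights":
        return cls(**{n: np.zeros(s) for n, s in cls._SHAPES.items()})

    def copy(self) -> "ModelWeights":
        return ModelWeights(**{n: v.copy() for n, v in self.groups().items()})

    def save(self, path: str | Path) -> None:
        """Write the weight container (JSON, versioned, named groups)."""
        payload = {
            "format_version": WEIGHT_FORMAT_VERSION,
            "kind": "float",
            "weights": {n: v.tolist() for n, v in self.groups().items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelWeights":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != WEIGHT_FORMAT_VERSION:
            raise ValueError(f"unsupported weight file version {payload.get('format_version')!r}")
        if payload.get("kind") != "float":
            raise ValueError(f"expected a float weight file, got kind={payload.get('kind')!r}")
        w = cls(**{n: np.asarray(v) for n, v in payload["weights"].items()})
        if count_parameters(w)["total"] != TOTAL_PARAMETERS:
            raise ValueError("weight file violates the 297-parameter invariant")
        return w


def count_parameters(w: ModelWeights) -> dict[str, int]:
    """Per-layer and total scalar parameter counts (21/3/21/126/126 = 297)."""
    counts = {name: int(arr.size) for name, arr in w.groups().items()}
    counts["total"] = sum(counts.values())
    return counts


def as_input_tensor(values: Iterable) -> np.ndarray:
    """Validate and return a 2x24 finite input tensor."""
    arr = np.asarray(values, dtype=np.float64)
    _require(arr.shape == (INPUT_ROWS, INPUT_COLS), f"input must be 2x24, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input tensor contains non-finite entries")
    return arr


def preprocess_beat(samples: Iterable) -> np.ndarray:
    """Turn a 48-sample beat window into the 2x24 network input.

    The window is amplitude-normalized to [-1, 1] (by its maximum absolute
    value; an all-zero window is left as zeros) and reshaped row-major into
    2 rows x 24 columns.  The 48-sample window and this reshape are a
    convention of this implementation, not a published fact.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    _require(x.size == WINDOW_SAMPLES, f"beat window must have {WINDOW_SAMPLES} samples, got {x.size}")
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return x.reshape(INPUT_ROWS, INPUT_COLS)


# ---------------------------------------------------------------------------
# Layer operations
# ---------------------------------------------------------------------------

def conv_rowwise(map_: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid (no padding) per-row correlation of a 2xC map with a 1x7 kernel.

    ``out[r, j] = sum_k map[r, j+k] * kernel[k]`` for j in 0..C-7.
    """
    m = np.asarray(map_, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    _require(m.ndim == 2, f"map must be 2-D, got {m.ndim}-D")
    _require(k.shape == (7,), f"kernel must have length 7, got shape {k.shape}")
    _require(m.shape[1] >= 7, f"map width {m.shape[1]} < kernel length 7")
    windows = np.lib.stride_tricks.sliding_window_view(m, 7, axis=1)
    return windows @ k


def conv_1x1(maps: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Collapse 3 channels to 1 with a 1x1 convolution (3 weights)."""
    ms = np.asarray(maps, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    _require(ms.ndim == 3 and ms.shape[0] == 3, f"expected 3 channels, got shape {ms.shape}")
    _require(w.shape == (3,), f"1x1 weights must have length 3, got shape {w.shape}")
    return np.einsum("crj,c->rj", ms, w)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def maxpool_row(map_: np.ndarray, width: int) -> np.ndarray:
    """Non-overlapping left-aligned row-wise max pooling of width 2 or 3.

    Trailing remainder columns (C mod width) are dropped.
    """
    m = np.asarray(map_, dtype=np.float64)
    _require(width in (2, 3), f"pool width must be 2 or 3, got {width}")
    _require(m.ndim == 2, f"map must be 2-D, got {m.ndim}-D")
    rows, cols = m.shape
    _require(cols >= width, f"map width {cols} < pool width {width}")
    n_out = cols // width
    return m[:, : n_out * width].reshape(rows, n_out, width).max(axis=2)


def dense(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bias-free dense layer: ``out[j] = sum_i x[i] * W[i, j]``."""
    xv = np.asarray(x, dtype=np.float64)
    Wm = np.asarray(W, dtype=np.float64)
    _require(xv.ndim == 1 and Wm.ndim == 2, "dense expects a vector and a matrix")
    _require(xv.shape[0] == Wm.shape[0], f"dense shape mismatch: {xv.shape[0]} vs {Wm.shape[0]}")
    return xv @ Wm


def flatten_features(pooled: np.ndarray) -> np.ndarray:
    """Row-major flatten of the 3@2x1 pooled maps (channel, then row)."""
    p = np.asarray(pooled, dtype=np.float64)
    _require(p.shape == (3, 2, 1), f"expected 3@2x1 maps, got {p.shape}")
    return p.ravel()


def forward(input_: np.ndarray, w: ModelWeights) -> tuple[np.ndarray, BeatClass]:
    """Full forward pass: returns the 6 class scores and the argmax class.

    Ties in the argmax resolve to the lowest class index (deterministic,
    hardware-like behavior).
    """
    x = as_input_tensor(input_)
    a1 = np.stack([relu(conv_rowwise(x, k)) for k in w.conv1])          # 3@2x18
    p1 = np.stack([maxpool_row(ch, 2) for ch in a1])                    # 3@2x9
    a2 = relu(conv_1x1(p1, w.conv2))                                    # 1@2x9
    a3 = np.stack([relu(conv_rowwise(a2, k)) for k in w.conv3])         # 3@2x3
    p3 = np.stack([maxpool_row(ch, 3) for ch in a3])                    # 3@2x1
    feats = flatten_features(p3)                                        # 6
    h = relu(dense(feats, w.fc1))                                       # 21
    scores = dense(h, w.fc2)                                            # 6
    return scores, BeatClass(int(np.argmax(scores)))
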