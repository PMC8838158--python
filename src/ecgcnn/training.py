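"""Training of the 297 weights by mini-batch gradient descent.

The published design loads weights trained offline but does not state the
procedure, so everything here is a documented choice: softmax cross-entropy
loss, plain SGD with momentum, Glorot-uniform initialization, mandatory
seed.  Gradients are computed by hand-written backpropagation through the
five layer operations (there is no autodiff dependency), vectorized over
the batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ecgcnn import model
from ecgcnn.model import ModelWeights
from ecgcnn.datapath import FixedPointFormat, quantize_weights

__all__ = [
    "TrainConfig",
    "TrainReport",
    "softmax_prob",
    "init_weights",
    "batch_forward",
    "batch_loss_and_gradients",
    "train",
    "calibrate_weights",
    "quantize_weights",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 64
    seed: int = 1234
    momentum: float = 0.9
    optimizer: str = "sgd-momentum"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible training")
        if self.optimizer not in ("sgd", "sgd-momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainReport:
    losses: list[float] = field(default_factory=list)
    train_accuracy: float = 0.0
    val_accuracy: float | None = None

    def to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["epoch\tloss"]
        lines += [f"{i + 1}\t{l:.8g}" for i, l in enumerate(self.losses)]
        lines.append(f"# train_accuracy\t{self.train_accuracy:.6f}")
        if self.val_accuracy is not None:
            lines.append(f"# val_accuracy\t{self.val_accuracy:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def softmax_prob(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis; rows sum to 1."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


def init_weights(seed: int) -> ModelWeights:
    """Glorot-uniform initialization, per layer, from a seeded generator."""
    rng = np.random.default_rng(seed)
    fans = {  # (fan_in, fan_out) per group
        "conv1": (7, 7 * 3),
        "conv2": (3, 1),
        "conv3": (7, 7 * 3),
        "fc1": (6, 21),
        "fc2": (21, 6),
    }
    groups = {}
    for name, shape in ModelWeights._SHAPES.items():
        fan_in, fan_out = fans[name]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        groups[name] = rng.uniform(-limit, limit, size=shape)
    return ModelWeights(**groups)


# ---------------------------------------------------------------------------
# Vectorized forward/backward over a batch
# ---------------------------------------------------------------------------

def _sliding(x: np.ndarray) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, 7, axis=-1)


def batch_forward(x: np.ndarray, w: ModelWeights) -> dict[str, np.ndarray]:
    """Forward pass over a batch (n, 2, 24); returns all activations.

    Matches :func:`ecgcnn.model.forward` exactly (same pooling tie-breaks:
    leftmost element of each window wins).
    """
    x = np.asarray(x, dtype=np.float64)
    win1 = _sliding(x)                                            # (n,2,18,7)
    z1 = np.einsum("brjk,ck->bcrj", win1, w.conv1)                # (n,3,2,18)
    a1 = np.maximum(z1, 0.0)
    a1w = a1.reshape(*a1.shape[:3], 9, 2)
    i1 = np.argmax(a1w, axis=-1)                                  # first max wins
    p1 = np.take_along_axis(a1w, i1[..., None], axis=-1)[..., 0]  # (n,3,2,9)
    z2 = np.einsum("bcrj,c->brj", p1, w.conv2)                    # (n,2,9)
    a2 = np.maximum(z2, 0.0)
    win3 = _sliding(a2)                                           # (n,2,3,7)
    z3 = np.einsum("brjk,ck->bcrj", win3, w.conv3)                # (n,3,2,3)
    a3 = np.maximum(z3, 0.0)
    i3 = np.argmax(a3, axis=-1)                                   # (n,3,2)
    p3 = np.take_along_axis(a3, i3[..., None], axis=-1)[..., 0]   # (n,3,2)
    feats = p3.reshape(len(x), 6)
    z4 = feats @ w.fc1                                            # (n,21)
    a4 = np.maximum(z4, 0.0)
    scores = a4 @ w.fc2                                           # (n,6)
    return {
        "x": x, "win1": win1, "z1": z1, "a1w": a1w, "i1": i1, "p1": p1,
        "z2": z2, "a2": a2, "win3": win3, "z3": z3, "i3": i3,
        "feats": feats, "z4": z4, "a4": a4, "scores": scores,
    }


def batch_predict(x: np.ndarray, w: ModelWeights) -> np.ndarray:
    return np.argmax(batch_forward(x, w)["scores"], axis=1)


def batch_loss_and_gradients(
    x: np.ndarray, y: np.ndarray, w: ModelWeights
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy of softmax(scores) and its weight gradients."""
    cache = batch_forward(x, w)
    n = len(cache["x"])
    probs = softmax_prob(cache["scores"])
    eps = np.finfo(np.float64).tiny
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))

    dz5 = probs.copy()
    dz5[np.arange(n), y] -= 1.0
    dz5 /= n                                                      # (n,6)
    d_fc2 = cache["a4"].T @ dz5                                   # (21,6)
    da4 = dz5 @ w.fc2.T
    dz4 = da4 * (cache["z4"] > 0)
    d_fc1 = cache["feats"].T @ dz4                                # (6,21)
    dfeats = dz4 @ w.fc1.T                                        # (n,6)

    dp3 = dfeats.reshape(n, 3, 2)
    da3 = np.zeros_like(cache["z3"])                              # (n,3,2,3)
    np.put_along_axis(da3, cache["i3"][..., None], dp3[..., None], axis=-1)
    dz3 = da3 * (cache["z3"] > 0)
    d_conv3 = np.einsum("bcrj,brjk->ck", dz3, cache["win3"])

    da2 = np.zeros_like(cache["a2"])                              # (n,2,9)
    for j in range(3):  # transpose of the valid row-wise correlation
        da2[:, :, j : j + 7] += np.einsum("bcr,ck->brk", dz3[:, :, :, j], w.conv3)
    dz2 = da2 * (cache["z2"] > 0)
    d_conv2 = np.einsum("brj,bcrj->c", dz2, cache["p1"])

    dp1 = np.einsum("brj,c->bcrj", dz2, w.conv2)                  # (n,3,2,9)
    da1w = np.zeros_like(cache["a1w"])                            # (n,3,2,9,2)
    np.put_along_axis(da1w, cache["i1"][..., None], dp1[..., None], axis=-1)
    dz1 = da1w.reshape(*cache["z1"].shape) * (cache["z1"] > 0)
    d_conv1 = np.einsum("bcrj,brjk->ck", dz1, cache["win1"])

    grads = {"conv1": d_conv1, "conv2": d_conv2, "conv3": d_conv3,
             "fc1": d_fc1, "fc2": d_fc2}
    return loss, grads


def calibrate_weights(
    w: ModelWeights,
    x_calib: np.ndarray,
    fmt: FixedPointFormat,
    headroom: float = 0.5,
) -> ModelWeights:
    """Rescale layer weights so all activations fit the fixed-point range.

    The network has no biases, so it is positively homogeneous: scaling a
    layer's weights by λ>0 scales every downstream activation (and the
    final scores) by λ without changing any ReLU/pooling decision or the
    argmax.  This picks one λ per layer so that, on the calibration batch,
    every pre-activation magnitude stays below ``headroom`` times the
    largest representable value and every weight stays representable —
    the standard calibration step before fixed-point deployment.
    """
    if not 0 < headroom <= 1:
        raise ValueError("headroom must be in (0, 1]")
    cache = batch_forward(x_calib, w)
    stage_max = [float(np.max(np.abs(cache[k]))) for k in ("z1", "z2", "z3", "z4", "scores")]
    limit = fmt.int_max / fmt.scale
    act_target = limit * headroom
    out = w.copy()
    cum = 1.0
    for name, mx in zip(("conv1", "conv2", "conv3", "fc1", "fc2"), stage_max):
        lam = act_target / (cum * mx) if mx > 0 else 1.0
        w_max = float(np.max(np.abs(getattr(out, name))))
        if w_max > 0:
            lam = min(lam, act_target / w_max)
        getattr(out, name)[...] *= lam
        cum *= lam
    return out


def train(
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
    init: ModelWeights | None = None,
) -> tuple[ModelWeights, TrainReport]:
    """Fit the 297 weights on labeled beat tensors (x: (n,2,24), y: (n,)).

    Deterministic given ``config.seed``: initialization and the per-epoch
    shuffle both derive from it.
    """
    config = config or TrainConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    w = (init or init_weights(config.seed)).copy()
    rng = np.random.default_rng(config.seed + 1)
    velocity = {n: np.zeros_like(g) for n, g in w.groups().items()}
    mu = config.momentum if config.optimizer == "sgd-momentum" else 0.0

    report = TrainReport()
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            loss, grads = batch_loss_and_gradients(x[idx], y[idx], w)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1}; reduce the learning rate"
                )
            epoch_loss += loss * len(idx)
            for name, g in grads.items():
                v = velocity[name]
                v *= mu
                v -= config.learning_rate * g
                getattr(w, name)[...] += v
        report.losses.append(epoch_loss / n)
    report.train_accuracy = float(np.mean(batch_predict(x, w) == y))
    if val_x is not None and val_y is not None:
        report.val_accuracy = float(np.mean(batch_predict(val_x, w) == np.asarray(val_y)))
    return w, report
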