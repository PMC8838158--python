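"""Bit-accurate behavioral simulator of the resource-shared hardware datapath.

Five shared units — a 7-lane multiply-accumulate processing element (PE), a
ReLU unit with a partial-sum register, a 1x2/1x3 max-pooling unit, a
54-register control buffer, and an argmax ("softmax") unit with six result
registers — execute the eight layers of the fixed network under a
multiplexer schedule (signals S1..S6).

All arithmetic is two's-complement fixed point.  Defaults: 16-bit words
with 12 fractional bits for weights and activations; PE sums are carried at
full product precision (2x the fractional bits) and never rounded
mid-accumulation; values are requantized only at unit outputs, with
round-to-nearest-even and saturation.  The published design does not state
word lengths; these defaults are a documented choice and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ecgcnn import model
from ecgcnn.model import BeatClass, ModelWeights

__all__ = [
    "DONT_CARE",
    "FixedPointFormat",
    "MuxState",
    "PEUnit",
    "ReluUnit",
    "ControlBuffer",
    "SoftmaxUnit",
    "QuantizedWeights",
    "InferenceResult",
    "SchedulingError",
    "BufferOverflowError",
    "quantize",
    "dequantize",
    "quantize_weights",
    "maxpool_unit",
    "softmax_unit",
    "schedule_layer",
    "run_inference",
    "score_error_bound",
    "compare_against_reference",
]


class SchedulingError(RuntimeError):
    """A unit was driven with inputs inconsistent with the mux schedule."""


class BufferOverflowError(RuntimeError):
    """More than 54 live values were written to the control buffer."""


# ---------------------------------------------------------------------------
# Fixed-point representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPointFormat:
    """Signed two's-complement Q-format: ``total_bits`` with ``frac_bits``."""

    total_bits: int = 16
    frac_bits: int = 12

    def __post_init__(self) -> None:
        if not (2 <= self.total_bits <= 32):
            raise ValueError(f"total_bits must be in [2, 32], got {self.total_bits}")
        if not (0 <= self.frac_bits < self.total_bits):
            raise ValueError(
                f"frac_bits must be in [0, total_bits), got {self.frac_bits}/{self.total_bits}"
            )

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def int_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def int_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def lsb(self) -> float:
        return 1.0 / self.scale


def quantize(x, fmt: FixedPointFormat):
    """Real -> integer code: round(x * 2^f) to nearest (ties to even), saturate.

    Accepts scalars or arrays; returns Python int for scalars, an int64
    array otherwise.
    """
    arr = np.rint(np.asarray(x, dtype=np.float64) * fmt.scale)  # rint = half-to-even
    arr = np.clip(arr, fmt.int_min, fmt.int_max).astype(np.int64)
    if arr.ndim == 0:
        return int(arr)
    return arr


def dequantize(q, fmt: FixedPointFormat):
    return np.asarray(q, dtype=np.float64) / fmt.scale


def _round_half_even_shift(value: int, shift: int) -> int:
    # Integer round-to-nearest-even of value / 2^shift.
    if shift == 0:
        return value
    step = 1 << shift
    half = step >> 1
    q, r = divmod(value, step)  # Python divmod floors; r is in [0, step)
    if r > half or (r == half and (q & 1)):
        q += 1
    return q


def _saturate(value: int, fmt: FixedPointFormat) -> int:
    return max(fmt.int_min, min(fmt.int_max, value))


@dataclass
class QuantizedWeights:
    """Integer codes of the 297 weights plus their fixed-point format."""

    conv1: np.ndarray
    conv2: np.ndarray
    conv3: np.ndarray
    fc1: np.ndarray
    fc2: np.ndarray
    fmt: FixedPointFormat

    def groups(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in ("conv1", "conv2", "conv3", "fc1", "fc2")}

    def dequantized(self) -> ModelWeights:
        return ModelWeights(**{n: dequantize(v, self.fmt) for n, v in self.groups().items()})

    def total_count(self) -> int:
        return sum(int(v.size) for v in self.groups().values())

    def save(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "format_version": model.WEIGHT_FORMAT_VERSION,
            "kind": "quantized",
            "fixed_point": {"total_bits": self.fmt.total_bits, "frac_bits": self.fmt.frac_bits},
            "weights": {n: v.tolist() for n, v in self.groups().items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "QuantizedWeights":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != model.WEIGHT_FORMAT_VERSION:
            raise ValueError(f"unsupported weight file version {payload.get('format_version')!r}")
        if payload.get("kind") != "quantized":
            raise ValueError(f"expected a quantized weight file, got kind={payload.get('kind')!r}")
        fp = payload["fixed_point"]
        qw = cls(
            fmt=FixedPointFormat(fp["total_bits"], fp["frac_bits"]),
            **{n: np.asarray(v, dtype=np.int64) for n, v in payload["weights"].items()},
        )
        if qw.total_count() != model.TOTAL_PARAMETERS:
            raise ValueError("quantized weight file violates the 297-parameter invariant")
        return qw


def quantize_weights(w: ModelWeights, fmt: FixedPointFormat) -> QuantizedWeights:
    return QuantizedWeights(fmt=fmt, **{n: quantize(v, fmt) for n, v in w.groups().items()})


# ---------------------------------------------------------------------------
# Mux schedule (select signals S1..S6 per layer)
# ---------------------------------------------------------------------------

class _DontCare:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "×"


DONT_CARE = _DontCare()


@dataclass(frozen=True)
class MuxState:
    """Select-signal assignment for one layer.

    S1..S4 are single bits, S5/S6 two-bit codes; ``DONT_CARE`` marks unused
    signals.  S5 for the 1x1 convolution cycles through the three channel
    codes and is carried as a tuple.
    """

    S1: object = DONT_CARE
    S2: object = DONT_CARE
    S3: object = DONT_CARE
    S4: object = DONT_CARE
    S5: object = DONT_CARE
    S6: object = DONT_CARE

    def __post_init__(self) -> None:
        for name, width in (("S1", 1), ("S2", 1), ("S3", 1), ("S4", 1), ("S5", 2), ("S6", 2)):
            val = getattr(self, name)
            if val is DONT_CARE:
                continue
            vals = val if isinstance(val, tuple) else (val,)
            for v in vals:
                if not (isinstance(v, int) and 0 <= v < (1 << width)):
                    raise ValueError(f"{name}={val!r} outside its {width}-bit field")


_SCHEDULE: dict[int, MuxState] = {
    1: MuxState(S1=0, S2=1),
    2: MuxState(S3=1, S4=1),
    3: MuxState(S1=1, S2=0, S4=0, S5=(0b00, 0b01, 0b10), S6=0b00),
    4: MuxState(S1=1, S2=1, S6=0b10),
    5: MuxState(S3=0, S4=1),
    6: MuxState(),
    7: MuxState(S1=1, S2=1, S4=0, S6=0b11),
    8: MuxState(S1=1, S6=0b01),
}

LAYER_NAMES = {
    1: "Convolution",
    2: "MaxPooling",
    3: "Convolution",
    4: "Convolution",
    5: "MaxPooling",
    6: "Flatten",
    7: "Fully Connected",
    8: "Fully Connected",
}


def schedule_layer(layer_index: int) -> MuxState:
    """Mux select values for layer 1..8 of the pipeline."""
    try:
        return _SCHEDULE[layer_index]
    except KeyError:
        raise ValueError(f"layer index must be 1..8, got {layer_index}") from None


# ---------------------------------------------------------------------------
# Hardware units
# ---------------------------------------------------------------------------

PE_LANES = 7


class PEUnit:
    """7-lane multiply-accumulate element: 7 multipliers feeding 6 adders.

    One invocation performs exactly 7 multiplications and 6 additions; the
    sum is carried at full precision in a wide accumulator (saturated to the
    accumulator width, 32 bits by default).
    """

    def __init__(self, accumulator_bits: int = 32):
        self.accumulator_bits = accumulator_bits
        self.invocations = 0
        self.multiplications = 0

    @property
    def _acc_min(self) -> int:
        return -(1 << (self.accumulator_bits - 1))

    @property
    def _acc_max(self) -> int:
        return (1 << (self.accumulator_bits - 1)) - 1

    def execute(self, x: Sequence[int], w: Sequence[int]) -> int:
        if len(x) != PE_LANES or len(w) != PE_LANES:
            raise SchedulingError(
                f"PE requires exactly {PE_LANES} input and coefficient lanes "
                f"(pad unused lanes with zeros); got {len(x)}/{len(w)}"
            )
        acc = 0
        for xi, wi in zip(x, w):
            acc += int(xi) * int(wi)
        self.invocations += 1
        self.multiplications += PE_LANES
        return max(self._acc_min, min(self._acc_max, acc))


class ReluUnit:
    """Rectifier with an adder+register for the 1x1-convolution partial sums.

    ``process(sum, s2=1)`` requantizes a PE sum (which carries doubled
    fractional bits) back to the activation format and clamps negatives to
    zero.  ``process(sum, s2=0)`` accumulates channel partial sums in the
    register; ``flush()`` applies the requantize+ReLU to the accumulated
    value and clears the register.
    """

    def __init__(self, fmt: FixedPointFormat):
        self.fmt = fmt
        self.reg = 0

    def _requant_relu(self, wide_sum: int) -> int:
        if wide_sum <= 0:
            return 0
        q = _round_half_even_shift(wide_sum, self.fmt.frac_bits)
        return _saturate(q, self.fmt)

    def process(self, wide_sum: int, s2: int) -> int | None:
        if s2 not in (0, 1):
            raise SchedulingError(f"S2 must be 0 or 1, got {s2}")
        if s2 == 1:
            return self._requant_relu(int(wide_sum))
        self.reg += int(wide_sum)
        return None

    def flush(self) -> int:
        out = self._requant_relu(self.reg)
        self.reg = 0
        return out


def maxpool_unit(values: Sequence[int], s3: int) -> int:
    """Windowed maximum; S3=1 selects the 1x2 window, S3=0 the 1x3 window."""
    if s3 not in (0, 1):
        raise SchedulingError(f"S3 must be 0 or 1, got {s3}")
    expected = 2 if s3 == 1 else 3
    if len(values) != expected:
        raise SchedulingError(f"maxpool with S3={s3} needs {expected} values, got {len(values)}")
    best = int(values[0])  # leftmost wins on ties
    for v in values[1:]:
        if int(v) > best:
            best = int(v)
    return best


class ControlBuffer:
    """54-register temporary store for inter-layer activations.

    ``store`` replaces the buffer contents with one layer's output (the
    hardware overwrites consumed registers in place); writing more than 54
    live values is a scheduling bug and raises.
    """

    CAPACITY = 54

    def __init__(self):
        self.registers: list[int] = []
        self.peak = 0

    @property
    def occupancy(self) -> int:
        return len(self.registers)

    def store(self, values: Sequence[int]) -> None:
        if len(values) > self.CAPACITY:
            raise BufferOverflowError(
                f"{len(values)} live values exceed the {self.CAPACITY}-register buffer"
            )
        self.registers = [int(v) for v in values]
        self.peak = max(self.peak, len(self.registers))

    def read(self) -> list[int]:
        return list(self.registers)


class SoftmaxUnit:
    """Output-stage accumulator and argmax over six result registers.

    Each output node's value is the sum of exactly three PE results; after
    all six nodes are accumulated into R0..R5, the predicted class is the
    index of the maximum (lowest index on ties).  No exponential is
    computed: the inference-time "softmax" is an argmax.
    """

    PARTIALS_PER_NODE = 3
    N_NODES = 6

    def __init__(self):
        self.R: list[int | None] = [None] * self.N_NODES
        self._acc = 0
        self._count = 0

    def accumulate(self, node: int, wide_sum: int) -> None:
        if not 0 <= node < self.N_NODES:
            raise SchedulingError(f"node index must be 0..5, got {node}")
        if self.R[node] is not None:
            raise SchedulingError(f"node {node} already finalized")
        self._acc += int(wide_sum)
        self._count += 1
        if self._count > self.PARTIALS_PER_NODE:
            raise SchedulingError("more than 3 partials accumulated for one node")
        if self._count == self.PARTIALS_PER_NODE:
            self.R[node] = self._acc
            self._acc = 0
            self._count = 0

    def predict(self) -> BeatClass:
        if self._count != 0 or any(r is None for r in self.R):
            raise SchedulingError("argmax requested before all 6 nodes finished (3 partials each)")
        best = 0
        for i in range(1, self.N_NODES):
            if self.R[i] > self.R[best]:  # type: ignore[operator]
                best = i
        return BeatClass(best)


def softmax_unit(partials_per_node: Sequence[Sequence[int]]) -> tuple[list[int], BeatClass]:
    """Convenience wrapper: feed 6 nodes x 3 partials, return (R, predicted)."""
    unit = SoftmaxUnit()
    for node, partials in enumerate(partials_per_node):
        if len(partials) != SoftmaxUnit.PARTIALS_PER_NODE:
            raise SchedulingError(
                f"node {node} got {len(partials)} partials, need {SoftmaxUnit.PARTIALS_PER_NODE}"
            )
        for p in partials:
            unit.accumulate(node, p)
    return [int(r) for r in unit.R], unit.predict()  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Full inference schedule
# ---------------------------------------------------------------------------

@dataclass
class InferenceResult:
    predicted: BeatClass
    scores: list[int]              # R0..R5, integer codes with 2*frac_bits
    pe_invocations: dict[int, int]  # per-layer PE invocation counts
    buffer_peak: int
    multiplications: int

    def dequantized_scores(self, fmt: FixedPointFormat) -> np.ndarray:
        # fc2 sums carry products of two frac_bits-scaled operands.
        return np.asarray(self.scores, dtype=np.float64) / float(fmt.scale) ** 2


def _pe_lanes(values: Sequence[int]) -> list[int]:
    lanes = [int(v) for v in values]
    if len(lanes) > PE_LANES:
        raise SchedulingError(f"{len(lanes)} values exceed the {PE_LANES} PE lanes")
    return lanes + [0] * (PE_LANES - len(lanes))


def run_inference(
    input_q: np.ndarray,
    weights: QuantizedWeights,
    accumulator_bits: int = 32,
) -> InferenceResult:
    """Execute layers 1-8 on the five shared units under the mux schedule.

    ``input_q`` is the 2x24 integer-code input tensor in ``weights.fmt``.
    Returns the predicted class, the six wide output-register values, the
    per-layer PE invocation counts and the control-buffer peak occupancy.
    """
    fmt = weights.fmt
    x = np.asarray(input_q, dtype=np.int64)
    if x.shape != (model.INPUT_ROWS, model.INPUT_COLS):
        raise model.InvalidShapeError(f"quantized input must be 2x24, got {x.shape}")

    pe = PEUnit(accumulator_bits=accumulator_bits)
    relu_u = ReluUnit(fmt)
    buffer = ControlBuffer()
    softmax = SoftmaxUnit()
    pe_per_layer: dict[int, int] = {}

    def tally(layer: int, start: int) -> None:
        pe_per_layer[layer] = pe.invocations - start

    # Layers 1+2: 3x(1x7) convolution -> ReLU -> 1x2 max pooling.  Pooling
    # consumes conv outputs pairwise as they stream out, so only the pooled
    # 54 values (3 channels x 2x9) ever reach the buffer.
    mux1, mux2 = schedule_layer(1), schedule_layer(2)
    start = pe.invocations
    pooled1: list[int] = []
    for kernel in weights.conv1:
        for r in range(2):
            row_out = [
                relu_u.process(pe.execute(_pe_lanes(x[r, j : j + 7]), _pe_lanes(kernel)), mux1.S2)
                for j in range(model.INPUT_COLS - 6)
            ]
            for j in range(0, len(row_out), 2):
                pooled1.append(maxpool_unit(row_out[j : j + 2], mux2.S3))
    tally(1, start)
    pe_per_layer[2] = 0
    buffer.store(pooled1)

    # Layer 3: 1x1 convolution.  S5 cycles the three channels through the
    # PE; partial sums accumulate in the ReLU unit's register before the
    # rectifier fires (S2=0 path).
    mux3 = schedule_layer(3)
    start = pe.invocations
    chans = np.asarray(buffer.read(), dtype=np.int64).reshape(3, 2, 9)
    mixed: list[int] = []
    for r in range(2):
        for j in range(9):
            for s5 in mux3.S5:
                s = pe.execute(_pe_lanes([chans[s5, r, j]]), _pe_lanes([weights.conv2[s5]]))
                relu_u.process(s, mux3.S2)
            mixed.append(relu_u.flush())
    tally(3, start)
    buffer.store(mixed)

    # Layers 4+5: 3x(1x7) convolution on the single 2x9 map -> ReLU ->
    # 1x3 max pooling, again fused so only 6 pooled values are buffered.
    mux4, mux5 = schedule_layer(4), schedule_layer(5)
    start = pe.invocations
    m2 = np.asarray(buffer.read(), dtype=np.int64).reshape(2, 9)
    pooled2: list[int] = []
    for kernel in weights.conv3:
        for r in range(2):
            row_out = [
                relu_u.process(pe.execute(_pe_lanes(m2[r, j : j + 7]), _pe_lanes(kernel)), mux4.S2)
                for j in range(3)
            ]
            pooled2.append(maxpool_unit(row_out, mux5.S3))
    tally(4, start)
    pe_per_layer[5] = 0
    buffer.store(pooled2)

    # Layer 6: flatten is pure wiring (channel-major order, matching the
    # reference model's row-major ravel of the 3@2x1 maps).
    pe_per_layer[6] = 0
    feats = buffer.read()  # already [c0r0, c0r1, c1r0, c1r1, c2r0, c2r1]

    # Layer 7: 6->21 dense + ReLU; 6 taps fit one PE invocation per node.
    mux7 = schedule_layer(7)
    start = pe.invocations
    hidden = [
        relu_u.process(pe.execute(_pe_lanes(feats), _pe_lanes(weights.fc1[:, node])), mux7.S2)
        for node in range(21)
    ]
    tally(7, start)
    buffer.store(hidden)

    # Layer 8: 21->6 dense; 21 MACs = exactly 3 PE executions per node,
    # accumulated in the softmax unit's register into R0..R5.
    start = pe.invocations
    hv = buffer.read()
    for node in range(6):
        col = weights.fc2[:, node]
        for part in range(3):
            lo = part * 7
            s = pe.execute(_pe_lanes(hv[lo : lo + 7]), _pe_lanes(col[lo : lo + 7]))
            softmax.accumulate(node, s)
    tally(8, start)

    predicted = softmax.predict()
    return InferenceResult(
        predicted=predicted,
        scores=[int(r) for r in softmax.R],  # type: ignore[arg-type]
        pe_invocations=pe_per_layer,
        buffer_peak=buffer.peak,
        multiplications=pe.multiplications,
    )


# ---------------------------------------------------------------------------
# Error analysis and reference comparison
# ---------------------------------------------------------------------------

def score_error_bound(w: ModelWeights, fmt: FixedPointFormat, input_bound: float = 1.0) -> float:
    """Worst-case |datapath score − float score| from per-stage rounding.

    Composes, layer by layer, (i) the amplification of the incoming
    activation error by the layer's absolute weight sums, (ii) the error
    contributed by weight quantization against a bound on the activation
    magnitude, and (iii) the half-LSB requantization step at each unit
    output.  ReLU and max pooling are 1-Lipschitz and add nothing.
    """
    q = 0.5 * fmt.lsb  # half-LSB: rounding of inputs, weights and requantization

    def stage(amp: float, err: float, kernels: np.ndarray, taps: int, requant: bool):
        # kernels: rows = output units; worst-case over output units.
        s = float(np.max(np.sum(np.abs(kernels), axis=1)))
        new_err = s * err + amp * taps * q + taps * q * err
        new_amp = s * amp
        if requant:
            new_err += q
        return new_amp, new_err

    amp, err = input_bound, q  # input quantization error
    amp, err = stage(amp, err, w.conv1, 7, requant=True)
    amp, err = stage(amp, err, w.conv2.reshape(1, 3), 3, requant=True)
    amp, err = stage(amp, err, w.conv3, 7, requant=True)
    amp, err = stage(amp, err, w.fc1.T, 6, requant=True)
    amp, err = stage(amp, err, w.fc2.T, 21, requant=False)  # wide sums read out directly
    return err


@dataclass
class ComparisonReport:
    """Per-beat agreement between the datapath and the float reference."""

    agreement: float
    n_beats: int
    n_agree: int
    max_score_deviation: float
    per_beat: list[tuple[int, int, int, float]] = field(repr=False, default_factory=list)
    # (beat index, reference class, datapath class, max |score diff|)

    def to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["beat\treference_class\tdatapath_class\tagree\tmax_score_deviation"]
        for i, ref, hw, dev in self.per_beat:
            lines.append(f"{i}\t{ref}\t{hw}\t{int(ref == hw)}\t{dev:.6g}")
        lines.append(f"# agreement\t{self.agreement:.6f}\t({self.n_agree}/{self.n_beats})")
        Path(path).write_text("\n".join(lines) + "\n")


def compare_against_reference(
    inputs: np.ndarray,
    weights: ModelWeights,
    fmt: FixedPointFormat,
    accumulator_bits: int = 32,
) -> ComparisonReport:
    """Run every beat through both paths with the same weights and compare.

    ``inputs`` is (n, 2, 24).  The float reference uses the weights as
    given; the datapath uses their quantized codes.
    """
    qw = quantize_weights(weights, fmt)
    per_beat = []
    n_agree = 0
    max_dev = 0.0
    for i, beat in enumerate(np.asarray(inputs, dtype=np.float64)):
        ref_scores, ref_cls = model.forward(beat, weights)
        res = run_inference(quantize(beat, fmt), qw, accumulator_bits=accumulator_bits)
        dev = float(np.max(np.abs(res.dequantized_scores(fmt) - ref_scores)))
        max_dev = max(max_dev, dev)
        agree = res.predicted == ref_cls
        n_agree += agree
        per_beat.append((i, int(ref_cls), int(res.predicted), dev))
    n = len(per_beat)
    return ComparisonReport(
        agreement=n_agree / n if n else 1.0,
        n_beats=n,
        n_agree=n_agree,
        max_score_deviation=max_dev,
        per_beat=per_beat,
    )
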