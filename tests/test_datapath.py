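"""Fixed-point datapath units, mux schedule, and full-inference behavior."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecgcnn import model
from ecgcnn.datapath import (
    DONT_CARE,
    BufferOverflowError,
    ControlBuffer,
    FixedPointFormat,
    MuxState,
    PEUnit,
    ReluUnit,
    SchedulingError,
    SoftmaxUnit,
    compare_against_reference,
    dequantize,
    maxpool_unit,
    quantize,
    quantize_weights,
    run_inference,
    schedule_layer,
    score_error_bound,
    softmax_unit,
)
from ecgcnn.model import BeatClass
from ecgcnn.training import calibrate_weights, init_weights

FMT = FixedPointFormat(16, 12)


def oracle_quantize(x: float, fmt: FixedPointFormat) -> int:
    """Exact rational round-half-even quantization, then saturation."""
    v = Fraction(x) * (1 << fmt.frac_bits)
    floor = v.numerator // v.denominator
    rem = v - floor
    if rem > Fraction(1, 2) or (rem == Fraction(1, 2) and floor % 2 != 0):
        floor += 1
    return max(fmt.int_min, min(fmt.int_max, floor))


class TestFixedPointFormat:
    def test_defaults(self):
        assert FMT.scale == 4096 and FMT.int_max == 32767 and FMT.int_min == -32768

    @pytest.mark.parametrize("total,frac", [(1, 0), (33, 0), (16, 16), (16, -1)])
    def test_invalid_formats(self, total, frac):
        with pytest.raises(ValueError):
            FixedPointFormat(total, frac)


class TestQuantize:
    def test_zero(self):
        assert quantize(0.0, FMT) == 0

    def test_saturates_high(self):
        assert quantize(100.0, FMT) == FMT.int_max

    def test_saturates_low(self):
        assert quantize(-100.0, FMT) == FMT.int_min

    def test_ties_to_even(self):
        fmt = FixedPointFormat(16, 1)  # steps of 0.5
        assert quantize(0.25, fmt) == 0   # 0.5 -> even 0
        assert quantize(0.75, fmt) == 2   # 1.5 -> even 2
        assert quantize(-0.25, fmt) == 0

    def test_matches_rational_oracle(self, rng):
        fmt = FixedPointFormat(16, 12)
        xs = rng.uniform(-10, 10, size=200)
        qs = quantize(xs, fmt)
        for x, q in zip(xs, qs):
            assert q == oracle_quantize(float(x), fmt)

    @given(st.floats(-1e4, 1e4))
    def test_always_in_range(self, x):
        q = quantize(x, FMT)
        assert FMT.int_min <= q <= FMT.int_max

    def test_roundtrip_error_bound(self, rng):
        xs = rng.uniform(-7.9, 7.9, size=500)
        err = np.abs(dequantize(quantize(xs, FMT), FMT) - xs)
        assert np.all(err <= 2.0 ** (-FMT.frac_bits - 1) + 1e-15)


class TestPEUnit:
    def test_all_zero(self):
        pe = PEUnit()
        assert pe.execute([0] * 7, [0] * 7) == 0

    def test_seven_ones_closed_form(self):
        pe = PEUnit()
        one = quantize(1.0, FMT)  # 2^12
        assert pe.execute([one] * 7, [one] * 7) == 7 * (1 << 12) ** 2

    def test_matches_integer_dot_oracle(self, rng):
        pe = PEUnit(accumulator_bits=64)
        for _ in range(100):
            x = rng.integers(-(2**15), 2**15, size=7)
            w = rng.integers(-(2**15), 2**15, size=7)
            expected = sum(int(a) * int(b) for a, b in zip(x, w))
            assert pe.execute(x, w) == expected

    def test_counts_seven_multiplications_per_invocation(self):
        pe = PEUnit()
        for _ in range(5):
            pe.execute([1] * 7, [1] * 7)
        assert pe.invocations == 5 and pe.multiplications == 35

    def test_lane_count_enforced(self):
        with pytest.raises(SchedulingError):
            PEUnit().execute([1] * 6, [1] * 7)

    def test_accumulator_saturates(self):
        pe = PEUnit(accumulator_bits=8)
        assert pe.execute([100] * 7, [100] * 7) == 127


class TestReluUnit:
    def test_negative_sum_clamps(self):
        assert ReluUnit(FMT).process(-12345, s2=1) == 0

    def test_positive_sum_requantized(self):
        # 1.5 * 1.0 in Q12 products carries 24 frac bits
        wide = quantize(1.5, FMT) * quantize(1.0, FMT)
        assert ReluUnit(FMT).process(wide, s2=1) == quantize(1.5, FMT)

    def test_1x1_accumulation_matches_reference_composition(self, rng):
        for _ in range(50):
            maps = rng.uniform(-2, 2, size=(3, 2, 9))
            w2 = rng.uniform(-1, 1, size=3)
            qmaps, qw2 = quantize(maps, FMT), quantize(w2, FMT)
            unit = ReluUnit(FMT)
            got = np.zeros((2, 9), dtype=np.int64)
            for r in range(2):
                for j in range(9):
                    for c in range(3):
                        unit.process(int(qmaps[c, r, j]) * int(qw2[c]), s2=0)
                    got[r, j] = unit.flush()
            # reference: float 1x1+relu on the dequantized operands, requantized
            ref = model.relu(model.conv_1x1(dequantize(qmaps, FMT), dequantize(qw2, FMT)))
            np.testing.assert_array_equal(got, quantize(ref, FMT))

    def test_bad_s2(self):
        with pytest.raises(SchedulingError):
            ReluUnit(FMT).process(1, s2=2)


class TestMaxpoolUnit:
    def test_pair(self):
        assert maxpool_unit([3, 7], s3=1) == 7

    def test_tie_leftmost(self):
        assert maxpool_unit([5, 5, 5], s3=0) == 5

    def test_matches_max_oracle(self, rng):
        for _ in range(100):
            vals = [int(v) for v in rng.integers(-1000, 1000, size=3)]
            assert maxpool_unit(vals, s3=0) == max(vals)

    def test_wrong_count_for_width(self):
        with pytest.raises(SchedulingError):
            maxpool_unit([1, 2, 3], s3=1)


class TestSoftmaxUnit:
    def test_partials_sum(self):
        R, _ = softmax_unit([[1, 2, 3]] + [[0, 0, 0]] * 5)
        assert R[0] == 6

    def test_all_equal_ties_to_normal(self):
        _, predicted = softmax_unit([[1, 1, 1]] * 6)
        assert predicted == BeatClass.NORMAL

    def test_wrong_partial_count(self):
        with pytest.raises(SchedulingError):
            softmax_unit([[1, 2]] + [[0, 0, 0]] * 5)

    def test_predict_before_done(self):
        unit = SoftmaxUnit()
        unit.accumulate(0, 5)
        with pytest.raises(SchedulingError):
            unit.predict()


class TestSchedule:
    def test_layer1(self):
        mux = schedule_layer(1)
        assert mux.S1 == 0 and mux.S2 == 1
        assert mux.S3 is DONT_CARE and mux.S6 is DONT_CARE

    def test_layer3_cycles_channels(self):
        mux = schedule_layer(3)
        assert mux.S1 == 1 and mux.S2 == 0 and mux.S4 == 0
        assert mux.S5 == (0b00, 0b01, 0b10) and mux.S6 == 0b00

    def test_layer7(self):
        mux = schedule_layer(7)
        assert mux.S1 == 1 and mux.S2 == 1 and mux.S4 == 0 and mux.S6 == 0b11

    def test_flatten_all_dont_care(self):
        mux = schedule_layer(6)
        assert all(getattr(mux, s) is DONT_CARE for s in ("S1", "S2", "S3", "S4", "S5", "S6"))

    @pytest.mark.parametrize("layer,fields", [
        (2, {"S3": 1, "S4": 1}),
        (4, {"S1": 1, "S2": 1, "S6": 0b10}),
        (5, {"S3": 0, "S4": 1}),
        (8, {"S1": 1, "S6": 0b01}),
    ])
    def test_remaining_rows(self, layer, fields):
        mux = schedule_layer(layer)
        for name, value in fields.items():
            assert getattr(mux, name) == value

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            schedule_layer(9)

    def test_mux_field_width_enforced(self):
        with pytest.raises(ValueError):
            MuxState(S1=2)
        with pytest.raises(ValueError):
            MuxState(S6=4)


class TestControlBuffer:
    def test_capacity_54(self):
        buf = ControlBuffer()
        buf.store(list(range(54)))
        assert buf.occupancy == 54 and buf.peak == 54

    def test_overflow_raises(self):
        with pytest.raises(BufferOverflowError):
            ControlBuffer().store(list(range(55)))


@pytest.fixture(scope="module")
def result():
    w = calibrate_weights(init_weights(42), np.zeros((1, 2, 24)) + 0.5, FMT)
    qw = quantize_weights(w, FMT)
    x = quantize(np.random.default_rng(0).uniform(-1, 1, size=(2, 24)), FMT)
    return run_inference(x, qw)


class TestRunInference:
    def test_buffer_peak_is_54(self, result):
        # 3 channels x 2x9 after the first pooling stage fill the buffer
        assert result.buffer_peak == 54

    def test_conv1_pe_invocations(self, result):
        # 3 kernels x 2 rows x 18 sliding positions, counted by brute force
        positions = sum(1 for _ in range(3) for _ in range(2) for _j in range(24 - 6))
        assert positions == 108
        assert result.pe_invocations[1] == 108

    def test_fc2_three_invocations_per_node(self, result):
        assert result.pe_invocations[8] == 6 * 3

    def test_per_layer_counts(self, result):
        assert result.pe_invocations == {1: 108, 2: 0, 3: 54, 4: 18, 5: 0, 6: 0, 7: 21, 8: 18}

    def test_multiplications_are_seven_per_invocation(self, result):
        assert result.multiplications == 7 * sum(result.pe_invocations.values())

    def test_deterministic_bit_identical(self):
        w = init_weights(8)
        qw = quantize_weights(w, FMT)
        x = quantize(np.random.default_rng(5).uniform(-1, 1, size=(2, 24)), FMT)
        r1, r2 = run_inference(x, qw), run_inference(x, qw)
        assert r1.scores == r2.scores
        assert r1.predicted == r2.predicted
        assert r1.pe_invocations == r2.pe_invocations

    def test_rejects_bad_shape(self):
        qw = quantize_weights(init_weights(0), FMT)
        with pytest.raises(model.InvalidShapeError):
            run_inference(np.zeros((2, 23), dtype=np.int64), qw)


class TestQuantizationError:
    def test_score_deviation_within_analytic_bound(self, rng):
        for seed in range(20):
            w = calibrate_weights(init_weights(seed),
                                  rng.uniform(-1, 1, size=(8, 2, 24)), FMT)
            bound = score_error_bound(w, FMT)
            x = rng.uniform(-1, 1, size=(2, 24))
            ref_scores, _ = model.forward(x, w)
            res = run_inference(quantize(x, FMT), quantize_weights(w, FMT))
            dev = np.max(np.abs(res.dequantized_scores(FMT) - ref_scores))
            assert dev <= bound

    def test_argmax_agrees_when_margin_exceeds_bound(self, rng):
        checked = 0
        for seed in range(30):
            w = calibrate_weights(init_weights(seed),
                                  rng.uniform(-1, 1, size=(8, 2, 24)), FMT)
            bound = score_error_bound(w, FMT)
            x = rng.uniform(-1, 1, size=(2, 24))
            scores, ref_cls = model.forward(x, w)
            top2 = np.sort(scores)[-2:]
            if top2[1] - top2[0] <= 2 * bound:
                continue
            res = run_inference(quantize(x, FMT), quantize_weights(w, FMT))
            assert res.predicted == ref_cls
            checked += 1
        assert checked > 0


class TestCompareAgainstReference:
    def test_high_precision_full_agreement(self, rng):
        # 32-bit words with 24 fractional bits on unit-scale weights: the
        # error bound is far below any score margin, so agreement is 100%.
        fmt = FixedPointFormat(32, 24)
        w = init_weights(3)
        inputs = rng.uniform(-1, 1, size=(100, 2, 24))
        report = compare_against_reference(inputs, w, fmt, accumulator_bits=64)
        assert report.agreement == 1.0
        assert report.max_score_deviation <= score_error_bound(w, fmt)

    def test_exact_equality_with_integer_valued_operands(self, rng):
        # Integer-valued weights and inputs are exactly representable and
        # every requantization shift is lossless, so both paths compute
        # the identical scores.
        fmt = FixedPointFormat(20, 4)
        groups = {n: rng.integers(-2, 3, size=s).astype(float)
                  for n, s in model.ModelWeights._SHAPES.items()}
        w = model.ModelWeights(**groups)
        inputs = rng.integers(-1, 2, size=(20, 2, 24)).astype(float)
        report = compare_against_reference(inputs, w, fmt, accumulator_bits=64)
        assert report.agreement == 1.0
        assert report.max_score_deviation == 0.0

    def test_report_tsv(self, tmp_path, rng):
        w = init_weights(1)
        report = compare_against_reference(rng.uniform(-1, 1, size=(5, 2, 24)), w, FMT)
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("beat\t") and len(lines) == 7


class TestQuantizedWeightsContainer:
    def test_roundtrip(self, tmp_path):
        qw = quantize_weights(init_weights(2), FMT)
        path = tmp_path / "qweights.json"
        qw.save(path)
        from ecgcnn.datapath import QuantizedWeights

        loaded = QuantizedWeights.load(path)
        assert loaded.fmt == FMT
        for name, arr in qw.groups().items():
            np.testing.assert_array_equal(arr, getattr(loaded, name))

    def test_count_preserved(self):
        assert quantize_weights(init_weights(0), FMT).total_count() == 297
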