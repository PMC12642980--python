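import numpy as np
import pytest

import contractile as ct
from contractile.metrics import MetricParams, brightness_compensate, pv_frame

from conftest import random_stack


# ---------------------------------------------------------------------------
# independent brute-force oracles (literal loops, no vectorisation)


def oracle_mm_speed(frames, N, roi=None):
    frames = frames.astype(float)
    if roi is not None:
        frames = frames[:, roi.row0 : roi.row1, roi.col0 : roi.col1]
    T, H, W = frames.shape
    out = np.full(T, np.nan)
    for t in range(N, T):
        acc = 0.0
        for r in range(H):
            for c in range(W):
                acc += abs(frames[t, r, c] - frames[t - N, r, c])
        out[t] = acc
    return out


def oracle_mm_contraction(frames, ref):
    frames = frames.astype(float)
    T, H, W = frames.shape
    out = np.zeros(T)
    for t in range(T):
        acc = 0.0
        for r in range(H):
            for c in range(W):
                acc += abs(frames[t, r, c] - frames[ref, r, c])
        out[t] = acc
    return out


def oracle_pixel_std(frames, lo, hi):
    """Population std per pixel over frames lo..hi inclusive."""
    frames = frames.astype(float)
    _, H, W = frames.shape
    out = np.zeros((H, W))
    n = hi - lo + 1
    for r in range(H):
        for c in range(W):
            vals = [frames[t, r, c] for t in range(lo, hi + 1)]
            m = sum(vals) / n
            out[r, c] = (sum((v - m) ** 2 for v in vals) / n) ** 0.5
    return out


def oracle_pv_speed(frames, N):
    T = frames.shape[0]
    out = np.full(T, np.nan)
    for t in range(N, T):
        out[t] = oracle_pixel_std(frames, t - N, t).sum()
    return out


# ---------------------------------------------------------------------------


class TestMmSpeed:
    def test_constant_stack_is_zero(self):
        frames = np.full((6, 4, 4), 123, dtype=np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        trace = ct.mm_speed(stack, MetricParams(frame_delay_N=2))
        assert np.all(trace.defined_values == 0)
        assert np.all(np.isnan(trace.values[:2]))

    def test_uniform_step(self):
        frames = np.stack([np.full((4, 4), 100), np.full((4, 4), 107)]).astype(np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        trace = ct.mm_speed(stack, MetricParams(frame_delay_N=1))
        assert trace.values[1] == 7 * 16

    @pytest.mark.parametrize("N", [1, 2])
    def test_matches_brute_force_oracle(self, rng, N):
        stack = random_stack(rng, shape=(5, 4, 4))
        trace = ct.mm_speed(stack, MetricParams(frame_delay_N=N))
        np.testing.assert_allclose(
            trace.values, oracle_mm_speed(stack.frames, N), equal_nan=True
        )

    def test_roi_restricts_sum(self, rng):
        stack = random_stack(rng, shape=(6, 8, 8))
        roi = ct.RoiSpec(2, 6, 1, 5)
        trace = ct.mm_speed(stack, MetricParams(frame_delay_N=1, roi=roi))
        np.testing.assert_allclose(
            trace.values, oracle_mm_speed(stack.frames, 1, roi), equal_nan=True
        )

    def test_frame_delay_too_large(self, rng):
        stack = random_stack(rng, shape=(4, 3, 3))
        with pytest.raises(ValueError, match="frame delay"):
            ct.mm_speed(stack, MetricParams(frame_delay_N=4))


class TestMmContraction:
    def test_reference_sample_is_zero_and_oracle_match(self, rng):
        stack = random_stack(rng, shape=(7, 4, 4))
        p = MetricParams(reference_frame=3, brightness_compensation=False)
        trace = ct.mm_contraction(stack, p)
        assert trace.values[3] == 0
        np.testing.assert_allclose(trace.values, oracle_mm_contraction(stack.frames, 3))
        assert trace.valid_from == 0

    def test_constant_stack_zero_any_reference(self):
        frames = np.full((5, 3, 3), 50, dtype=np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        trace = ct.mm_contraction(stack, MetricParams(reference_frame=2))
        assert np.all(trace.values == 0)

    def test_reference_out_of_range(self, rng):
        stack = random_stack(rng, shape=(5, 3, 3))
        with pytest.raises(IndexError):
            ct.mm_contraction(stack, MetricParams(reference_frame=9))


class TestBrightnessCompensation:
    def test_pure_gain_change_is_nulled(self, rng):
        base = rng.integers(100, 1000, size=(4, 4)).astype(float)
        frames = np.stack([base, base * 1.5, base, base * 0.75]).round().astype(np.uint16)
        # rounding breaks exactness; rebuild exactly scalable frames
        base = (rng.integers(25, 250, size=(4, 4)) * 4).astype(np.uint16)
        frames = np.stack([base, base * 1.5, base, base // 2]).astype(np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        trace = ct.mm_contraction(stack, MetricParams(reference_frame=0))
        np.testing.assert_allclose(trace.values, 0, atol=1e-6)

    def test_compensated_means_equal_reference_mean(self, rng):
        stack = random_stack(rng, shape=(6, 5, 5))
        comp = brightness_compensate(stack, reference_frame=2)
        means = comp.frames.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[2])

    def test_ramp_drift_on_static_scene(self, rng):
        base = rng.integers(2000, 20000, size=(8, 8)).astype(float)
        gains = 1 + 0.01 * np.arange(10)
        frames = (base[None] * gains[:, None, None]).round().astype(np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        raw = ct.mm_speed(stack, MetricParams(frame_delay_N=1, brightness_compensation=False))
        comp = ct.mm_speed(stack, MetricParams(frame_delay_N=1, brightness_compensation=True))
        assert np.nanmean(comp.values) < 0.02 * np.nanmean(raw.values)

    def test_zero_mean_frame_rejected(self):
        frames = np.zeros((3, 4, 4), dtype=np.uint16)
        frames[0] = 10
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        with pytest.raises(ValueError, match="zero mean"):
            brightness_compensate(stack, 0)


class TestPvSpeed:
    def test_constant_stack_is_zero(self):
        frames = np.full((8, 4, 4), 77, dtype=np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        trace = ct.pv_speed(stack, MetricParams(frame_delay_N=3))
        assert np.all(trace.defined_values == 0)

    def test_two_point_window_is_half_mm(self, rng):
        # population std of two values is exactly half their absolute difference
        for _ in range(10):
            stack = random_stack(rng, shape=(12, 5, 5))
            p = MetricParams(frame_delay_N=1)
            pv = ct.pv_speed(stack, p)
            mm = ct.mm_speed(stack, p)
            np.testing.assert_allclose(pv.defined_values, mm.defined_values / 2)

    @pytest.mark.parametrize("N", [2, 3])
    def test_matches_brute_force_oracle(self, rng, N):
        stack = random_stack(rng, shape=(6, 3, 3))
        trace = ct.pv_speed(stack, MetricParams(frame_delay_N=N))
        np.testing.assert_allclose(
            trace.values, oracle_pv_speed(stack.frames, N), equal_nan=True, rtol=1e-10
        )

    def test_step_stack_nonzero_exactly_at_straddling_windows(self):
        # static scene with a single global step between frames 9 and 10
        frames = np.full((20, 4, 4), 100, dtype=np.uint16)
        frames[10:] = 200
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        N = 4
        trace = ct.pv_speed(stack, MetricParams(frame_delay_N=N))
        nonzero = np.flatnonzero(trace.defined_values > 0) + N
        np.testing.assert_array_equal(nonzero, np.arange(10, 10 + N))

    def test_sum_variances_option(self, rng):
        stack = random_stack(rng, shape=(6, 3, 3))
        tr = ct.pv_speed(stack, MetricParams(frame_delay_N=2, sum_variances=True))
        expect = np.nansum(
            [oracle_pixel_std(stack.frames, t - 2, t) ** 2 for t in range(2, 6)], axis=(1, 2)
        )
        np.testing.assert_allclose(tr.defined_values, expect, rtol=1e-10)


class TestPvFrame:
    def test_sum_consistency_with_trace(self, rng):
        stack = random_stack(rng, shape=(8, 4, 4))
        p = MetricParams(frame_delay_N=2)
        trace = ct.pv_speed(stack, p)
        for t in range(2, 8):
            assert pv_frame(stack, t, 2).sum() == pytest.approx(trace.values[t])

    def test_locality_single_oscillating_pixel(self):
        frames = np.full((6, 4, 4), 100, dtype=np.uint16)
        frames[::2, 2, 1] = 140
        stack = ct.FrameSequence(frames, camera_fps=10.0).as_single_well()
        fmap = pv_frame(stack, 3, 2)
        assert fmap[2, 1] > 0
        fmap[2, 1] = 0
        assert np.all(fmap == 0)

    def test_matches_oracle_map(self, rng):
        stack = random_stack(rng, shape=(7, 3, 3))
        np.testing.assert_allclose(
            pv_frame(stack, 5, 3), oracle_pixel_std(stack.frames, 2, 5), rtol=1e-10
        )

    def test_rejects_t_before_first_window(self, rng):
        stack = random_stack(rng)
        with pytest.raises(ValueError):
            pv_frame(stack, 1, 2)


class TestPvContraction:
    def test_reference_sample_is_zero(self, rng):
        stack = random_stack(rng, shape=(10, 3, 3))
        trace = ct.pv_contraction(stack, MetricParams(reference_frame=5, adjacent_k=3))
        assert trace.values[5] == 0

    def test_toy_stack_matches_loop_oracle(self, rng):
        stack = random_stack(rng, shape=(8, 3, 1))
        k, ref = 3, 4
        trace = ct.pv_contraction(stack, MetricParams(reference_frame=ref, adjacent_k=k))
        s_ref = oracle_pixel_std(stack.frames, ref - 1, ref + 1)
        for t in range(1, 7):  # interior timepoints with full centred windows
            s_t = oracle_pixel_std(stack.frames, t - 1, t + 1)
            assert trace.values[t] == pytest.approx(np.abs(s_t - s_ref).sum())

    def test_stationary_noise_residual_shrinks_with_k(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(1000, 20, size=(120, 6, 6)).round().astype(np.uint16)
        stack = ct.FrameSequence(frames, camera_fps=100.0).as_single_well()
        resid = []
        for k in (3, 30):
            tr = ct.pv_contraction(stack, MetricParams(reference_frame=60, adjacent_k=k))
            resid.append(np.mean(tr.values[20:100]))
        assert resid[1] < resid[0]

    def test_diff_of_sums_option(self, rng):
        stack = random_stack(rng, shape=(8, 3, 3))
        p = MetricParams(reference_frame=4, adjacent_k=3, pv_diff_of_sums=True)
        trace = ct.pv_contraction(stack, p)
        s_ref = oracle_pixel_std(stack.frames, 3, 5).sum()
        s_2 = oracle_pixel_std(stack.frames, 1, 3).sum()
        assert trace.values[2] == pytest.approx(abs(s_2 - s_ref))


class TestBoundedness:
    def test_mm_bounded_by_range_times_area(self, rng):
        stack = random_stack(rng, shape=(10, 4, 4), bit_depth=8)
        trace = ct.mm_speed(stack, MetricParams(frame_delay_N=1))
        assert np.nanmax(trace.values) <= 255 * 16

    def test_pv_per_pixel_std_bounded_by_half_range(self, rng):
        stack = random_stack(rng, shape=(30, 4, 4), bit_depth=8)
        for t in range(5, 30, 5):
            assert pv_frame(stack, t, 5).max() <= 255 / 2 + 1e-9


class TestDerivativeRelation:
    def test_speed_correlates_with_contraction_derivative(self, beating_phantom_100fps):
        # on a noiseless phantom with N=1, mm_speed ~ |d/dt mm_contraction|
        _, seq, _ = beating_phantom_100fps
        stack = seq.as_single_well()
        p = MetricParams(frame_delay_N=1, reference_frame=0, brightness_compensation=False)
        speed = ct.mm_speed(stack, p).defined_values
        contraction = ct.mm_contraction(stack, p).values
        deriv = np.abs(np.diff(contraction))
        a = speed - speed.mean()
        b = deriv - deriv.mean()
        xcorr = np.correlate(a, b, mode="full")
        lag = int(np.argmax(xcorr)) - (len(a) - 1)
        assert lag == 0


class TestMovingAverage:
    def _trace(self, values):
        return ct.ContractionTrace(
            values=np.asarray(values, float),
            frame_times_s=np.arange(len(values)) / 10.0,
            metric_name="mm_speed",
            frame_delay_N=1,
        )

    def test_window_one_is_identity(self):
        tr = self._trace([1, 5, 2, 8])
        np.testing.assert_array_equal(ct.moving_average(tr, 1).values, tr.values)

    def test_constant_trace_unchanged(self):
        tr = self._trace([3.0] * 10)
        np.testing.assert_allclose(ct.moving_average(tr, 4).values, 3.0)

    def test_impulse_spread_by_even_window(self):
        vals = np.zeros(12)
        vals[6] = 8.0
        out = ct.moving_average(self._trace(vals), 4).values
        np.testing.assert_allclose(np.flatnonzero(out > 0), [5, 6, 7, 8])
        np.testing.assert_allclose(out[5:9], 2.0)  # h / window

    def test_length_and_undefined_head_preserved(self):
        vals = np.concatenate([[np.nan, np.nan], np.arange(8.0)])
        tr = ct.ContractionTrace(
            values=vals,
            frame_times_s=np.arange(10) / 10.0,
            metric_name="mm_speed",
            frame_delay_N=2,
            valid_from=2,
        )
        out = ct.moving_average(tr, 3)
        assert len(out) == 10
        assert np.all(np.isnan(out.values[:2]))
        # truncated edge window: mean of first two defined samples
        assert out.values[2] == pytest.approx(0.5)


class TestNormalize:
    def test_peak_is_one_and_scale_invariant(self, rng):
        vals = rng.random(50) + 0.1
        tr = ct.ContractionTrace(
            values=vals, frame_times_s=np.arange(50.0), metric_name="pv_speed", frame_delay_N=1
        )
        out = ct.normalize_trace(tr)
        assert np.nanmax(out.values) == 1.0
        out2 = ct.normalize_trace(tr.with_values(vals * 7.3))
        np.testing.assert_allclose(out.values, out2.values)

    def test_all_zero_rejected(self):
        tr = ct.ContractionTrace(
            values=np.zeros(5), frame_times_s=np.arange(5.0), metric_name="pv_speed", frame_delay_N=1
        )
        with pytest.raises(ValueError):
            ct.normalize_trace(tr)
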