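import numpy as np
import pytest
from scipy import stats

import contractile as ct
from contractile.phantom import (
    PhantomConfig,
    load_phantom_config,
    save_phantom_config,
    twitch_peak_time_s,
)


@pytest.fixture
def cfg():
    return PhantomConfig(image_px=(48, 48), seed=42)


class TestTexture:
    def test_deterministic_under_seed(self, cfg):
        np.testing.assert_array_equal(ct.make_texture(cfg), ct.make_texture(cfg))

    def test_histogram_spans_most_of_bit_range(self, cfg):
        tex = ct.make_texture(cfg)
        assert tex.max() - tex.min() == pytest.approx(0.8 * 65535, rel=0.01)
        assert tex.min() >= 0 and tex.max() <= 65535

    def test_power_concentrated_in_band(self):
        cfg = PhantomConfig(image_px=(128, 128), texture_band_px=(8.0, 16.0), seed=1)
        tex = ct.make_texture(cfg)
        f = np.fft.fft2(tex - tex.mean())
        power = np.abs(f) ** 2
        fy = np.fft.fftfreq(128)[:, None]
        fx = np.fft.fftfreq(128)[None, :]
        freq = np.hypot(fy, fx)
        in_band = (freq >= 1 / 16.0) & (freq <= 1 / 8.0)
        assert power[in_band].sum() / power.sum() > 0.99

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(texture_band_px=(8.0, 8.0))


class TestTwitchWaveform:
    def test_zero_before_first_beat(self, cfg):
        t0 = cfg.first_beat_time_s
        assert ct.twitch_waveform(cfg, t0 - 0.01) == 0.0
        assert ct.twitch_waveform(cfg, 0.0) == 0.0

    def test_peak_at_closed_form_argmax(self, cfg):
        # t* = rise_tau * ln(1 + fall_tau / rise_tau), from d/dt = 0
        t_star = cfg.rise_tau_s * np.log(1 + cfg.fall_tau_s / cfg.rise_tau_s)
        assert twitch_peak_time_s(cfg) == pytest.approx(t_star)
        t = cfg.first_beat_time_s + np.linspace(0, cfg.beat_period_s / 2, 2001)
        s = ct.twitch_waveform(cfg, t)
        assert t[np.argmax(s)] - cfg.first_beat_time_s == pytest.approx(t_star, abs=2e-3)
        assert np.max(s) == pytest.approx(1.0, abs=0.01)

    def test_speed_has_two_maxima_per_beat(self, cfg):
        t = np.linspace(0, 1.5, 3001)
        s = ct.twitch_waveform(cfg, t)
        speed = np.abs(np.diff(s))
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(speed, prominence=0.02 * speed.max())
        beat_window = (t[peaks] >= cfg.first_beat_time_s - 0.01) & (
            t[peaks] < cfg.first_beat_time_s + 1.0
        )
        assert beat_window.sum() == 2  # contraction and relaxation phases


class TestDisplacementField:
    def test_zero_amplitude_gives_zero_field(self, cfg):
        assert np.all(ct.displacement_field(cfg, 0.0) == 0)

    def test_single_focus_points_inward(self, cfg):
        u = ct.displacement_field(cfg, 1.0)
        h, w = cfg.image_px
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        toward = np.stack([h / 2 - rows, w / 2 - cols])
        dot = (u * toward).sum(axis=0)
        mask = np.hypot(*toward) > 1.0  # away from the exact centre
        assert np.all(dot[mask] >= 0)

    def test_magnitude_bounded_by_peak_displacement(self, cfg):
        for s in (0.3, 1.0):
            u = ct.displacement_field(cfg, s)
            mag = np.hypot(u[0], u[1])
            assert mag.max() <= s * cfg.peak_displacement_px + 1e-9


class TestRenderFrame:
    def test_static_noiseless_is_exact_texture_copy(self):
        cfg = PhantomConfig(image_px=(32, 32), noise_gain=0.0, first_beat_s=100.0, seed=5)
        tex = ct.make_texture(cfg)
        f1 = ct.render_frame(cfg, tex, t=0.0)
        f2 = ct.render_frame(cfg, tex, t=0.5)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(f1, np.round(tex).astype(np.uint16))
        stack = ct.FrameSequence(np.stack([f1] * 5), camera_fps=10.0).as_single_well()
        assert np.all(ct.pv_speed(stack, ct.MetricParams(frame_delay_N=1)).defined_values == 0)
        assert np.all(ct.mm_speed(stack, ct.MetricParams(frame_delay_N=1)).defined_values == 0)

    def test_noise_variance_scales_linearly_with_mean(self):
        """Shot-noise model: pixel variance vs mean regresses to the gain."""
        gain = 0.8
        rng = np.random.default_rng(7)
        means, variances = [], []
        for level in np.linspace(2000, 30000, 10):
            cfg = PhantomConfig(
                image_px=(64, 64), noise_gain=gain, first_beat_s=1e9,
                baseline_mean=level, seed=9,
            )
            tex = np.full((64, 64), level)
            frames = np.stack([
                ct.render_frame(cfg, tex, t=0.0, rng=rng).astype(float) for _ in range(30)
            ])
            means.append(frames.mean())
            variances.append(frames.var(axis=0).mean())
        res = stats.linregress(means, variances)
        assert res.slope == pytest.approx(gain, rel=0.10)
        assert res.rvalue**2 > 0.95

    def test_jolt_is_pure_translation(self):
        cfg = PhantomConfig(
            image_px=(32, 32), noise_gain=0.0, first_beat_s=100.0,
            jolt_shift_px=(3.0, 0.0), seed=6,
        )
        tex = ct.make_texture(cfg)
        still = ct.render_frame(cfg, tex, t=0.0)
        jolted = ct.render_frame(cfg, tex, t=0.1, jolt=True)
        # integer shift: interior rows simply move down by 3
        np.testing.assert_array_equal(jolted[3:], still[:-3])

    def test_brightness_drift_modulates_mean(self):
        cfg = PhantomConfig(
            image_px=(32, 32), noise_gain=0.0, first_beat_s=100.0,
            brightness_drift_amplitude=0.1, brightness_drift_period_s=4.0, seed=6,
        )
        tex = ct.make_texture(cfg)
        up = ct.render_frame(cfg, tex, t=1.0)  # sin peak
        down = ct.render_frame(cfg, tex, t=3.0)  # sin trough
        assert up.mean() == pytest.approx(1.1 / 0.9 * down.mean(), rel=0.01)

    def test_bubble_attenuates_locally(self):
        cfg = PhantomConfig(
            image_px=(48, 48), noise_gain=0.0, first_beat_s=100.0,
            bubble_count=1, bubble_radius_px=6.0, bubble_depth=0.8, seed=6,
        )
        tex = ct.make_texture(cfg)
        clean = ct.render_frame(cfg, tex, t=0.0)
        with_bubble = ct.render_frame(cfg, tex, t=0.0, bubble_centres=np.array([[24.0, 24.0]]))
        assert with_bubble.astype(int).sum() < clean.astype(int).sum()
        # far corner untouched
        np.testing.assert_array_equal(with_bubble[:4, :4], clean[:4, :4])


class TestGenerateAcquisition:
    def test_schedule_arithmetic_and_demux_counts(self, nine_well_acquisition):
        _, layout, seq, _ = nine_well_acquisition
        assert seq.n_frames == 1500
        stacks = ct.demux(seq, layout)
        assert len(stacks) == 27
        counts = {s.n_frames for s in stacks.values()}
        assert counts <= {55, 56}

    def test_single_well_single_colour_plain_movie(self):
        cfg = PhantomConfig(image_px=(32, 32), seed=2)
        layout = ct.AcquisitionLayout(wells=("w",), colours=("R",), camera_fps=50.0)
        seq, truth = ct.generate_acquisition(cfg, layout, 2.0)
        assert seq.n_frames == 100
        assert list(truth.beat_times_s) == ["w"]

    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(image_px=(24, 24), seed=3)
        layout = ct.AcquisitionLayout(wells=("a", "b"), colours=("R", "G"), camera_fps=20.0)
        s1, _ = ct.generate_acquisition(cfg, layout, 1.0)
        s2, _ = ct.generate_acquisition(cfg, layout, 1.0)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_chromatic_consistency_across_wells(self, nine_well_acquisition):
        """Monolayer at the red focal depth: red scores sharpest in every well."""
        _, layout, seq, _ = nine_well_acquisition
        stacks = ct.demux(seq, layout)
        report = ct.focus_report(stacks)
        sel = report[report["selected"]]
        assert set(sel["colour"]) == {"R"}
        assert len(sel) == 9

    def test_truth_beat_times_consistent_with_rate(self, nine_well_acquisition):
        cfg, _, _, truth = nine_well_acquisition
        for times in truth.beat_times_s.values():
            d = np.diff(times)
            np.testing.assert_allclose(d, cfg.beat_period_s)


class TestConfigYaml:
    def test_round_trip(self, tmp_path, cfg):
        p = tmp_path / "phantom.yaml"
        save_phantom_config(cfg, p)
        assert load_phantom_config(p) == cfg
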