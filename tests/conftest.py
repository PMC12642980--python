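import numpy as np
import pytest

import contractile as ct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stack(rng, shape=(10, 6, 6), bit_depth=16, fps=100.0):
    """Random integer WellChannelStack for metric tests."""
    frames = rng.integers(0, 2**bit_depth, size=shape).astype(
        np.uint8 if bit_depth == 8 else np.uint16
    )
    return ct.FrameSequence(frames, camera_fps=fps, bit_depth=bit_depth).as_single_well()


@pytest.fixture(scope="session")
def beating_phantom_100fps():
    """Noiseless single-well 1 Hz phantom at 100 fps for 7 s (700 frames)."""
    cfg = ct.PhantomConfig(image_px=(48, 48), beat_rate_hz=1.0, noise_gain=0.0, seed=7)
    layout = ct.AcquisitionLayout(wells=("w0",), colours=("R",), camera_fps=100.0)
    seq, truth = ct.generate_acquisition(cfg, layout, 7.0, phase_jitter=0.0)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def nine_well_acquisition():
    """Nine wells x three colours at 100 fps camera rate, 0.25 Hz beats, 15 s.

    The cooled-monolayer regime: slow beats, ~4 s contraction interval,
    3.7 fps effective sampling per well and colour.
    """
    cfg = ct.PhantomConfig(
        image_px=(48, 48),
        beat_rate_hz=0.25,
        rise_tau_s=0.3,
        fall_tau_s=1.0,
        noise_gain=0.5,
        seed=11,
    )
    layout = ct.AcquisitionLayout(
        wells=tuple(f"w{i}" for i in range(9)), colours=("R", "G", "B"), camera_fps=100.0
    )
    seq, truth = ct.generate_acquisition(cfg, layout, 15.0)
    return cfg, layout, seq, truth
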