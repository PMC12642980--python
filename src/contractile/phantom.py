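"""Synthetic contracting-monolayer acquisitions with known ground truth.

The phantom emulates the features of real multi-well brightfield recordings
that the analysis pipeline has to cope with:

* a high-contrast, band-limited "Schlieren-like" monolayer texture;
* periodic twitches that elastically warp the texture toward one or more
  contraction foci, with an exponential rise/decay kinetic;
* per-colour defocus blur from chromatic focal shifts (zero inside a
  colour's depth-of-field interval, growing linearly with excess depth);
* shot noise whose variance scales linearly with the pixel value;
* optional artefacts: drifting dark bubble annuli, whole-frame "jolt"
  translations on chosen frames, and slow baseline brightness drift.

Everything is driven by one seeded generator (bit-reproducible); per-well
substreams are derived deterministically, so wells differ in texture and
beat phase while the whole acquisition replays exactly under the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import FrameSequence
from .optics import OpticalConfig, defocus_sigma_px, multiwell_preset
from .schedule import AcquisitionLayout, build_schedule, effective_rate

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "make_texture",
    "twitch_waveform",
    "twitch_peak_time_s",
    "displacement_field",
    "render_frame",
    "generate_acquisition",
    "load_phantom_config",
    "save_phantom_config",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth description of one synthetic monolayer well.

    Units: times in seconds, lengths in pixels unless suffixed ``_mm``.
    ``noise_gain`` is the shot-noise variance per unit mean pixel value
    (counts); ``texture_band_px`` is the spatial-period band of the base
    texture.  Defaults describe a desk-scale version of a nine-well
    recording: 64 x 64 px frames, 1 Hz spontaneous beating with a ~1 s
    contraction (rise tau 0.08 s, fall tau 0.25 s), 3 px peak displacement
    toward a single central focus, 16-bit counts around a 20000-count
    baseline with shot-noise gain 0.5.
    """

    image_px: tuple[int, int] = (64, 64)
    texture_band_px: tuple[float, float] = (4.0, 16.0)
    beat_rate_hz: float = 1.0
    rise_tau_s: float = 0.08
    fall_tau_s: float = 0.25
    peak_displacement_px: float = 3.0
    foci: tuple[tuple[tuple[float, float], float, float], ...] | None = None
    monolayer_z_mm: float = 0.46
    noise_gain: float = 0.5
    baseline_mean: float = 20000.0
    bit_depth: int = 16
    first_beat_s: float | None = None
    # artefacts (all off by default)
    bubble_count: int = 0
    bubble_radius_px: float = 6.0
    bubble_drift_px: float = 0.5
    bubble_depth: float = 0.5
    jolt_frames: tuple[int, ...] = ()
    jolt_shift_px: tuple[float, float] = (5.0, 0.0)
    brightness_drift_amplitude: float = 0.0
    brightness_drift_period_s: float = 10.0
    poisson_noise: bool = False
    blur_px_per_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_rate_hz <= 0 or self.rise_tau_s <= 0 or self.fall_tau_s <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.texture_band_px[0] <= 0 or self.texture_band_px[1] <= self.texture_band_px[0]:
            raise ValueError("texture band must be a non-degenerate positive interval")
        if self.noise_gain < 0 or self.baseline_mean <= 0:
            raise ValueError("noise_gain must be >= 0 and baseline_mean > 0")
        if self.foci is None:
            h, w = self.image_px
            object.__setattr__(
                self,
                "foci",
                (((h / 2.0, w / 2.0), 0.4 * min(h, w), 1.0),),
            )

    @property
    def beat_period_s(self) -> float:
        return 1.0 / self.beat_rate_hz

    @property
    def first_beat_time_s(self) -> float:
        return 0.5 * self.beat_period_s if self.first_beat_s is None else self.first_beat_s

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class GroundTruth:
    """Truth channel recorded alongside a synthetic acquisition."""

    beat_times_s: dict[str, list[float]]
    beat_rate_hz: float
    jolt_frames: list[int]
    twitch_amplitude: dict[str, list[float]]  # s(t) at each well's frame times
    config: dict

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "beat_times_s": self.beat_times_s,
                    "beat_rate_hz": self.beat_rate_hz,
                    "jolt_frames": self.jolt_frames,
                    "twitch_amplitude": self.twitch_amplitude,
                    "config": self.config,
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# building blocks


def make_texture(cfg: PhantomConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Band-passed white-noise texture stretched over ~80% of the bit range.

    The spatial band ``texture_band_px`` is a period band: Fourier
    components with periods inside it are kept, everything else removed.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    h, w = cfg.image_px
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    freq = np.hypot(fy, fx)
    lo_p, hi_p = cfg.texture_band_px
    band = (freq >= 1.0 / hi_p) & (freq <= 1.0 / lo_p)
    if not band.any():
        raise ValueError("texture band keeps no Fourier components at this image size")
    filtered = np.fft.ifft2(np.fft.fft2(noise) * band).real
    lo_v, hi_v = filtered.min(), filtered.max()
    if hi_v - lo_v == 0:
        raise ValueError("degenerate texture (no variation in band)")
    unit = (filtered - lo_v) / (hi_v - lo_v)
    # occupy the central ~80% of the bit range around the baseline mean
    span = 0.8 * cfg.max_count
    lo_count = max(0.0, cfg.baseline_mean - span / 2)
    tex = lo_count + unit * span
    return np.clip(tex, 0, cfg.max_count)


def twitch_peak_time_s(cfg: PhantomConfig) -> float:
    """Closed-form time from beat onset to peak twitch amplitude."""
    return cfg.rise_tau_s * np.log(1.0 + cfg.fall_tau_s / cfg.rise_tau_s)


def _beat_onsets(cfg: PhantomConfig, t_max: float) -> np.ndarray:
    t0 = cfg.first_beat_time_s
    if t_max < t0:
        return np.array([])
    n = int(np.floor((t_max - t0) * cfg.beat_rate_hz)) + 1
    return t0 + np.arange(n) * cfg.beat_period_s


def twitch_waveform(cfg: PhantomConfig, t) -> np.ndarray | float:
    """Normalized twitch amplitude s(t) in [0, 1].

    Each beat contributes ``(1 - exp(-dt/rise_tau)) * exp(-dt/fall_tau)``
    for dt >= 0, normalized to unit peak; contributions from successive
    beats superpose (negligibly, at physiological duty cycles).  s = 0
    before the first beat.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    onsets = _beat_onsets(cfg, float(t_arr.max(initial=0.0)))
    s = np.zeros_like(t_arr)
    t_star = twitch_peak_time_s(cfg)
    peak = (1 - np.exp(-t_star / cfg.rise_tau_s)) * np.exp(-t_star / cfg.fall_tau_s)
    for t_k in onsets:
        dt = t_arr - t_k
        m = dt >= 0
        s[m] += (1 - np.exp(-dt[m] / cfg.rise_tau_s)) * np.exp(-dt[m] / cfg.fall_tau_s) / peak
    s = np.clip(s, 0.0, None)
    return s if np.ndim(t) else float(s[0])


def displacement_field(cfg: PhantomConfig, s: float) -> np.ndarray:
    """Displacement field (2, H, W) in px pulling pixels toward the foci.

    ``u(p) = s * peak_displacement * sum_j w_j exp(-|p-c_j|^2 / 2 r_j^2) *
    (c_j - p)/max(|c_j - p|, eps)``; focus weights are normalized to sum to
    1, so ``|u| <= s * peak_displacement`` everywhere.
    """
    h, w = cfg.image_px
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    u = np.zeros((2, h, w))
    weights = np.array([f[2] for f in cfg.foci], dtype=float)
    weights = weights / weights.sum()
    eps = 1e-9
    for ((cr, cc), radius, _), wgt in zip(cfg.foci, weights):
        dr = cr - rows
        dc = cc - cols
        dist = np.hypot(dr, dc)
        gauss = np.exp(-(dist**2) / (2.0 * radius**2))
        denom = np.maximum(dist, eps)
        u[0] += wgt * gauss * dr / denom
        u[1] += wgt * gauss * dc / denom
    return s * cfg.peak_displacement_px * u


def _warp(texture: np.ndarray, u: np.ndarray) -> np.ndarray:
    h, w = texture.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    # inverse mapping: the pixel now at p came from p - u(p)
    return ndimage.map_coordinates(
        texture, [rows - u[0], cols - u[1]], order=1, mode="nearest"
    )


def _bubble_mask(cfg: PhantomConfig, centres: np.ndarray) -> np.ndarray:
    h, w = cfg.image_px
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    att = np.ones((h, w))
    ring_width = max(1.0, cfg.bubble_radius_px / 3.0)
    for cr, cc in centres:
        dist = np.hypot(rows - cr, cols - cc)
        ring = np.exp(-((dist - cfg.bubble_radius_px) ** 2) / (2 * ring_width**2))
        att *= 1.0 - cfg.bubble_depth * ring
    return att


def render_frame(
    cfg: PhantomConfig,
    texture: np.ndarray,
    t: float,
    colour: str | None = None,
    optics: OpticalConfig | None = None,
    rng: np.random.Generator | None = None,
    bubble_centres: np.ndarray | None = None,
    jolt: bool = False,
) -> np.ndarray:
    """Render one camera frame of the phantom at time t.

    Pipeline: warp the texture by the twitch displacement field, apply the
    colour's defocus blur (from the optics model and ``monolayer_z_mm``),
    multiply in the baseline brightness drift, attenuate by bubble annuli,
    translate the whole frame if this is a jolt frame, then add shot noise
    (normal approximation with variance ``noise_gain x mean``, or exact
    Poisson with ``poisson_noise``) and clip to the bit range.
    """
    s = twitch_waveform(cfg, t)
    u = displacement_field(cfg, float(s))
    frame = _warp(texture, u)

    if colour is not None:
        optics = optics or multiwell_preset()
        sigma = defocus_sigma_px(optics, colour, cfg.monolayer_z_mm, cfg.blur_px_per_mm)
        if sigma > 0:
            frame = ndimage.gaussian_filter(frame, sigma)

    if cfg.brightness_drift_amplitude:
        frame = frame * (
            1.0
            + cfg.brightness_drift_amplitude
            * np.sin(2 * np.pi * t / cfg.brightness_drift_period_s)
        )

    if bubble_centres is not None and len(bubble_centres):
        frame = frame * _bubble_mask(cfg, bubble_centres)

    if jolt:
        frame = ndimage.shift(frame, cfg.jolt_shift_px, order=1, mode="nearest")

    if cfg.noise_gain > 0:
        rng = np.random.default_rng(cfg.seed) if rng is None else rng
        if cfg.poisson_noise:
            g = cfg.noise_gain
            frame = rng.poisson(np.maximum(frame, 0) / g) * g
        else:
            frame = frame + rng.standard_normal(frame.shape) * np.sqrt(
                cfg.noise_gain * np.maximum(frame, 0)
            )
    return np.clip(np.round(frame), 0, cfg.max_count).astype(
        np.uint8 if cfg.bit_depth == 8 else np.uint16
    )


# ---------------------------------------------------------------------------
# full acquisitions


def generate_acquisition(
    cfg: PhantomConfig,
    layout: AcquisitionLayout,
    duration_s: float,
    optics: OpticalConfig | None = None,
    phase_jitter: float = 0.2,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a full interleaved camera-order acquisition.

    Each well gets its own texture, bubble walk and beat-phase offset
    (up to ``phase_jitter`` of a beat period, emulating natural well-to-well
    variation) from a deterministic substream of ``cfg.seed``.  Frames are
    rendered at each well's scheduled camera-frame times and interleaved
    into one :class:`FrameSequence`; the returned :class:`GroundTruth`
    records per-well beat times, per-frame twitch amplitudes and jolt
    frames.
    """
    n_frames = int(round(duration_s * layout.camera_fps))
    if n_frames < 1:
        raise ValueError("duration too short for a single frame")
    schedule = build_schedule(layout, n_frames)
    optics = optics or multiwell_preset()

    root = np.random.SeedSequence(cfg.seed)
    well_seeds = root.spawn(layout.n_wells + 1)
    noise_rng = np.random.default_rng(well_seeds[-1])

    well_cfg: dict[str, PhantomConfig] = {}
    textures: dict[str, np.ndarray] = {}
    bubbles: dict[str, np.ndarray] = {}
    bubble_rngs: dict[str, np.random.Generator] = {}
    for i, well in enumerate(layout.wells):
        sub = np.random.default_rng(well_seeds[i])
        offset = float(sub.uniform(-phase_jitter, phase_jitter)) * cfg.beat_period_s
        wcfg = replace(cfg, first_beat_s=cfg.first_beat_time_s + offset)
        well_cfg[well] = wcfg
        textures[well] = make_texture(wcfg, sub)
        h, w = cfg.image_px
        bubbles[well] = sub.uniform([0, 0], [h, w], size=(cfg.bubble_count, 2))
        bubble_rngs[well] = sub

    frames = np.empty((n_frames, *cfg.image_px), dtype=np.uint8 if cfg.bit_depth == 8 else np.uint16)
    twitch_amp: dict[str, list[float]] = {w: [] for w in layout.wells}
    jolts = sorted(set(int(j) for j in cfg.jolt_frames if 0 <= j < n_frames))
    jolt_set = set(jolts)

    last_seen: dict[str, int] = {}
    for e in schedule:
        wcfg = well_cfg[e.well_id]
        if cfg.bubble_count and e.well_id in last_seen:
            steps = e.frame_index - last_seen[e.well_id]
            walk = bubble_rngs[e.well_id].normal(
                0.0, cfg.bubble_drift_px * np.sqrt(steps), size=bubbles[e.well_id].shape
            )
            bubbles[e.well_id] = np.clip(
                bubbles[e.well_id] + walk, 0, np.array(cfg.image_px) - 1
            )
        last_seen[e.well_id] = e.frame_index
        frames[e.frame_index] = render_frame(
            wcfg,
            textures[e.well_id],
            e.time_s,
            colour=e.colour,
            optics=optics,
            rng=noise_rng,
            bubble_centres=bubbles[e.well_id] if cfg.bubble_count else None,
            jolt=e.frame_index in jolt_set,
        )
        twitch_amp[e.well_id].append(float(twitch_waveform(wcfg, e.time_s)))

    beat_times = {
        w: list(_beat_onsets(well_cfg[w], duration_s)) for w in layout.wells
    }
    truth = GroundTruth(
        beat_times_s=beat_times,
        beat_rate_hz=cfg.beat_rate_hz,
        jolt_frames=jolts,
        twitch_amplitude=twitch_amp,
        config={
            **{k: v for k, v in asdict(cfg).items() if not isinstance(v, np.ndarray)},
            "layout_wells": list(layout.wells),
            "layout_colours": list(layout.colours),
            "camera_fps": layout.camera_fps,
            "duration_s": duration_s,
            "effective_fps": effective_rate(layout),
        },
    )
    seq = FrameSequence(frames=frames, camera_fps=layout.camera_fps, bit_depth=cfg.bit_depth)
    return seq, truth


# ---------------------------------------------------------------------------
# config I/O


def load_phantom_config(path) -> PhantomConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "image_px" in data:
        data["image_px"] = tuple(data["image_px"])
    if "texture_band_px" in data:
        data["texture_band_px"] = tuple(data["texture_band_px"])
    if "jolt_frames" in data:
        data["jolt_frames"] = tuple(data["jolt_frames"])
    if "jolt_shift_px" in data:
        data["jolt_shift_px"] = tuple(data["jolt_shift_px"])
    if data.get("foci") is not None:
        data["foci"] = tuple(
            ((float(f[0][0]), float(f[0][1])), float(f[1]), float(f[2])) for f in data["foci"]
        )
    return PhantomConfig(**data)


def save_phantom_config(cfg: PhantomConfig, path) -> None:
    import yaml

    data = asdict(cfg)
    data["image_px"] = list(cfg.image_px)
    data["texture_band_px"] = list(cfg.texture_band_px)
    data["jolt_frames"] = list(cfg.jolt_frames)
    data["jolt_shift_px"] = list(cfg.jolt_shift_px)
    data["foci"] = [[list(c), r, w] for (c, r, w) in cfg.foci]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
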