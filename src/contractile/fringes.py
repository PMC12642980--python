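"""False-colour overlays of pixel-variance maps at two beat timepoints.

The per-pixel std map underlying the PV speed trace retains spatial
structure: during a contraction it shows band-like "fringes" orthogonal to
the local displacement direction, with wider spacing where displacement is
larger.  Overlaying the maps from the peak-contraction-velocity and
peak-relaxation-velocity timepoints (red and blue channels) visualises the
displacement pattern across the monolayer, e.g. how well-connected the
syncytium is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ContractionTrace, WellChannelStack
from .metrics import pv_frame

__all__ = [
    "FringeOverlay",
    "pick_fringe_timepoints",
    "fringe_overlay",
    "fringe_spacing_map",
    "save_overlay_png",
]


@dataclass
class FringeOverlay:
    """Two-timepoint false-colour overlay.

    ``rgb_image`` is (H, W, 3) float in [0, 1]: red = std map at the first
    timepoint, blue = std map at the second, green all zero.  Each channel
    is min-max normalized independently.
    """

    rgb_image: np.ndarray
    t_contraction: int
    t_relaxation: int
    frame_delay_N: int


def pick_fringe_timepoints(
    trace: ContractionTrace, beats: pd.DataFrame, beat_index: int = 0
) -> tuple[int, int]:
    """Frame indices of a beat's contraction and relaxation velocity peaks."""
    if not (0 <= beat_index < len(beats)):
        raise IndexError(f"beat_index {beat_index} out of range for {len(beats)} beats")
    row = beats.iloc[beat_index]
    t_rel = row["relaxation_peak_time_s"]
    if not np.isfinite(t_rel):
        raise ValueError("beat has no relaxation peak (single-peak beat)")
    times = trace.frame_times_s
    t1 = int(np.argmin(np.abs(times - row["contraction_peak_time_s"])))
    t2 = int(np.argmin(np.abs(times - t_rel)))
    return t1, t2


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo == 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def fringe_overlay(stack: WellChannelStack, t1: int, t2: int, N: int) -> FringeOverlay:
    """Overlay the PV std maps at frames t1 (red) and t2 (blue)."""
    if t1 < N or t2 < N:
        raise ValueError(f"both timepoints must be >= N={N}")
    red = _minmax(pv_frame(stack, t1, N))
    blue = _minmax(pv_frame(stack, t2, N))
    rgb = np.zeros((*red.shape, 3))
    rgb[..., 0] = red
    rgb[..., 2] = blue
    return FringeOverlay(rgb_image=rgb, t_contraction=t1, t_relaxation=t2, frame_delay_N=N)


def fringe_spacing_map(
    pv_map: np.ndarray,
    window_px: int = 32,
    min_contrast: float = 8.0,
    stride: int | None = None,
) -> np.ndarray:
    """Local dominant fringe spacing (px) via a windowed spectral peak.

    The map is tiled with ``window_px`` Hann-windowed patches (stride
    ``window_px // 2`` by default); in each patch the radially binned power
    spectrum's peak gives the dominant spatial period, refined by parabolic
    interpolation.  Patches whose spectral peak is weaker than
    ``min_contrast`` times the median non-DC power are left NaN (no
    measurable fringes).  Returns a full-resolution map (NaN where
    undefined).
    """
    pv_map = np.asarray(pv_map, dtype=float)
    h, w = pv_map.shape
    if window_px > min(h, w):
        raise ValueError("window larger than image")
    stride = stride or max(1, window_px // 2)
    hann = np.hanning(window_px)
    win2d = np.outer(hann, hann)
    out = np.full((h, w), np.nan)
    counts = np.zeros((h, w))
    acc = np.zeros((h, w))

    fy = np.fft.fftfreq(window_px)[:, None]
    fx = np.fft.fftfreq(window_px)[None, :]
    freq = np.hypot(fy, fx)
    n_bins = window_px // 2
    bin_idx = np.minimum((freq * window_px).round().astype(int), n_bins)

    for r0 in range(0, h - window_px + 1, stride):
        for c0 in range(0, w - window_px + 1, stride):
            patch = pv_map[r0 : r0 + window_px, c0 : c0 + window_px]
            patch = (patch - patch.mean()) * win2d
            power = np.abs(np.fft.fft2(patch)) ** 2
            radial = np.bincount(bin_idx.ravel(), power.ravel(), minlength=n_bins + 1)
            radial_n = np.bincount(bin_idx.ravel(), minlength=n_bins + 1)
            radial = radial / np.maximum(radial_n, 1)
            radial[0] = 0.0  # DC removed by mean subtraction anyway
            if radial[1:].max() <= 0:
                continue
            k = int(np.argmax(radial[1:n_bins])) + 1
            med = np.median(radial[1:n_bins])
            if med <= 0 or radial[k] < min_contrast * med:
                continue
            # parabolic refinement of the peak bin
            if 1 <= k < n_bins - 1:
                y0, y1, y2 = radial[k - 1], radial[k], radial[k + 1]
                denom = y0 - 2 * y1 + y2
                delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            else:
                delta = 0.0
            period = window_px / (k + float(np.clip(delta, -0.5, 0.5)))
            acc[r0 : r0 + window_px, c0 : c0 + window_px] += period
            counts[r0 : r0 + window_px, c0 : c0 + window_px] += 1
    defined = counts > 0
    out[defined] = acc[defined] / counts[defined]
    return out


def save_overlay_png(overlay: FringeOverlay, path) -> None:
    """Write the overlay as an 8-bit RGB PNG."""
    import imageio.v3 as iio
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(overlay.rgb_image * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(path, img8)
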