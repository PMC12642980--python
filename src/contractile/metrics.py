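"""Motion metrics for contracting-monolayer image stacks.

Two families of scalar metrics are computed from an image stack, each in a
"speed" (running) and an "absolute contraction" (fixed-reference) form:

* **MM** (absolute difference): pixel-wise ``|I(t) - I(t')|`` summed over the
  ROI.  With ``t' = t - N`` (the frame delay N) this is the contraction
  *speed*; against a fixed quiescent reference frame it is the absolute
  contraction.  Optionally the stack is brightness-compensated first, which
  nulls pure global-gain drift.
* **PV** (pixel variance): instead of only the two endpoint frames, the
  per-pixel *population standard deviation* over all N+1 frames of the
  trailing window ``[t-N, t]`` is computed and summed over the ROI.  Using
  every frame in the window makes the trace noise shrink as N grows, unlike
  the two-point absolute difference.  The fixed-reference form differences
  per-pixel standard deviations estimated in small windows centred on the
  current and reference timepoints.

All arithmetic is double precision after integer promotion.  Samples that
have no comparison window (the first N frames of a running metric) are
emitted as NaN, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ContractionTrace, RoiSpec, WellChannelStack

__all__ = [
    "MetricParams",
    "mm_speed",
    "mm_contraction",
    "pv_speed",
    "pv_contraction",
    "pv_frame",
    "brightness_compensate",
    "moving_average",
    "normalize_trace",
]


@dataclass(frozen=True)
class MetricParams:
    """Parameters shared by the PV/MM metric computations.

    Attributes
    ----------
    frame_delay_N
        Frames between the compared timepoints (MM) or spanned by the
        variance window (PV).  2–5 frames suit 100 Hz data; scale with the
        contraction duration at other rates (~20% of it accentuates shape
        differences).
    reference_frame
        Index of the quiescent reference frame for the absolute-contraction
        metrics, or ``"auto"`` to pick the centre of the longest quiescent
        stretch of the corresponding speed trace.
    adjacent_k
        Frames in the small centred window used to estimate per-pixel
        standard deviation at a single timepoint (PV absolute contraction).
    brightness_compensation
        Rescale every frame to the reference frame's mean brightness before
        differencing (MM metrics only; PV scaling is nonlinear so PV traces
        are left uncompensated).  ``None`` uses the per-metric default:
        off for the running speed metric, on for the amplitude
        (absolute-contraction) metric, which is the one whose baseline a
        slow brightness drift corrupts.
    roi
        Region of interest to sum over; ``None`` = full frame.
    sum_variances
        Sum per-pixel variances instead of standard deviations (PV).
    pv_diff_of_sums
        Absolute-contraction variant: difference the ROI-summed std images
        rather than summing per-pixel absolute differences.
    """

    frame_delay_N: int = 2
    reference_frame: int | str = "auto"
    adjacent_k: int = 5
    brightness_compensation: bool | None = None
    roi: RoiSpec | None = None
    sum_variances: bool = False
    pv_diff_of_sums: bool = False

    def __post_init__(self) -> None:
        if self.frame_delay_N < 1:
            raise ValueError("frame_delay_N must be >= 1")
        if self.adjacent_k < 2:
            raise ValueError("adjacent_k must be >= 2")
        if isinstance(self.reference_frame, str) and self.reference_frame != "auto":
            raise ValueError("reference_frame must be an index or 'auto'")


def _roi_view(frames: np.ndarray, roi: RoiSpec | None) -> np.ndarray:
    if roi is None:
        return frames
    roi.check_within(frames.shape[1:])
    rs, cs = roi.slices()
    return frames[:, rs, cs]


def _trace(stack: WellChannelStack, values, name: str, N: int, valid_from: int) -> ContractionTrace:
    return ContractionTrace(
        values=values,
        frame_times_s=stack.frame_times_s,
        metric_name=name,
        frame_delay_N=N,
        valid_from=valid_from,
    )


def _resolve_reference(stack: WellChannelStack, p: MetricParams, speed_fn) -> int:
    if p.reference_frame == "auto":
        from .beats import select_reference

        speed = speed_fn(stack, replace(p, reference_frame=0))
        return select_reference(speed)
    ref = int(p.reference_frame)
    if not (0 <= ref < stack.n_frames):
        raise IndexError(f"reference frame {ref} out of range for {stack.n_frames} frames")
    return ref


# ---------------------------------------------------------------------------
# MM (absolute difference)


def mm_speed(stack: WellChannelStack, p: MetricParams = MetricParams()) -> ContractionTrace:
    """Running absolute-difference contraction speed.

    ``trace[t] = sum_ROI |I(t) - I(t-N)|`` for ``t >= N``; earlier samples
    are NaN.
    """
    N = p.frame_delay_N
    T = stack.n_frames
    if N >= T:
        raise ValueError(f"frame delay N={N} must be smaller than stack length {T}")
    frames = stack.frames
    if p.brightness_compensation is True:  # default off for the speed metric
        frames = _compensate_frames(frames, 0)
    f = _roi_view(frames, p.roi).astype(np.float64, copy=False)
    vals = np.full(T, np.nan)
    vals[N:] = np.abs(f[N:] - f[:-N]).sum(axis=(1, 2))
    return _trace(stack, vals, "mm_speed", N, N)


def mm_contraction(stack: WellChannelStack, p: MetricParams = MetricParams()) -> ContractionTrace:
    """Absolute contraction: absolute difference against a fixed reference.

    ``trace[t] = sum_ROI |I'(t) - I'(ref)|`` where ``I'`` is the
    brightness-compensated stack when compensation is enabled;
    ``trace[ref] = 0`` by construction.
    """
    ref = _resolve_reference(stack, p, mm_speed)
    frames = stack.frames
    if p.brightness_compensation is not False:  # default on for amplitude data
        frames = _compensate_frames(frames, ref)
    f = _roi_view(frames, p.roi).astype(np.float64, copy=False)
    vals = np.abs(f - f[ref]).sum(axis=(1, 2))
    return _trace(stack, vals, "mm_contraction", p.frame_delay_N, 0)


def _compensate_frames(frames: np.ndarray, reference_frame: int) -> np.ndarray:
    f = frames.astype(np.float64, copy=False)
    means = f.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("cannot brightness-compensate a frame with zero mean")
    return f * (means[reference_frame] / means)[:, None, None]


def brightness_compensate(stack: WellChannelStack, reference_frame: int = 0) -> WellChannelStack:
    """Rescale every frame so its mean equals the reference frame's mean.

    Returns a float-valued copy of the stack (stored back as the same
    integer type after rounding would lose the exact gain removal, so the
    frames attribute of the returned stack is floating point and intended
    for metric computation only).
    """
    comp = _compensate_frames(stack.frames, reference_frame)
    out = replace(stack)
    out.frames = comp  # assigned post-validation: intermediate float frames
    return out


# ---------------------------------------------------------------------------
# PV (pixel variance)


def _windowed_std(frames: np.ndarray, lo: int, hi: int, sum_variances: bool) -> np.ndarray:
    """Per-pixel population std (or variance) over frames [lo, hi]."""
    window = frames[lo : hi + 1].astype(np.float64, copy=False)
    var = window.var(axis=0)  # population (ddof=0)
    return var if sum_variances else np.sqrt(var)


def pv_frame(
    stack: WellChannelStack, t: int, N: int, sum_variances: bool = False
) -> np.ndarray:
    """Per-pixel std map over the trailing window [t-N, t] (N+1 frames).

    This is the spatial image underlying :func:`pv_speed` at time ``t``;
    summing it over the ROI gives the trace value.
    """
    if t < N:
        raise ValueError(f"t={t} precedes the first full window (N={N})")
    if t >= stack.n_frames:
        raise IndexError(f"t={t} out of range")
    return _windowed_std(stack.frames, t - N, t, sum_variances)


def pv_speed(stack: WellChannelStack, p: MetricParams = MetricParams()) -> ContractionTrace:
    """Pixel-variance contraction speed.

    For each ``t >= N``, the population standard deviation of each ROI
    pixel's values over ``tau = t-N .. t`` is summed over the ROI.  With
    N = 1 this equals exactly half the MM speed (two-point population std).
    """
    N = p.frame_delay_N
    T = stack.n_frames
    if N >= T:
        raise ValueError(f"frame delay N={N} must be smaller than stack length {T}")
    f = _roi_view(stack.frames, p.roi).astype(np.float64, copy=False)
    # sliding-window mean/mean-square via cumulative sums over time
    c1 = np.cumsum(f, axis=0)
    c2 = np.cumsum(f * f, axis=0)
    w = N + 1
    s1 = c1[N:].copy()
    s1[1:] -= c1[:-w]
    s2 = c2[N:].copy()
    s2[1:] -= c2[:-w]
    mean = s1 / w
    var = np.maximum(s2 / w - mean * mean, 0.0)
    per_pixel = var if p.sum_variances else np.sqrt(var)
    vals = np.full(T, np.nan)
    vals[N:] = per_pixel.sum(axis=(1, 2))
    return _trace(stack, vals, "pv_speed", N, N)


def _centred_window(t: int, k: int, T: int) -> tuple[int, int]:
    """Symmetrically truncated centred window of nominal length k at t."""
    left = (k - 1) // 2
    right = k // 2
    if t - left < 0 or t + right > T - 1:
        # keep the window centred: shrink both sides to what fits
        m = min(t, T - 1 - t)
        left = min(left, m)
        right = min(right, m)
    return t - left, t + right


def pv_contraction(stack: WellChannelStack, p: MetricParams = MetricParams()) -> ContractionTrace:
    """Absolute contraction from pixel variance.

    Per-pixel standard deviations are estimated in ``adjacent_k``-frame
    windows centred on the current timepoint and on the reference; the
    default output sums per-pixel absolute differences of the two std maps
    (preserving a spatial map), with ``pv_diff_of_sums`` offering the
    difference-of-ROI-sums variant.
    """
    k = p.adjacent_k
    T = stack.n_frames
    if k > T:
        raise ValueError(f"adjacent_k={k} exceeds stack length {T}")
    ref = _resolve_reference(stack, p, pv_speed)
    f = _roi_view(stack.frames, p.roi)
    lo_r, hi_r = _centred_window(ref, k, T)
    s_ref = _windowed_std(f, lo_r, hi_r, p.sum_variances)
    vals = np.empty(T)
    for t in range(T):
        lo, hi = _centred_window(t, k, T)
        s_t = _windowed_std(f, lo, hi, p.sum_variances)
        if p.pv_diff_of_sums:
            vals[t] = abs(s_t.sum() - s_ref.sum())
        else:
            vals[t] = np.abs(s_t - s_ref).sum()
    vals[ref] = 0.0
    return _trace(stack, vals, "pv_contraction", p.frame_delay_N, 0)


# ---------------------------------------------------------------------------
# trace post-processing


def moving_average(trace: ContractionTrace, window: int) -> ContractionTrace:
    """Centred box-car mean of the defined samples; length preserved.

    Edges use truncated windows.  For even ``window`` the box is centred
    between samples; the earlier-shifted alignment is used, i.e. the window
    at index i covers ``[i - window//2, i + window//2 - 1]``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return replace(trace)
    v = trace.defined_values
    left = window // 2
    right = window - 1 - left  # even windows: one fewer on the right
    kernel = np.ones(window)
    padded_sum = np.convolve(v, kernel, mode="full")
    counts = np.convolve(np.ones_like(v), kernel, mode="full")
    # window [i - left, i + right] is full-convolution index i + right
    idx = np.arange(len(v)) + right
    out = padded_sum[idx] / counts[idx]
    vals = np.full(len(trace), np.nan)
    vals[trace.valid_from :] = out
    return replace(trace, values=vals)


def normalize_trace(trace: ContractionTrace) -> ContractionTrace:
    """Divide by the maximum defined value, so the peak is exactly 1."""
    peak = np.nanmax(trace.values)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("cannot normalize a trace with no positive values")
    return replace(trace, values=trace.values / peak)
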