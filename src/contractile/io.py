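"""Image-stack and trace I/O plus the shared raw-data model.

A recording is a stack of monochrome camera frames (time x rows x cols) with
timing metadata.  Raw camera-order recordings are :class:`FrameSequence`
objects; after demultiplexing, each well/colour combination becomes a
:class:`WellChannelStack`.  Scalar motion metrics computed from a stack are
:class:`ContractionTrace` objects.

Canonical on-disk formats are multi-page grayscale TIFF (8- or 16-bit) for
stacks and UTF-8 CSV with a small ``# key=value`` metadata header for traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameSequence",
    "WellChannelStack",
    "ContractionTrace",
    "RoiSpec",
    "read_stack",
    "write_stack",
    "crop_roi",
    "read_trace",
    "write_trace",
]

_TRACE_MAGIC = "# contractile-trace v1"

METRIC_NAMES = ("pv_speed", "mm_speed", "pv_contraction", "mm_contraction")


def _check_frames(frames: np.ndarray, bit_depth: int, min_frames: int = 2) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"frames must be 3-D (time, rows, cols); got shape {frames.shape}")
    if frames.shape[0] < min_frames:
        raise ValueError(f"a stack needs at least {min_frames} frame(s)")
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if np.issubdtype(frames.dtype, np.floating):
        raise ValueError("pixel values must be unsigned integers")
    if frames.min() < 0:
        raise ValueError("pixel values must be non-negative")
    if frames.max() > 2**bit_depth - 1:
        raise ValueError(
            f"pixel values exceed the {bit_depth}-bit range (max {frames.max()})"
        )
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return frames.astype(dtype, copy=False)


@dataclass
class FrameSequence:
    """Raw camera-order image stack.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative integers within the bit range.
    camera_fps
        Camera frame rate in frames/second.  Frame ``i`` is taken at
        ``i / camera_fps`` seconds (first frame at t = 0).
    bit_depth
        Bits per pixel, 8 or 16.
    pixel_size_um
        Physical camera pixel pitch in micrometres (optional metadata).
    """

    frames: np.ndarray
    camera_fps: float
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.camera_fps <= 0:
            raise ValueError("camera_fps must be positive")
        self.frames = _check_frames(self.frames, self.bit_depth)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.camera_fps

    def as_single_well(self, well_id: str = "0", colour: str = "white") -> "WellChannelStack":
        """View this sequence as one well imaged in one colour."""
        return WellChannelStack(
            well_id=well_id,
            colour=colour,
            frames=self.frames,
            effective_fps=self.camera_fps,
            frame_times_s=self.frame_times_s,
            bit_depth=self.bit_depth,
        )


@dataclass
class WellChannelStack:
    """Single-well, single-colour image stack after demultiplexing."""

    well_id: str
    colour: str
    frames: np.ndarray
    effective_fps: float
    frame_times_s: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.effective_fps <= 0:
            raise ValueError("effective_fps must be positive")
        # a demuxed stack from a trailing partial cycle may hold one frame
        self.frames = _check_frames(self.frames, self.bit_depth, min_frames=1)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.frames.shape[0],):
            raise ValueError("frame_times_s length must match frame count")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest, 0-based, half-open.

    Covers rows ``[row0, row1)`` and columns ``[col0, col1)``.
    """

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"ROI must be non-empty and non-negative: {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    @property
    def area(self) -> int:
        h, w = self.shape
        return h * w

    def check_within(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        if self.row1 > h or self.col1 > w:
            raise ValueError(f"ROI {self} extends past frame bounds {frame_shape}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    @classmethod
    def full_frame(cls, frame_shape: tuple[int, int]) -> "RoiSpec":
        return cls(0, frame_shape[0], 0, frame_shape[1])


@dataclass
class ContractionTrace:
    """A 1-D motion-metric time series with its frame-delay provenance.

    ``values[t]`` is undefined (NaN) for ``t < valid_from``; for the running
    ("speed") metrics ``valid_from`` equals the frame delay N, because the
    first N frames have no comparison frame N frames earlier.
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    metric_name: str
    frame_delay_N: int
    valid_from: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.values.ndim != 1 or self.values.shape != self.frame_times_s.shape:
            raise ValueError("values and frame_times_s must be matching 1-D arrays")
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric_name {self.metric_name!r}")
        if not (0 <= self.valid_from < len(self.values)):
            raise ValueError("valid_from outside trace")
        if np.any(np.isnan(self.values[self.valid_from :])):
            raise ValueError("values must be defined at indices >= valid_from")
        if self.valid_from and not np.all(np.isnan(self.values[: self.valid_from])):
            raise ValueError("values before valid_from must be NaN")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.valid_from :]

    @property
    def defined_times(self) -> np.ndarray:
        return self.frame_times_s[self.valid_from :]

    @property
    def sampling_fps(self) -> float:
        dt = np.diff(self.frame_times_s)
        return 1.0 / float(np.median(dt))

    def with_values(self, values: np.ndarray, metric_name: str | None = None) -> "ContractionTrace":
        return replace(
            self, values=values, metric_name=metric_name or self.metric_name
        )


# ---------------------------------------------------------------------------
# stack I/O


def read_stack(path, camera_fps: float, bit_depth: int = 16) -> FrameSequence:
    """Read a multi-page TIFF or a directory of single-frame images.

    Directory frames are taken in lexicographic filename order.  Colour
    (multi-channel) pages are rejected: the data model is monochrome.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ValueError(f"no image files in {path}")
        pages = [np.asarray(iio.imread(f)) for f in files]
    else:
        with tifffile.TiffFile(path) as tf:
            if not len(tf.pages):
                raise ValueError(f"empty TIFF: {path}")
            pages = [page.asarray() for page in tf.pages]
    shapes = {p.shape for p in pages}
    for p in pages:
        if p.ndim != 2:
            raise ValueError("inconsistent dimensions: colour or non-2D page found")
    if len(shapes) != 1:
        raise ValueError(f"inconsistent dimensions across frames: {sorted(shapes)}")
    frames = np.stack(pages)
    return FrameSequence(frames=frames, camera_fps=camera_fps, bit_depth=bit_depth)


def write_stack(seq: FrameSequence, path) -> None:
    """Write a FrameSequence as a multi-page grayscale TIFF (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")


def crop_roi(stack: WellChannelStack, roi: RoiSpec) -> WellChannelStack:
    """Restrict a stack to an ROI; timing metadata is unchanged."""
    roi.check_within(stack.frame_shape)
    rs, cs = roi.slices()
    return replace(stack, frames=stack.frames[:, rs, cs])


# ---------------------------------------------------------------------------
# trace I/O


def write_trace(trace: ContractionTrace, path) -> None:
    """Write a trace as CSV with a metadata header, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        fh.write(f"# metric_name={trace.metric_name}\n")
        fh.write(f"# frame_delay_N={trace.frame_delay_N}\n")
        fh.write(f"# valid_from={trace.valid_from}\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.frame_times_s, trace.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_trace(path) -> ContractionTrace:
    """Read a trace CSV written by :func:`write_trace` (lossless round trip)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != _TRACE_MAGIC:
            raise ValueError(f"{path}: not a contractile trace CSV (missing magic header)")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, float_precision="round_trip")
    for key in ("metric_name", "frame_delay_N", "valid_from"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata header {key!r}")
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected columns time_s,value; got {list(df.columns)}")
    return ContractionTrace(
        values=df["value"].to_numpy(float),
        frame_times_s=df["time_s"].to_numpy(float),
        metric_name=meta["metric_name"],
        frame_delay_N=int(meta["frame_delay_N"]),
        valid_from=int(meta["valid_from"]),
    )
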