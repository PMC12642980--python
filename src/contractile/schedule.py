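"""Acquisition scheduling and demultiplexing for interleaved multi-well video.

The instrument images wells one at a time with switchable coloured LEDs:
each well is captured once per colour (colour is the fast axis), then the
next well, cycling through all wells before the sequence repeats.  A single
camera therefore records an interleaved frame stream; the per-well,
per-colour sampling rate is ``camera_fps / (wells x colours x
frames_per_slot)`` — e.g. 100 fps over 9 wells x 3 colours gives 3.7 fps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io import FrameSequence, WellChannelStack

__all__ = [
    "AcquisitionLayout",
    "ScheduleEntry",
    "build_schedule",
    "effective_rate",
    "demux",
    "interleave",
    "plan_two_stage",
    "load_layout",
    "save_layout",
]


@dataclass(frozen=True)
class AcquisitionLayout:
    """Well x colour interleave description.

    ``frames_per_slot`` consecutive camera frames are devoted to each
    (well, colour) slot; the default 1 matches one frame per LED flash.
    """

    wells: tuple[str, ...]
    colours: tuple[str, ...] = ("R", "G", "B")
    camera_fps: float = 100.0
    frames_per_slot: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(str(w) for w in self.wells))
        object.__setattr__(self, "colours", tuple(str(c) for c in self.colours))
        if not self.wells or not self.colours:
            raise ValueError("need at least one well and one colour")
        if len(set(self.wells)) != len(self.wells):
            raise ValueError("well labels must be unique")
        if self.camera_fps <= 0 or self.frames_per_slot < 1:
            raise ValueError("camera_fps must be > 0 and frames_per_slot >= 1")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def n_colours(self) -> int:
        return len(self.colours)

    @property
    def cycle_frames(self) -> int:
        return self.n_wells * self.n_colours * self.frames_per_slot


@dataclass(frozen=True)
class ScheduleEntry:
    frame_index: int
    well_id: str
    colour: str
    time_s: float


def build_schedule(layout: AcquisitionLayout, n_camera_frames: int) -> list[ScheduleEntry]:
    """Assign each camera frame to its (well, colour) slot.

    Colour is the fast axis: frame k (with one frame per slot) maps to
    well ``wells[(k // C) % W]`` and colour ``colours[k % C]``; the schedule
    is periodic with period W x C x frames_per_slot.
    """
    if n_camera_frames < 1:
        raise ValueError("n_camera_frames must be >= 1")
    entries = []
    C = layout.n_colours
    W = layout.n_wells
    for k in range(n_camera_frames):
        slot = k // layout.frames_per_slot
        entries.append(
            ScheduleEntry(
                frame_index=k,
                well_id=layout.wells[(slot // C) % W],
                colour=layout.colours[slot % C],
                time_s=k / layout.camera_fps,
            )
        )
    return entries


def effective_rate(layout: AcquisitionLayout) -> float:
    """Per-well, per-colour sampling rate in fps."""
    return layout.camera_fps / layout.cycle_frames


def demux(seq: FrameSequence, layout: AcquisitionLayout) -> dict[tuple[str, str], WellChannelStack]:
    """Split a camera-order sequence into per-(well, colour) stacks.

    Every camera frame lands in exactly one stack; trailing incomplete
    cycles are kept, so stack lengths may differ by one.
    """
    schedule = build_schedule(layout, seq.n_frames)
    groups: dict[tuple[str, str], list[int]] = {}
    for e in schedule:
        groups.setdefault((e.well_id, e.colour), []).append(e.frame_index)
    eff = effective_rate(layout)
    out: dict[tuple[str, str], WellChannelStack] = {}
    for (well, colour), idx in groups.items():
        idx_arr = np.asarray(idx)
        out[(well, colour)] = WellChannelStack(
            well_id=well,
            colour=colour,
            frames=seq.frames[idx_arr],
            effective_fps=eff,
            frame_times_s=idx_arr / seq.camera_fps,
            bit_depth=seq.bit_depth,
        )
    return out


def interleave(
    stacks: Mapping[tuple[str, str], WellChannelStack],
    layout: AcquisitionLayout,
) -> FrameSequence:
    """Re-interleave demuxed stacks back into camera order (demux inverse)."""
    n_total = sum(s.n_frames for s in stacks.values())
    schedule = build_schedule(layout, n_total)
    cursors: dict[tuple[str, str], int] = {k: 0 for k in stacks}
    first = next(iter(stacks.values()))
    frames = np.empty((n_total, *first.frame_shape), dtype=first.frames.dtype)
    for e in schedule:
        key = (e.well_id, e.colour)
        i = cursors[key]
        frames[e.frame_index] = stacks[key].frames[i]
        cursors[key] = i + 1
    return FrameSequence(frames=frames, camera_fps=layout.camera_fps, bit_depth=first.bit_depth)


def plan_two_stage(n_wells: int, seconds_per_well: float) -> dict[str, float]:
    """Stage-2 plan: dwell sequentially on each well at full camera rate.

    Stage 1 (three-colour interleave) picks the best-focused colour per
    well; stage 2 then revisits wells one at a time in that single colour,
    giving full-rate sampling at the cost of ``n_wells x seconds_per_well``
    total duration.
    """
    if n_wells < 1 or seconds_per_well <= 0:
        raise ValueError("need n_wells >= 1 and seconds_per_well > 0")
    return {
        "n_wells": n_wells,
        "per_well_dwell_s": float(seconds_per_well),
        "total_duration_s": float(n_wells * seconds_per_well),
    }


# ---------------------------------------------------------------------------
# YAML layout config


def load_layout(path) -> AcquisitionLayout:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return AcquisitionLayout(
        wells=tuple(str(w) for w in data["wells"]),
        colours=tuple(str(c) for c in data.get("colours", ("R", "G", "B"))),
        camera_fps=float(data.get("camera_fps", 100.0)),
        frames_per_slot=int(data.get("frames_per_slot", 1)),
    )


def save_layout(layout: AcquisitionLayout, path) -> None:
    data = {
        "wells": list(layout.wells),
        "colours": list(layout.colours),
        "camera_fps": layout.camera_fps,
        "frames_per_slot": layout.frames_per_slot,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
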