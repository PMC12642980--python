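"""Beat-level analysis of contraction-speed traces.

A contraction-speed trace shows two peaks per beat — one at peak contraction
velocity, one at peak relaxation velocity — separated by a dip at maximum
contraction.  This module detects those peaks, pairs them into beats,
measures rates and durations, picks quiescent reference frames for the
absolute-contraction metrics, recommends frame delays, and rejects
mechanical "jolts" (disturbances that spike every well's trace at the same
instant).

Detection thresholds are expressed in robust MAD units so they are
invariant to trace scaling/normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import ContractionTrace

__all__ = [
    "BEAT_COLUMNS",
    "JoltReport",
    "detect_beats",
    "beat_rate_hz",
    "recommend_frame_delay",
    "select_reference",
    "detect_jolts",
]

BEAT_COLUMNS = (
    "contraction_peak_time_s",
    "relaxation_peak_time_s",
    "max_contraction_time_s",
    "peak_amplitude",
    "duration_s",
)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def detect_beats(
    trace: ContractionTrace,
    min_prominence_mads: float = 5.0,
    pair_window_s: float | None = None,
    duration_threshold: float = 0.1,
) -> pd.DataFrame:
    """Detect beats in a contraction-speed trace.

    Local maxima with prominence >= ``min_prominence_mads`` x MAD(trace) are
    peaks.  Consecutive peaks closer than ``pair_window_s`` (default: 60% of
    the median inter-peak interval) are paired into one beat — contraction
    peak then relaxation peak — with the interior minimum recorded as the
    moment of maximum contraction.  An unpaired peak forms a single-peak
    beat (NaN relaxation/dip fields), as happens when low sampling rates
    merge the two velocity peaks.

    Returns a DataFrame with columns :data:`BEAT_COLUMNS`, one row per beat.
    ``duration_s`` spans the crossings of ``duration_threshold`` x peak
    amplitude around the beat.
    """
    v = trace.defined_values
    t = trace.defined_times
    if len(v) < 3:
        raise ValueError("trace needs at least 3 defined samples")
    mad = _mad(v)
    empty = pd.DataFrame(columns=list(BEAT_COLUMNS))
    if mad == 0 and np.ptp(v) == 0:
        return empty
    prominence = min_prominence_mads * mad if mad > 0 else min_prominence_mads * np.ptp(v) / 10
    peaks, _ = find_peaks(v, prominence=prominence)
    if len(peaks) == 0:
        return empty
    if pair_window_s is None:
        if len(peaks) >= 2:
            pair_window_s = 0.6 * float(np.median(np.diff(t[peaks])))
        else:
            pair_window_s = 0.0

    rows = []
    i = 0
    while i < len(peaks):
        p1 = peaks[i]
        if i + 1 < len(peaks) and (t[peaks[i + 1]] - t[p1]) <= pair_window_s:
            p2 = peaks[i + 1]
            dip = p1 + int(np.argmin(v[p1 : p2 + 1]))
            rows.append((p1, p2, dip))
            i += 2
        else:
            rows.append((p1, None, None))
            i += 1

    records = []
    for p1, p2, dip in rows:
        amp = float(v[p1])
        thr = duration_threshold * amp
        onset = p1
        while onset > 0 and v[onset - 1] >= thr:
            onset -= 1
        off_peak = p2 if p2 is not None else p1
        offset = off_peak
        while offset < len(v) - 1 and v[offset + 1] >= duration_threshold * float(v[off_peak]):
            offset += 1
        records.append(
            {
                "contraction_peak_time_s": t[p1],
                "relaxation_peak_time_s": t[p2] if p2 is not None else np.nan,
                "max_contraction_time_s": t[dip] if dip is not None else np.nan,
                "peak_amplitude": amp,
                "duration_s": t[offset] - t[onset],
            }
        )
    return pd.DataFrame.from_records(records, columns=list(BEAT_COLUMNS))


def beat_rate_hz(beats: pd.DataFrame) -> float:
    """Reciprocal of the mean inter-beat (contraction-peak) interval."""
    times = beats["contraction_peak_time_s"].to_numpy(float)
    if len(times) < 2:
        raise ValueError("need at least 2 beats to estimate a rate")
    return 1.0 / float(np.mean(np.diff(times)))


def recommend_frame_delay(
    contraction_duration_s: float, fps: float, fraction: float = 0.2
) -> int:
    """Frame delay N sized to a fraction of the contraction duration.

    ~20% of the contraction duration at the trace's sampling rate (e.g.
    20 frames for a 1 s contraction at 100 fps; 40 frames when cooling
    stretches the contraction to 4 s at 50 fps).  Minimum 1 frame.
    """
    if contraction_duration_s <= 0 or fps <= 0 or fraction <= 0:
        raise ValueError("all arguments must be positive")
    return max(1, round(fraction * contraction_duration_s * fps))


def select_reference(
    trace_speed: ContractionTrace, quiescent_quantile: float = 0.2
) -> int:
    """Pick a quiescent reference frame from a speed trace.

    Returns the centre frame of the longest run of samples at or below the
    given quantile of the defined speed values (the earliest such run on
    ties), expressed as an index into the full trace.
    """
    v = trace_speed.defined_values
    if len(v) == 0:
        raise ValueError("trace has no defined samples")
    q = float(np.quantile(v, quiescent_quantile))
    below = v <= q
    if not below.any():
        raise ValueError("no samples at or below the quiescent quantile")
    best_start, best_len = 0, 0
    start = None
    for i, b in enumerate(np.append(below, False)):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    centre = best_start + (best_len - 1) // 2
    return centre + trace_speed.valid_from


@dataclass
class JoltReport:
    """Synchronised-spike (jolt) detection result.

    ``flagged_frames`` are sample indices where at least ``quorum`` wells
    spike within +/-1 frame; ``wells_affected`` maps each flagged frame to
    the wells involved; ``z_scores`` holds the robust per-well z-score of
    every sample (wells x samples).
    """

    flagged_frames: list[int]
    wells_affected: dict[int, list[str]]
    z_scores: pd.DataFrame
    quorum: int

    def mask(self, n_samples: int, pad: int = 1) -> np.ndarray:
        """Boolean mask, True where samples should be excluded downstream."""
        m = np.zeros(n_samples, dtype=bool)
        for f in self.flagged_frames:
            m[max(0, f - pad) : f + pad + 1] = True
        return m


def detect_jolts(
    traces: Mapping[str, ContractionTrace],
    z_thresh: float = 5.0,
    quorum: int | None = None,
) -> JoltReport:
    """Flag frames where a mechanical jolt spikes many wells at once.

    A jolt shakes the whole plate, so unlike a biological event it appears
    in (nearly) all wells simultaneously.  Per well, spike samples have
    robust z-score (vs. median / 1.4826 MAD) above ``z_thresh``; a frame is
    flagged when at least ``quorum`` wells (default ceil(2W/3)) spike within
    +/-1 frame of it and at least one well spikes exactly at it.
    """
    if len(traces) < 2:
        raise ValueError("need traces from at least 2 wells")
    wells = list(traces)
    # common time base: equal sampling rate and sample times aligned to
    # within one sample period (demuxed wells are staggered by sub-cycle
    # camera-frame offsets; trailing partial cycles may differ by 1 sample)
    n = min(len(traces[w]) for w in wells)
    if max(len(traces[w]) for w in wells) - n > 1:
        raise ValueError("traces must share a common time base")
    t0 = traces[wells[0]].frame_times_s[:n]
    dt = float(np.median(np.diff(t0)))
    for w in wells[1:]:
        tw = traces[w].frame_times_s[:n]
        if tw.shape != t0.shape or np.max(np.abs(tw - t0)) >= dt:
            raise ValueError("traces must share a common time base")
    if quorum is None:
        quorum = math.ceil(2 * len(wells) / 3)

    z_rows = {}
    spikes = {}
    for w in wells:
        v = traces[w].values[:n]
        defined = ~np.isnan(v)
        med = np.median(v[defined])
        scale = 1.4826 * _mad(v[defined])
        z = np.full(n, np.nan)
        z[defined] = (v[defined] - med) / (scale if scale > 0 else np.inf)
        z_rows[w] = z
        spikes[w] = (z > z_thresh) & defined
    z_df = pd.DataFrame(z_rows).T  # wells x samples

    # count wells spiking within +/-1 frame of each sample
    dilated = {}
    for w in wells:
        s = spikes[w]
        d = s.copy()
        d[:-1] |= s[1:]
        d[1:] |= s[:-1]
        dilated[w] = d
    counts = np.sum([dilated[w] for w in wells], axis=0)
    any_exact = np.any([spikes[w] for w in wells], axis=0)
    flagged = np.flatnonzero((counts >= quorum) & any_exact)
    affected = {
        int(f): [w for w in wells if dilated[w][f]] for f in flagged
    }
    return JoltReport(
        flagged_frames=[int(f) for f in flagged],
        wells_affected=affected,
        z_scores=z_df,
        quorum=quorum,
    )
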