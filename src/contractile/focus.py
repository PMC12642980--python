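"""Post-hoc focus selection across interleaved colour channels.

Chromatic aberration puts each illumination colour's focal plane at a
different depth, so for every well one of the three colour stacks is closest
to focus.  The focus score is the normalized variance (spatial variance over
squared spatial mean) averaged over a few frames — invariant to the LED
brightness differences between channels and monotone in sharpness.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import WellChannelStack

__all__ = ["focus_score", "tenengrad_score", "select_channel", "focus_report"]

_COLOUR_ORDER = ("R", "G", "B", "white")


def focus_score(stack: WellChannelStack, n_frames: int = 5) -> float:
    """Normalized-variance focus score, averaged over the first n_frames.

    Scaling a frame by any c > 0 leaves the score unchanged; sharper
    texture scores strictly higher than the same texture blurred.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    frames = stack.frames[: max(1, n_frames)].astype(np.float64, copy=False)
    scores = []
    for frame in frames:
        mean = frame.mean()
        if mean == 0:
            raise ValueError("cannot score a zero-mean frame")
        scores.append(frame.var() / mean**2)
    return float(np.mean(scores))


def tenengrad_score(stack: WellChannelStack, n_frames: int = 5) -> float:
    """Alternative gradient-energy (Tenengrad) focus score, mean-normalised."""
    from scipy import ndimage

    frames = stack.frames[: max(1, n_frames)].astype(np.float64, copy=False)
    scores = []
    for frame in frames:
        mean = frame.mean()
        if mean == 0:
            raise ValueError("cannot score a zero-mean frame")
        gx = ndimage.sobel(frame, axis=1)
        gy = ndimage.sobel(frame, axis=0)
        scores.append((gx**2 + gy**2).mean() / mean**2)
    return float(np.mean(scores))


def _colour_rank(colour: str) -> tuple[int, str]:
    try:
        return (_COLOUR_ORDER.index(colour), colour)
    except ValueError:
        return (len(_COLOUR_ORDER), colour)


def select_channel(
    stacks: Mapping[str, WellChannelStack],
    n_frames: int = 5,
    metric: str = "normalized_variance",
) -> tuple[str, dict[str, float], float]:
    """Pick the best-focused colour for one well.

    Returns ``(selected_colour, scores, margin)`` where margin is the score
    gap between the winner and the runner-up.  Ties break deterministically
    by colour order (R, G, B).
    """
    if len(stacks) < 2:
        raise ValueError("need at least 2 colour channels to select from")
    scorer = focus_score if metric == "normalized_variance" else tenengrad_score
    scores = {c: scorer(s, n_frames) for c, s in stacks.items()}
    ranked = sorted(scores, key=lambda c: (-scores[c], _colour_rank(c)))
    best, runner = ranked[0], ranked[1]
    return best, scores, scores[best] - scores[runner]


def focus_report(
    stacks: Mapping[tuple[str, str], WellChannelStack],
    n_frames: int = 5,
    metric: str = "normalized_variance",
) -> pd.DataFrame:
    """Score every (well, colour) stack and mark the selected colour per well.

    Returns a DataFrame with columns well, colour, score, selected, margin.
    """
    wells: dict[str, dict[str, WellChannelStack]] = {}
    for (well, colour), stack in stacks.items():
        wells.setdefault(well, {})[colour] = stack
    rows = []
    for well in wells:
        best, scores, margin = select_channel(wells[well], n_frames, metric)
        for colour, score in scores.items():
            rows.append(
                {
                    "well": well,
                    "colour": colour,
                    "score": score,
                    "selected": colour == best,
                    "margin": margin,
                }
            )
    return pd.DataFrame(rows)
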