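"""Foot and peak detection on clipped pulse-wave segments.

The peak of a pulse wave is the maximum of the (filtered) PPG within
the clipped segment, located with an excursion-based local-maximum
detector: a candidate maximum is confirmed once the signal falls by
more than ``delta = delta_frac * (segment max - segment min)`` below
it.  The highest confirmed local maximum wins; if none is confirmed
the global argmax of the segment is used.  The foot is the maximum of
the second derivative of the segment — a curvature landmark on the
anacrotic rise, not the physiological onset itself.

Both searches are restricted to the clipped segment.  That choice is
deliberate: on truncated or distorted waves the detections land on
boundaries or on the wrong limb, and the suitability criteria must be
able to see those failures rather than have them masked here.  All
ties break to the earliest sample, and detections are invariant to
amplitude scaling and constant offsets of the PPG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import BeatContext
from .errors import InputError
from .signals import SampledSignal

#: default excursion threshold as a fraction of the segment's range
DELTA_FRAC = 0.1


@dataclass(frozen=True)
class Landmarks:
    """Detected fiducial points of one clipped pulse wave.

    Indices are absolute sample indices into the recording; amplitudes
    are in filtered-PPG units.  ``degenerate`` marks a constant
    segment, for which no meaningful landmarks exist — the criteria
    stage fails such beats by construction.
    """

    foot_idx: int
    peak_idx: int
    foot_amp: float
    peak_amp: float
    d1_at_foot: float
    d2_at_peak: float
    d1_argmax_idx: int
    degenerate: bool = False


def _local_maxima_by_excursion(y: np.ndarray, delta: float) -> list[int]:
    """Indices of local maxima confirmed by a fall of > delta (earliest tie)."""
    maxima: list[int] = []
    mx, mx_pos = -np.inf, 0
    mn = np.inf
    looking_for_max = True
    for i, v in enumerate(y):
        if v > mx:
            mx, mx_pos = v, i
        if v < mn:
            mn = v
        if looking_for_max:
            if v < mx - delta:
                maxima.append(mx_pos)
                mn = v
                looking_for_max = False
        else:
            if v > mn + delta:
                mx, mx_pos = v, i
                looking_for_max = True
    return maxima


def detect_peak(
    seg: BeatContext, ppg_filtered: SampledSignal, delta_frac: float = DELTA_FRAC
) -> tuple[int, bool]:
    """Absolute index of the pulse-wave peak within the clipped segment.

    Returns ``(index, degenerate)``; a constant segment returns the
    segment start index flagged degenerate.
    """
    y = ppg_filtered.samples[seg.seg_start_idx : seg.seg_end_idx]
    if y.size < 3:
        raise InputError(f"beat {seg.n}: segment shorter than 3 samples")
    rng = float(np.max(y) - np.min(y))
    if rng == 0.0:
        return seg.seg_start_idx, True
    maxima = _local_maxima_by_excursion(y, delta_frac * rng)
    if maxima:
        # highest local maximum; np.argmax-style earliest tie-break
        best = max(maxima, key=lambda i: (y[i], -i))
        return seg.seg_start_idx + best, False
    return seg.seg_start_idx + int(np.argmax(y)), False


def detect_foot(seg: BeatContext, d2: SampledSignal) -> int:
    """Absolute index of the maximum of the second derivative in the segment."""
    y = d2.samples[seg.seg_start_idx : seg.seg_end_idx]
    if y.size < 3:
        raise InputError(f"beat {seg.n}: segment shorter than 3 samples")
    return seg.seg_start_idx + int(np.argmax(y))


def annotate(
    seg: BeatContext,
    ppg_filtered: SampledSignal,
    d1: SampledSignal,
    d2: SampledSignal,
    delta_frac: float = DELTA_FRAC,
) -> Landmarks:
    """Detect both landmarks and look up the derivative values at them."""
    peak_idx, degenerate = detect_peak(seg, ppg_filtered, delta_frac)
    foot_idx = detect_foot(seg, d2)
    seg_d1 = d1.samples[seg.seg_start_idx : seg.seg_end_idx]
    d1_argmax_idx = seg.seg_start_idx + int(np.argmax(seg_d1))
    return Landmarks(
        foot_idx=foot_idx,
        peak_idx=peak_idx,
        foot_amp=float(ppg_filtered.samples[foot_idx]),
        peak_amp=float(ppg_filtered.samples[peak_idx]),
        d1_at_foot=float(d1.samples[foot_idx]),
        d2_at_peak=float(d2.samples[peak_idx]),
        d1_argmax_idx=d1_argmax_idx,
        degenerate=degenerate,
    )
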