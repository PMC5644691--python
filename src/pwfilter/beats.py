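"""ECG R-peak detection and per-beat clipping of the PPG.

R-peaks are found with a Pan-Tompkins-style detector: band-pass,
differentiate, square, moving-window integrate, then adaptive
thresholding with a refractory period.  Each detection is refined to
the local ECG maximum within +/-25 ms.  The detector is deliberately
pluggable — any strictly increasing array of sample indices can be
wrapped in :class:`RPeakSeries` and fed downstream, e.g. indices
exported by other QRS software.

Each heartbeat's candidate pulse wave is clipped from the PPG between
50 ms after its R-peak and 80% of the *recording-wide mean* R-R
interval after it.  Using the global mean interval (not the per-beat
interval) means arrhythmic beats produce segments that overrun their
own next R-peak — which is exactly the situation the S2/S3 suitability
criteria are designed to catch downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InputError, InsufficientBeatsError
from .preprocess import FilterSpec, lowpass
from .signals import SampledSignal

log = logging.getLogger(__name__)

#: clip start offset after the R-peak, seconds
CLIP_OFFSET_S = 0.050
#: clip end as a fraction of the mean R-R interval
CLIP_FRACTION = 0.8
#: half-width of the R-peak refinement window, seconds
REFINE_HALF_WINDOW_S = 0.025


def round_half_away(x: float) -> int:
    """Nearest integer, ties rounded half away from zero (platform-stable)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class RPeakSeries:
    """Strictly increasing R-peak sample indices into an ECG."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InputError("R-peak indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise InputError("R-peak indices must be non-negative")
        if idx.size >= 2:
            rate_bpm = 60.0 / (float(np.mean(np.diff(idx))) / self.fs)
            if not (20.0 <= rate_bpm <= 300.0):
                log.warning("implied heart rate %.1f bpm outside [20, 300]", rate_bpm)

    def __len__(self) -> int:
        return self.indices.size

    def times(self, t0: float = 0.0) -> np.ndarray:
        return t0 + self.indices / self.fs


@dataclass(frozen=True)
class BeatContext:
    """One heartbeat: bounding R-peaks and the PPG clip bounds.

    ``seg_start_idx``/``seg_end_idx`` delimit the half-open clip
    ``[start, end)`` into the PPG sample array.
    """

    n: int
    r1_idx: int
    r2_idx: int
    seg_start_idx: int
    seg_end_idx: int

    def __post_init__(self) -> None:
        if not (self.r1_idx < self.seg_start_idx < self.seg_end_idx):
            raise InputError(
                f"beat {self.n}: invalid clip bounds "
                f"({self.r1_idx}, {self.seg_start_idx}, {self.seg_end_idx})"
            )


def detect_r_peaks(ecg: SampledSignal, min_rr_s: float = 0.25) -> RPeakSeries:
    """Locate QRS R-waves in a single-lead ECG.

    Pipeline: 5-15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise threshold with a
    refractory period of ``min_rr_s``, then refinement of each
    detection to the raw-ECG local maximum within +/-25 ms.

    A flat signal yields an empty series (not an error); NaN samples
    are an input error (enforced by :class:`SampledSignal`).
    """
    x = ecg.samples
    if not np.all(np.isfinite(x)):
        raise InputError("ECG contains NaN/inf samples")
    if np.ptp(x) == 0.0:
        return RPeakSeries(np.empty(0, dtype=int), ecg.fs)
    fs = ecg.fs

    # band-pass 5-15 Hz (classic QRS energy band); clamp for low fs
    high = min(15.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, high], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    # candidate humps of the integrated energy, refractory-separated
    distance = max(1, int(round(min_rr_s * fs)))
    cand, _ = sps.find_peaks(integrated, distance=distance)
    if cand.size == 0:
        return RPeakSeries(np.empty(0, dtype=int), ecg.fs)

    # adaptive signal/noise levels (Pan-Tompkins running estimates)
    lead_in = integrated[: min(integrated.size, int(2 * fs))]
    spki = float(np.max(lead_in))
    npki = float(np.mean(lead_in))
    peaks: list[int] = []
    for c in cand:
        threshold = npki + 0.25 * (spki - npki)
        if integrated[c] >= threshold:
            peaks.append(int(c))
            spki = 0.125 * integrated[c] + 0.875 * spki
        else:
            npki = 0.125 * integrated[c] + 0.875 * npki

    # refine to the raw-ECG local maximum within +/-25 ms
    half = max(1, int(round(REFINE_HALF_WINDOW_S * fs)))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    # deduplicate after refinement, enforce refractory spacing
    out: list[int] = []
    for r in sorted(set(refined)):
        if not out or r - out[-1] >= distance:
            out.append(r)
        elif x[r] > x[out[-1]]:
            out[-1] = r
    return RPeakSeries(np.asarray(out, dtype=int), ecg.fs)


def mean_rr(rpeaks: RPeakSeries) -> float:
    """Arithmetic mean of successive R-R intervals, in seconds."""
    if len(rpeaks) < 2:
        raise InsufficientBeatsError("mean R-R interval needs at least 2 R-peaks")
    return float(np.mean(np.diff(rpeaks.indices))) / rpeaks.fs


def clip_pulse_waves(
    ppg: SampledSignal,
    rpeaks: RPeakSeries,
    clip_offset_s: float = CLIP_OFFSET_S,
    clip_fraction: float = CLIP_FRACTION,
) -> list[BeatContext]:
    """Clip one candidate pulse-wave segment per bounded heartbeat.

    Segment ``n`` spans ``[r_n + round(clip_offset_s*fs),
    r_n + round(clip_fraction * meanRR_samples))``.  The final R-peak
    has no following R-peak and yields no segment; segments that would
    overrun the end of the PPG are dropped with a logged count.
    """
    if len(rpeaks) < 2:
        raise InsufficientBeatsError("pulse-wave clipping needs at least 2 R-peaks")
    fs = rpeaks.fs
    mean_rr_samples = float(np.mean(np.diff(rpeaks.indices)))
    start_off = round_half_away(clip_offset_s * fs)
    end_off = round_half_away(clip_fraction * mean_rr_samples)
    beats: list[BeatContext] = []
    dropped = 0
    for n in range(len(rpeaks) - 1):
        r1 = int(rpeaks.indices[n])
        r2 = int(rpeaks.indices[n + 1])
        start = r1 + start_off
        end = r1 + end_off
        if end > len(ppg):
            dropped += 1
            continue
        beats.append(BeatContext(n=n, r1_idx=r1, r2_idx=r2,
                                 seg_start_idx=start, seg_end_idx=end))
    if dropped:
        log.info("dropped %d beat segment(s) overrunning the PPG end", dropped)
    return beats
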