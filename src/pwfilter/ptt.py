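"""Pulse transit time: per-beat values, window averaging, range filter.

PTT(n) is the time from the n-th ECG R-peak to the detected foot of
the same heartbeat's pulse wave, reported in milliseconds.  Because
clipping starts 50 ms after the R-peak, no PTT can be below 50 ms.

Window averaging reproduces the common practice of reporting PTT
means over 60/30/5/1 heartbeats: windows are consecutive and
non-overlapping; with masking enabled, beats judged unsuitable are
excluded from each window's mean and empty windows yield NaN (never
0).  A trailing partial window is emitted and flagged.

The range filter of Gil et al. — drop PTT values below 150 ms or
above 400 ms — is provided as a comparison baseline.  Boundaries are
inclusive (only strictly-outside values are dropped).  A distorted
pulse wave can yield a wrong foot whose PTT still lies inside that
band; the morphological criteria catch those, the range filter cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import FilterResult
from .errors import ParameterError

GIL_LOW_MS = 150.0
GIL_HIGH_MS = 400.0


@dataclass(frozen=True)
class PTTSeries:
    """Per-beat pulse transit times with a suitability mask."""

    n: np.ndarray          # beat numbers
    ptt_ms: np.ndarray     # per-beat PTT, milliseconds
    suitable: np.ndarray   # boolean mask from the criteria filter

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        object.__setattr__(self, "ptt_ms", np.asarray(self.ptt_ms, dtype=float))
        object.__setattr__(self, "suitable", np.asarray(self.suitable, dtype=bool))

    def __len__(self) -> int:
        return self.ptt_ms.size


@dataclass(frozen=True)
class WindowMean:
    """Mean PTT over one averaging window of beats."""

    window_index: int
    n_used: int
    mean_ptt_ms: float   # NaN when no usable beats
    sem_ptt_ms: float    # NaN when fewer than 2 usable beats
    partial: bool


def compute_ptt(result: FilterResult) -> PTTSeries:
    """Per-beat PTT (ms) from a filter pass: t_foot - t_R1 per beat."""
    fs = result.record.fs
    n = np.array([v.n for v in result.verdicts], dtype=int)
    ptt = np.array(
        [(lm.foot_idx - b.r1_idx) / fs * 1000.0
         for b, lm in zip(result.beats, result.landmarks)]
    )
    suitable = np.array([v.suitable for v in result.verdicts], dtype=bool)
    return PTTSeries(n=n, ptt_ms=ptt, suitable=suitable)


def average_ptt(
    series: PTTSeries, window_beats: int, use_mask: bool = True
) -> list[WindowMean]:
    """Means over consecutive non-overlapping windows of beats."""
    if window_beats < 1:
        raise ParameterError(f"window_beats must be >= 1, got {window_beats}")
    out: list[WindowMean] = []
    total = len(series)
    for w, start in enumerate(range(0, total, window_beats)):
        stop = min(start + window_beats, total)
        vals = series.ptt_ms[start:stop]
        if use_mask:
            vals = vals[series.suitable[start:stop]]
        mean = float(np.mean(vals)) if vals.size else float("nan")
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else float("nan")
        out.append(
            WindowMean(
                window_index=w,
                n_used=int(vals.size),
                mean_ptt_ms=mean,
                sem_ptt_ms=sem,
                partial=(stop - start) < window_beats,
            )
        )
    return out


def gil_filter(
    series: PTTSeries, low_ms: float = GIL_LOW_MS, high_ms: float = GIL_HIGH_MS
) -> np.ndarray:
    """Boolean keep-mask of the Gil range filter (inclusive boundaries)."""
    if low_ms >= high_ms:
        raise ParameterError(f"low_ms {low_ms} must be below high_ms {high_ms}")
    return (series.ptt_ms >= low_ms) & (series.ptt_ms <= high_ms)


def windows_frame(windows: list[WindowMean]) -> pd.DataFrame:
    """Averaging-window table for CSV export."""
    return pd.DataFrame(
        [
            {
                "window_index": w.window_index,
                "n_used": w.n_used,
                "mean_ptt_ms": w.mean_ptt_ms,
                "sem_ptt_ms": w.sem_ptt_ms,
                "partial": int(w.partial),
            }
            for w in windows
        ]
    )
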