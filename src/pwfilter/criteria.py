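"""The seven-criterion morphological suitability filter.

A clipped pulse wave is *suitable* for PTT analysis iff all seven
criteria hold (times in seconds, amplitudes in filtered-PPG units,
all inequalities strict):

S1  t_foot < t_peak                     foot precedes peak
S2  t_R1 < t_peak < t_R2                peak inside its own heartbeat
S3  t_R1 < t_foot < t_R2                foot inside its own heartbeat
S4  peak_amp - foot_amp > 0             peak above foot
S5  d1(foot) > 0                        foot on an upward slope
S6  d2(peak) < 0                        peak at a convex maximum
S7  t_foot < t_d1max < t_peak           steepest rise between foot and peak

A beat failing one or more criteria is eliminated.  Strict
inequalities follow the criteria as stated; boundary equality fails
(equality is measure-zero on real signals anyway).  "Same heartbeat"
means the open interval between the bounding R-peaks, even though the
clip window may extend past the next R-peak for short beats — that is
how arrhythmic overrun gets caught.  Degenerate (constant) segments
fail S4 and S6 by construction.

Beats without a following R-peak cannot be evaluated (S2/S3 need it)
and are reported in a separate "not evaluated" bucket, inflating
neither the suitable nor the eliminated rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import beats as beats_mod
from . import landmarks as lm_mod
from . import preprocess
from .beats import BeatContext, RPeakSeries
from .landmarks import Landmarks
from .signals import Record, SampledSignal

log = logging.getLogger(__name__)

CRITERIA = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")


@dataclass(frozen=True)
class CriterionVerdict:
    """Per-beat outcome of the seven criteria (True = criterion met)."""

    n: int
    s1: bool
    s2: bool
    s3: bool
    s4: bool
    s5: bool
    s6: bool
    s7: bool

    @property
    def flags(self) -> tuple[bool, ...]:
        return (self.s1, self.s2, self.s3, self.s4, self.s5, self.s6, self.s7)

    @property
    def suitable(self) -> bool:
        return all(self.flags)

    @property
    def failed(self) -> tuple[str, ...]:
        return tuple(c for c, ok in zip(CRITERIA, self.flags) if not ok)


def evaluate_criteria(seg: BeatContext, lm: Landmarks, fs: float) -> CriterionVerdict:
    """Evaluate S1-S7 for one beat from its clip bounds and landmarks."""
    t_r1 = seg.r1_idx / fs
    t_r2 = seg.r2_idx / fs
    t_foot = lm.foot_idx / fs
    t_peak = lm.peak_idx / fs
    t_d1max = lm.d1_argmax_idx / fs

    s1 = t_foot < t_peak
    s2 = t_r1 < t_peak < t_r2
    s3 = t_r1 < t_foot < t_r2
    s4 = (lm.peak_amp - lm.foot_amp > 0.0) and not lm.degenerate
    s5 = lm.d1_at_foot > 0.0
    s6 = (lm.d2_at_peak < 0.0) and not lm.degenerate
    s7 = t_foot < t_d1max < t_peak
    return CriterionVerdict(n=seg.n, s1=s1, s2=s2, s3=s3, s4=s4, s5=s5, s6=s6, s7=s7)


@dataclass
class FilterSummary:
    """Beat tallies for one record run through the filter."""

    n_rpeaks: int = 0
    evaluated: int = 0
    suitable: int = 0
    eliminated: int = 0
    not_evaluated: int = 0
    failure_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_rpeaks": self.n_rpeaks,
            "evaluated": self.evaluated,
            "suitable": self.suitable,
            "eliminated": self.eliminated,
            "not_evaluated": self.not_evaluated,
            "failure_counts": dict(self.failure_counts),
        }


@dataclass
class FilterResult:
    """Everything produced by one pass of the filter over a record.

    Carries the intermediate signals and per-beat artefacts so the PTT
    stage can reuse the same landmarks without recomputation.
    """

    record: Record
    rpeaks: RPeakSeries
    ppg_filtered: SampledSignal
    d1: SampledSignal
    d2: SampledSignal
    beats: list[BeatContext]
    landmarks: list[Landmarks]
    verdicts: list[CriterionVerdict]
    summary: FilterSummary


def filter_record(
    record: Record,
    filter_spec: preprocess.FilterSpec | None = None,
    delta_frac: float = lm_mod.DELTA_FRAC,
    rpeaks: RPeakSeries | None = None,
    clip_offset_s: float = beats_mod.CLIP_OFFSET_S,
    clip_fraction: float = beats_mod.CLIP_FRACTION,
) -> FilterResult:
    """Run the full pipeline over one record and judge every beat.

    preprocess -> R-peak detection -> clipping -> landmark detection ->
    criteria.  Precomputed R-peaks may be supplied to bypass detection.
    """
    spec = filter_spec or preprocess.FilterSpec()
    ppg_f = preprocess.lowpass(record.ppg, spec)
    d1 = preprocess.derivative(ppg_f, 1)
    d2 = preprocess.derivative(ppg_f, 2)
    if rpeaks is None:
        rpeaks = beats_mod.detect_r_peaks(record.ecg)
    beat_list = beats_mod.clip_pulse_waves(
        record.ppg, rpeaks, clip_offset_s=clip_offset_s, clip_fraction=clip_fraction
    )
    landmark_list = [lm_mod.annotate(b, ppg_f, d1, d2, delta_frac) for b in beat_list]
    verdicts = [
        evaluate_criteria(b, lm, record.fs) for b, lm in zip(beat_list, landmark_list)
    ]

    summary = FilterSummary(
        n_rpeaks=len(rpeaks),
        evaluated=len(verdicts),
        suitable=sum(v.suitable for v in verdicts),
        eliminated=sum(not v.suitable for v in verdicts),
        not_evaluated=max(0, len(rpeaks) - 1 - len(verdicts)) + (1 if len(rpeaks) else 0),
        failure_counts={c: 0 for c in CRITERIA},
    )
    for v in verdicts:
        for c in v.failed:
            summary.failure_counts[c] += 1
    log.info(
        "record %r: %d R-peaks, %d beats evaluated, %d suitable, %d eliminated",
        record.id, summary.n_rpeaks, summary.evaluated,
        summary.suitable, summary.eliminated,
    )
    return FilterResult(
        record=record,
        rpeaks=rpeaks,
        ppg_filtered=ppg_f,
        d1=d1,
        d2=d2,
        beats=beat_list,
        landmarks=landmark_list,
        verdicts=verdicts,
        summary=summary,
    )


def verdicts_frame(result: FilterResult):
    """Per-beat verdict table (pandas DataFrame) for CSV export."""
    import pandas as pd

    fs = result.record.fs
    t0 = result.record.ecg.t0
    rows = []
    for b, v in zip(result.beats, result.verdicts):
        rows.append(
            {
                "beat": v.n,
                "r1_time_s": t0 + b.r1_idx / fs,
                **{c.lower(): int(ok) for c, ok in zip(CRITERIA, v.flags)},
                "suitable": int(v.suitable),
                "failed": ";".join(v.failed),
            }
        )
    return pd.DataFrame(rows)
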