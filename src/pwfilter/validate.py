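"""Binary-classification comparison of filter verdicts against reference labels.

Convention: *positive* means a pulse wave was marked unsuitable and
eliminated; *negative* means it was kept.  The reference is whatever
labelling serves as ground truth — expert manual elimination on real
recordings, generator labels on synthetic ones.

sensitivity = 100 * tp / (tp + fn)     ability to eliminate what the
                                       reference eliminates
specificity = 100 * tn / (fp + tn)     ability to keep what the
                                       reference keeps
accuracy    = 100 * (tp + tn) / total

Metrics with an undefined denominator are reported as None rather
than raising.  Reported percentages round to one decimal, half away
from zero; full precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .criteria import FilterResult
from .errors import InputError
from .synth import GroundTruth


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with positive = eliminated/unsuitable."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(pred, ref) -> ConfusionCounts:
    """Confusion counts from two boolean eliminate-flags sequences."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise InputError(f"length mismatch: pred {pred.shape} vs ref {ref.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & ref)),
        fn=int(np.sum(~pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity and overall accuracy as percentages."""
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.fp + c.tn) if (c.fp + c.tn) > 0 else None
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total > 0 else None
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def round1(x: float | None) -> float | None:
    """One-decimal rounding, ties half away from zero (as printed reports do)."""
    if x is None:
        return None
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def compare_to_truth(result: FilterResult, truth: GroundTruth) -> ConfusionCounts:
    """Confusion of one record's verdicts against generator ground truth.

    Beats are aligned by matching each detected bounding R-peak to the
    nearest true R-peak (within 50 ms); beats without a match and
    beats the pipeline could not evaluate are excluded.
    """
    fs = result.record.fs
    true_r = truth.r_peak_times_s
    pred_elim: list[bool] = []
    ref_elim: list[bool] = []
    for beat, verdict in zip(result.beats, result.verdicts):
        t_r1 = beat.r1_idx / fs
        j = int(np.argmin(np.abs(true_r - t_r1)))
        if abs(true_r[j] - t_r1) > 0.050:
            continue
        pred_elim.append(not verdict.suitable)
        ref_elim.append(not bool(truth.suitable[j]))
    return confusion(pred_elim, ref_elim)
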