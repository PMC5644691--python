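"""Shared fixtures: synthetic records are generated once per session."""

import numpy as np
import pytest

import pwfilter as pw


@pytest.fixture(scope="session")
def clean_record():
    """A clean 60 s recording at 60 bpm with its ground truth."""
    return pw.generate(pw.SynthConfig(duration_s=60.0, hr_bpm=60.0, seed=101))


@pytest.fixture(scope="session")
def clean_result(clean_record):
    record, _ = clean_record
    return pw.filter_record(record)


@pytest.fixture(scope="session")
def stress_corpus():
    """Mixed-artefact corpus at the worst-subject elimination rate (~15%)."""
    return pw.make_validation_set(6, artefact_rate=0.15, seed=202)


@pytest.fixture(scope="session")
def foot_offset_ms():
    """Template-constant offset between true onset and detected foot."""
    return pw.calibrated_foot_offset_ms()


def brute_force_criteria(t_r1, t_r2, t_foot, t_peak, t_d1max,
                         foot_amp, peak_amp, d1_at_foot, d2_at_peak,
                         degenerate):
    """Independent straight-line implementation of the seven predicates.

    Used as the oracle against ``evaluate_criteria``; deliberately
    written as bare comparisons with no shared code.
    """
    s1 = t_foot < t_peak
    s2 = (t_r1 < t_peak) and (t_peak < t_r2)
    s3 = (t_r1 < t_foot) and (t_foot < t_r2)
    s4 = (peak_amp - foot_amp) > 0 and not degenerate
    s5 = d1_at_foot > 0
    s6 = d2_at_peak < 0 and not degenerate
    s7 = (t_foot < t_d1max) and (t_d1max < t_peak)
    return (s1, s2, s3, s4, s5, s6, s7)


def random_beat_and_landmarks(rng, fs=2000.0):
    """A randomized (BeatContext, Landmarks) pair covering edge cases.

    Indices include ties and boundary equalities with sizeable
    probability so the strictness of each inequality is exercised.
    """
    r1 = int(rng.integers(0, 5000))
    seg_start = r1 + int(rng.integers(1, 200))
    seg_end = seg_start + int(rng.integers(2, 2000))
    r2 = r1 + int(rng.integers(2, 2500))
    while not (r1 < seg_start):
        r1 -= 1

    def pick_idx():
        if rng.random() < 0.3:
            # force coincidences with structural indices
            return int(rng.choice([r1, r2, seg_start, seg_end - 1]))
        return int(rng.integers(seg_start, seg_end))

    foot_idx, peak_idx, d1max_idx = pick_idx(), pick_idx(), pick_idx()

    def pick_val():
        if rng.random() < 0.2:
            return 0.0
        return float(rng.normal(0, 1))

    degenerate = rng.random() < 0.1
    beat = pw.BeatContext(n=0, r1_idx=r1, r2_idx=r2,
                          seg_start_idx=seg_start, seg_end_idx=seg_end)
    lm = pw.Landmarks(
        foot_idx=foot_idx, peak_idx=peak_idx,
        foot_amp=pick_val(), peak_amp=pick_val(),
        d1_at_foot=pick_val(), d2_at_peak=pick_val(),
        d1_argmax_idx=d1max_idx, degenerate=degenerate,
    )
    return beat, lm, fs
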