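"""The seven suitability criteria and the whole-record filter."""

import numpy as np
import pytest

import pwfilter as pw
from conftest import brute_force_criteria, random_beat_and_landmarks

FS = 2000.0


def _lm(**kw):
    defaults = dict(
        foot_idx=2500, peak_idx=2900, foot_amp=0.1, peak_amp=1.0,
        d1_at_foot=2.0, d2_at_peak=-30.0, d1_argmax_idx=2600, degenerate=False,
    )
    defaults.update(kw)
    return pw.Landmarks(**defaults)


def _beat():
    return pw.BeatContext(n=0, r1_idx=2000, r2_idx=4000,
                          seg_start_idx=2100, seg_end_idx=3600)


class TestEvaluateCriteria:
    def test_clean_landmarks_pass_all_seven(self):
        v = pw.evaluate_criteria(_beat(), _lm(), FS)
        assert v.flags == (True,) * 7
        assert v.suitable and v.failed == ()

    def test_foot_after_peak_fails_s1(self):
        # archetype: distorted wave where the detected foot lands after
        # the detected peak
        v = pw.evaluate_criteria(
            _beat(), _lm(foot_idx=3000, peak_idx=2400, d1_argmax_idx=2600), FS
        )
        assert not v.s1 and not v.suitable

    def test_peak_below_foot_fails_s4(self):
        v = pw.evaluate_criteria(_beat(), _lm(peak_amp=0.3, foot_amp=0.5), FS)
        assert not v.s4 and not v.suitable

    def test_foot_equal_to_peak_fails_strict_s1(self):
        v = pw.evaluate_criteria(
            _beat(), _lm(foot_idx=2900, peak_idx=2900), FS
        )
        assert not v.s1

    def test_peak_outside_heartbeat_fails_s2(self):
        v = pw.evaluate_criteria(_beat(), _lm(peak_idx=4100), FS)
        assert not v.s2

    def test_degenerate_fails_s4_and_s6(self):
        v = pw.evaluate_criteria(
            _beat(), _lm(degenerate=True, peak_amp=1.0, d2_at_peak=-1.0), FS
        )
        assert not v.s4 and not v.s6

    def test_suitable_is_conjunction_and_failed_lists_labels(self):
        v = pw.evaluate_criteria(
            _beat(), _lm(d1_at_foot=0.0, d2_at_peak=0.0), FS
        )
        assert v.failed == ("S5", "S6")
        assert v.suitable == all(v.flags)

    def test_matches_bruteforce_oracle_on_randomized_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            beat, lm, fs = random_beat_and_landmarks(rng)
            v = pw.evaluate_criteria(beat, lm, fs)
            expected = brute_force_criteria(
                beat.r1_idx / fs, beat.r2_idx / fs,
                lm.foot_idx / fs, lm.peak_idx / fs, lm.d1_argmax_idx / fs,
                lm.foot_amp, lm.peak_amp, lm.d1_at_foot, lm.d2_at_peak,
                lm.degenerate,
            )
            assert v.flags == expected


class TestFilterRecord:
    def test_clean_record_eliminates_nothing(self, clean_result):
        assert clean_result.summary.eliminated == 0
        assert clean_result.summary.suitable == clean_result.summary.evaluated

    def test_noise_burst_beats_all_flagged(self):
        record, truth = pw.generate(
            pw.SynthConfig(duration_s=30.0, seed=7,
                           artefacts=(("C", 3), ("C", 11), ("C", 19)))
        )
        result = pw.filter_record(record)
        flagged = {v.n for v in result.verdicts if not v.suitable}
        assert {3, 11, 19} <= flagged

    def test_failure_counts_sum_at_least_eliminated(self, stress_corpus):
        record, _ = stress_corpus[0]
        result = pw.filter_record(record)
        assert sum(result.summary.failure_counts.values()) >= result.summary.eliminated

    def test_last_beat_counted_as_not_evaluated(self, clean_result):
        s = clean_result.summary
        assert s.not_evaluated >= 1
        assert s.evaluated + s.not_evaluated == s.n_rpeaks

    def test_verdicts_are_pure_functions_of_landmarks(self):
        # identical (seg, lm) inputs always produce identical verdicts
        rng = np.random.default_rng(3)
        beat, lm, fs = random_beat_and_landmarks(rng)
        v1 = pw.evaluate_criteria(beat, lm, fs)
        v2 = pw.evaluate_criteria(beat, lm, fs)
        assert v1 == v2

    def test_verdicts_frame_layout(self, clean_result):
        from pwfilter.criteria import verdicts_frame

        df = verdicts_frame(clean_result)
        assert list(df.columns) == [
            "beat", "r1_time_s", "s1", "s2", "s3", "s4", "s5", "s6", "s7",
            "suitable", "failed",
        ]
        assert df["suitable"].all()
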