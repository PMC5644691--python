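"""The synthetic generator: determinism, ground truth, artefact classes."""

import numpy as np
import pytest

import pwfilter as pw


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        cfg = pw.SynthConfig(duration_s=10.0, seed=5, artefact_rate=0.2)
        r1, t1 = pw.generate(cfg)
        r2, t2 = pw.generate(cfg)
        np.testing.assert_array_equal(r1.ppg.samples, r2.ppg.samples)
        np.testing.assert_array_equal(r1.ecg.samples, r2.ecg.samples)
        np.testing.assert_array_equal(t1.onset_times_s, t2.onset_times_s)
        assert t1.artefact_class == t2.artefact_class

    def test_beat_count_at_constant_rate(self):
        _, truth = pw.generate(
            pw.SynthConfig(duration_s=60.0, hr_bpm=60.0, hr_sd_bpm=0.0, seed=1)
        )
        assert len(truth) == 60

    def test_true_onset_is_r_peak_plus_delay(self):
        _, truth = pw.generate(pw.SynthConfig(duration_s=20.0, seed=2))
        np.testing.assert_allclose(
            truth.onset_times_s - truth.r_peak_times_s, 0.250, atol=1e-12
        )

    def test_clean_onset_precedes_clean_peak(self):
        _, truth = pw.generate(pw.SynthConfig(duration_s=30.0, seed=3))
        assert np.all(truth.onset_times_s < truth.peak_times_s)

    def test_clean_ppg_energy_below_9_hz(self, clean_record):
        record, _ = clean_record
        y = record.ppg.samples - np.mean(record.ppg.samples)
        spectrum = np.abs(np.fft.rfft(y)) ** 2
        freqs = np.fft.rfftfreq(len(y), d=1.0 / record.fs)
        frac = spectrum[freqs <= 9.0].sum() / spectrum.sum()
        assert frac >= 0.99

    def test_artefact_labels_match_injection(self):
        cfg = pw.SynthConfig(duration_s=30.0, seed=4,
                             artefacts=(("A", 2), ("D", 9)))
        _, truth = pw.generate(cfg)
        assert truth.artefact_class[2] == "A"
        assert truth.artefact_class[9] == "D"
        assert int(np.sum(~truth.suitable)) == 2

    def test_invalid_configs_rejected(self):
        with pytest.raises(pw.ParameterError):
            pw.SynthConfig(fs=100.0)
        with pytest.raises(pw.ParameterError):
            pw.SynthConfig(hr_bpm=20.0)
        with pytest.raises(pw.ParameterError):
            pw.SynthConfig(true_delay_ms=40.0)
        with pytest.raises(pw.ParameterError):
            pw.SynthConfig(artefacts=(("X", 1),))


class TestArtefactClasses:
    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_class_c_always_fails_a_criterion(self, seed):
        record, truth = pw.generate(
            pw.SynthConfig(duration_s=40.0, seed=seed,
                           artefacts=(("C", 2), ("C", 10), ("C", 25)))
        )
        result = pw.filter_record(record)
        verdicts = {v.n: v for v in result.verdicts}
        for n in (2, 10, 25):
            assert not verdicts[n].suitable

    @pytest.mark.parametrize("cls", ["A", "B", "C", "D"])
    def test_each_class_is_eliminated_at_default_severity(self, cls):
        record, _ = pw.generate(
            pw.SynthConfig(duration_s=30.0, seed=8, artefacts=((cls, 6), (cls, 14)))
        )
        result = pw.filter_record(record)
        verdicts = {v.n: v for v in result.verdicts}
        assert not verdicts[6].suitable and not verdicts[14].suitable

    def test_artefacts_do_not_spill_into_neighbouring_beats(self):
        record, _ = pw.generate(
            pw.SynthConfig(duration_s=40.0, seed=9,
                           artefacts=(("A", 5), ("B", 12), ("C", 20), ("D", 28)))
        )
        result = pw.filter_record(record)
        flagged = {v.n for v in result.verdicts if not v.suitable}
        assert flagged == {5, 12, 20, 28}


class TestValidationSet:
    def test_zero_rate_labels_all_suitable(self):
        corpus = pw.make_validation_set(2, artefact_rate=0.0, seed=1,
                                        duration_s=20.0)
        for _, truth in corpus:
            assert truth.suitable.all()

    def test_rate_roughly_matches_worst_subject(self):
        # the hardest recording in the validation study lost ~16% of waves
        corpus = pw.make_validation_set(6, artefact_rate=0.15, seed=12,
                                        duration_s=60.0)
        labels = np.concatenate([t.suitable for _, t in corpus])
        rate = 1.0 - labels.mean()
        assert 0.08 <= rate <= 0.22

    def test_label_counts_equal_injected_counts(self):
        cfg = pw.SynthConfig(duration_s=30.0, seed=6, artefact_rate=0.3)
        _, truth = pw.generate(cfg)
        injected = sum(c is not None for c in truth.artefact_class)
        assert int(np.sum(~truth.suitable)) == injected


class TestFootOffsetCalibration:
    def test_offset_is_a_small_positive_constant(self, foot_offset_ms):
        # the 9 Hz filter rounds the onset corner, so the curvature
        # maximum sits a little after the physiological onset
        assert 0.0 < foot_offset_ms < 50.0

    def test_offset_independent_of_amplitude(self):
        a = pw.calibrated_foot_offset_ms(amp=1.0)
        b = pw.calibrated_foot_offset_ms(amp=10.0)
        assert a == b
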