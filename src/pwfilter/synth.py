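"""Seeded synthetic ECG+PPG generator with ground truth.

The generator is the test substrate for the whole pipeline: it emits a
paired recording plus per-beat ground truth (R-peak times, true pulse
onsets, true peaks, suitability labels), deterministically for a fixed
seed.

Waveform model
--------------
Each clean pulse wave is a sum of two asymmetric bumps with an
analytically known onset: a main systolic wave

    p(u) = (u / 2b)^2 * exp(2 - u/b),   u > 0   (peak 1 at u = 2b)

rising from exactly u = 0 (the annotated *onset*), plus a smaller
dicrotic bump of the same family delayed along the catacrotic decay.
The onset is the physiological start of the rise; the foot the
pipeline detects is a *curvature* landmark (second-derivative maximum)
that sits a few milliseconds after the onset once the 9 Hz low-pass
has rounded the corner.  :func:`calibrated_foot_offset_ms` measures
that constant template offset so recovery tests compare detected PTT
against ``true_delay + offset`` rather than conflating the two
definitions.  The ECG is a minimal biphasic (Mexican-hat) spike per
beat — R-peak timing is all the pipeline consumes.

Artefact classes
----------------
Four archetypes of distorted pulse waves, applied to designated beats
(severities in :class:`ArtefactParams`; positions scale with the beat
period ``s``):

A   early/truncated rise: the pulse is advanced so its rise completes
    before the clip window opens; the detected foot lands on the
    catacrotic limb after the detected peak (fails S1).
B   amplitude collapse: the pulse is replaced by a smooth decline
    carrying a concave-up knee at ~0.25 periods — the detected foot,
    whose nonactual PTT still falls inside the Gil 150-400 ms band —
    plus a lower late local maximum; the detected peak collapses onto
    the falling clip boundary, so the wave fails S1/S5/S7.  (A strict
    S4 failure is unreachable through the full pipeline: the detected
    peak is the *highest* confirmed local maximum, which bounds every
    candidate foot sample from above except in degenerate ties.)
C   unrecognizable wave: a large excursion just before the clip window
    with a smooth decaying return; both landmarks collapse onto the
    clip boundary, the classic signature of a wave with no
    recognizable shape (fails S1 and/or S5/S6).
D   time-warped wave: a wide spurious early maximum precedes a late
    steep rise, so the detected foot (on the late rise) follows the
    detected peak (fails S1); its nonactual PTT is biased high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .preprocess import FilterSpec, derivative, lowpass
from .signals import Record, SampledSignal

ARTEFACT_CLASSES = ("A", "B", "C", "D")

#: rise-time constant of the main systolic bump, seconds (peak at 2b)
PULSE_B = 0.09
#: rise-time constant of the dicrotic bump, seconds
DICROTIC_B = 0.08
#: delay of the dicrotic onset after the main onset, seconds
DICROTIC_DELAY = 0.28
#: width of the ECG Mexican-hat spike, seconds
ECG_SIGMA = 0.010
#: time of the first R-peak, seconds
FIRST_BEAT_T = 0.4


@dataclass(frozen=True)
class ArtefactParams:
    """Severity parameters of the four artefact archetypes.

    Positions/widths marked "phi" are fractions of the nominal beat
    period; amplitudes are multiples of the clean pulse amplitude.
    """

    # A: onset shift (seconds, relative to the R-peak; negative = early)
    a_onset_s: float = -0.10
    # B: decline slopes (amp per period) along the piecewise profile
    b_slope_steep: float = 3.6
    b_slope_shelf: float = 0.3
    b_slope_steep2: float = 2.7
    b_slope_flat: float = 0.12
    b_bump_amp: float = 0.5
    b_bump_phi: float = 0.66
    b_bump_sigma_phi: float = 0.08
    b_recovery_periods: float = 8.0
    # C: excursion height (amp) and decay time constant (seconds)
    c_height: float = 6.0
    c_tau_s: float = 0.15
    c_rise_s: float = 0.03
    # D: spurious bump and late-rise onset
    d_bump_amp: float = 1.2
    d_bump_t_s: float = 0.18
    d_bump_sigma_s: float = 0.10
    d_onset_phi: float = 0.55


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of a synthetic recording."""

    duration_s: float = 60.0
    fs: float = 2000.0
    hr_bpm: float = 60.0
    hr_sd_bpm: float = 2.0
    true_delay_ms: float = 250.0
    amp: float = 1.0
    dicrotic: float = 0.20
    noise_sd: float = 0.005
    ecg_noise_sd: float = 0.01
    artefacts: tuple[tuple[str, int], ...] = ()
    artefact_rate: float = 0.0
    artefact_classes: tuple[str, ...] = ARTEFACT_CLASSES
    artefact_params: ArtefactParams = field(default_factory=ArtefactParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 200:
            raise ParameterError(f"fs must be >= 200 Hz, got {self.fs}")
        if not (30 <= self.hr_bpm <= 200):
            raise ParameterError(f"heart rate must be in [30, 200] bpm, got {self.hr_bpm}")
        if self.true_delay_ms < 60:
            raise ParameterError(
                f"true_delay_ms must be >= 60 so the onset lies inside the clip window"
            )
        if not (0 <= self.dicrotic <= 1):
            raise ParameterError("dicrotic relative amplitude must be in [0, 1]")
        if not (0 <= self.artefact_rate < 1):
            raise ParameterError("artefact_rate must be in [0, 1)")
        for cls, _ in self.artefacts:
            if cls not in ARTEFACT_CLASSES:
                raise ParameterError(f"unknown artefact class {cls!r}")


@dataclass
class GroundTruth:
    """Per-beat truth emitted alongside a synthetic record."""

    r_peak_times_s: np.ndarray
    onset_times_s: np.ndarray
    peak_times_s: np.ndarray
    suitable: np.ndarray           # bool; False for artefact-bearing beats
    artefact_class: list[str | None]

    def __len__(self) -> int:
        return self.r_peak_times_s.size


def _gamma_pulse(u: np.ndarray, b: float) -> np.ndarray:
    """Asymmetric bump with onset at u=0 and unit peak at u=2b."""
    out = np.zeros_like(u)
    m = u > 0
    x = u[m]
    out[m] = (x / (2 * b)) ** 2 * np.exp(2.0 - x / b)
    return out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _clean_pulse(u: np.ndarray, amp: float, dicrotic: float) -> np.ndarray:
    """Clean PW: main systolic bump + dicrotic bump, onset at u=0."""
    return amp * (
        _gamma_pulse(u, PULSE_B) + dicrotic * _gamma_pulse(u - DICROTIC_DELAY, DICROTIC_B)
    )


def _ecg_spike(u: np.ndarray) -> np.ndarray:
    """Biphasic QRS-like spike, maximum exactly at u=0."""
    x = u / ECG_SIGMA
    return (1.0 - 0.5 * x * x) * np.exp(-0.5 * x * x)


def _b_shape(phi: np.ndarray, amp: float, p: ArtefactParams) -> np.ndarray:
    """Class-B amplitude-collapse profile on the period fraction axis."""
    dphi = float(phi[1] - phi[0]) if phi.size > 1 else 0.0
    slope = np.zeros_like(phi)
    s1, s2, s3, s4 = (p.b_slope_steep, p.b_slope_shelf,
                      p.b_slope_steep2, p.b_slope_flat)
    # piecewise slope profile with smooth blends; always strictly declining.
    # Only the knee at ~0.25 periods is a *sharp* concave-up feature; the
    # unavoidable concave-up level-off is spread over 0.3 periods so its
    # curvature stays far below the knee's after low-pass filtering.
    slope -= s1 * _smoothstep((phi - 0.02) / 0.08)             # ramp-in (concave down)
    slope += (s1 - s2) * _smoothstep((phi - 0.23) / 0.04)      # knee: foot bait
    slope -= (s3 - s2) * _smoothstep((phi - 0.33) / 0.04)      # shelf end (concave down)
    slope += (s3 - s4) * _smoothstep((phi - 0.50) / 0.30)      # long shallow level-off
    slope += s4 * _smoothstep((phi - 0.95) / 0.02)             # stop
    v = np.cumsum(slope) * dphi
    v += p.b_bump_amp * np.exp(-0.5 * ((phi - p.b_bump_phi) / p.b_bump_sigma_phi) ** 2)
    # slow recovery toward baseline, spread over several following beats so
    # the residual drift slope stays well below the clean pulse decay slope
    rec = phi >= 1.0
    fade = 0.5 + 0.5 * np.cos(
        np.pi * np.clip((phi[rec] - 1.0) / p.b_recovery_periods, 0.0, 1.0)
    )
    v[rec] = v[np.searchsorted(phi, 1.0) - 1] * fade
    return amp * v


def _c_shape(u: np.ndarray, amp: float, p: ArtefactParams) -> np.ndarray:
    """Class-C excursion: fast rise before the clip window, smooth decay."""
    v = np.zeros_like(u)
    rise = (u >= 0) & (u < p.c_rise_s)
    v[rise] = p.c_height * _smoothstep(u[rise] / p.c_rise_s)
    tail = u >= p.c_rise_s
    v[tail] = p.c_height * np.exp(-(u[tail] - p.c_rise_s) / p.c_tau_s)
    return amp * v


def _d_shape(u: np.ndarray, period: float, amp: float, p: ArtefactParams) -> np.ndarray:
    """Class-D time-warp: wide early bump, then a late steep rise."""
    bump = p.d_bump_amp * np.exp(-0.5 * ((u - p.d_bump_t_s) / p.d_bump_sigma_s) ** 2)
    late = _gamma_pulse(u - p.d_onset_phi * period, PULSE_B)
    return amp * (bump + late)


def generate(config: SynthConfig) -> tuple[Record, GroundTruth]:
    """Generate one paired ECG+PPG record with ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    period = 60.0 / config.hr_bpm
    rr_sd = period * config.hr_sd_bpm / config.hr_bpm
    delay = config.true_delay_ms / 1000.0

    # beat times with beat-to-beat jitter
    r_times: list[float] = []
    r = FIRST_BEAT_T
    while r < config.duration_s - 0.1:
        r_times.append(r)
        rr = period + rng.normal(0.0, rr_sd)
        r += float(np.clip(rr, 0.5 * period, 1.5 * period))
    r_times_arr = np.asarray(r_times)
    n_beats = r_times_arr.size

    # artefact assignment: explicit list plus optional random rate
    art: dict[int, str] = {int(i): c for c, i in config.artefacts}
    if config.artefact_rate > 0:
        for i in range(1, n_beats - 1):
            if i not in art and rng.random() < config.artefact_rate:
                art[i] = str(rng.choice(config.artefact_classes))

    ecg = np.zeros(n)
    ppg = np.zeros(n)
    onset_times = np.empty(n_beats)
    peak_times = np.empty(n_beats)
    suitable = np.ones(n_beats, dtype=bool)
    classes: list[str | None] = [None] * n_beats
    p = config.artefact_params

    for i, r_i in enumerate(r_times_arr):
        lo = max(0, int((r_i - 0.3) * fs))
        # class-B recovery spans several periods; the slice must cover it
        # fully so the contribution returns to baseline inside the slice
        span = (
            (1.0 + p.b_recovery_periods + 0.1) * period
            if art.get(i) == "B"
            else 2.5 * period + 0.5
        )
        hi = min(n, int((r_i + span) * fs))
        u = t[lo:hi] - r_i
        ecg[lo:hi] += _ecg_spike(u)

        onset = r_i + delay
        onset_times[i] = onset
        cls = art.get(i)
        classes[i] = cls
        if cls is None:
            wave = _clean_pulse(t[lo:hi] - onset, config.amp, config.dicrotic)
            ppg[lo:hi] += wave
            # true peak: argmax of this beat's own noiseless contribution
            peak_times[i] = t[lo:hi][int(np.argmax(wave))]
        else:
            suitable[i] = False
            peak_times[i] = np.nan
            if cls == "A":
                early = t[lo:hi] - (r_i + p.a_onset_s)
                ppg[lo:hi] += _clean_pulse(early, config.amp, config.dicrotic)
            elif cls == "B":
                ppg[lo:hi] += _b_shape(u / period, config.amp, p)
            elif cls == "C":
                ppg[lo:hi] += _c_shape(u, config.amp, p)
            elif cls == "D":
                ppg[lo:hi] += _d_shape(u, period, config.amp, p)

    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, size=n)
    if config.ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0.0, config.ecg_noise_sd, size=n)

    record = Record(
        ecg=SampledSignal(ecg, fs),
        ppg=SampledSignal(ppg, fs),
        id=f"synth-seed{config.seed}",
        meta={"synthetic": True, "seed": config.seed, "hr_bpm": config.hr_bpm},
    )
    truth = GroundTruth(
        r_peak_times_s=r_times_arr,
        onset_times_s=onset_times,
        peak_times_s=peak_times,
        suitable=suitable,
        artefact_class=classes,
    )
    return record, truth


def make_validation_set(
    n_records: int,
    artefact_rate: float,
    seed: int,
    duration_s: float = 60.0,
    fs: float = 2000.0,
    classes: Sequence[str] = ARTEFACT_CLASSES,
) -> list[tuple[Record, GroundTruth]]:
    """A reproducible labelled corpus for sensitivity/specificity runs.

    Heart rates are drawn uniformly in 60-80 bpm per record; artefact
    beats are drawn independently at ``artefact_rate`` with classes
    sampled uniformly from ``classes``.
    """
    if n_records < 1:
        raise ParameterError("n_records must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_records):
        config = SynthConfig(
            duration_s=duration_s,
            fs=fs,
            hr_bpm=float(rng.uniform(60.0, 80.0)),
            artefact_rate=artefact_rate,
            artefact_classes=tuple(classes),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate(config))
    return out


def calibrated_foot_offset_ms(
    fs: float = 2000.0,
    filter_spec: FilterSpec | None = None,
    amp: float = 1.0,
    dicrotic: float = 0.20,
) -> float:
    """Constant offset (ms) between the template onset and the detected foot.

    Builds one noiseless clean pulse, applies the standard low-pass,
    and returns ``t(argmax d2) - t(onset)`` within a clip-like window.
    The foot is a curvature landmark, so this offset is a property of
    the template + filter, not an error of the detector; PTT recovery
    is judged against ``true_delay + offset``.
    """
    spec = filter_spec or FilterSpec()
    onset = 1.0
    tt = np.arange(int(3.0 * fs)) / fs
    sig = SampledSignal(_clean_pulse(tt - onset, amp, dicrotic), fs)
    d2 = derivative(lowpass(sig, spec), 2)
    # clip-like search window around the onset (R-peak 250 ms earlier)
    lo = int((onset - 0.2) * fs)
    hi = int((onset + 0.55) * fs)
    foot = lo + int(np.argmax(d2.samples[lo:hi]))
    return (foot / fs - onset) * 1000.0
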