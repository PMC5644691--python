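"""PPG conditioning and discrete derivatives.

The PPG channel is conditioned with a low-pass Butterworth filter
(default: 4th order, 9 Hz cut-off) before any landmark detection.
Filtering is zero-phase by default (forward-backward application):
landmark *times* feed the pulse transit time directly, and a causal
filter's group delay would bias every PTT by a constant.  The squared
magnitude response of forward-backward filtering means the gain at the
cut-off frequency is 0.5 rather than 1/sqrt(2).

Derivatives use central finite differences on the interior and
first-order one-sided differences at the two ends, scaled by the
sampling rate so units are signal-units per second.  The second
derivative applies the operator twice.  The ECG is deliberately not
touched here; its conditioning lives inside R-peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InputError, ParameterError
from .signals import SampledSignal


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification for PPG conditioning."""

    order: int = 4
    cutoff_hz: float = 9.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff_hz}")


def lowpass(sig: SampledSignal, spec: FilterSpec = FilterSpec()) -> SampledSignal:
    """Apply the low-pass Butterworth filter to a signal.

    Raises :class:`ParameterError` if the cut-off is at or above the
    Nyquist frequency.
    """
    nyquist = sig.fs / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=sig.fs, output="sos")
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, sig.samples)
    else:
        y = sps.sosfilt(sos, sig.samples)
    return sig.with_samples(np.asarray(y))


def derivative(sig: SampledSignal, n: int = 1) -> SampledSignal:
    """n-th discrete time derivative (n in {1, 2}), same length as input."""
    if n not in (1, 2):
        raise ParameterError(f"derivative order must be 1 or 2, got {n}")
    if len(sig) < 3:
        raise InputError("derivative needs at least 3 samples")
    y = sig.samples
    for _ in range(n):
        # np.gradient: central differences interior, one-sided at ends
        y = np.gradient(y) * sig.fs
    return sig.with_samples(y)
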