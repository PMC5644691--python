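"""Core waveform containers and CSV I/O for paired ECG+PPG recordings.

A recording is a pair of uniformly sampled channels (ECG and PPG) at a
common sampling rate.  All processing in this package works on sample
indices internally (0-based, seconds via ``t0 + i/fs``); milliseconds
appear only at reporting boundaries.

The canonical on-disk format is a CSV with header ``time,ecg,ppg``
(UTF-8, decimal point, full float precision) plus an optional JSON
sidecar ``<path>.meta.json`` holding ``{id, fs, meta}``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParameterError, SamplingError

log = logging.getLogger(__name__)

#: relative tolerance on time-step uniformity when inferring fs from timestamps
TIME_STEP_RTOL = 1e-6


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Real-valued samples in arbitrary units; all finite, length >= 2.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InputError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    def time(self, i: int | np.ndarray) -> float | np.ndarray:
        """Time in seconds of sample index ``i`` (0-based)."""
        return self.t0 + np.asarray(i) / self.fs

    def index(self, t: float | np.ndarray) -> int | np.ndarray:
        """Nearest sample index for time ``t`` in seconds."""
        return np.rint((np.asarray(t) - self.t0) * self.fs).astype(int)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (self.samples.size - 1) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SampledSignal":
        """A copy of this signal carrying new samples (same fs, t0)."""
        return SampledSignal(samples=samples, fs=self.fs, t0=self.t0)


@dataclass
class Record:
    """A paired ECG+PPG recording with a shared time base."""

    ecg: SampledSignal
    ppg: SampledSignal
    id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ecg.fs != self.ppg.fs:
            raise InputError(
                f"channel sampling rates differ: ecg {self.ecg.fs} Hz vs ppg {self.ppg.fs} Hz"
            )
        if len(self.ecg) != len(self.ppg):
            n = min(len(self.ecg), len(self.ppg))
            log.warning(
                "record %r: unequal channel lengths (%d vs %d); trimming to %d samples",
                self.id, len(self.ecg), len(self.ppg), n,
            )
            self.ecg = SampledSignal(self.ecg.samples[:n], self.ecg.fs, self.ecg.t0)
            self.ppg = SampledSignal(self.ppg.samples[:n], self.ppg.fs, self.ppg.t0)

    @property
    def fs(self) -> float:
        return self.ecg.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_record(path: str | Path, format: str = "csv") -> Record:
    """Read a paired recording from a ``time,ecg,ppg`` CSV.

    The sampling rate is inferred from the median time step; the time
    column must be strictly increasing and uniform within a relative
    tolerance of 1e-6.  A JSON sidecar written by :func:`write_record`
    restores ``id`` and ``meta`` when present.
    """
    if format != "csv":
        raise ParameterError(f"unsupported record format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = {"time", "ecg", "ppg"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError(f"{path}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > TIME_STEP_RTOL * step:
        raise SamplingError(f"{path}: non-uniform time step beyond tolerance")
    fs = 1.0 / step
    t0 = float(t[0])

    rec_id, meta = "", {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        rec_id = info.get("id", "")
        meta = info.get("meta", {})

    return Record(
        ecg=SampledSignal(df["ecg"].to_numpy(dtype=float), fs, t0),
        ppg=SampledSignal(df["ppg"].to_numpy(dtype=float), fs, t0),
        id=rec_id,
        meta=meta,
    )


def write_record(record: Record, path: str | Path) -> None:
    """Write a record as a ``time,ecg,ppg`` CSV plus a JSON sidecar.

    Floats are written at full round-trip precision so that
    ``read_record(write_record(r))`` reproduces samples to 1e-9.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": record.ecg.times,
            "ecg": record.ecg.samples,
            "ppg": record.ppg.samples,
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.17g")
        _sidecar_path(path).write_text(
            json.dumps({"id": record.id, "fs": record.fs, "meta": record.meta}, indent=1)
        )
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
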