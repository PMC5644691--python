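"""Pipeline configuration: defaults, file loading, provenance dump.

Precedence is CLI flags > config file > defaults; every CLI run writes
the fully resolved configuration next to its outputs so a run can be
reproduced bit-exactly from that file and the same seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, ParameterError
from .preprocess import FilterSpec


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the filtering pipeline."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    clip_offset_ms: float = 50.0
    clip_fraction: float = 0.8
    delta_frac: float = 0.1
    gil_low_ms: float = 150.0
    gil_high_ms: float = 400.0
    window_beats: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_fraction < 1.0):
            raise ParameterError(f"clip_fraction must be in (0, 1), got {self.clip_fraction}")
        if self.clip_offset_ms <= 0:
            raise ParameterError(f"clip_offset_ms must be positive, got {self.clip_offset_ms}")
        if self.gil_low_ms >= self.gil_high_ms:
            raise ParameterError("gil_low_ms must be below gil_high_ms")
        if self.window_beats < 1:
            raise ParameterError("window_beats must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = asdict(self.filter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        return PipelineConfig.from_dict(data)
    except (TypeError, ValueError, yaml.YAMLError) as exc:
        raise FormatError(f"{path}: cannot parse config ({exc})") from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the resolved config as YAML next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
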