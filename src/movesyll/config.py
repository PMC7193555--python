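"""Pipeline configuration.

Defaults are the analysis parameters of the in-clinic protocol: 25 Hz working
rate, 0.2-3 Hz order-3 Butterworth band-pass, 1 s windows stepped by 0.24 s,
24-syllable vocabulary, 1e-10 transition smoothing, 3-D MDS, clock-defined
night (00:00-06:00) and day (08:00-20:00) phases in 30-minute segments, and a
0.16 Cook's-distance exclusion threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from movesyll.errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    rate_hz: float = 25.0
    band_low_hz: float = 0.2
    band_high_hz: float = 3.0
    filter_order: int = 3
    window_s: float = 1.0
    step_s: float = 0.24
    k: int = 24
    smoothing_eps: float = 1e-10
    mds_dims: int = 3
    mds_flavor: str = "classical"
    night_span: tuple[float, float] = (0.0, 6.0)   # clock hours, [start, end)
    day_span: tuple[float, float] = (8.0, 20.0)
    segment_minutes: int = 30
    min_segment_transitions: int = 100
    cook_threshold: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < self.rate_hz / 2:
            raise ValidationError(
                f"invalid band ({self.band_low_hz}, {self.band_high_hz}) "
                f"for rate {self.rate_hz} Hz"
            )
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValidationError("window_s and step_s must be positive")
        if self.k < 2:
            raise ValidationError("vocabulary size k must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["night_span"] = list(d["night_span"])
        d["day_span"] = list(d["day_span"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key in ("night_span", "day_span"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON (YAML is a superset; one loader serves both)."""
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        """Short stable digest recorded in every output's metadata header."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def replace(cfg: PipelineConfig, **overrides: Any) -> PipelineConfig:
    return dataclasses.replace(cfg, **overrides)
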