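"""Analysis configuration.

All tunable thresholds of the pipeline live here, grouped by stage and
addressable with dotted keys (e.g. ``baseline.smoothness``) in the JSON
config file the CLI accepts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class BaselineConfig:
    smoothness: float = 1e5      # AsLS second-difference penalty (lambda)
    asymmetry: float = 1e-3      # AsLS asymmetry weight p
    iterations: int = 10


@dataclass
class WavelengthConfig:
    min: float | None = None     # nm; None keeps the detector's full range
    max: float | None = None


@dataclass
class PeakConfig:
    rel_height: float = 0.01     # fraction of the tallest maximum
    snr_min: float = 10.0        # apex height over noise sigma
    saturation_mau: float = 2000.0


@dataclass
class PurityConfig:
    r_min: float = 0.95          # min flank-vs-apex spectral correlation
    ev_min: float = 0.995        # min first-PC explained variance


@dataclass
class DeconvConfig:
    match_r_min: float = 0.90    # spectral correlation to accept a library match
    k_max: int = 4
    tol: float = 1e-8
    max_iter: int = 500
    restarts: int = 10
    seed: int = 0


@dataclass
class AssignConfig:
    rt_window: float = 0.1       # minutes
    spec_r_min: float = 0.97


@dataclass
class Config:
    """Full pipeline configuration with field-of-practice defaults."""

    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    wavelength: WavelengthConfig = field(default_factory=WavelengthConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    purity: PurityConfig = field(default_factory=PurityConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "Config":
        """Build from a nested dict or a flat dict with dotted keys."""
        nested: dict[str, dict] = {}
        for key, value in data.items():
            if isinstance(value, dict):
                nested.setdefault(key, {}).update(value)
            elif "." in key:
                group, _, leaf = key.partition(".")
                nested.setdefault(group, {})[leaf] = value
            else:
                raise KeyError(f"unrecognized config key {key!r}")
        cfg = cls()
        for group, entries in nested.items():
            if not hasattr(cfg, group):
                raise KeyError(f"unrecognized config group {group!r}")
            section = getattr(cfg, group)
            for leaf, value in entries.items():
                if not hasattr(section, leaf):
                    raise KeyError(f"unrecognized config key {group}.{leaf}")
                setattr(section, leaf, value)
        return cfg

    @classmethod
    def from_json(cls, path) -> "Config":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
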