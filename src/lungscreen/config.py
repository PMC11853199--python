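"""Declarative pipeline configuration.

One document collects every stage default — working sample rate, filter
design, segment length, entropy binning, wavelet, selection alpha, model
hyperparameters and seeds — so a run is a pure function of (inputs, config,
seeds). The config hash embedded in artifacts makes silent drift detectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from lungscreen.classifier import ModelConfig
from lungscreen.errors import ContractError

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    sample_rate: int = 4000
    filter_family: str = "butterworth"
    filter_order: int = 5
    low_cut_hz: float = 80.0
    high_cut_hz: float = 1000.0
    segment_seconds: float = 6.0
    entropy_bins: int = 256
    wavelet: str = "db7"
    dwt_levels: int = 10
    selection_alpha: float = 0.05
    test_fraction: float = 0.2
    split_seed: int = 0
    balance_seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ContractError(
                f"unsupported config schema version {self.schema_version}"
            )
        if not 0 < self.low_cut_hz < self.high_cut_hz < self.sample_rate / 2:
            raise ContractError("filter band must satisfy 0 < low < high < Nyquist")
        if self.segment_seconds <= 0:
            raise ContractError("segment_seconds must be positive")
        if not 0 < self.selection_alpha < 1:
            raise ContractError("selection_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short digest of the full configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        model = data.pop("model", {})
        if isinstance(model, dict):
            model = ModelConfig(**model)
        known = cls.__dataclass_fields__
        unknown = [k for k in data if k not in known]
        if unknown:
            raise ContractError(f"unknown config keys: {unknown}")
        return cls(model=model, **data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
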