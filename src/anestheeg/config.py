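"""Pipeline configuration: a validated, fully-defaulted parameter bundle."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class SpectralParams:
    window: float = 2.0
    step: float = 0.1
    nw: float = 3.0
    k: int = 5
    epoch_nw: float = 6.0
    epoch_k: int = 11

    def validate(self) -> None:
        for nw, k in ((self.nw, self.k), (self.epoch_nw, self.epoch_k)):
            if k > 2 * nw - 1:
                raise ValueError(f"taper count k={k} exceeds 2*nw-1 (nw={nw})")


@dataclass
class EpochRules:
    washout_s: float = 300.0
    epoch_s: float = 120.0


@dataclass
class SuppressionParams:
    threshold_uv: float = 5.0
    min_event_s: float = 0.5


@dataclass
class RegressionParams:
    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 1


@dataclass
class CohortParams:
    n_asd: int = 42
    n_nt: int = 110
    duration_s: float = 600.0


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    epochs: EpochRules = field(default_factory=EpochRules)
    suppression: SuppressionParams = field(default_factory=SuppressionParams)
    regression: RegressionParams = field(default_factory=RegressionParams)

    def validate(self) -> None:
        self.spectral.validate()
        if self.cohort.n_asd < 1 or self.cohort.n_nt < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.cohort.duration_s < 600:
            raise ValueError("record duration must be >= 600 s")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in fields(cls)}
        for key, val in raw.items():
            if key not in sections:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(val, dict):
                sub = getattr(cfg, key)
                known = {f.name for f in fields(sub)}
                for k2, v2 in val.items():
                    if k2 not in known:
                        raise ValueError(f"unknown config key {key}.{k2}")
                    setattr(sub, k2, v2)
            else:
                setattr(cfg, key, val)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)
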