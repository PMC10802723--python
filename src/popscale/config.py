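"""YAML-backed configuration mirroring every tunable across the modules."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Optional

import yaml

from .errors import ParameterError
from .gp import SVGPConfig


@dataclass
class SimulateConfig:
    n_genes: int = 200
    variants_per_gene: int = 50
    base_correlation: float = 0.5
    gene_sd: float = 1.0
    within_sd: float = 1.0
    constrained_fraction: float = 0.05
    constrained_shift: float = 5.0
    link_a: float = 1.2
    link_b: float = 3.0
    total_mu: float = 0.35
    n_cases: int = 1000
    n_controls: int = 1000
    causal_fraction: float = 0.5
    severe_shift: float = 3.0
    inherited_mean: float = 0.0


@dataclass
class MixtureConfig:
    severe_level: float = 0.9999
    moderate_level: float = 0.99
    per_observation: bool = False  # fit on per-patient observations, not unique variants


@dataclass
class CohortConfig:
    n_sims: int = 10_000
    n_random: int = 999
    q_threshold: float = 0.05


@dataclass
class IOConfig:
    gene_column: str = "gene"
    variant_column: str = "variant"
    orientation: Dict[str, str] = field(default_factory=dict)

    def column_spec(self) -> dict:
        return {
            "gene_column": self.gene_column,
            "variant_column": self.variant_column,
            "orientation": dict(self.orientation),
        }


@dataclass
class Config:
    io: IOConfig = field(default_factory=IOConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    gp: SVGPConfig = field(default_factory=SVGPConfig)
    gp_joint: bool = False
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls()
        sections = {
            "io": IOConfig,
            "simulate": SimulateConfig,
            "gp": SVGPConfig,
            "mixture": MixtureConfig,
            "cohort": CohortConfig,
        }
        for key, val in (d or {}).items():
            if key == "gp_joint":
                cfg.gp_joint = bool(val)
                continue
            if key not in sections:
                raise ParameterError(f"unknown config section {key!r}")
            klass = sections[key]
            known = klass().__dict__
            for k in val:
                if k not in known:
                    raise ParameterError(f"unknown config key {key}.{k}")
            setattr(cfg, key, klass(**{**known, **val}))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
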