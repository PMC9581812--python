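"""Run configuration: YAML round-trip, defaults, provenance."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml

from . import __version__
from .engine import EngineConfig
from .forcefield import ForceFieldParams
from .sysbuild import SystemSpec


@dataclass
class AnalysisConfig:
    cluster_cutoff_nm: float = 0.9
    rg_cutoff_nm: float = 2.5
    min_aggregate_molecules: int = 5
    window_fraction: float = 1.0 / 3.0


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable losslessly."""

    system: SystemSpec = field(
        default_factory=lambda: SystemSpec(n_lipids=50))
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    engine: EngineConfig = field(default_factory=EngineConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    n_steps: int = 1_000_000
    equilibration_steps_per_stage: int = 10_000
    output_prefix: str = "run"

    def to_dict(self) -> dict:
        d = {
            "system": asdict(self.system),
            "forcefield": self.forcefield.to_dict(),
            "engine": asdict(self.engine),
            "analysis": asdict(self.analysis),
            "n_steps": self.n_steps,
            "equilibration_steps_per_stage":
                self.equilibration_steps_per_stage,
            "output_prefix": self.output_prefix,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            system=SystemSpec(**d["system"]),
            forcefield=ForceFieldParams.from_dict(d["forcefield"]),
            engine=EngineConfig(**d["engine"]),
            analysis=AnalysisConfig(**d["analysis"]),
            n_steps=d["n_steps"],
            equilibration_steps_per_stage=d[
                "equilibration_steps_per_stage"],
            output_prefix=d["output_prefix"],
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def provenance(self, seed: int | None = None) -> dict:
        return {
            "config_hash": self.config_hash(),
            "seed": self.engine.seed if seed is None else seed,
            "version": __version__,
        }
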