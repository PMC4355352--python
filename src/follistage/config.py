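"""Pipeline configuration with lossless YAML round-trips."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from follistage.cytometry import DnaModelConfig, GateConfig
from follistage.microarray import DEGCriteria
from follistage.staging import StagingConfig


@dataclass
class SimulationConfig:
    n_follicles: int = 27
    n_low_rin: int = 2
    n_events: int = 10_000
    n_probes: int = 2000
    n_replicates: int = 4
    dye_bias: float = 0.3
    debris_frac: float = 0.05
    doublet_frac: float = 0.03
    qpcr_genes: list = field(default_factory=lambda: ["VNN1", "ANGPT2", "CCNB1", "PTTG1"])


@dataclass
class QpcrOptions:
    marker_gene: str = "CYP17A1"
    contamination_fold: float = 5.0
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gating: GateConfig = field(default_factory=GateConfig)
    dna_model: DnaModelConfig = field(default_factory=DnaModelConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    deg: DEGCriteria = field(default_factory=DEGCriteria)
    qpcr: QpcrOptions = field(default_factory=QpcrOptions)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        for name, sub in (
            ("simulation", SimulationConfig),
            ("gating", GateConfig),
            ("dna_model", DnaModelConfig),
            ("staging", StagingConfig),
            ("deg", DEGCriteria),
            ("qpcr", QpcrOptions),
        ):
            if name in kw and isinstance(kw[name], dict):
                allowed = {f.name for f in fields(sub)}
                unknown = set(kw[name]) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in {name!r} config: {sorted(unknown)}")
                kw[name] = sub(**kw[name])
        return cls(**kw)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
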