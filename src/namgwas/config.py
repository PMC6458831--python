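"""Schema-validated pipeline configuration (YAML-backed).

Unknown keys are rejected so silent typos cannot change an analysis; the
fully resolved configuration is serialised into every output directory
for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .traits import TRAIT_NAMES


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulationConfig:
    n_snps_per_chrom: int = 40
    chrom_length_cM: float = 150.0
    n_families: int = 25
    family_size: int | None = None       # fixed size; None samples low..high
    family_size_low: int = 23
    family_size_high: int = 61
    missing_rate: float = 0.0
    # ground-truth QTL: list of {snp_index: int, effect: float | {family: f}}
    qtl: list = field(default_factory=list)
    intercept: float = 0.0
    family_effect_sd: float = 0.0
    truth: dict = field(default_factory=dict)  # SimulationTruth overrides


@dataclass
class DesignConfig:
    zones: int = 6
    lanes: int = 4
    positions: int = 22
    n_check_mainplots_per_zone: int = 6
    n_recurrent_mainplots: int | None = None  # None: flex 4-5 per house


@dataclass
class SmoothingConfig:
    lam: float | None = None   # None: generalised cross-validation
    df: float | None = None


@dataclass
class GwasSection:
    maf_threshold: float = 0.01
    alpha: float = 0.001
    folds: int = 5
    repeats: int = 20
    detection_threshold: int = 20
    window_cM: float = 5.0


@dataclass
class ReportConfig:
    group_window_cM: float = 4.0
    match_window_cM: float = 4.0
    gene_table: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    years: int = 1
    traits: list = field(default_factory=lambda: ["SAsm", "DW"])
    treatments: list = field(default_factory=lambda: ["control", "drought"])
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    gwas: GwasSection = field(default_factory=GwasSection)
    report: ReportConfig = field(default_factory=ReportConfig)

    def __post_init__(self) -> None:
        bad = set(self.traits) - set(TRAIT_NAMES)
        if bad:
            raise ValueError(f"unknown traits: {sorted(bad)}")
        bad_t = set(self.treatments) - {"control", "drought"}
        if bad_t:
            raise ValueError(f"unknown treatments: {sorted(bad_t)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "simulation": SimulationConfig,
            "design": DesignConfig,
            "smoothing": SmoothingConfig,
            "gwas": GwasSection,
            "report": ReportConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                kwargs[key] = _from_mapping(sections[key], value or {}, key)
            elif key in {f.name for f in fields(cls)}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown top-level config key: {key}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
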