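"""Pipeline configuration: one master seed plus per-stage parameter blocks.

The config serializes losslessly to YAML. Each stage derives its own
random stream from ``(master_seed, stage name)`` (see
:func:`migpipe._util.stage_rng`), so stage order never changes results.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import numpy as np

from ._util import stage_rng

STAGE_NAMES = ("simulate", "assemble", "damage", "context", "divergence", "tree", "date")

DEFAULT_STAGES: dict[str, dict] = {
    "simulate": {
        "n_species": 12,
        "birth_rate": 0.1,
        "root_age": 45.0,
        "n_loci": 60,
        "locus_length_range": [300, 800],
        "subst_rate": 0.001,
        "p0_ct": 0.3,
        "p0_ga": 0.3,
        "damage_decay": 0.4,
        "dropout_intercept": 30.0,
        "dropout_age_coef": 0.0,
        "dropout_herbarium_coef": 0.0,
        "read_depth": 12,
        "error_rate": 0.001,
        "mode": "amplicon",
    },
    "assemble": {
        "min_depth": 5,
        "max_alleles_per_locus": 2,
        "max_n_per_consensus": 5,
        "max_het_sites_per_consensus": 8,
        "max_indels_per_locus": 40,
        "min_taxa": 4,
        "within_sample_identity": 0.85,
        "across_sample_identity": 0.85,
        "max_low_quality_bases": 50,
        "low_quality_threshold": 20,
    },
    "damage": {"window": 25, "terminal_k": 3, "interior_from": 11},
    "context": {"near_bp": 1000},
    "divergence": {"configurations": ["zones2", "zones4", "zones6"]},
    "tree": {"metric": "mismatch", "n_bootstrap": 1000},
    "date": {
        "smoothing": 0.01,
        "cv": False,
        "lambda_grid": [1e5, 1e4, 1e3, 1e2, 1e1, 1e0, 1e-1, 1e-2, 1e-3],
        "n_restarts": 5,
    },
}


@dataclass
class PipelineConfig:
    master_seed: int = 0
    out_dir: str = "migpipe_out"
    verbosity: str = "info"
    stages: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.master_seed < 0:
            raise ValueError("master_seed must be >= 0")
        merged = copy.deepcopy(DEFAULT_STAGES)
        for stage, params in self.stages.items():
            if stage not in merged:
                raise ValueError(f"unknown stage {stage!r} in config")
            unknown = set(params) - set(merged[stage])
            if unknown:
                raise ValueError(f"unknown parameter(s) {sorted(unknown)} for stage {stage!r}")
            merged[stage].update(params)
        self.stages = merged

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.master_seed, stage)

    # -- serialization ------------------------------------------------------

    def to_yaml(self) -> str:
        payload = {
            "master_seed": self.master_seed,
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
            "stages": self.stages,
        }
        return yaml.safe_dump(payload, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        payload = yaml.safe_load(text) or {}
        return cls(
            master_seed=payload.get("master_seed", 0),
            out_dir=payload.get("out_dir", "migpipe_out"),
            verbosity=payload.get("verbosity", "info"),
            stages=payload.get("stages", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
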