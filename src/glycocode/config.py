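"""Run configuration: one YAML file, one mandatory seed, per-stage blocks.

Every stage's numeric defaults live here and can be overridden from the
file; unknown keys anywhere are rejected up front so a typo cannot
silently run a stage with defaults.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "STAGE_DEFAULTS"]

STAGE_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "bulk": {},  # overrides for BulkSimConfig fields
        "survival": {},  # overrides for SurvSimConfig fields
        "single_cell": {},  # overrides for SCSimConfig fields
    },
    "de": {"use_adjusted": False},
    "panel": {"p_max": 0.01, "min_cohorts": 2},
    "cluster": {
        "cohort": "cohort1",
        "k_range": [2, 3, 4, 5],
        "n_iterations": 2000,
        "subsample_fraction": 0.9,
        "delta_min": 0.1,
        "center": True,
    },
    "score": {"tau": 1.0},
    "network": {"alpha": 0.05, "on_adjusted": True, "n_iterations": 100},
    "survival": {},
    "sc": {
        "n_hvg": 3000,
        "n_comp": 10,
        "k_neighbors": 20,
        "resolution": 1.0,
        "cytokines": ["IL6", "CXCL8", "TGFB1"],
        "method": "spearman",
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with a mandatory master seed."""

    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        merged: dict[str, dict] = {}
        for stage, defaults in STAGE_DEFAULTS.items():
            block = copy.deepcopy(defaults)
            overrides = self.stages.get(stage, {})
            unknown = set(overrides) - set(defaults) if defaults else set(overrides)
            if stage == "simulate":
                unknown = set(overrides) - {"bulk", "survival", "single_cell"}
            if unknown:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(unknown)}")
            block.update(copy.deepcopy(overrides))
            merged[stage] = block
        extra = set(self.stages) - set(STAGE_DEFAULTS)
        if extra:
            raise ValueError(f"unknown stages: {sorted(extra)}")
        self.stages = merged

    def __getitem__(self, stage: str) -> dict:
        return self.stages[stage]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "seed" not in raw:
            raise ValueError(f"{path}: seed is mandatory")
        seed = raw.pop("seed")
        return cls(seed=seed, stages=raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump({"seed": self.seed, **self.stages}, handle, sort_keys=True)
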