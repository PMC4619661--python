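"""Pipeline configuration: declarative TOML/YAML file plus CLI overrides.

Defaults mirror the analysis constants of the study design: SNP coverage
window 30–120×, pool frequency > 0.20, parental frequency ≥ 0.80, Δf
threshold 0.25, LOESS span 0.75 / degree 2, 140 bp junction flanks, 5%
read-difference budget, ≥ 2 unique core reads per breakpoint.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

_KNOWN_STAGES = ("pools", "reads", "coverage", "ct", "phenotype", "mapdelta", "genotype", "exonusage", "ddct", "age", "correlate")

#: Stages that consume another stage's output when run from one config.
_STAGE_DEPS = {
    "mapdelta": "pools",
    "genotype": "reads",
    "exonusage": "coverage",
    "ddct": "ct",
    "correlate": "phenotype",
}


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: ["pools", "mapdelta"])
    seed: int = 0
    out_dir: str = "flm_sweepmap_out"
    verbose: bool = False

    # bsa_mapping
    cov_min: int = 30
    cov_max: int = 120
    min_freq: float = 0.20
    parental_min: float = 0.80
    span: float = 0.75
    degree: int = 2
    delta_threshold: float = 0.25
    n_boot: int = 0

    # insertion genotyping
    flank: int = 140
    max_diff: float = 0.05
    min_reads: int = 2
    dedup: bool = False

    # simulation conditions (see simulate.F2SimConfig for the mapping design)
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in _KNOWN_STAGES:
                raise ValueError(f"unknown stage {stage!r}; known: {_KNOWN_STAGES}")
        for stage, dep in _STAGE_DEPS.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r} in the same run")
        if not self.cov_min <= self.cov_max:
            raise ValueError("cov_min must be <= cov_max")
        for name, lo, hi in (
            ("min_freq", 0.0, 1.0),
            ("parental_min", 0.0, 1.0),
            ("delta_threshold", -1.0, 1.0),
            ("max_diff", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0.0 < self.span <= 1.0:
            raise ValueError("span must be in (0, 1]")
        if self.degree < 0 or self.flank <= 0 or self.min_reads < 1:
            raise ValueError("degree, flank, min_reads out of range")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load TOML or YAML config; keyword overrides win. Unknown keys rejected."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text()) or {}
        else:
            raise ValueError(f"unsupported config format {path.suffix!r}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
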