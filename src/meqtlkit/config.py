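"""Pipeline configuration: the analytic thresholds and file locations.

Defaults collect the analysis constants used throughout: candidate CpGs at
meta p < 1e-4, meQTL pairs at BH-FDR < 0.05, LD clumping at r^2 > 0.1,
a +/-500 kb cis window, instrument selection at p < 0.05, and the
genome-wide 5e-8 screen for the PheWAS step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # thresholds
    candidate_meta_p: float = 1e-4
    fdr_level: float = 0.05
    clump_r2: float = 0.1
    cis_window: int = 500_000
    iv_p: float = 0.05
    phewas_genomewide_p: float = 5e-8
    phewas_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    mr_alpha: float = 0.05
    prune_r2: float = 0.02
    knn_k: int = 20
    n_ancestral_pops: int = 4
    # QC
    maf_min: float = 0.05
    miss_max: float = 0.05
    hwe_p_min: float = 1e-6
    detection_p_max: float = 1e-12
    snp_exclusion_bp: int = 10
    # cohort labels
    cohorts: tuple = ("450K", "EPIC")
    # reproducibility and layout
    seed: int = 0
    bundle_dir: str = "bundle"
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("candidate_meta_p", "fdr_level", "iv_p",
                     "phewas_genomewide_p", "phewas_alpha",
                     "enrichment_alpha", "mr_alpha", "detection_p_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not (0 <= self.clump_r2 < 1) or not (0 <= self.prune_r2 < 1):
            raise ValueError("r^2 thresholds must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohorts" in raw:
            raw["cohorts"] = tuple(raw["cohorts"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohorts"] = list(d["cohorts"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
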