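"""Pipeline configuration (YAML-backed, strictly validated).

Every analysis threshold appears exactly once, named after the step it
controls; unknown keys are rejected so typos cannot silently fall back to a
default.  A full default template is produced by :func:`default_config`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import SimulationParams


class VariantSimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    prevalence: float = Field(default=0.404, ge=0.0, le=1.0)
    hazard_ratio: float = Field(default=2.0, gt=0.0)
    baseline_hazard: float = Field(default=0.02, gt=0.0)
    censor_time: float = Field(default=60.0, gt=0.0)
    fail_qual_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    fail_dp4_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    fail_pl_fraction: float = Field(default=0.1, ge=0.0, le=1.0)


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # detection filter: DABG p < alpha in >= detect_fraction of one group
    dabg_alpha: float = Field(default=0.05, gt=0.0, le=1.0)
    detect_fraction: float = Field(default=0.5, gt=0.0, le=1.0)
    unique_exon_rule: Literal["single_transcript", "private_to_transcript"] = "single_transcript"
    gene_summary_method: Literal["median", "mean"] = "median"
    # differential exon usage
    correction: Literal["BH", "bonferroni"] = "BH"
    si_alpha_tumor: float = Field(default=0.001, gt=0.0, le=1.0)
    si_alpha_recurrence: float = Field(default=0.01, gt=0.0, le=1.0)
    shrink_variance: bool = True
    # variant quality filters
    qual_min: float = Field(default=20.0, ge=0.0)
    dp4_min: int = Field(default=20, ge=0)
    pl_min: int = Field(default=100, ge=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: Path = Path("pipeline_out")
    simulate: bool = True
    recurrence_rate: float = Field(default=0.75, ge=0.0, le=1.0)
    run_qpcr: bool = True
    sim: SimulationParams = Field(default_factory=SimulationParams)
    variant_sim: VariantSimSettings = Field(default_factory=VariantSimSettings)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    # user-supplied inputs, used when simulate is false
    design_path: Optional[Path] = None
    probe_matrix_path: Optional[Path] = None
    background_path: Optional[Path] = None
    sample_sheet_path: Optional[Path] = None
    clinical_path: Optional[Path] = None
    vcf_path: Optional[Path] = None
    cq_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_config(**overrides) -> PipelineConfig:
    """The shipped default configuration, optionally overridden per key."""
    return PipelineConfig.model_validate(overrides)
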