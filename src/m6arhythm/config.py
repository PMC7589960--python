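"""Schema-validated pipeline configuration (unknown keys rejected)."""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FamilyConfig(_Strict):
    name: str
    copies: dict[str, int]
    ancestral_length: int = 300
    rate_ortholog: float = 0.25
    rate_paralog: float = 0.10
    variant_count: int = 0
    variant_species: Optional[str] = None


class SimilarityConfig(_Strict):
    hard_mode: bool = False
    between_hit_prob: float = 0.1  # only used in hard mode


class DesignConfig(_Strict):
    species: list[str]
    time_points_h: list[float]
    n_bio: int = 3
    n_tech: int = 3
    reference_gene: str = "eIF4A"
    tech_noise_sd: float = 0.1


class RhythmConfig(_Strict):
    gene: str
    species: str
    baseline_ct: float
    amplitude_ct: float
    peak_time: float
    noise_sd: float = 0.3
    reference_baseline_ct: float = 20.0


class TruePercentEntry(_Strict):
    species: str
    time_h: float
    percent: float


class ElisaConfig(_Strict):
    curve_slope: float = 0.5
    nc_od: float = 0.05
    standard_points: list[float] = Field(default=[0.05, 0.1, 0.2, 0.5, 1.0])
    true_percent: list[TruePercentEntry] = Field(default_factory=list)
    input_rna_ng: float = 100.0
    noise_sd: float = 0.005
    n_bio_plates: int = 3


class GridConfig(_Strict):
    loose: float = 1e-3
    strict: float = 1e-18
    step_decades: int = 3


class StatsConfig(_Strict):
    n_perm: int = 999
    n_mc: int = 2000
    alpha: float = 0.05
    grid: GridConfig = Field(default_factory=GridConfig)


class NightConfig(_Strict):
    """Night period annotation: from sunset (start_h) to sunrise (end_h), wrapping midnight."""

    start_h: float = 20.5
    end_h: float = 6.5


class PipelineConfig(_Strict):
    seed: int = 0
    species: list[str]  # all species entering the homology comparison
    families: list[FamilyConfig]
    similarity: SimilarityConfig = Field(default_factory=SimilarityConfig)
    design: DesignConfig
    rhythms: list[RhythmConfig]
    elisa: ElisaConfig = Field(default_factory=ElisaConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    night: NightConfig = Field(default_factory=NightConfig)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
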