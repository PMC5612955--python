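"""Pipeline configuration: a strict YAML-backed schema.

Unknown keys are rejected (a typo must not silently change a threshold) and
the configuration round-trips unchanged through serialisation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import simulate
from .models import (
    CloneConfig,
    ConfigurationError,
    diploid_clone,
    trisomic_clone,
    x8_translocation_clone,
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChromosomeConfig(_Strict):
    name: str
    length: int = Field(gt=0)
    n_genes: int = Field(gt=0)
    line_per_mb: float = Field(default=150.0, ge=0)
    sine_per_mb: float = Field(default=180.0, ge=0)
    is_x: bool = False


class GenomeConfig(_Strict):
    chromosomes: list[ChromosomeConfig] = Field(
        default_factory=lambda: [
            ChromosomeConfig(name="chrX", length=171_000_000, n_genes=242,
                             line_per_mb=240.0, sine_per_mb=110.0, is_x=True),
            ChromosomeConfig(name="chr12", length=120_000_000, n_genes=351),
            ChromosomeConfig(name="chr8", length=129_000_000, n_genes=336),
        ]
    )
    mean_snps_per_gene: float = Field(default=3.0, gt=0)
    escape_fraction: float = Field(default=0.05, ge=0, le=1)
    baseline_expression: float = Field(default=500.0, gt=0)
    expression_log_sd: float = Field(default=0.5, ge=0)
    repeat_clustering_sd: float = Field(default=0.6, ge=0)
    n_region_blocks: int = Field(default=4, ge=0)

    def to_params(self) -> simulate.GenomeParams:
        return simulate.GenomeParams(
            chromosomes=[simulate.ChromosomeSpec(**c.model_dump()) for c in self.chromosomes],
            mean_snps_per_gene=self.mean_snps_per_gene,
            escape_fraction=self.escape_fraction,
            baseline_expression=self.baseline_expression,
            expression_log_sd=self.expression_log_sd,
            repeat_clustering_sd=self.repeat_clustering_sd,
            n_region_blocks=self.n_region_blocks,
        )


class CloneSpec(_Strict):
    clone_id: str
    kind: Literal["diploid", "trisomic", "x8"]
    transgene_chrom: str = "chrX"
    transgene_pos: int = Field(ge=0)
    transgene_allele: Literal["129", "Cast"] = "Cast"
    extra_allele: Literal["129", "Cast"] = "Cast"
    breakpoint: Optional[int] = None
    coating_fraction: float = Field(default=0.65, ge=0, le=1)

    def build(self, chromosomes: dict[str, int]) -> CloneConfig:
        if self.kind == "diploid":
            return diploid_clone(
                self.clone_id, chromosomes, self.transgene_chrom, self.transgene_pos,
                self.transgene_allele, self.coating_fraction,
            )
        if self.kind == "trisomic":
            return trisomic_clone(
                self.clone_id, chromosomes, self.transgene_chrom, self.transgene_pos,
                self.transgene_allele, self.extra_allele, self.coating_fraction,
            )
        return x8_translocation_clone(
            self.clone_id, chromosomes, self.transgene_pos,
            x_chrom=self.transgene_chrom, breakpoint=self.breakpoint,
            coating_fraction=self.coating_fraction,
        )


class SilencingConfig(_Strict):
    s_max: float = Field(default=1.0, ge=0, le=1)
    distance_halfwidth: float = Field(default=10e6, gt=0)
    base_weight: float = 0.3
    distance_weight: float = 0.3
    line_weight: float = 0.0015
    dispersion: float = Field(default=0.1, ge=0)

    def to_model(self, seed: int | None = None):
        from .models import SilencingModel

        return SilencingModel(seed=seed, **self.model_dump())


class FilterConfig(_Strict):
    min_snp_coverage: int = Field(default=5, ge=1)
    single_snp_min: int = Field(default=8, ge=1)
    delta_low: float = 0.1
    delta_high: float = 0.5
    category_high: float = 0.2
    category_low: float = 0.1

    @field_validator("delta_high")
    @classmethod
    def _ordered(cls, v, info):
        if "delta_low" in info.data and v <= info.data["delta_low"]:
            raise ValueError("delta_high must exceed delta_low")
        return v


class RankingGroup(_Strict):
    name: str
    chrom: str
    clone_ids: list[str]


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "results/pipeline"
    n_replicates: int = Field(default=2, ge=1)
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    silencing: SilencingConfig = Field(default_factory=SilencingConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    clones: list[CloneSpec] = Field(default_factory=list)
    ranking_groups: list[RankingGroup] = Field(default_factory=list)
    repeat_window: int = Field(default=1_000_000, gt=0)
    profile_span: int = Field(default=8000, gt=0)
    profile_bin: int = Field(default=200, gt=0)
    distance_half_widths: list[int] = Field(
        default_factory=lambda: [2_000_000, 20_000_000, 100_000_000]
    )
    distance_mode: Literal["nested", "annular"] = "nested"
    density_bin: int = Field(default=500_000, gt=0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def build_clones(self) -> list[CloneConfig]:
        chroms = {c.name: c.length for c in self.genome.chromosomes}
        clones = [spec.build(chroms) for spec in self.clones]
        ids = [c.clone_id for c in clones]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate clone_id in configuration")
        return clones


def default_config(seed: int = 0, outdir: str = "results/pipeline") -> PipelineConfig:
    """The stated default world: clones mirroring the four transgenic
    families (endogenous-locus X, distal X, trisomy-12 with the transgene on
    either the 129 or a Cast copy, and an X;8 translocation)."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        clones=[
            CloneSpec(clone_id="TgE-87", kind="diploid", transgene_chrom="chrX",
                      transgene_pos=103_480_000, transgene_allele="Cast",
                      coating_fraction=0.65),
            CloneSpec(clone_id="TgX-86", kind="diploid", transgene_chrom="chrX",
                      transgene_pos=134_400_000, transgene_allele="Cast",
                      coating_fraction=0.6),
            CloneSpec(clone_id="Tg12-55", kind="trisomic", transgene_chrom="chr12",
                      transgene_pos=104_500_000, transgene_allele="129",
                      coating_fraction=0.65),
            CloneSpec(clone_id="Tg12-292", kind="trisomic", transgene_chrom="chr12",
                      transgene_pos=89_400_000, transgene_allele="Cast",
                      coating_fraction=0.6),
            CloneSpec(clone_id="TgX8-267", kind="x8", transgene_chrom="chrX",
                      transgene_pos=110_000_000, coating_fraction=0.65),
        ],
        ranking_groups=[
            RankingGroup(name="X", chrom="chrX",
                         clone_ids=["TgE-87", "TgX-86", "TgX8-267"]),
            RankingGroup(name="12", chrom="chr12",
                         clone_ids=["Tg12-55", "Tg12-292"]),
            RankingGroup(name="8", chrom="chr8", clone_ids=["TgX8-267"]),
        ],
    )
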