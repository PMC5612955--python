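"""Domain objects shared across the pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to and
from 1-based formats (GTF) happens only at the I/O boundary.

The biological setting: F1 hybrid (129/Sv x Cast/Ei) mouse ES cell clones
carrying a doxycycline-inducible Xist transgene on chromosome X, on a trisomic
chromosome 12, or on an X;8 translocation product.  Induced Xist RNA coats the
carrying chromosome in cis in a fraction ``f`` of cells and silences the
targeted parental copy, shifting the allelic balance of every gene on that
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

ALLELES = ("129", "Cast")
REPEAT_CLASSES = ("LINE", "SINE")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class DegenerateInputError(ValueError):
    """Input for which the requested quantity is undefined (e.g. zero copies)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: TSS, strand, exonic SNP positions and simulation truth.

    ``baseline_expression`` is the expected allele-informative read count per
    diploid gene and replicate (lambda_g); ``escape_flag`` marks constitutive
    escapees whose silencing degree is forced to zero; ``evo_class`` tags the
    evolutionary stratum of X-linked genes (old = shared with chicken
    orthologous autosomes, new = mammal-specific additions).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    snp_positions: tuple[int, ...]
    baseline_expression: float = 500.0
    escape_flag: bool = False
    evo_class: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.snp_positions:
            raise ConfigurationError(f"{self.gene_id}: snp_positions must be non-empty")
        pos = tuple(self.snp_positions)
        if list(pos) != sorted(set(pos)):
            raise ConfigurationError(f"{self.gene_id}: snp_positions must be sorted and unique")
        if self.baseline_expression <= 0:
            raise ConfigurationError(f"{self.gene_id}: baseline_expression must be > 0")
        if self.evo_class not in ("old", "new", "none"):
            raise ConfigurationError(f"{self.gene_id}: bad evo_class {self.evo_class!r}")


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(
                f"repeat {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.repeat_class not in REPEAT_CLASSES:
            raise ConfigurationError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RegionBlock:
    name: str
    chrom: str
    start: int
    end: int


@dataclass
class GenomeModel:
    """Chromosomes, genes, repeats and optional named region blocks."""

    chromosomes: dict[str, int]
    genes: list[GeneAnnotation]
    repeats: list[RepeatElement] = field(default_factory=list)
    region_blocks: list[RegionBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome {name}: non-positive length")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ConfigurationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            L = self.chromosomes[g.chrom]
            if not (0 <= g.tss < L):
                raise ConfigurationError(f"{g.gene_id}: TSS {g.tss} outside {g.chrom} (len {L})")
        for r in self.repeats:
            if r.chrom not in self.chromosomes:
                raise ConfigurationError(f"repeat on unknown chromosome {r.chrom}")
            if r.end > self.chromosomes[r.chrom]:
                raise ConfigurationError(
                    f"repeat {r.chrom}:{r.start}-{r.end} extends past chromosome end"
                )
        by_chrom: dict[str, list[RegionBlock]] = {}
        for b in self.region_blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, blocks in by_chrom.items():
            blocks = sorted(blocks, key=lambda b: b.start)
            for a, b in zip(blocks, blocks[1:]):
                if b.start < a.end:
                    raise ConfigurationError(
                        f"region blocks {a.name} and {b.name} overlap on {chrom}"
                    )

    def genes_on(self, chrom: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class Segment:
    """A copy-number segment of a clone's genome.

    ``n_129``/``n_cast`` are parental copy counts for genes whose TSS lies in
    [start, end) of ``chrom``.  ``targeted_allele`` is set when one copy of
    that allele lies in cis with the Xist transgene and is silenced upon
    induction; None means the segment is not coated.  ``cis_anchor`` supplies
    a linear distance to the transgene for segments on a different chromosome
    record than the transgene (translocation products): distance =
    anchor_offset + |TSS - anchor_pos|, with anchor_pos the fusion breakpoint
    in this segment's native coordinates and anchor_offset the distance from
    the transgene to the fusion junction.
    """

    chrom: str
    start: int
    end: int
    n_129: int
    n_cast: int
    name: str = ""
    targeted_allele: Optional[str] = None
    cis_anchor: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n_129 < 0 or self.n_cast < 0:
            raise ConfigurationError(f"segment {self.name}: negative copy number")
        if self.end <= self.start:
            raise ConfigurationError(f"segment {self.name}: empty interval")
        if self.targeted_allele is not None and self.targeted_allele not in ALLELES:
            raise ConfigurationError(f"segment {self.name}: bad allele {self.targeted_allele!r}")

    @property
    def total_copies(self) -> int:
        return self.n_129 + self.n_cast


@dataclass
class CloneConfig:
    """Karyotype, transgene location and coating fraction for one ES clone."""

    clone_id: str
    segments: list[Segment]
    transgene_chrom: str
    transgene_pos: int
    transgene_allele: str
    coating_fraction: float = 0.65

    def __post_init__(self) -> None:
        if self.transgene_allele not in ALLELES:
            raise ConfigurationError(
                f"{self.clone_id}: transgene_allele must be one of {ALLELES}"
            )
        if not (0.0 <= self.coating_fraction <= 1.0):
            raise ConfigurationError(f"{self.clone_id}: coating_fraction outside [0, 1]")
        # segments must partition each chromosome they cover
        by_chrom: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start != a.end:
                    raise ConfigurationError(
                        f"{self.clone_id}: segments on {chrom} do not tile ({a.end} vs {b.start})"
                    )

    def segment_for(self, chrom: str, pos: int) -> Segment:
        for s in self.segments:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s
        raise KeyError(f"{self.clone_id}: no segment covering {chrom}:{pos}")

    def transgene_distance(self, chrom: str, pos: int) -> Optional[float]:
        """Linear distance from a position to the transgene, through fusion
        junctions where a cis anchor is configured; None when not in cis."""
        seg = self.segment_for(chrom, pos)
        if chrom == self.transgene_chrom:
            return float(abs(pos - self.transgene_pos))
        if seg.cis_anchor is not None:
            anchor_pos, anchor_offset = seg.cis_anchor
            return float(anchor_offset + abs(pos - anchor_pos))
        return None


@dataclass
class SilencingModel:
    """Ground-truth silencing degree for the simulator.

    The per-gene degree is ``s_g = s_max * (1 - escape) * clamp(w, 0, 1)``
    with ``w = base_weight + distance_weight * exp(-d / distance_halfwidth)
    + line_weight * (LINE count in the 1 Mb TSS window)`` and d the linear
    distance to the transgene; genes not in cis with the transgene have
    s_g = 0.  base_weight = 1 with zero distance/LINE weights gives uniform
    silencing; positive weights express the proximal- and LINE-facilitated
    silencing the analysis is meant to detect.
    """

    s_max: float = 0.8
    distance_halfwidth: float = 10e6
    base_weight: float = 1.0
    distance_weight: float = 0.0
    line_weight: float = 0.0
    dispersion: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_max <= 1.0):
            raise ConfigurationError("s_max must lie in [0, 1]")
        if self.distance_halfwidth <= 0:
            raise ConfigurationError("distance_halfwidth must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")


def diploid_clone(
    clone_id: str,
    chromosomes: dict[str, int],
    transgene_chrom: str,
    transgene_pos: int,
    transgene_allele: str = "Cast",
    coating_fraction: float = 0.65,
) -> CloneConfig:
    """40,XX-style clone: one 129 and one Cast copy of every chromosome; the
    transgene chromosome's ``transgene_allele`` copy is silenced in cis."""
    segs = []
    for chrom, length in chromosomes.items():
        targeted = transgene_allele if chrom == transgene_chrom else None
        segs.append(
            Segment(chrom, 0, length, 1, 1, name=chrom, targeted_allele=targeted)
        )
    return CloneConfig(
        clone_id, segs, transgene_chrom, transgene_pos, transgene_allele, coating_fraction
    )


def trisomic_clone(
    clone_id: str,
    chromosomes: dict[str, int],
    trisomic_chrom: str,
    transgene_pos: int,
    transgene_allele: str = "Cast",
    extra_allele: str = "Cast",
    coating_fraction: float = 0.65,
) -> CloneConfig:
    """41,XX,dup12-style clone: ``trisomic_chrom`` carries one 129 and two
    Cast copies (default) and the transgene sits on one of them."""
    segs = []
    for chrom, length in chromosomes.items():
        if chrom == trisomic_chrom:
            n_129, n_cast = (2, 1) if extra_allele == "129" else (1, 2)
            segs.append(
                Segment(
                    chrom, 0, length, n_129, n_cast,
                    name=chrom, targeted_allele=transgene_allele,
                )
            )
        else:
            segs.append(Segment(chrom, 0, length, 1, 1, name=chrom))
    return CloneConfig(
        clone_id, segs, trisomic_chrom, transgene_pos, transgene_allele, coating_fraction
    )


def x8_translocation_clone(
    clone_id: str,
    chromosomes: dict[str, int],
    transgene_pos: int,
    x_chrom: str = "chrX",
    a_chrom: str = "chr8",
    breakpoint: Optional[int] = None,
    coating_fraction: float = 0.65,
) -> CloneConfig:
    """40,XX,t(X;8)-style clone.

    The 129 X chromosome is fused to a duplicated Cast-origin distal segment
    of chromosome 8 (two intact chr8 copies remain).  The transgene lies on
    the fused 129 X, so induction silences the 129 copy of X-linked genes and
    one of the two Cast copies of distal chr8 genes.  ``breakpoint`` is the
    chr8 coordinate of the fusion (default: proximal third kept disomic,
    matching a duplication of the distal two-thirds).
    """
    x_len = chromosomes[x_chrom]
    a_len = chromosomes[a_chrom]
    if breakpoint is None:
        breakpoint = a_len // 3
    # distance from the transgene to the fusion junction, along the X portion
    junction_offset = abs(x_len - transgene_pos)
    segs = []
    for chrom, length in chromosomes.items():
        if chrom == x_chrom:
            segs.append(
                Segment(chrom, 0, length, 1, 1, name=f"{chrom}", targeted_allele="129")
            )
        elif chrom == a_chrom:
            segs.append(Segment(chrom, 0, breakpoint, 1, 1, name=f"{chrom}-proximal"))
            segs.append(
                Segment(
                    chrom, breakpoint, length, 1, 2,
                    name=f"{chrom}-distal",
                    targeted_allele="Cast",
                    cis_anchor=(breakpoint, junction_offset),
                )
            )
        else:
            segs.append(Segment(chrom, 0, length, 1, 1, name=chrom))
    return CloneConfig(clone_id, segs, x_chrom, transgene_pos, "129", coating_fraction)


__all__ = [
    "ALLELES",
    "REPEAT_CLASSES",
    "ConfigurationError",
    "DegenerateInputError",
    "GeneAnnotation",
    "RepeatElement",
    "RegionBlock",
    "GenomeModel",
    "Segment",
    "CloneConfig",
    "SilencingModel",
    "diploid_clone",
    "trisomic_clone",
    "x8_translocation_clone",
]
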