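"""Synthetic hybrid-cross world: genomes, silencing truth and allelic counts.

The generator emulates the statistical structure the downstream analysis
assumes: per-gene exonic SNPs, negative-binomially overdispersed totals,
binomial 129/Cast splits whose expectation follows karyotype and induction
state, a partial coating fraction, X-linked escapees, and LINE/SINE tracks
with the X enriched for LINEs.  It stands in for allele-specific RNA-seq of
the transgenic clones; it does not model read-level artefacts (mapping bias,
positional coverage) — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    ALLELES,
    CloneConfig,
    ConfigurationError,
    DegenerateInputError,
    GeneAnnotation,
    GenomeModel,
    RegionBlock,
    RepeatElement,
    SilencingModel,
)

#: length draws for simulated repeat elements (bp); LINEs are an order of
#: magnitude longer than SINEs, matching L1 vs B1/B2 element scale.
_REPEAT_LENGTH = {"LINE": 5000, "SINE": 300}

#: size of the piecewise-constant intensity domains used to cluster repeats,
#: so per-gene 1 Mb window counts vary between genomic neighbourhoods.
_REPEAT_DOMAIN_BP = 5_000_000


@dataclass
class ChromosomeSpec:
    """Simulation settings for one chromosome."""

    name: str
    length: int
    n_genes: int
    line_per_mb: float = 150.0
    sine_per_mb: float = 180.0
    is_x: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"{self.name}: non-positive length")
        if self.n_genes <= 0:
            raise ConfigurationError(f"{self.name}: non-positive gene count")
        if self.line_per_mb < 0 or self.sine_per_mb < 0:
            raise ConfigurationError(f"{self.name}: negative repeat density")


@dataclass
class GenomeParams:
    """Settings for :func:`simulate_genome`.

    Defaults state the world the analysis targets: mouse chromosomes X, 12
    and 8 at their approximate physical sizes with the gene counts evaluated
    by the allele-specific analysis (242 X, 351 chr12, 336 chr8 genes), the X
    LINE-enriched and SINE-depleted relative to autosomes, ~3 exonic SNPs per
    gene (the F1 129/Sv x Cast/Ei cross is SNP dense), 5% of X genes escaping,
    and mean allele-informative expression of 500 reads per gene.
    """

    chromosomes: list[ChromosomeSpec] = field(
        default_factory=lambda: [
            ChromosomeSpec("chrX", 171_000_000, 242, line_per_mb=240.0,
                           sine_per_mb=110.0, is_x=True),
            ChromosomeSpec("chr12", 120_000_000, 351, line_per_mb=150.0,
                           sine_per_mb=180.0),
            ChromosomeSpec("chr8", 129_000_000, 336, line_per_mb=150.0,
                           sine_per_mb=180.0),
        ]
    )
    mean_snps_per_gene: float = 3.0
    escape_fraction: float = 0.05
    baseline_expression: float = 500.0
    expression_log_sd: float = 0.5
    repeat_clustering_sd: float = 0.6
    n_region_blocks: int = 4
    gene_span: int = 20_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.escape_fraction <= 1.0):
            raise ConfigurationError("escape_fraction must lie in [0, 1]")
        if self.baseline_expression <= 0:
            raise ConfigurationError("baseline_expression must be positive")
        if self.mean_snps_per_gene <= 0:
            raise ConfigurationError("mean_snps_per_gene must be positive")


def _simulate_repeats(
    rng: np.random.Generator, spec: ChromosomeSpec, repeat_class: str,
    per_mb: float, clustering_sd: float,
) -> list[RepeatElement]:
    """Place repeats with piecewise-constant intensity so densities differ
    between Mb-scale neighbourhoods (real LINE/SINE distributions are highly
    clustered, which is what gives the 1 Mb TSS-window counts their spread)."""
    if per_mb == 0:
        return []
    n_domains = max(1, spec.length // _REPEAT_DOMAIN_BP)
    weights = np.exp(rng.normal(0.0, clustering_sd, size=n_domains))
    weights /= weights.sum()
    total = rng.poisson(per_mb * spec.length / 1e6)
    per_domain = rng.multinomial(total, weights)
    elem_len = _REPEAT_LENGTH[repeat_class]
    out: list[RepeatElement] = []
    bounds = np.linspace(0, spec.length, n_domains + 1).astype(int)
    for k, n_k in enumerate(per_domain):
        if n_k == 0:
            continue
        lo, hi = bounds[k], bounds[k + 1]
        starts = rng.integers(lo, max(lo + 1, hi - elem_len), size=n_k)
        for s in np.sort(starts):
            out.append(RepeatElement(spec.name, int(s), int(s) + elem_len, repeat_class))
    return out


def simulate_genome(params: GenomeParams, seed: int) -> GenomeModel:
    """Draw a genome: gene positions, strands, SNPs, expression, escape flags,
    clustered LINE/SINE tracks and equal-width region blocks A, B, ...

    Deterministic for a fixed seed.  Escape flags are assigned only on
    chromosomes marked ``is_x``; evolutionary classes on the X follow the
    centromere-proximal enrichment of young genes (new genes, like escapees,
    concentrate near the centromeric end).
    """
    rng = np.random.default_rng(seed)
    chromosomes = {c.name: c.length for c in params.chromosomes}
    genes: list[GeneAnnotation] = []
    repeats: list[RepeatElement] = []
    blocks: list[RegionBlock] = []

    for spec in params.chromosomes:
        tss = np.sort(rng.integers(0, spec.length - params.gene_span, size=spec.n_genes))
        strands = rng.choice(["+", "-"], size=spec.n_genes)
        lam = params.baseline_expression * np.exp(
            rng.normal(0.0, params.expression_log_sd, size=spec.n_genes)
            - params.expression_log_sd**2 / 2
        )
        if spec.is_x and params.escape_fraction > 0:
            # escapees concentrate toward the centromeric (low-coordinate) end
            p_escape = params.escape_fraction * 2.0 * (1.0 - tss / spec.length)
            escape = rng.random(spec.n_genes) < np.clip(p_escape, 0.0, 1.0)
        else:
            escape = np.zeros(spec.n_genes, dtype=bool)
        for i in range(spec.n_genes):
            n_snps = max(1, int(rng.poisson(params.mean_snps_per_gene)))
            offsets = rng.choice(params.gene_span, size=n_snps, replace=False)
            snps = tuple(sorted(int(tss[i]) + int(o) for o in offsets))
            if spec.is_x:
                evo = "new" if tss[i] < spec.length * 0.3 else "old"
            else:
                evo = "none"
            genes.append(
                GeneAnnotation(
                    gene_id=f"{spec.name}_g{i:04d}",
                    chrom=spec.name,
                    strand=str(strands[i]),
                    tss=int(tss[i]),
                    snp_positions=snps,
                    baseline_expression=float(lam[i]),
                    escape_flag=bool(escape[i]),
                    evo_class=evo,
                )
            )
        repeats.extend(
            _simulate_repeats(rng, spec, "LINE", spec.line_per_mb, params.repeat_clustering_sd)
        )
        repeats.extend(
            _simulate_repeats(rng, spec, "SINE", spec.sine_per_mb, params.repeat_clustering_sd)
        )
        if params.n_region_blocks > 0:
            bounds = np.linspace(0, spec.length, params.n_region_blocks + 1).astype(int)
            for k in range(params.n_region_blocks):
                blocks.append(
                    RegionBlock(chr(ord("A") + k), spec.name, int(bounds[k]), int(bounds[k + 1]))
                )
    return GenomeModel(chromosomes, genes, repeats, blocks)


def expected_cast_fraction(
    gene: GeneAnnotation,
    clone: CloneConfig,
    s_g: float,
    condition: str,
) -> float:
    """Expected Cast/all read fraction for one gene in one condition.

    Untreated, the fraction is the Cast copy share c_Cast / (c_Cast + c_129):
    0.5 for disomic segments, 2/3 when two of three copies are Cast.  Under
    doxycycline, induced Xist coats the transgene chromosome in a fraction f
    of cells and silences one targeted copy to degree s_g, removing f*s_g
    copy-equivalents of the targeted allele from the expressed pool:

        Cast-targeted:  (c_Cast - f*s_g) / (c_Cast + c_129 - f*s_g)
        129-targeted:    c_Cast / (c_Cast + c_129 - f*s_g)

    Genes on untargeted segments keep their untreated fraction.
    """
    if condition not in ("untreated", "nodox", "treated", "dox"):
        raise ConfigurationError(f"unknown condition {condition!r}")
    if not (0.0 <= s_g <= 1.0):
        raise ConfigurationError(f"s_g must lie in [0, 1], got {s_g}")
    seg = clone.segment_for(gene.chrom, gene.tss)
    total = seg.total_copies
    if total == 0:
        raise DegenerateInputError(f"{gene.gene_id}: zero total copies")
    if condition in ("untreated", "nodox") or seg.targeted_allele is None:
        return seg.n_cast / total
    f = clone.coating_fraction
    removed = f * s_g
    if seg.targeted_allele == "Cast":
        num = seg.n_cast - removed
    else:
        num = seg.n_cast
    denom = total - removed
    if denom <= 0:
        raise DegenerateInputError(f"{gene.gene_id}: no expressed copies remain")
    return num / denom


def silencing_degree(
    gene: GeneAnnotation,
    clone: CloneConfig,
    model: SilencingModel,
    line_count: float = 0.0,
) -> float:
    """Ground-truth silencing degree s_g in [0, 1] (see SilencingModel)."""
    d = clone.transgene_distance(gene.chrom, gene.tss)
    if d is None:
        return 0.0
    if gene.escape_flag:
        return 0.0
    w = (
        model.base_weight
        + model.distance_weight * np.exp(-d / model.distance_halfwidth)
        + model.line_weight * line_count
    )
    return model.s_max * float(np.clip(w, 0.0, 1.0))


def _line_counts_for(genome: GenomeModel, window_size: int = 1_000_000) -> dict[str, int]:
    # local import: repeats module holds the window-counting primitive
    from .repeats import count_repeats_in_tss_windows

    counts = count_repeats_in_tss_windows(
        repeats_table(genome), genes_table(genome),
        chrom_lengths=genome.chromosomes, window_size=window_size, repeat_class="LINE",
    )
    return dict(zip(counts["gene_id"], counts["count"]))


def genes_table(genome: GenomeModel) -> pd.DataFrame:
    """Gene annotation as a DataFrame (the package's tabular interchange)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genome.genes],
            "chrom": [g.chrom for g in genome.genes],
            "strand": [g.strand for g in genome.genes],
            "tss": [g.tss for g in genome.genes],
            "n_snps": [len(g.snp_positions) for g in genome.genes],
            "snp_positions": [",".join(map(str, g.snp_positions)) for g in genome.genes],
            "baseline_expression": [g.baseline_expression for g in genome.genes],
            "escape_flag": [g.escape_flag for g in genome.genes],
            "evo_class": [g.evo_class for g in genome.genes],
        }
    )


def repeats_table(genome: GenomeModel) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in genome.repeats],
            "start": [r.start for r in genome.repeats],
            "end": [r.end for r in genome.repeats],
            "repeat_class": [r.repeat_class for r in genome.repeats],
        }
    )


def true_silencing_table(
    genome: GenomeModel, clone: CloneConfig, model: SilencingModel
) -> pd.DataFrame:
    """Per-gene ground-truth silencing degrees for one clone (for parameter-
    recovery and calibration checks; not visible to the analysis stages)."""
    line_counts = _line_counts_for(genome) if model.line_weight != 0 else {}
    rows = []
    for g in genome.genes:
        s = silencing_degree(g, clone, model, line_counts.get(g.gene_id, 0.0))
        rows.append((g.gene_id, g.chrom, clone.clone_id, s))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "clone_id", "s_true"])


def simulate_counts(
    genome: GenomeModel,
    clone: CloneConfig,
    model: SilencingModel,
    condition: str = "both",
    n_replicates: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a SNP-level allelic count table for one clone.

    Per gene and replicate the total allele-informative read count is drawn
    negative-binomially (gamma-Poisson; Poisson in the dispersion -> 0 limit)
    around lambda_g scaled by copy number and residual expression under
    treatment; reads are apportioned uniformly-multinomially across the
    gene's SNPs and each SNP's reads split binomially between Cast and 129
    with the closed-form expected Cast fraction.

    Returns a tidy frame: sample_id, condition, replicate, gene_id, chrom,
    pos, n_129, n_cast.  Reproducible for a fixed seed.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    conditions = {"both": ["nodox", "dox"], "nodox": ["nodox"], "dox": ["dox"]}.get(condition)
    if conditions is None:
        raise ConfigurationError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    line_counts = _line_counts_for(genome) if model.line_weight != 0 else {}

    rows: list[tuple] = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{clone.clone_id}_{cond}_r{rep}"
            for g in genome.genes:
                seg = clone.segment_for(g.chrom, g.tss)
                if seg.total_copies == 0:
                    continue
                s_g = silencing_degree(g, clone, model, line_counts.get(g.gene_id, 0.0))
                p_cast = expected_cast_fraction(g, clone, s_g, cond)
                expressed = seg.total_copies
                if cond == "dox" and seg.targeted_allele is not None:
                    expressed = seg.total_copies - clone.coating_fraction * s_g
                mean_total = g.baseline_expression * expressed / 2.0
                if model.dispersion > 0:
                    lam = rng.gamma(1.0 / model.dispersion, mean_total * model.dispersion)
                else:
                    lam = mean_total
                total = int(rng.poisson(lam))
                n_snps = len(g.snp_positions)
                per_snp = rng.multinomial(total, np.full(n_snps, 1.0 / n_snps))
                cast = rng.binomial(per_snp, p_cast)
                for pos, n_tot, n_cast in zip(g.snp_positions, per_snp, cast):
                    rows.append(
                        (sample, cond, rep, g.gene_id, g.chrom, int(pos),
                         int(n_tot - n_cast), int(n_cast))
                    )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "replicate", "gene_id", "chrom", "pos",
                 "n_129", "n_cast"],
    )


def simulate_track_reads(
    genome: GenomeModel,
    enriched_genes: list[str] | set[str],
    reads_per_enriched_tss: int = 50,
    background_per_mb: float = 200.0,
    read_length: int = 50,
    peak_sd: float = 300.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a ChIP-like read-interval track: uniform background plus
    Gaussian peaks centred on the TSSs of ``enriched_genes`` (e.g. a
    CTCF-like factor bound at escapee promoters).  Returns BED-style
    chrom/start/end rows."""
    rng = np.random.default_rng(seed)
    enriched = set(enriched_genes)
    rows: list[tuple[str, int, int]] = []
    for chrom, length in genome.chromosomes.items():
        n_bg = rng.poisson(background_per_mb * length / 1e6)
        starts = rng.integers(0, max(1, length - read_length), size=n_bg)
        rows.extend((chrom, int(s), int(s) + read_length) for s in starts)
    for g in genome.genes:
        if g.gene_id not in enriched:
            continue
        centers = rng.normal(g.tss, peak_sd, size=reads_per_enriched_tss)
        length = genome.chromosomes[g.chrom]
        starts = np.clip(centers - read_length / 2, 0, length - read_length).astype(int)
        rows.extend((g.chrom, int(s), int(s) + read_length) for s in starts)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
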