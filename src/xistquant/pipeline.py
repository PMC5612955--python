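"""End-to-end pipeline stages over the library modules.

Each stage reads its inputs from and writes TSV/BED/YAML reports into the
configured output directory, so the CLI subcommands and the analysis
drivers stay thin.  Every output is reproducible byte-for-byte for a fixed
(config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, profiles, quantify, repeats as repeats_mod, silencing, simulate
from .config import PipelineConfig
from .models import GenomeModel
from .positional import DistanceBinSpec, density_track, region_block_composition, \
    silencing_by_distance

logger = logging.getLogger(__name__)


def _hash(cfg: PipelineConfig) -> str:
    # outdir does not influence any computed value; exclude it so runs into
    # different directories with one seed are byte-identical
    return io.config_hash(cfg.model_dump(exclude={"outdir"}))


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_genome(out: Path) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    genes = io.read_report(out / "genes.tsv")
    rep = io.read_bed(out / "repeats.bed", extra_columns=["repeat_class"])
    chroms = io.read_report(out / "chromosomes.tsv")
    lengths = dict(zip(chroms["chrom"], chroms["length"]))
    return genes, rep, lengths


def stage_simulate(cfg: PipelineConfig) -> GenomeModel:
    """Generate the genome, clone configurations, allelic count tables and a
    CTCF-like chromatin track enriched at escapee promoters."""
    out = _outdir(cfg)
    h = _hash(cfg)
    genome = simulate.simulate_genome(cfg.genome.to_params(), cfg.seed)
    clones = cfg.build_clones()
    model = cfg.silencing.to_model(cfg.seed)

    genes_df = simulate.genes_table(genome)
    io.write_report(genes_df, out / "genes.tsv", seed=cfg.seed, config_hash=h,
                    comment="gene annotation; tss 0-based")
    io.write_gene_annotation(genome.genes, out / "genes.gtf", fmt="gtf")
    rep_df = simulate.repeats_table(genome)
    io.write_bed(rep_df[["chrom", "start", "end", "repeat_class"]], out / "repeats.bed")
    io.write_report(
        pd.DataFrame({"chrom": list(genome.chromosomes),
                      "length": list(genome.chromosomes.values())}),
        out / "chromosomes.tsv", seed=cfg.seed, config_hash=h,
    )
    io.write_bed(
        pd.DataFrame(
            {
                "chrom": [b.chrom for b in genome.region_blocks],
                "start": [b.start for b in genome.region_blocks],
                "end": [b.end for b in genome.region_blocks],
                "name": [b.name for b in genome.region_blocks],
            }
        ),
        out / "region_blocks.bed",
    )
    io.write_clones(clones, out / "clones.yaml")

    for i, clone in enumerate(clones):
        counts = simulate.simulate_counts(
            genome, clone, model, condition="both",
            n_replicates=cfg.n_replicates, seed=cfg.seed + 1000 + i,
        )
        io.write_snp_counts(counts, out / f"counts_{clone.clone_id}.tsv",
                            seed=cfg.seed, config_hash=h)
        truth = simulate.true_silencing_table(genome, clone, model)
        io.write_report(truth, out / f"truth_{clone.clone_id}.tsv",
                        seed=cfg.seed, config_hash=h,
                        comment="simulation ground truth (not a pipeline input)")

    escapees = [g.gene_id for g in genome.genes if g.escape_flag]
    track = simulate.simulate_track_reads(
        genome, escapees, reads_per_enriched_tss=60, seed=cfg.seed + 500
    )
    io.write_bed(track, out / "track_CTCF.bed")
    with open(out / "gene_set_escapees.txt", "w") as fh:
        fh.write("# simulated constitutive escapees (ground truth)\n")
        fh.writelines(g + "\n" for g in escapees)
    logger.info("simulate: %d genes, %d repeats, %d clones",
                len(genome.genes), len(genome.repeats), len(clones))
    return genome


def stage_quantify(cfg: PipelineConfig) -> pd.DataFrame:
    """SNP filter, gene aggregation and karyotype-aware oriented ratios for
    every clone; writes gene_ratios.tsv."""
    out = _outdir(cfg)
    genes_df, _, _ = _load_genome(out)
    tss = dict(zip(genes_df["gene_id"], genes_df["tss"]))
    clones = io.read_clones(out / "clones.yaml")
    frames = []
    for clone in clones:
        counts = io.read_snp_counts(out / f"counts_{clone.clone_id}.tsv")
        rec = quantify.quantify_clone(
            counts, clone, gene_tss=tss,
            min_coverage=cfg.filters.min_snp_coverage,
            single_snp_min=cfg.filters.single_snp_min,
        )
        rec.insert(0, "clone_id", clone.clone_id)
        frames.append(rec)
        logger.info("quantify %s: %d SNP rows -> %d gene records",
                    clone.clone_id, len(counts), len(rec))
    ratios = pd.concat(frames, ignore_index=True)
    io.write_report(ratios, out / "gene_ratios.tsv", seed=cfg.seed, config_hash=_hash(cfg))
    return ratios


def clone_gene_stats(records: pd.DataFrame, pairing: str = "replicate") -> pd.DataFrame:
    """Replicate-mean treated ratio and delta per gene for one clone's
    oriented gene-level records."""
    calls = silencing.compute_delta(records, pairing=pairing)
    return (
        calls.groupby("gene_id")
        .agg(ratio_dox=("ratio_dox", "mean"), delta=("delta", "mean"))
        .reset_index()
    )


def stage_classify(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Delta ratios, affected calls and fractions per clone; cross-clone
    ranking into the three silencing categories per chromosome group; overlap
    of category III with the simulated escapee set."""
    out = _outdir(cfg)
    genes_df, _, _ = _load_genome(out)
    gene_chrom = dict(zip(genes_df["gene_id"], genes_df["chrom"]))
    ratios = io.read_report(out / "gene_ratios.tsv")
    h = _hash(cfg)

    all_calls, frac_rows = [], []
    per_clone_stats = {}
    for clone_id, rec in ratios.groupby("clone_id"):
        calls = silencing.compute_delta(rec)
        calls.insert(0, "clone_id", clone_id)
        calls["affected"] = silencing.call_affected(
            calls["delta"], cfg.filters.delta_low, cfg.filters.delta_high
        )
        all_calls.append(calls)
        per_clone_stats[clone_id] = clone_gene_stats(rec)
        # affected fraction on the clone's targeted chromosome(s)
        clone = next(c for c in io.read_clones(out / "clones.yaml")
                     if c.clone_id == clone_id)
        targeted = sorted({s.chrom for s in clone.segments if s.targeted_allele})
        for chrom in targeted:
            sub = calls[calls["gene_id"].map(gene_chrom) == chrom]
            if sub.empty:
                continue
            frac = silencing.affected_fraction(
                sub, cfg.filters.delta_low, cfg.filters.delta_high
            )
            frac.insert(0, "clone_id", clone_id)
            frac.insert(1, "chrom", chrom)
            frac_rows.append(frac)
    calls_df = pd.concat(all_calls, ignore_index=True)
    io.write_report(calls_df, out / "silencing_calls.tsv", seed=cfg.seed, config_hash=h)
    frac_df = pd.concat(frac_rows, ignore_index=True)
    io.write_report(frac_df, out / "affected_fractions.tsv", seed=cfg.seed, config_hash=h)

    categories = {}
    overlap_rows = []
    escapees = io.read_gene_set(out / "gene_set_escapees.txt")
    for grp in cfg.ranking_groups:
        frames = []
        for clone_id in grp.clone_ids:
            stats = per_clone_stats.get(clone_id)
            if stats is None:
                continue
            sub = stats[stats["gene_id"].map(gene_chrom) == grp.chrom].copy()
            sub["clone_id"] = clone_id
            frames.append(sub)
        if not frames:
            continue
        per_clone = pd.concat(frames, ignore_index=True)
        cat = silencing.rank_and_categorize(
            per_clone, thresholds=(cfg.filters.category_high, cfg.filters.category_low)
        )
        categories[grp.name] = cat
        io.write_report(cat, out / f"categories_{grp.name}.tsv", seed=cfg.seed, config_hash=h)
        grp_escapees = [g for g in escapees if gene_chrom.get(g) == grp.chrom]
        if grp_escapees:
            for target in silencing.CATEGORIES:
                pct = silencing.overlap_with_gene_sets(cat, grp_escapees, target)
                overlap_rows.append(
                    {"group": grp.name, "gene_set": "escapees", "category": target,
                     "percent_overlap": pct}
                )
    if overlap_rows:
        io.write_report(pd.DataFrame(overlap_rows), out / "overlaps.tsv",
                        seed=cfg.seed, config_hash=h)
    return categories


def stage_positional(cfg: PipelineConfig) -> pd.DataFrame:
    """Distance-bin summaries around each transgene, region-block category
    composition and gene-density tracks."""
    out = _outdir(cfg)
    genes_df, _, lengths = _load_genome(out)
    tss = dict(zip(genes_df["gene_id"], genes_df["tss"]))
    gene_chrom = dict(zip(genes_df["gene_id"], genes_df["chrom"]))
    ratios = io.read_report(out / "gene_ratios.tsv")
    clones = io.read_clones(out / "clones.yaml")
    h = _hash(cfg)
    spec = DistanceBinSpec(tuple(cfg.distance_half_widths), cfg.distance_mode)

    rows = []
    for clone in clones:
        rec = ratios[(ratios["clone_id"] == clone.clone_id)
                     & (ratios["condition"] == "dox")
                     & (ratios["chrom"] == clone.transgene_chrom)]
        per_gene = rec.groupby("gene_id", as_index=False)["oriented_ratio"].mean()
        if per_gene.empty:
            continue
        _, summary = silencing_by_distance(per_gene, tss, clone.transgene_pos, spec)
        summary.insert(0, "clone_id", clone.clone_id)
        rows.append(summary)
    dist_df = pd.concat(rows, ignore_index=True)
    io.write_report(dist_df, out / "distance_bins.tsv", seed=cfg.seed, config_hash=h)

    blocks = io.read_bed(out / "region_blocks.bed")
    block_rows = []
    for grp in cfg.ranking_groups:
        cat_path = out / f"categories_{grp.name}.tsv"
        if not cat_path.exists():
            continue
        cat = io.read_report(cat_path)
        comp = region_block_composition(
            cat, tss, gene_chrom, blocks[blocks["chrom"] == grp.chrom]
        )
        comp.insert(0, "group", grp.name)
        block_rows.append(comp)
    if block_rows:
        io.write_report(pd.concat(block_rows, ignore_index=True),
                        out / "region_block_composition.tsv", seed=cfg.seed, config_hash=h)

    for chrom, length in lengths.items():
        sub = genes_df[genes_df["chrom"] == chrom]
        track = density_track(sub["tss"].to_numpy(), int(length), cfg.density_bin)
        io.write_report(track, out / f"gene_density_{chrom}.tsv",
                        seed=cfg.seed, config_hash=h)
    return dist_df


def stage_repeats(cfg: PipelineConfig) -> pd.DataFrame:
    """1 Mb TSS-window LINE/SINE counts, category comparisons and LINE
    density tracks."""
    out = _outdir(cfg)
    genes_df, rep_df, lengths = _load_genome(out)
    h = _hash(cfg)

    window_frames = []
    for rc in ("LINE", "SINE"):
        counts = repeats_mod.count_repeats_in_tss_windows(
            rep_df, genes_df, chrom_lengths=lengths,
            window_size=cfg.repeat_window, repeat_class=rc,
        )
        window_frames.append(counts)
    windows = pd.concat(window_frames, ignore_index=True)
    io.write_report(windows, out / "repeat_windows.tsv", seed=cfg.seed, config_hash=h)

    comp_rows = []
    for grp in cfg.ranking_groups:
        cat_path = out / f"categories_{grp.name}.tsv"
        if not cat_path.exists():
            continue
        cat = io.read_report(cat_path)
        for rc in ("LINE", "SINE"):
            sub = windows[windows["repeat_class"] == rc]
            comp = repeats_mod.category_repeat_comparison(sub, cat)
            if comp.empty:
                continue
            comp.insert(0, "group", grp.name)
            comp.insert(1, "repeat_class", rc)
            comp_rows.append(comp)
    if comp_rows:
        io.write_report(pd.concat(comp_rows, ignore_index=True),
                        out / "repeat_comparisons.tsv", seed=cfg.seed, config_hash=h)

    for chrom, length in lengths.items():
        track = repeats_mod.repeat_density_track(rep_df, chrom, int(length),
                                                bin_size=1_000_000)
        io.write_report(track, out / f"line_density_{chrom}.tsv",
                        seed=cfg.seed, config_hash=h)
    return windows


def stage_profile(cfg: PipelineConfig) -> pd.DataFrame:
    """Category-averaged RPKM metaprofiles of the simulated CTCF-like track
    around X-linked and autosomal TSSs."""
    out = _outdir(cfg)
    genes_df, _, lengths = _load_genome(out)
    reads = io.read_bed(out / "track_CTCF.bed", extra_columns=[])
    h = _hash(cfg)
    frames = []
    for grp in cfg.ranking_groups:
        cat_path = out / f"categories_{grp.name}.tsv"
        if not cat_path.exists():
            continue
        cat = io.read_report(cat_path)
        gsub = genes_df[genes_df["chrom"] == grp.chrom]
        raw, ids = profiles.bin_reads_around_tss(
            reads, gsub, chrom_lengths=lengths,
            span=cfg.profile_span, bin_size=cfg.profile_bin,
        )
        mat = profiles.rpkm_normalize(
            raw, total_mapped_reads=len(reads), gene_ids=ids, track_label="CTCF",
            bin_size=cfg.profile_bin, span=cfg.profile_span,
        )
        avg = profiles.average_profile_by_category(mat, cat)
        avg.insert(0, "group", grp.name)
        frames.append(avg)
    prof = pd.concat(frames, ignore_index=True)
    io.write_report(prof, out / "profiles_CTCF.tsv", seed=cfg.seed, config_hash=h)
    return prof


STAGES = ["simulate", "quantify", "classify", "positional", "repeats", "profile"]


def run_all(cfg: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory."""
    stage_simulate(cfg)
    stage_quantify(cfg)
    stage_classify(cfg)
    stage_positional(cfg)
    stage_repeats(cfg)
    stage_profile(cfg)
    return _outdir(cfg)
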