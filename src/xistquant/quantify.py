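"""Gene-level allele-specific quantification.

SNP-level allelic counts are filtered for informativeness (>= 5 reads per
polymorphic site; >= 8 for genes whose only informative site survives the
per-SNP filter), summed per gene to N_129 and N_Cast, and expressed as the
Cast/all ratio N_Cast / (N_Cast + N_129).  Karyotype-aware transforms map
every clone onto a common diploid, target-on-Cast scale: trisomic segments
are converted with (N_Cast/2) / (N_Cast/2 + N_129) and clones whose transgene
sits on a 129 copy are mirrored with 1 - ratio, so silencing always pushes
the oriented ratio downward from 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import ALLELES, CloneConfig, ConfigurationError

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["sample_id", "condition", "replicate", "gene_id", "chrom", "pos",
               "n_129", "n_cast"]


def filter_informative_snps(counts: pd.DataFrame, min_coverage: int = 5) -> pd.DataFrame:
    """Keep SNP rows with allelic coverage n_129 + n_cast >= min_coverage."""
    if min_coverage < 1:
        raise ConfigurationError("min_coverage must be >= 1")
    if counts.empty:
        return counts.copy()
    keep = (counts["n_129"] + counts["n_cast"]) >= min_coverage
    return counts.loc[keep].reset_index(drop=True)


def aggregate_gene_counts(
    filtered: pd.DataFrame, single_snp_min: int = 8
) -> pd.DataFrame:
    """Sum informative-SNP counts to gene level.

    Input must already be SNP-filtered.  Genes whose retained SNPs number
    exactly one are kept only if that single site's coverage reaches
    ``single_snp_min`` (inclusive).  Returns one row per
    (sample_id, condition, replicate, gene_id) with N_129, N_Cast,
    n_informative_snps and the Cast/all ratio (NaN when no reads).
    """
    if filtered.empty:
        return pd.DataFrame(
            columns=["sample_id", "condition", "replicate", "gene_id", "chrom",
                     "N_129", "N_Cast", "n_informative_snps", "ratio"]
        )
    grouped = (
        filtered.groupby(["sample_id", "condition", "replicate", "gene_id"], sort=True)
        .agg(
            chrom=("chrom", "first"),
            N_129=("n_129", "sum"),
            N_Cast=("n_cast", "sum"),
            n_informative_snps=("pos", "size"),
        )
        .reset_index()
    )
    single = grouped["n_informative_snps"] == 1
    low_single = single & ((grouped["N_129"] + grouped["N_Cast"]) < single_snp_min)
    if low_single.any():
        logger.debug("dropping %d single-SNP gene records below coverage %d",
                     int(low_single.sum()), single_snp_min)
    out = grouped.loc[~low_single].reset_index(drop=True)
    out["ratio"] = compute_cast_ratio(out["N_Cast"], out["N_129"])
    return out


def compute_cast_ratio(n_cast, n_129):
    """Cast/all ratio N_Cast / (N_Cast + N_129); NaN where the total is zero.

    Accepts scalars or array-likes; always returns a float scalar or array.
    """
    n_cast = np.asarray(n_cast, dtype=float)
    n_129 = np.asarray(n_129, dtype=float)
    total = n_cast + n_129
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, n_cast / np.where(total > 0, total, 1.0), np.nan)
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def trisomic_to_disomic(n_cast, n_129):
    """Convert a two-Cast-copy baseline onto the diploid scale:
    (N_Cast/2) / (N_Cast/2 + N_129); maps an untreated 2/3 to 0.5."""
    return compute_cast_ratio(np.asarray(n_cast, dtype=float) / 2.0, n_129)


def disomic_mirror_trisomic(n_cast, n_129):
    """Mirror conversion for segments with two 129 and one Cast copy:
    N_Cast / (N_Cast + N_129/2)."""
    return compute_cast_ratio(n_cast, np.asarray(n_129, dtype=float) / 2.0)


def orient_ratio(ratio, transgene_allele: str):
    """Orient a ratio so the transgene-targeted allele's share decreases
    under silencing: identity when the transgene is on a Cast copy, the
    complement 1 - ratio when on a 129 copy."""
    if transgene_allele not in ALLELES:
        raise ConfigurationError(f"unknown allele label {transgene_allele!r}")
    if transgene_allele == "Cast":
        return ratio
    if np.isscalar(ratio):
        return 1.0 - ratio
    return 1.0 - np.asarray(ratio, dtype=float)


def apply_clone_transforms(records: pd.DataFrame, clone: CloneConfig,
                           gene_tss: dict[str, int] | None = None) -> pd.DataFrame:
    """Add karyotype-aware oriented ratios to a gene-level record table.

    Per gene the covering copy-number segment is looked up by TSS (falling
    back to the chromosome's single segment when no TSS map is given);
    trisomic segments are converted to the disomic scale, then the ratio is
    mirrored when the segment's targeted allele (or the clone's transgene
    allele for untargeted segments) is 129.  Adds columns ``segment``,
    ``converted_ratio`` and ``oriented_ratio``.
    """
    out = records.copy()
    segments, converted, oriented = [], [], []
    for row in out.itertuples():
        pos = gene_tss.get(row.gene_id, 0) if gene_tss else 0
        try:
            seg = clone.segment_for(row.chrom, pos)
        except KeyError:
            logger.warning("%s: no segment for %s:%s; treating as disomic untargeted",
                           clone.clone_id, row.chrom, pos)
            segments.append("none")
            converted.append(row.ratio)
            oriented.append(row.ratio)
            continue
        if (seg.n_129, seg.n_cast) == (1, 2):
            conv = trisomic_to_disomic(row.N_Cast, row.N_129)
        elif (seg.n_129, seg.n_cast) == (2, 1):
            conv = disomic_mirror_trisomic(row.N_Cast, row.N_129)
        else:
            conv = row.ratio
        allele = seg.targeted_allele or clone.transgene_allele
        segments.append(seg.name or seg.chrom)
        converted.append(conv)
        oriented.append(orient_ratio(conv, allele))
    out["segment"] = segments
    out["converted_ratio"] = converted
    out["oriented_ratio"] = oriented
    return out


def quantify_clone(
    counts: pd.DataFrame,
    clone: CloneConfig,
    gene_tss: dict[str, int] | None = None,
    min_coverage: int = 5,
    single_snp_min: int = 8,
) -> pd.DataFrame:
    """Full quantification for one clone: SNP filter, gene aggregation and
    karyotype-aware oriented ratios."""
    filtered = filter_informative_snps(counts, min_coverage)
    records = aggregate_gene_counts(filtered, single_snp_min)
    return apply_clone_transforms(records, clone, gene_tss)
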