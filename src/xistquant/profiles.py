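"""TSS metaprofiles of chromatin tracks.

Read intervals (ChIP-seq style) are counted in 200 bp bins spanning
TSS +/- 4 kb, RPKM-normalised, and averaged per silencing category.  Bins
are promoter-oriented: minus-strand gene profiles are reversed so upstream
is always leftward, and a read is assigned by its 5'-most oriented position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 8000
DEFAULT_BIN = 200


@dataclass
class ProfileMatrix:
    """RPKM profile matrix: one row per gene, one column per oriented bin.

    Bin k covers [TSS - span/2 + k*bin, TSS - span/2 + (k+1)*bin) in
    promoter-oriented coordinates (bin span//(2*bin) is the first bin
    downstream of the TSS).
    """

    track_label: str
    gene_ids: list[str]
    values: np.ndarray
    bin_size: int
    span: int
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), self.span // self.bin_size):
            raise ConfigurationError("profile matrix shape mismatch")
        if (self.values < 0).any():
            raise ConfigurationError("profile values must be non-negative")


def bin_reads_around_tss(
    reads: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    span: int = DEFAULT_SPAN,
    bin_size: int = DEFAULT_BIN,
) -> tuple[np.ndarray, list[str]]:
    """Raw read counts in oriented TSS bins.

    ``reads`` needs chrom/start/end (0-based half-open); ``genes`` needs
    gene_id/chrom/strand/tss.  A read's anchor is its 5'-most position in
    gene orientation (start for plus-strand genes, end - 1 for minus).
    Windows crossing a chromosome end keep their out-of-range bins zero
    (flagged in the log).  Returns (matrix genes x bins, gene_ids).
    """
    if span % bin_size != 0:
        raise ConfigurationError("span must be divisible by bin_size")
    n_bins = span // bin_size
    half = span // 2
    genes = genes.reset_index(drop=True)
    mat = np.zeros((len(genes), n_bins), dtype=float)
    for chrom, gsub in genes.groupby("chrom"):
        rsub = reads[reads["chrom"] == chrom]
        if chrom_lengths is not None and chrom in chrom_lengths:
            L = chrom_lengths[chrom]
            clipped = gsub[(gsub["tss"] < half) | (gsub["tss"] > L - half)]
            if len(clipped):
                logger.info("%d gene windows on %s cross a chromosome end (zero-filled)",
                            len(clipped), chrom)
        if rsub.empty:
            continue
        starts = rsub["start"].to_numpy(np.int64)
        ends = rsub["end"].to_numpy(np.int64)
        for i, g in gsub.iterrows():
            if g["strand"] == "+":
                offset = starts - g["tss"]
            else:
                offset = g["tss"] - (ends - 1)
            idx = np.floor_divide(offset + half, bin_size)
            valid = (idx >= 0) & (idx < n_bins)
            if valid.any():
                mat[i] += np.bincount(idx[valid].astype(int), minlength=n_bins)
    return mat, list(genes["gene_id"])


def rpkm_normalize(
    raw: np.ndarray,
    total_mapped_reads: int,
    gene_ids: list[str],
    track_label: str = "track",
    bin_size: int = DEFAULT_BIN,
    span: int = DEFAULT_SPAN,
) -> ProfileMatrix:
    """Reads-per-kilobase-per-million normalisation of a raw count matrix:
    value = count / (bin length in kb * total mapped reads in millions)."""
    if total_mapped_reads <= 0:
        raise DegenerateInputError("total_mapped_reads must be positive")
    scale = (bin_size / 1000.0) * (total_mapped_reads / 1e6)
    return ProfileMatrix(
        track_label=track_label,
        gene_ids=list(gene_ids),
        values=np.asarray(raw, dtype=float) / scale,
        bin_size=bin_size,
        span=span,
        total_mapped_reads=int(total_mapped_reads),
    )


def average_profile_by_category(
    profile: ProfileMatrix, categories: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted per-bin mean of gene profiles within each category.

    Profiled genes without a category are dropped (logged); empty categories
    are omitted.  Returns a tidy frame: category, bin index, bin start
    relative to the TSS, mean RPKM.
    """
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    labels = np.array([cat_map.get(g) for g in profile.gene_ids], dtype=object)
    n_missing = sum(1 for l in labels if l is None)
    if n_missing:
        logger.info("dropping %d profiled genes without a category", n_missing)
    rows = []
    half = profile.span // 2
    for cat in sorted({l for l in labels if l is not None}):
        sel = labels == cat
        mean = profile.values[sel].mean(axis=0)
        for k, v in enumerate(mean):
            rows.append(
                {
                    "track": profile.track_label,
                    "category": cat,
                    "bin": k,
                    "offset": -half + k * profile.bin_size,
                    "mean_rpkm": float(v),
                    "n_genes": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
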