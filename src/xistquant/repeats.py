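"""LINE/SINE context of gene promoters.

Repeat elements (RepeatMasker-style intervals carrying a LINE or SINE class)
are counted in windows centred on gene TSSs — 1 Mb by default — and the
counts compared between silencing categories with rank-sum tests.  An
element belongs to a window when its midpoint lies in
[TSS - w/2, TSS + w/2) (closed left, open right), so each element counts at
most once per window; overlap counting is available as a mode.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .models import REPEAT_CLASSES, ConfigurationError
from .positional import density_track
from .silencing import CATEGORIES, compare_ratio_distributions

logger = logging.getLogger(__name__)


def count_repeats_in_tss_windows(
    repeats: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    window_size: int = 1_000_000,
    repeat_class: str = "LINE",
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Count repeats of one class in TSS-centred windows.

    ``repeats`` needs chrom/start/end/repeat_class columns; ``genes`` needs
    gene_id/chrom/tss.  Windows are clipped at chromosome boundaries (when
    lengths are given) without rescaling the count.  ``mode`` is
    ``midpoint`` (default, containment of the element midpoint) or
    ``overlap`` (any overlap between element and window).  Returns
    gene_id/repeat_class/window_size/count.
    """
    if repeat_class not in REPEAT_CLASSES:
        raise ConfigurationError(f"unknown repeat class {repeat_class!r}")
    if mode not in ("midpoint", "overlap"):
        raise ConfigurationError(f"unknown counting mode {mode!r}")
    if window_size <= 0:
        raise ConfigurationError("window_size must be positive")
    sel = repeats[repeats["repeat_class"] == repeat_class]
    genes = genes.reset_index(drop=True)
    half = window_size // 2
    counts = np.zeros(len(genes), dtype=np.int64)
    for chrom, gsub in genes.groupby("chrom"):
        rsub = sel[sel["chrom"] == chrom]
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        lo = tss - half
        hi = tss + half
        if chrom_lengths is not None and chrom in chrom_lengths:
            lo = np.clip(lo, 0, chrom_lengths[chrom])
            hi = np.clip(hi, 0, chrom_lengths[chrom])
        if rsub.empty:
            continue
        if mode == "midpoint":
            mid = np.sort(
                ((rsub["start"].to_numpy(np.int64) + rsub["end"].to_numpy(np.int64)) // 2)
            )
            counts[gsub.index] = np.searchsorted(mid, hi, side="left") - np.searchsorted(
                mid, lo, side="left"
            )
        else:
            starts = np.sort(rsub["start"].to_numpy(np.int64))
            ends = np.sort(rsub["end"].to_numpy(np.int64))
            # overlap iff element.start < window.hi and element.end > window.lo
            counts[gsub.index] = np.searchsorted(starts, hi, side="left") - np.searchsorted(
                ends, lo, side="right"
            )
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "repeat_class": repeat_class,
            "window_size": window_size,
            "count": counts,
        }
    )


def category_repeat_comparison(
    window_counts: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of repeat-window counts between
    silencing categories (I vs II, I vs III, II vs III).

    Empty or singleton categories are skipped with a log entry.  Returns one
    row per pair with group sizes, medians, U and p.
    """
    df = window_counts.merge(categories[["gene_id", "category"]], on="gene_id")
    rows = []
    present = [c for c in CATEGORIES if (df["category"] == c).sum() >= 2]
    skipped = set(CATEGORIES) - set(present)
    if skipped:
        logger.info("categories too small for comparison: %s", sorted(skipped))
    for c1, c2 in itertools.combinations(present, 2):
        x = df.loc[df["category"] == c1, "count"].to_numpy(float)
        y = df.loc[df["category"] == c2, "count"].to_numpy(float)
        u, p = compare_ratio_distributions(x, y)
        rows.append(
            {
                "category_a": c1, "category_b": c2,
                "n_a": len(x), "n_b": len(y),
                "median_a": float(np.median(x)), "median_b": float(np.median(y)),
                "U": u, "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def repeat_density_track(
    repeats: pd.DataFrame, chrom: str, chrom_length: int,
    bin_size: int = 1_000_000, repeat_class: str = "LINE",
) -> pd.DataFrame:
    """Binned repeat-midpoint counts along one chromosome (1 Mb or 200 kb
    bins in the figures); conserves the element total."""
    if repeat_class not in REPEAT_CLASSES:
        raise ConfigurationError(f"unknown repeat class {repeat_class!r}")
    sel = repeats[(repeats["chrom"] == chrom) & (repeats["repeat_class"] == repeat_class)]
    mid = (sel["start"].to_numpy(np.int64) + sel["end"].to_numpy(np.int64)) // 2
    mid = np.clip(mid, 0, chrom_length - 1)
    return density_track(mid, chrom_length, bin_size)
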