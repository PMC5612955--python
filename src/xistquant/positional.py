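"""Silencing versus linear position: distance bins around the transgene
integration site, category composition of chromosomal region blocks, and
simple feature-density tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ConfigurationError

#: nested half-widths around the integration site; a "2 Mb bin" is the
#: +/- 2 Mb window (total span 4 Mb), so the 2/20/100 Mb bins correspond to
#: 4/40/200 Mb regions
DEFAULT_HALF_WIDTHS = (2_000_000, 20_000_000, 100_000_000)


@dataclass(frozen=True)
class DistanceBinSpec:
    half_widths: tuple[int, ...] = DEFAULT_HALF_WIDTHS
    mode: str = "nested"

    def __post_init__(self) -> None:
        hw = tuple(self.half_widths)
        if any(h <= 0 for h in hw) or list(hw) != sorted(set(hw)):
            raise ConfigurationError("half_widths must be strictly increasing and positive")
        if self.mode not in ("nested", "annular"):
            raise ConfigurationError(f"unknown bin mode {self.mode!r}")


def silencing_by_distance(
    ratios: pd.DataFrame,
    gene_tss: dict[str, int],
    integration_pos: int,
    spec: DistanceBinSpec = DistanceBinSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribute oriented treated ratios into distance bins around the
    transgene integration site.

    ``ratios`` needs gene_id and ``oriented_ratio`` columns for genes on the
    integration chromosome.  Nested mode assigns a gene to every bin whose
    half-width covers |TSS - integration|; annular mode only to the
    innermost.  Returns (per-gene bin membership, per-bin summary with n,
    median and quartiles; empty bins reported with n = 0).
    """
    df = ratios.copy()
    df["distance"] = df["gene_id"].map(gene_tss).astype(float).sub(integration_pos).abs()
    rows = []
    prev = 0
    for hw in spec.half_widths:
        if spec.mode == "nested":
            member = df["distance"] <= hw
        else:
            member = (df["distance"] > prev) & (df["distance"] <= hw)
            prev = hw
        sub = df.loc[member]
        rows.append((hw, sub))
    membership = pd.concat(
        [sub.assign(half_width=hw) for hw, sub in rows], ignore_index=True
    ) if rows else pd.DataFrame()
    summary = pd.DataFrame(
        [
            {
                "half_width": hw,
                "n_genes": len(sub),
                "median": sub["oriented_ratio"].median() if len(sub) else np.nan,
                "q1": sub["oriented_ratio"].quantile(0.25) if len(sub) else np.nan,
                "q3": sub["oriented_ratio"].quantile(0.75) if len(sub) else np.nan,
            }
            for hw, sub in rows
        ]
    )
    return membership, summary


def region_block_composition(
    categories: pd.DataFrame,
    gene_tss: dict[str, int],
    gene_chrom: dict[str, str],
    blocks: pd.DataFrame,
) -> pd.DataFrame:
    """Category fractions and gene density per named chromosomal block.

    ``blocks`` needs name/chrom/start/end columns (disjoint per chromosome).
    Fractions over the categories present in a block sum to one; blocks
    without genes are flagged (``n_genes`` 0, NaN fractions).  Density is
    genes per Mb of block length.
    """
    df = categories[["gene_id", "category"]].copy()
    df["tss"] = df["gene_id"].map(gene_tss)
    df["chrom"] = df["gene_id"].map(gene_chrom)
    out = []
    for blk in blocks.itertuples():
        sub = df[(df["chrom"] == blk.chrom) & (df["tss"] >= blk.start) & (df["tss"] < blk.end)]
        length_mb = (blk.end - blk.start) / 1e6
        row = {
            "block": blk.name, "chrom": blk.chrom, "start": blk.start, "end": blk.end,
            "n_genes": len(sub), "genes_per_mb": len(sub) / length_mb,
        }
        for cat in ("I", "II", "III"):
            row[f"frac_{cat}"] = (
                (sub["category"] == cat).mean() if len(sub) else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


def density_track(positions, chrom_length: int, bin_size: int) -> pd.DataFrame:
    """Count features in half-open bins [k*b, (k+1)*b) along a chromosome.

    A feature exactly on a bin boundary belongs to the right (higher) bin.
    Totals are conserved for every bin size.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= chrom_length):
        raise ConfigurationError("positions outside [0, chrom_length)")
    n_bins = int(np.ceil(chrom_length / bin_size))
    counts = np.bincount(pos // bin_size, minlength=n_bins) if pos.size else np.zeros(
        n_bins, dtype=int
    )
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    return pd.DataFrame(
        {"start": starts, "end": np.minimum(starts + bin_size, chrom_length),
         "count": counts}
    )
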