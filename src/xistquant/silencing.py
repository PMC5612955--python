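"""Silencing calls and chromosome-wide categorisation.

The per-gene effect statistic is the delta ratio, the oriented Cast/all
ratio without doxycycline minus the ratio with doxycycline; because only a
fraction of cells is ever coated by induced Xist, genes with delta in
[0.1, 0.5] are called affected.  Ranking genes by their cross-clone averaged
treated ratio yields three categories: (I) efficiently silenced, (II)
partially affected, (III) not silenced.
"""

from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .models import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

CATEGORIES = ("I", "II", "III")

#: averaged-delta boundaries for the three categories; consistent with the
#: 0.1 affected cutoff (III below it) and splitting the affected range at 0.2
DEFAULT_CATEGORY_THRESHOLDS = (0.2, 0.1)


def compute_delta(records: pd.DataFrame, pairing: str = "replicate") -> pd.DataFrame:
    """Per-gene silencing calls from oriented gene-level records.

    ``records`` must carry condition in {nodox, dox}, replicate, gene_id and
    ``oriented_ratio``.  With replicate pairing (default) replicate k without
    doxycycline is paired with replicate k with doxycycline; ``pooled`` first
    averages replicates within condition.  Genes missing in either condition
    are excluded (logged).  Returns gene_id, replicate, ratio_nodox,
    ratio_dox and delta = ratio_nodox - ratio_dox.
    """
    if pairing not in ("replicate", "pooled"):
        raise ConfigurationError(f"unknown pairing mode {pairing!r}")
    df = records.copy()
    if pairing == "pooled":
        df = (
            df.groupby(["gene_id", "condition"], as_index=False)["oriented_ratio"].mean()
        )
        df["replicate"] = 0
    wide = df.pivot_table(
        index=["gene_id", "replicate"], columns="condition",
        values="oriented_ratio", aggfunc="mean",
    )
    n_before = wide.shape[0]
    wide = wide.dropna(subset=[c for c in ("nodox", "dox") if c in wide.columns])
    if "nodox" not in wide.columns or "dox" not in wide.columns:
        logger.info("one condition entirely missing; no deltas computed")
        return pd.DataFrame(columns=["gene_id", "replicate", "ratio_nodox",
                                     "ratio_dox", "delta"])
    if wide.shape[0] < n_before:
        logger.info("excluded %d gene/replicate pairs missing one condition",
                    n_before - wide.shape[0])
    out = wide.reset_index()
    out = out.rename(columns={"nodox": "ratio_nodox", "dox": "ratio_dox"})
    out["delta"] = out["ratio_nodox"] - out["ratio_dox"]
    return out[["gene_id", "replicate", "ratio_nodox", "ratio_dox", "delta"]]


def call_affected(delta, low: float = 0.1, high: float = 0.5):
    """True where low <= delta <= high (both bounds inclusive)."""
    if np.isscalar(delta):
        return bool(low <= delta <= high)
    d = np.asarray(delta, dtype=float)
    return (d >= low) & (d <= high)


def affected_fraction(
    calls: pd.DataFrame, low: float = 0.1, high: float = 0.5,
    chroms: list[str] | None = None, gene_chrom: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Percentage of evaluable genes called affected, per replicate.

    Optionally restrict to genes on ``chroms`` (requires a gene -> chromosome
    map).  Raises on zero evaluable genes.
    """
    df = calls.copy()
    if chroms is not None:
        if gene_chrom is None:
            raise ConfigurationError("chromosome filter requires a gene_chrom map")
        df = df[df["gene_id"].map(gene_chrom).isin(chroms)]
    if df.empty:
        raise DegenerateInputError("no evaluable genes for affected_fraction")
    df = df.assign(affected=call_affected(df["delta"], low, high))
    out = (
        df.groupby("replicate")
        .agg(n_genes=("gene_id", "size"), n_affected=("affected", "sum"))
        .reset_index()
    )
    out["percent_affected"] = 100.0 * out["n_affected"] / out["n_genes"]
    return out


def rank_and_categorize(
    per_clone: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_CATEGORY_THRESHOLDS,
    method: str = "delta",
) -> pd.DataFrame:
    """Average oriented treated ratios across clones, rank, and categorise.

    ``per_clone`` needs one row per (gene_id, clone_id) with ``ratio_dox``
    (oriented, post-conversion) and ``delta`` columns, typically replicate
    means.  Genes are averaged unweighted over the clones where they are
    evaluable and ranked ascending by averaged treated ratio (strongest
    silencing first; ties broken by gene_id).  Categories:

    - ``delta`` (default): I if averaged delta >= thresholds[0], II if
      >= thresholds[1], III otherwise.
    - ``tertile``: the ranked list is split into three equal-size groups.
    """
    if method not in ("delta", "tertile"):
        raise ConfigurationError(f"unknown categorisation method {method!r}")
    avg = (
        per_clone.groupby("gene_id")
        .agg(avg_ratio_dox=("ratio_dox", "mean"), avg_delta=("delta", "mean"),
             n_clones=("clone_id", "nunique"))
        .reset_index()
    )
    avg = avg.sort_values(["avg_ratio_dox", "gene_id"], kind="stable").reset_index(drop=True)
    avg["rank"] = np.arange(1, len(avg) + 1)
    if method == "delta":
        hi, lo = thresholds
        avg["category"] = np.where(
            avg["avg_delta"] >= hi, "I", np.where(avg["avg_delta"] >= lo, "II", "III")
        )
    else:
        cuts = np.array_split(avg.index.to_numpy(), 3)
        cat = np.empty(len(avg), dtype=object)
        for c, idx in zip(CATEGORIES, cuts):
            cat[idx] = c
        avg["category"] = cat
    return avg


def overlap_with_gene_sets(
    categories: pd.DataFrame, gene_set, target_category: str
) -> float:
    """Percentage of the external gene set (restricted to ranked genes) that
    falls in ``target_category``."""
    if target_category not in CATEGORIES:
        raise ConfigurationError(f"unknown category {target_category!r}")
    ranked = set(categories["gene_id"])
    inter = set(gene_set) & ranked
    if not inter:
        raise DegenerateInputError("gene set does not intersect ranked genes")
    in_cat = set(categories.loc[categories["category"] == target_category, "gene_id"])
    return 100.0 * len(inter & in_cat) / len(inter)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration over group assignments
    (used below n = 20 with no ties; also the tests' brute-force oracle)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * len(b) / 2
    count = 0
    total = comb(len(pooled), n1)
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return float(u_obs), count / total


def compare_ratio_distributions(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two ratio samples.

    Returns (U statistic of the first sample, p value).  Exact enumeration
    is used when both samples are small (<= ``exact_max_n``) and tie-free;
    otherwise the tie-corrected normal approximation.  Degenerate input with
    every value identical across both groups yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= exact_max_n and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def category_expression_summary(
    categories: pd.DataFrame, expression: dict[str, float] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive expression statistics per category plus pairwise
    Mann-Whitney tests (efficiently silenced X-linked genes are expected to
    sit lower than escapees).

    Returns (summary, tests).  Categories with fewer than two genes are
    summarised but excluded from testing (logged); empty categories are
    omitted.
    """
    expr = pd.Series(expression, dtype=float)
    df = categories[["gene_id", "category"]].copy()
    df["expression"] = df["gene_id"].map(expr)
    df = df.dropna(subset=["expression"])
    if (df["expression"] <= 0).any():
        raise ConfigurationError("expression values must be positive")
    summary = (
        df.groupby("category")
        .agg(n=("gene_id", "size"), mean=("expression", "mean"),
             median=("expression", "median"))
        .reset_index()
    )
    rows = []
    present = [c for c in CATEGORIES if c in set(df["category"])]
    for c1, c2 in itertools.combinations(present, 2):
        x = df.loc[df["category"] == c1, "expression"].to_numpy()
        y = df.loc[df["category"] == c2, "expression"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            logger.info("skipping %s vs %s: category too small", c1, c2)
            continue
        u, p = compare_ratio_distributions(x, y)
        rows.append((c1, c2, u, p))
    tests = pd.DataFrame(rows, columns=["category_a", "category_b", "U", "p_value"])
    return summary, tests
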