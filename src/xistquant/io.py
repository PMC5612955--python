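"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; GTF (1-based closed)
is converted at this boundary only.  All TSV reports carry a provenance
comment (seed and configuration hash) in their header.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from .models import (
    CloneConfig,
    ConfigurationError,
    GeneAnnotation,
    Segment,
)
from .quantify import SNP_COLUMNS

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- annotation

_TSV_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "snp_positions",
                     "baseline_expression", "escape_flag", "evo_class"]


def read_gene_annotation(path, fmt: str = "tsv") -> list[GeneAnnotation]:
    """Read gene annotation from TSV (native) or GTF.

    GTF ``gene`` features are converted from 1-based closed to the internal
    0-based half-open convention; the TSS is the start for plus-strand and
    the end for minus-strand genes.  Duplicate gene_ids are rejected.  GTF
    rows carry no SNP/expression metadata, so those fields take defaults
    (a single placeholder SNP at the TSS).
    """
    path = Path(path)
    if fmt == "tsv":
        genes = _read_gene_tsv(path)
    elif fmt == "gtf":
        genes = _read_gene_gtf(path)
    else:
        raise ConfigurationError(f"unknown annotation format {fmt!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    if not genes:
        logger.warning("%s: empty annotation", path)
    return genes


def _read_gene_tsv(path: Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty and df.columns.empty:
        return []
    missing = set(_TSV_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        out.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                snp_positions=tuple(int(p) for p in str(row.snp_positions).split(",")),
                baseline_expression=float(row.baseline_expression),
                escape_flag=bool(row.escape_flag),
                evo_class=str(row.evo_class),
            )
        )
    return out


def _read_gene_gtf(path: Path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{lineno}: invalid GTF interval {start}-{end}")
            gene_id = None
            for item in attrs.rstrip(";").split(";"):
                key, _, value = item.strip().partition(" ")
                if key == "gene_id":
                    gene_id = value.strip().strip('"')
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF 1-based closed -> 0-based half-open [start-1, end)
            tss = start_i - 1 if strand == "+" else end_i - 1
            out.append(
                GeneAnnotation(
                    gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                    snp_positions=(tss,),
                )
            )
    return out


def write_gene_annotation(genes: list[GeneAnnotation], path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tss": g.tss,
                "snp_positions": ",".join(map(str, g.snp_positions)),
                "baseline_expression": g.baseline_expression,
                "escape_flag": g.escape_flag, "evo_class": g.evo_class,
            }
            for g in genes
        ]
        with open(path, "w") as fh:
            fh.write("# gene annotation; coordinates 0-based half-open; tss 0-based\n")
            pd.DataFrame(rows, columns=_TSV_GENE_COLUMNS).to_csv(fh, sep="\t", index=False)
    elif fmt == "gtf":
        with open(path, "w") as fh:
            fh.write("## gene annotation; GTF, 1-based closed coordinates\n")
            for g in genes:
                span = max(g.snp_positions) - g.tss + 1 if g.strand == "+" else 1
                if g.strand == "+":
                    start, end = g.tss + 1, g.tss + max(span, 1)
                else:
                    start, end = max(1, g.tss + 1 - span + 1), g.tss + 1
                fh.write(
                    f"{g.chrom}\txistquant\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )
    else:
        raise ConfigurationError(f"unknown annotation format {fmt!r}")


# ------------------------------------------------------------------- counts

def read_snp_counts(path) -> pd.DataFrame:
    """Read a SNP-level allelic count table (TSV), validating columns and
    non-negativity of counts and positions."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("n_129", "n_cast", "pos"):
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative values in column {col}")
    return df[SNP_COLUMNS]


def write_snp_counts(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    write_report(df[SNP_COLUMNS], path, seed=seed, config_hash=config_hash,
                 comment="SNP allelic counts; pos 0-based")


# --------------------------------------------------------------------- BED

def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end (+ name...).

    Intervals with end <= start or negative coordinates are rejected.
    """
    names = ["chrom", "start", "end"] + (extra_columns or ["name"])
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: invalid BED intervals (end <= start or negative)")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# BED; 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False, header=False)


def read_gene_set(path) -> list[str]:
    """Plain-text gene list, one gene_id per line; '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ----------------------------------------------------------------- reports

def write_report(df: pd.DataFrame, path, seed=None, config_hash=None,
                 comment: str | None = None) -> None:
    """Write a TSV report with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# xistquant report: {path.name}\n")
        if comment:
            fh.write(f"# {comment}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------------- clones

def clone_to_dict(clone: CloneConfig) -> dict:
    return {
        "clone_id": clone.clone_id,
        "transgene_chrom": clone.transgene_chrom,
        "transgene_pos": clone.transgene_pos,
        "transgene_allele": clone.transgene_allele,
        "coating_fraction": clone.coating_fraction,
        "segments": [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "n_129": s.n_129, "n_cast": s.n_cast, "name": s.name,
                "targeted_allele": s.targeted_allele,
                "cis_anchor": list(s.cis_anchor) if s.cis_anchor else None,
            }
            for s in clone.segments
        ],
    }


def clone_from_dict(d: dict) -> CloneConfig:
    segs = [
        Segment(
            chrom=s["chrom"], start=s["start"], end=s["end"],
            n_129=s["n_129"], n_cast=s["n_cast"], name=s.get("name", ""),
            targeted_allele=s.get("targeted_allele"),
            cis_anchor=tuple(s["cis_anchor"]) if s.get("cis_anchor") else None,
        )
        for s in d["segments"]
    ]
    return CloneConfig(
        clone_id=d["clone_id"], segments=segs,
        transgene_chrom=d["transgene_chrom"], transgene_pos=d["transgene_pos"],
        transgene_allele=d["transgene_allele"],
        coating_fraction=d.get("coating_fraction", 0.65),
    )


def write_clones(clones: list[CloneConfig], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"clones": [clone_to_dict(c) for c in clones]}, fh, sort_keys=False)


def read_clones(path) -> list[CloneConfig]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [clone_from_dict(d) for d in data["clones"]]


def config_hash(obj) -> str:
    """Stable short hash of any YAML-serialisable configuration object."""
    text = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
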