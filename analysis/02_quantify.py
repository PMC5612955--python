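"""Quantify allele-specific expression per clone: filter informative SNPs
(>= 5 reads; >= 8 for single-SNP genes), sum to gene-level N_129/N_Cast and
compute Cast/all ratios with karyotype-aware conversion and orientation.

Untreated ratios should sit at the copy-number baselines: 0.5 for disomic
chromosomes, ~0.66 where two of three copies are Cast."""

from common import get_config
from xistquant.pipeline import stage_quantify

cfg = get_config(__doc__)
ratios = stage_quantify(cfg)

base = (
    ratios[ratios["condition"] == "nodox"]
    .groupby(["clone_id", "segment"])["ratio"]
    .agg(["mean", "size"])
)
print(f"{len(ratios)} gene-level records -> {cfg.outdir}/gene_ratios.tsv")
print("untreated Cast/all ratio by clone and copy-number segment:")
print(base.round(3).to_string())
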