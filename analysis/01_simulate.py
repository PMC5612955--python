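"""Generate the synthetic world: a hybrid 129/Sv x Cast/Ei genome (chrX
LINE-enriched, 5% X-linked escapees), five transgenic clone configurations
(endogenous-locus X, distal X, two trisomy-12 clones, one X;8 translocation)
and SNP-level allelic count tables for both doxycycline conditions."""

from common import get_config
from xistquant.pipeline import stage_simulate

cfg = get_config(__doc__)
genome = stage_simulate(cfg)

n_esc = sum(g.escape_flag for g in genome.genes)
n_line = sum(r.repeat_class == "LINE" for r in genome.repeats)
print(f"genome: {len(genome.genes)} genes on {len(genome.chromosomes)} chromosomes")
print(f"  {n_esc} X-linked escapees, {n_line} LINEs, "
      f"{len(genome.repeats) - n_line} SINEs")
print(f"wrote genome, {len(cfg.clones)} clone count tables and the CTCF-like "
      f"track to {cfg.outdir}")
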