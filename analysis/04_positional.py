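"""Relate silencing to linear position: treated oriented ratios in nested
2/20/100 Mb windows around each transgene integration site (proximal genes
should silence more), category composition of chromosomal blocks A-D and
gene-density tracks."""

from common import get_config
from xistquant.pipeline import stage_positional

cfg = get_config(__doc__)
dist = stage_positional(cfg)

print("median treated oriented ratio by distance window (lower = more silenced):")
piv = dist.pivot(index="clone_id", columns="half_width", values="median")
piv.columns = [f"±{hw // 1_000_000} Mb" for hw in piv.columns]
print(piv.round(3).to_string())
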