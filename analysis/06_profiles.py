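"""Chromatin metaprofiles: the CTCF-like track averaged in 200 bp bins over
TSS +/- 4 kb (RPKM) per silencing category.  The simulated factor binds
escapee promoters, so category III on the X should peak at the TSS while
autosomal categories stay flat."""

from common import get_config
from xistquant.pipeline import stage_profile

cfg = get_config(__doc__)
prof = stage_profile(cfg)

center = prof[(prof["bin"] >= 18) & (prof["bin"] <= 21)]
flank = prof[(prof["bin"] < 5) | (prof["bin"] > 34)]
print("TSS-center minus flank mean RPKM per group and category:")
for (grp, cat), sub in center.groupby(["group", "category"]):
    f = flank[(flank["group"] == grp) & (flank["category"] == cat)]["mean_rpkm"].mean()
    print(f"  group {grp:>2} category {cat:>3}: {sub['mean_rpkm'].mean() - f:+.2f}")
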