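"""Repeat context of silencing: LINE and SINE elements counted in 1 Mb
windows centred on every TSS, compared between silencing categories with
two-sided rank-sum tests, plus LINE-density tracks per chromosome."""

from common import get_config
from xistquant.pipeline import stage_repeats
from xistquant import io

cfg = get_config(__doc__)
stage_repeats(cfg)

comp = io.read_report(f"{cfg.outdir}/repeat_comparisons.tsv")
sel = comp[(comp["category_a"] == "I") & (comp["category_b"] == "III")]
print("category I vs III repeat counts in 1 Mb TSS windows:")
for _, r in sel.iterrows():
    direction = ">" if r["median_a"] > r["median_b"] else "<="
    print(f"  group {r['group']:>2} {r['repeat_class']}: median "
          f"{r['median_a']:.0f} {direction} {r['median_b']:.0f}, "
          f"p = {r['p_value']:.2e}")
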