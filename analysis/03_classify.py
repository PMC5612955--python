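"""Call silencing per gene (delta = untreated minus treated oriented ratio;
affected when delta is in [0.1, 0.5]), rank genes by cross-clone averaged
treated ratio and split each chromosome group into categories I (efficiently
silenced), II (partially affected) and III (not silenced); overlap category
III with the simulated escapee list."""

import pandas as pd

from common import get_config
from xistquant.pipeline import stage_classify
from xistquant import io

cfg = get_config(__doc__)
categories = stage_classify(cfg)

frac = io.read_report(f"{cfg.outdir}/affected_fractions.tsv")
print("percent of genes affected (delta in [0.1, 0.5]) per clone and chromosome:")
print(frac.groupby(["clone_id", "chrom"])["percent_affected"].mean()
      .round(1).to_string())
for name, cat in categories.items():
    sizes = cat["category"].value_counts().reindex(["I", "II", "III"], fill_value=0)
    print(f"group {name}: {dict(sizes)}")
overlaps = io.read_report(f"{cfg.outdir}/overlaps.tsv")
iii = overlaps[(overlaps["category"] == "III")]
for _, r in iii.iterrows():
    print(f"  {r['percent_overlap']:.0f}% of simulated escapees fall in "
          f"category III of group {r['group']}")
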