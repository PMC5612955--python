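# xistquant

Allele-specific quantification of Xist-mediated gene silencing in hybrid
mouse ES cells.

## The problem

Xist is the long non-coding RNA that triggers X chromosome inactivation
(XCI): it spreads in *cis* along the chromosome it is transcribed from and
silences genes chromosome-wide. Why some genes (and some chromosomes) are
silenced efficiently while others escape is a central question in dosage
compensation. One powerful experimental design induces Xist ectopically —
from a doxycycline-responsive transgene placed at different positions on the
X, on a trisomic autosome, or on an X;autosome translocation — in F1 hybrid
(129/Sv × Cast/Ei) ES cells, and reads out silencing allele-specifically
from RNA-seq SNP counts.

`xistquant` implements the complete downstream analysis for that design, and
a synthetic data generator with the same statistical structure, so every
stage is testable without external sequencing data.

## The core statistics

For each gene, 129- and Cast-specific reads over its exonic SNPs are summed
to N₁₂₉ and N_Cast (per-SNP coverage ≥ 5 reads; ≥ 8 for genes with a single
informative SNP), giving the **Cast/all ratio**

    r = N_Cast / (N_Cast + N₁₂₉)

which is 0.5 for a balanced diploid locus and 2/3 where two of three copies
are Cast (trisomy 12, or the duplicated Cast chr8 segment of an X;8
translocation). Silencing of one targeted copy in a coated fraction *f* of
cells with degree *s* moves the treated ratio to

    r_dox = (c_Cast − f·s) / (c_Cast + c₁₂₉ − f·s)      (Cast copy targeted)

Two transformations place every clone on a common scale: trisomic segments
are converted to the disomic scale, r′ = (N_Cast/2)/(N_Cast/2 + N₁₂₉), and
clones whose transgene sits on a 129 copy are mirrored (1 − r), so silencing
always pushes the oriented ratio down from 0.5. The per-gene effect is the
**Δ ratio** = r(−dox) − r(+dox); genes with Δ ∈ [0.1, 0.5] are called
*affected* (the upper bound reflects partial coating, f ≈ 0.5–0.7). Ranking
genes by their cross-clone averaged treated ratio yields three categories:
**I** efficiently silenced, **II** partially affected, **III** not silenced.
Around these sit distance-bin analysis (±2/20/100 Mb windows around the
integration site), LINE/SINE counts in 1 Mb TSS windows with rank-sum
comparisons across categories, and RPKM metaprofiles (200 bp bins over
TSS ± 4 kb) of chromatin tracks. For the closed-form model above, the
product f·s is recoverable from a mean treated diploid ratio r via
fs = (1 − 2r)/(1 − r).

## Worked example

The numbered drivers under `analysis/` run the pipeline on the default
synthetic world (chrX/chr12/chr8 at realistic sizes, X LINE-enriched and
SINE-poor, 5% X escapees, five clones spanning the four transgene families):

```sh
cd analysis
python 01_simulate.py --seed 1 --outdir ../results/pipeline
python 02_quantify.py --seed 1 --outdir ../results/pipeline
python 03_classify.py --seed 1 --outdir ../results/pipeline
# ... 04_positional, 05_repeats, 06_profiles
```

`03_classify.py` prints (seed 1):

```
percent of genes affected (delta in [0.1, 0.5]) per clone and chromosome:
Tg12-292  chr12     7.3
Tg12-55   chr12    60.5
TgE-87    chrX     74.2
TgX-86    chrX     69.6
TgX8-267  chr8      2.5
          chrX     76.7
  100% of simulated escapees fall in category III of group X
```

X-linked genes are silenced efficiently from every integration site, the
trisomic autosome responds more variably, and the simulated escapees land in
the "not silenced" category. `05_repeats.py` then reports LINE enrichment
around silenced TSSs (`group X LINE: median 490 > 138, p = 1.9e-14`) and
`06_profiles.py` an X-specific TSS peak of the escapee-bound factor
(category III: +119.9 RPKM over flanks; all autosomal categories flat).

The same stages are available as a CLI
(`xistquant all --seed 1 --outdir out/`), which is byte-for-byte
reproducible per seed.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-simulates the three untreated clone karyotypes from scratch (200 genes,
500 reads/gene, 2 replicates each), runs the full quantification and writes
the mean gene-level Cast/all ratio for the trisomy-12 clone, the diploid XX
clone, and the duplicated distal chr8 segment of the X;8 clone.
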