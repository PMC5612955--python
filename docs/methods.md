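# Methods

This note documents the models, parameter choices and numerical conventions
behind `xistquant`, and what the synthetic-data generator does and does not
establish.

## Allelic quantification model

SNP-level input is a table of reads supporting the 129/Sv and Cast/Ei
alleles at exonic polymorphic sites. Sites with total coverage below 5 reads
are discarded; genes whose informative sites reduce to a single SNP after
that filter must reach 8 reads at that site (both thresholds inclusive, both
configurable). Gene-level counts are plain sums over retained sites, and the
Cast/all ratio is N_Cast/(N_Cast + N₁₂₉), undefined (NaN) at zero total.
Replicates are kept separate by default — Δ ratios pair untreated replicate
k with treated replicate k — with a pooled mode available; which pairing the
original experimental analyses used is not derivable from the data layout,
so the choice is exposed.

### Karyotype transformations

Each clone is described by copy-number *segments*: intervals of a chromosome
with (n₁₂₉, n_Cast) parental copy counts, an optional targeted allele (set
when one copy of that allele lies in *cis* with the Xist transgene) and an
optional *cis* anchor. Genes are assigned to segments by TSS.

- Segments with (1, 2) copies are converted to the disomic scale with
  (N_Cast/2)/(N_Cast/2 + N₁₂₉); (2, 1) segments use the mirror formula.
- "Reciprocal" orientation for 129-targeted clones is implemented as the
  complement 1 − r, not 1/r: the transformation must keep ratios in [0, 1]
  and make 129-targeted clones behave as if the transgene were on a Cast
  copy; conversion is applied before orientation.
- The X;8 translocation keeps genes on their native chromosome records. Its
  clone configuration carries: a disomic, 129-targeted X segment (the fused
  129 X carries the transgene); a disomic untargeted proximal chr8 segment;
  and a (1, 2) Cast-targeted distal chr8 segment (the duplicated Cast-origin
  material fused to the 129 X). The distal segment's cis anchor — the chr8
  breakpoint coordinate plus the transgene-to-junction distance along X —
  supplies linear distances across the fusion, so breakpoint-proximal chr8
  genes are modelled as closer to the silencing source.

A consequence worth noting: on the post-conversion scale, a clone whose
transgene sits on one of two Cast copies has a maximum attainable Δ of
(fs/2)/(4 − fs) ≈ 0.097 at f·s = 0.65, i.e. essentially no gene can cross
the 0.1 "affected" bound, whereas a transgene on the single 129 copy yields
diploid-scale Δ up to (fs/2)/(2 − fs) ≈ 0.24. The default world therefore
includes trisomic clones of both orientations; the damped response of
Cast-targeted trisomic clones is a property of the conversion, not a bug.

## Silencing calls and categories

Δ = r(−dox) − r(+dox) on oriented, converted ratios; *affected* means
Δ ∈ [0.1, 0.5], both bounds inclusive and configurable (the upper bound
guards against implausible swings given partial coating). Cross-clone
ranking averages each gene's oriented treated ratio unweighted over the
clones where it is evaluable, sorts ascending (ties broken by gene_id), and
assigns categories from the averaged Δ: I at Δ̄ ≥ 0.2, II at 0.1 ≤ Δ̄ < 0.2,
III below 0.1. These boundaries are this package's documented choice,
consistent with the 0.1 affected cutoff — no published formula exists for
the category boundaries, which were originally drawn on ranked plots. A
tertile mode (equal thirds of the ranked list) is provided and is the right
choice for calibration studies (below).

Rank-sum comparisons (ratio distributions, repeat counts, expression) use
the two-sided Mann–Whitney U test: exact enumeration when both groups have
≤ 20 tie-free observations, the tie-corrected normal approximation
otherwise; all-identical input returns p = 1 by contract (the asymptotic
statistic is 0/0 there).

## Positional and repeat context

Distance windows around the integration site default to ±2, ±20 and
±100 Mb half-widths — so the "2 Mb bin" spans a 4 Mb region — nested by
default (each gene contributes to every window containing it), with an
annular mode. The gene anchor is the TSS.

Repeat elements are counted in windows centred on TSSs (1 Mb default) by
**midpoint containment** in [TSS − w/2, TSS + w/2): each element counts at
most once per window and boundary double-counting is impossible; an overlap
mode is available since the original counting rule is not recorded. Windows
at chromosome ends are clipped, counts are raw (not length-normalised).

Chromatin metaprofiles count reads in 200 bp bins over TSS ± 4 kb and
normalise to RPKM = count/(0.2 kb × N/10⁶) with N the track's total mapped
reads. Reads anchor at their 5′-most position *in gene orientation* (start
for plus-strand genes, end − 1 for minus), and minus-strand profiles are
reversed so upstream is always leftward; no fragment extension is applied.
Windows crossing a chromosome end keep zero-filled bins and are logged.

## The synthetic world

The generator emulates the data layout and first-order statistics of
allele-specific RNA-seq of the transgenic clones:

- **Genome.** chrX (171 Mb, 242 genes), chr12 (120 Mb, 351), chr8 (129 Mb,
  336) — physical sizes and per-chromosome evaluable-gene counts at the
  scale of the real design. Genes get ~Poisson(3) exonic SNPs (the F1
  129×Cast cross is SNP-dense), lognormal baseline expression around 500
  allele-informative reads, and uniform positions.
- **Repeats.** LINE/SINE elements are placed with piecewise-constant
  intensity over 5 Mb domains whose weights are lognormal (σ = 0.6),
  mimicking the strong clustering of real repeat tracks; densities default
  to 240 LINEs/Mb on X vs 150 on autosomes (X-enriched) and 110 SINEs/Mb on
  X vs 180 (X-depleted).
- **Escape.** 5% of X genes are flagged escapees (the literature range is
  3–7%), with probability decaying along the chromosome so escapees
  concentrate toward the centromeric end; evolutionary "new" genes occupy
  the centromeric 30%. An escape flag forces silencing degree 0.
- **Silencing truth.** s_g = s_max·(1 − escape)·clamp(w, 0, 1) with
  w = base + w_d·exp(−d/λ) + w_L·(LINE count in the 1 Mb TSS window), d the
  linear distance to the transgene (through the fusion junction for X;8
  segments) and λ = 10 Mb by default. The functional form is a free choice:
  only the qualitative facts (proximal and LINE-dense genes silence more,
  escapees resist) are established biology; the coupling constants are not
  estimates of anything.
- **Counts.** Per gene/replicate, totals are gamma-Poisson (negative
  binomial, dispersion 0.1 — a standard bulk RNA-seq noise level; Poisson in
  the dispersion → 0 limit) around λ_g scaled by copy number and residual
  expression under treatment; Cast reads are binomial with the closed-form
  expected fraction; reads are apportioned uniformly-multinomially across
  the gene's SNPs. The coating fraction defaults to 0.65 (induction
  succeeds in 50–70% of cells).
- **Tracks.** The CTCF-like track is uniform background plus Gaussian
  (σ = 300 bp) read peaks at escapee TSSs on the X only.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the full pipeline is byte-for-byte reproducible
per (config, seed), verified by checksum tests.

**What a green test establishes.** The generator reproduces allelic ratios,
their copy-number baselines, overdispersion, partial coating and the
qualitative couplings — so tests verify the *analysis* (filters, sums,
transformations, ranking, window counting, binning, test statistics), and
parameter recovery verifies the closed-form model end to end. It does not
model mapping bias toward the reference allele, positional coverage along
transcripts, read-level artefacts, or single-cell heterogeneity beyond the
binary coated/uncoated mixture; agreement here says nothing about those.

**A calibration subtlety.** "Repeat-independent silencing gives uniform
rank-sum p-values" holds only when the silencing truth is spatially
unstructured (uniform s, categories formed from measurement noise via the
tertile rule). If silencing is distance-coupled, category membership and
repeat counts share genomic neighbourhoods — repeat tracks are clustered —
and rank-sum p-values are anti-conservative even with zero mechanistic
coupling. The null-calibration test uses the exchangeable design; real
analyses should treat repeat–category associations as correlational.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open internally; GTF converts at the I/O
boundary (minus-strand TSS = end − 1). Zero-coverage ratios are NaN and
propagate to exclusion, never to 0. Zero expressed copies raise a
degenerate-input error. Density-track bins are half-open, boundary features
belong to the right bin. Configuration is strict YAML (unknown keys are
errors). The Mann–Whitney exact/asymptotic switch is at n = 20.

## Known limitations

- The category thresholds (0.2/0.1 averaged Δ) are a design choice; results
  near the boundaries move between II and its neighbours under small
  perturbations.
- The spatial silencing model is phenomenological; it cannot distinguish
  "LINEs facilitate silencing" from "LINE-dense regions are pre-repressed",
  and is not meant to.
- Affected fractions of Cast-targeted trisomic clones are structurally
  damped on the converted scale (see above); comparisons across clone
  orientations should use the oriented ratios, not the affected percentages.
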