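"""Simulator contracts: closed-form allelic expectations, determinism,
conservation and the statistical structure downstream stages assume."""

import numpy as np
import pytest

from xistquant import (
    ConfigurationError,
    DegenerateInputError,
    GeneAnnotation,
    SilencingModel,
    diploid_clone,
    expected_cast_fraction,
    simulate_counts,
    simulate_genome,
    trisomic_clone,
)
from xistquant.simulate import (
    ChromosomeSpec,
    GenomeParams,
    genes_table,
    silencing_degree,
    simulate_track_reads,
)

CHROMS = {"chrX": 50_000_000}


def _gene(chrom="chrX", tss=1_000_000, escape=False):
    return GeneAnnotation("g", chrom, "+", tss, (tss + 100,), escape_flag=escape)


def mixture_oracle(c129, ccast, f, s, targeted="Cast", n_cells=2_000_000, seed=0):
    """Brute-force cell mixture: each copy emits one unit; in a coated cell
    the targeted copy emits (1 - s).  Returns the expected Cast share."""
    rng = np.random.default_rng(seed)
    coated = rng.random(n_cells) < f
    cast = np.full(n_cells, float(ccast))
    total = np.full(n_cells, float(c129 + ccast))
    if targeted == "Cast":
        cast[coated] -= s
    total[coated] -= s
    return cast.sum() / total.sum()


class TestExpectedCastFraction:
    def test_diploid_untreated_is_half(self):
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000)
        assert expected_cast_fraction(_gene(), clone, 0.0, "untreated") == 0.5

    def test_trisomic_untreated_is_two_thirds(self):
        clone = trisomic_clone("t", {"chr12": 40_000_000}, "chr12", 10_000_000)
        g = _gene("chr12")
        assert expected_cast_fraction(g, clone, 0.0, "untreated") == pytest.approx(2 / 3)

    def test_treated_matches_cell_mixture_oracle(self):
        # diploid, Cast-targeted, f=0.65, s=1 -> 0.35/1.35
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000, coating_fraction=0.65)
        got = expected_cast_fraction(_gene(), clone, 1.0, "treated")
        assert got == pytest.approx(0.35 / 1.35)
        oracle = mixture_oracle(1, 1, 0.65, 1.0)
        assert got == pytest.approx(oracle, abs=2e-3)

    def test_complete_monoallelic_silencing(self):
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000, coating_fraction=1.0)
        assert expected_cast_fraction(_gene(), clone, 1.0, "treated") == 0.0

    @pytest.mark.parametrize("f,s", [(0.3, 0.4), (0.65, 0.8), (1.0, 0.5)])
    def test_partial_silencing_matches_oracle(self, f, s):
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000, coating_fraction=f)
        got = expected_cast_fraction(_gene(), clone, s, "treated")
        assert got == pytest.approx(mixture_oracle(1, 1, f, s), abs=2e-3)

    def test_monotone_in_f_and_s(self):
        # increasing f or s never increases the treated Cast fraction
        vals = []
        for f in np.linspace(0.1, 1.0, 10):
            clone = diploid_clone("c", CHROMS, "chrX", 10_000_000, coating_fraction=f)
            vals.append(expected_cast_fraction(_gene(), clone, 0.7, "treated"))
        assert np.all(np.diff(vals) <= 0)
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000, coating_fraction=0.65)
        vals = [expected_cast_fraction(_gene(), clone, s, "treated")
                for s in np.linspace(0, 1, 11)]
        assert np.all(np.diff(vals) <= 0)

    def test_zero_copies_degenerate(self):
        clone = diploid_clone("c", CHROMS, "chrX", 10_000_000)
        object.__setattr__(clone.segments[0], "n_129", 0)
        object.__setattr__(clone.segments[0], "n_cast", 0)
        with pytest.raises(DegenerateInputError):
            expected_cast_fraction(_gene(), clone, 0.0, "untreated")


class TestSilencingDegree:
    def test_escape_forces_zero(self):
        clone = diploid_clone("c", CHROMS, "chrX", 1_000_000)
        model = SilencingModel(s_max=1.0, base_weight=1.0, distance_weight=1.0,
                               line_weight=1.0)
        assert silencing_degree(_gene(escape=True), clone, model, line_count=500) == 0.0
        assert silencing_degree(_gene(), clone, model, line_count=500) == 1.0

    def test_off_chromosome_genes_not_silenced(self):
        clone = diploid_clone("c", {**CHROMS, "chr12": 40_000_000}, "chrX", 1_000_000)
        model = SilencingModel(s_max=1.0)
        assert silencing_degree(_gene("chr12"), clone, model) == 0.0

    def test_distance_decay_monotone(self):
        clone = diploid_clone("c", CHROMS, "chrX", 0)
        model = SilencingModel(s_max=1.0, base_weight=0.0, distance_weight=0.8,
                               distance_halfwidth=5e6)
        s = [silencing_degree(_gene(tss=d), clone, model)
             for d in (0, 2_000_000, 10_000_000, 40_000_000)]
        assert np.all(np.diff(s) < 0)


class TestSimulateGenome:
    def test_determinism(self, small_params):
        g1 = simulate_genome(small_params, seed=3)
        g2 = simulate_genome(small_params, seed=3)
        assert genes_table(g1).equals(genes_table(g2))
        assert [(r.chrom, r.start, r.end, r.repeat_class) for r in g1.repeats] == [
            (r.chrom, r.start, r.end, r.repeat_class) for r in g2.repeats
        ]

    def test_escape_fraction_binomial_expectation(self):
        params = GenomeParams(
            chromosomes=[ChromosomeSpec("chrX", 171_000_000, 200, is_x=True)],
            escape_fraction=0.05,
        )
        n_flags = [sum(g.escape_flag for g in simulate_genome(params, seed=s).genes)
                   for s in range(10)]
        # E = 10 per genome; pooled mean within 3 SE of binomial expectation
        pooled = np.sum(n_flags)
        se = np.sqrt(2000 * 0.05 * 0.95)
        assert abs(pooled - 100) < 3 * se

    def test_escape_only_on_x(self, small_genome):
        assert all(not g.escape_flag for g in small_genome.genes if g.chrom != "chrX")

    def test_zero_line_density_gives_no_lines(self):
        params = GenomeParams(
            chromosomes=[ChromosomeSpec("chr1", 10_000_000, 5, line_per_mb=0.0,
                                        sine_per_mb=50.0)]
        )
        g = simulate_genome(params, seed=0)
        assert all(r.repeat_class != "LINE" for r in g.repeats)

    def test_x_line_enrichment(self, small_genome):
        dens = {}
        for chrom, length in small_genome.chromosomes.items():
            n = sum(1 for r in small_genome.repeats
                    if r.chrom == chrom and r.repeat_class == "LINE")
            dens[chrom] = n / (length / 1e6)
        assert dens["chrX"] > dens["chr12"]
        assert dens["chrX"] > dens["chr8"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ChromosomeSpec("chr1", -5, 10)
        with pytest.raises(ConfigurationError):
            ChromosomeSpec("chr1", 1000, 0)


class TestSimulateCounts:
    def test_determinism(self, small_genome, diploid_x):
        model = SilencingModel(s_max=0.5)
        a = simulate_counts(small_genome, diploid_x, model, n_replicates=2, seed=9)
        b = simulate_counts(small_genome, diploid_x, model, n_replicates=2, seed=9)
        assert a.equals(b)

    def test_counts_nonnegative_and_conserved(self, small_genome, diploid_x):
        model = SilencingModel(s_max=0.5)
        df = simulate_counts(small_genome, diploid_x, model, n_replicates=1, seed=9)
        assert (df["n_129"] >= 0).all() and (df["n_cast"] >= 0).all()
        # every simulated SNP of a gene appears, with all apportioned reads
        g = small_genome.genes[0]
        sub = df[(df["gene_id"] == g.gene_id) & (df["condition"] == "nodox")]
        assert sorted(sub["pos"]) == sorted(g.snp_positions)

    def test_no_silencing_null_keeps_baselines(self, small_genome, diploid_x):
        model = SilencingModel(s_max=0.0)
        df = simulate_counts(small_genome, diploid_x, model, n_replicates=2, seed=5)
        for cond in ("nodox", "dox"):
            sub = df[(df["condition"] == cond) & (df["chrom"] == "chrX")]
            agg = sub.groupby("gene_id")[["n_129", "n_cast"]].sum()
            ratios = agg["n_cast"] / (agg["n_cast"] + agg["n_129"])
            # mean over >=50 genes within 3 SE of 0.5
            assert abs(ratios.mean() - 0.5) < 3 * ratios.std() / np.sqrt(len(ratios))

    def test_mean_cast_fraction_matches_closed_form(self):
        # >=500 genes, treated: empirical mean within 3 SE of the closed form
        params = GenomeParams(
            chromosomes=[ChromosomeSpec("chrX", 171_000_000, 600, is_x=True)],
            escape_fraction=0.0,
        )
        genome = simulate_genome(params, seed=2)
        clone = diploid_clone("c", genome.chromosomes, "chrX", 85_000_000,
                              coating_fraction=0.65)
        model = SilencingModel(s_max=0.6, base_weight=1.0)
        df = simulate_counts(genome, clone, model, condition="dox",
                             n_replicates=1, seed=4)
        agg = df.groupby("gene_id")[["n_129", "n_cast"]].sum()
        ratios = (agg["n_cast"] / (agg["n_cast"] + agg["n_129"])).to_numpy()
        expected = expected_cast_fraction(
            genome.genes[0], clone, 0.6, "treated"
        )
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - expected) < 3 * se

    def test_dispersion_zero_limit_is_poisson(self):
        params = GenomeParams(
            chromosomes=[ChromosomeSpec("chr1", 10_000_000, 400)],
            expression_log_sd=0.0,
        )
        genome = simulate_genome(params, seed=1)
        clone = diploid_clone("c", genome.chromosomes, "chr1", 5_000_000)
        totals = {}
        for disp in (0.0, 0.3):
            model = SilencingModel(s_max=0.0, dispersion=disp)
            df = simulate_counts(genome, clone, model, condition="nodox",
                                 n_replicates=1, seed=8)
            agg = (df["n_129"] + df["n_cast"]).groupby(df["gene_id"]).sum()
            totals[disp] = agg.to_numpy(float)
        mean = totals[0.0].mean()
        # Poisson: var ~= mean; overdispersed: var >> mean
        assert totals[0.0].var() < 2.0 * mean
        assert totals[0.3].var() > 10.0 * mean

    def test_bad_replicates_rejected(self, small_genome, diploid_x):
        with pytest.raises(ConfigurationError):
            simulate_counts(small_genome, diploid_x, SilencingModel(), n_replicates=0)


def test_track_reads_peak_at_enriched_tss(small_genome):
    target = small_genome.genes[0]
    df = simulate_track_reads(small_genome, [target.gene_id],
                              reads_per_enriched_tss=200, background_per_mb=10.0,
                              seed=3)
    near = df[(df["chrom"] == target.chrom)
              & ((df["start"] - target.tss).abs() < 2000)]
    assert len(near) > 100
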