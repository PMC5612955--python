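"""Gene-level aggregation under the coverage filters, ratio arithmetic and
karyotype-aware transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xistquant import (
    ConfigurationError,
    SilencingModel,
    aggregate_gene_counts,
    compute_cast_ratio,
    diploid_clone,
    filter_informative_snps,
    orient_ratio,
    quantify_clone,
    simulate_counts,
    trisomic_clone,
    trisomic_to_disomic,
)
from xistquant.quantify import apply_clone_transforms, disomic_mirror_trisomic

from conftest import snp_table


class TestSnpFilter:
    def test_boundary_coverage_five_retained(self):
        df = snp_table([
            ("s", "nodox", 1, "g1", "chr1", 100, 3, 2),   # coverage 5: kept
            ("s", "nodox", 1, "g1", "chr1", 200, 2, 2),   # coverage 4: dropped
        ])
        out = filter_informative_snps(df, min_coverage=5)
        assert list(out["pos"]) == [100]

    def test_empty_input(self):
        df = snp_table([])
        assert filter_informative_snps(df).empty

    def test_min_coverage_validation(self):
        with pytest.raises(ConfigurationError):
            filter_informative_snps(snp_table([]), min_coverage=0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=30))
    def test_filter_idempotent(self, counts):
        df = snp_table([
            ("s", "nodox", 1, f"g{i}", "chr1", 100 + i, a, b)
            for i, (a, b) in enumerate(counts)
        ])
        once = filter_informative_snps(df, 5)
        twice = filter_informative_snps(once, 5)
        assert once.equals(twice)


class TestAggregation:
    def test_hand_summed_example(self):
        # SNPs (5+0) and (3+3): N_129=8, N_Cast=3, 2 informative SNPs
        df = snp_table([
            ("s", "nodox", 1, "g1", "chr1", 100, 5, 0),
            ("s", "nodox", 1, "g1", "chr1", 200, 3, 3),
        ])
        rec = aggregate_gene_counts(df)
        assert len(rec) == 1
        row = rec.iloc[0]
        assert (row["N_129"], row["N_Cast"], row["n_informative_snps"]) == (8, 3, 2)
        assert row["ratio"] == pytest.approx(3 / 11)

    @pytest.mark.parametrize("coverage,kept", [(7, False), (8, True)])
    def test_single_snp_threshold_inclusive(self, coverage, kept):
        df = snp_table([("s", "nodox", 1, "g1", "chr1", 100, coverage - 2, 2)])
        rec = aggregate_gene_counts(df, single_snp_min=8)
        assert (len(rec) == 1) is kept

    def test_single_snp_rule_applies_after_snp_filter(self):
        # two SNPs, one below the per-SNP filter: the gene is effectively
        # single-SNP and must meet the 8-read rule on the surviving site
        df = snp_table([
            ("s", "nodox", 1, "g1", "chr1", 100, 4, 3),   # kept, coverage 7
            ("s", "nodox", 1, "g1", "chr1", 200, 2, 2),   # dropped by >=5 filter
        ])
        rec = aggregate_gene_counts(filter_informative_snps(df, 5), single_snp_min=8)
        assert rec.empty

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_genes = data.draw(st.integers(1, 20))
        rows = []
        for gi in range(n_genes):
            n_snps = data.draw(st.integers(1, 5))
            for si in range(n_snps):
                a = data.draw(st.integers(0, 30))
                b = data.draw(st.integers(0, 30))
                rows.append(("s", "nodox", 1, f"g{gi}", "chr1", 100 * (si + 1), a, b))
        df = filter_informative_snps(snp_table(rows), 5)
        rec = aggregate_gene_counts(df, single_snp_min=8)
        # oracle: explicit per-gene python-loop summation
        expected = {}
        for _, r in df.iterrows():
            e = expected.setdefault(r["gene_id"], [0, 0, 0])
            e[0] += r["n_129"]
            e[1] += r["n_cast"]
            e[2] += 1
        expected = {g: e for g, e in expected.items()
                    if not (e[2] == 1 and e[0] + e[1] < 8)}
        got = {r["gene_id"]: [r["N_129"], r["N_Cast"], r["n_informative_snps"]]
               for _, r in rec.iterrows()}
        assert got == expected


class TestRatioArithmetic:
    @pytest.mark.parametrize("n129,ncast,expected", [
        (50, 50, 0.5), (40, 0, 0.0), (1, 2, 2 / 3),
    ])
    def test_cast_ratio(self, n129, ncast, expected):
        assert compute_cast_ratio(ncast, n129) == pytest.approx(expected)

    def test_zero_total_is_nan(self):
        assert np.isnan(compute_cast_ratio(0, 0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_complement_symmetry(self, a, b):
        if a + b == 0:
            return
        assert compute_cast_ratio(a, b) + compute_cast_ratio(b, a) == pytest.approx(1.0)

    @pytest.mark.parametrize("ncast,n129,expected", [
        (100, 50, 0.5), (0, 50, 0.0), (100, 100, 1 / 3),
    ])
    def test_trisomic_to_disomic(self, ncast, n129, expected):
        assert trisomic_to_disomic(ncast, n129) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_trisomic_equals_halved_cast_ratio(self, ncast, n129):
        if ncast / 2 + n129 == 0:
            return
        assert trisomic_to_disomic(ncast, n129) == pytest.approx(
            compute_cast_ratio(ncast / 2, n129)
        )

    def test_orientation(self):
        assert orient_ratio(0.3, "Cast") == 0.3
        assert orient_ratio(0.3, "129") == pytest.approx(0.7)
        assert orient_ratio(0.5, "129") == pytest.approx(orient_ratio(0.5, "Cast"))
        with pytest.raises(ConfigurationError):
            orient_ratio(0.3, "BL6")


class TestCloneTransforms:
    def test_trisomic_segment_converted_and_oriented(self):
        clone = trisomic_clone("t", {"chr12": 1_000_000}, "chr12", 500_000,
                               transgene_allele="Cast")
        rec = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr12"], "N_129": [100], "N_Cast": [200],
            "ratio": [2 / 3], "sample_id": ["s"], "condition": ["nodox"],
            "replicate": [1], "n_informative_snps": [2],
        })
        out = apply_clone_transforms(rec, clone, gene_tss={"g1": 100})
        assert out["converted_ratio"].iloc[0] == pytest.approx(0.5)
        assert out["oriented_ratio"].iloc[0] == pytest.approx(0.5)

    def test_129_transgene_mirrored(self):
        clone = trisomic_clone("t", {"chr12": 1_000_000}, "chr12", 500_000,
                               transgene_allele="129")
        rec = pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr12"], "N_129": [50], "N_Cast": [200],
            "ratio": [0.8], "sample_id": ["s"], "condition": ["dox"],
            "replicate": [1], "n_informative_snps": [2],
        })
        out = apply_clone_transforms(rec, clone, gene_tss={"g1": 100})
        conv = (200 / 2) / (200 / 2 + 50)
        assert out["converted_ratio"].iloc[0] == pytest.approx(conv)
        assert out["oriented_ratio"].iloc[0] == pytest.approx(1 - conv)

    def test_mirror_trisomy_with_two_129_copies(self):
        assert disomic_mirror_trisomic(50, 100) == pytest.approx(0.5)

    def test_x8_segments(self, small_genome, x8_clone):
        # distal chr8 segment is (1, 2) Cast-targeted; X is (1, 1) 129-targeted
        distal = x8_clone.segment_for("chr8", 39_000_000)
        assert (distal.n_129, distal.n_cast) == (1, 2)
        assert distal.targeted_allele == "Cast"
        xseg = x8_clone.segment_for("chrX", 1_000_000)
        assert (xseg.n_129, xseg.n_cast) == (1, 1)
        assert xseg.targeted_allele == "129"
        # distance through the fusion junction exceeds the junction offset
        d = x8_clone.transgene_distance("chr8", 39_000_000)
        assert d > x8_clone.transgene_distance("chrX", x8_clone.transgene_pos)


class TestPipelineBaselines:
    def test_null_pipeline_recovers_karyotype_baselines(self, small_genome,
                                                        diploid_x, trisomic_12):
        model = SilencingModel(s_max=0.0)
        tss = {g.gene_id: g.tss for g in small_genome.genes}
        for clone, chrom, baseline in ((diploid_x, "chrX", 0.5),
                                       (trisomic_12, "chr12", 2 / 3)):
            counts = simulate_counts(small_genome, clone, model, condition="nodox",
                                     n_replicates=2, seed=21)
            rec = quantify_clone(counts, clone, gene_tss=tss)
            sub = rec[rec["chrom"] == chrom]["ratio"].to_numpy()
            se = sub.std(ddof=1) / np.sqrt(len(sub))
            assert abs(sub.mean() - baseline) < 3 * max(se, 1e-4)
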