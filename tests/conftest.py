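import numpy as np
import pandas as pd
import pytest

from xistquant.models import GeneAnnotation, GenomeModel, RepeatElement
from xistquant.simulate import ChromosomeSpec, GenomeParams, simulate_genome
from xistquant import diploid_clone, trisomic_clone, x8_translocation_clone

CHROMS = {"chrX": 50_000_000, "chr12": 40_000_000, "chr8": 40_000_000}


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled genome: short chromosomes, few genes, X LINE-enriched."""
    return GenomeParams(
        chromosomes=[
            ChromosomeSpec("chrX", CHROMS["chrX"], 60, line_per_mb=240.0,
                           sine_per_mb=110.0, is_x=True),
            ChromosomeSpec("chr12", CHROMS["chr12"], 50),
            ChromosomeSpec("chr8", CHROMS["chr8"], 50),
        ],
        escape_fraction=0.05,
    )


@pytest.fixture(scope="session")
def small_genome(small_params):
    return simulate_genome(small_params, seed=11)


@pytest.fixture()
def diploid_x(small_genome):
    return diploid_clone("TgE", small_genome.chromosomes, "chrX", 25_000_000,
                         transgene_allele="Cast", coating_fraction=0.65)


@pytest.fixture()
def trisomic_12(small_genome):
    return trisomic_clone("Tg12", small_genome.chromosomes, "chr12", 20_000_000,
                          transgene_allele="Cast", coating_fraction=0.65)


@pytest.fixture()
def x8_clone(small_genome):
    return x8_translocation_clone("TgX8", small_genome.chromosomes, 25_000_000,
                                  coating_fraction=0.65)


@pytest.fixture()
def tiny_genome():
    """Hand-built two-chromosome genome for exact-value tests."""
    genes = [
        GeneAnnotation("gA", "chr1", "+", 1_000_000, (1_000_100, 1_000_500)),
        GeneAnnotation("gB", "chr1", "-", 2_000_000, (2_000_250,)),
        GeneAnnotation("gC", "chr2", "+", 500_000, (500_100, 500_200, 500_300)),
    ]
    repeats = [
        RepeatElement("chr1", 999_000, 1_004_000, "LINE"),
        RepeatElement("chr1", 1_600_000, 1_605_000, "LINE"),
        RepeatElement("chr1", 2_100_000, 2_100_300, "SINE"),
        RepeatElement("chr2", 400_000, 405_000, "LINE"),
    ]
    return GenomeModel({"chr1": 3_000_000, "chr2": 1_000_000}, genes, repeats)


def snp_table(rows):
    """rows: (sample, condition, replicate, gene, chrom, pos, n129, ncast)"""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "replicate", "gene_id", "chrom", "pos",
                 "n_129", "n_cast"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
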