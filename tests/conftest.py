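import numpy as np
import pytest

from triophase.trio_sim import SimParams, simulate_parental_genotypes, simulate_trio
from triophase.variant_filter import SampleCall, VariantRecord


@pytest.fixture(scope="session")
def small_trio():
    """1-Mb study-condition trio shared by read-only tests."""
    params = SimParams(ancestor_length=1_000_000, n_chromosomes=2, scaffold_n50=20_000, seed=11)
    return simulate_trio(params)


@pytest.fixture(scope="session")
def clean_genotypes(small_trio):
    """Noise-free genotype simulation on the shared trio."""
    return simulate_parental_genotypes(small_trio, depth=30.0, seed=11)


def make_record(
    scaffold="scf00000",
    position=100,
    qual=999.0,
    gt_a="0/1",
    gt_b="1/1",
    dp=(25, 25),
    gq=(30, 30),
    sample_a="parent_a",
    sample_b="parent_b",
):
    return VariantRecord(
        scaffold_id=scaffold,
        position=position,
        ref_allele="A",
        alt_alleles=("C",),
        qual=qual,
        samples={
            sample_a: SampleCall(gt=gt_a, dp=dp[0], gq=gq[0]),
            sample_b: SampleCall(gt=gt_b, dp=dp[1], gq=gq[1]),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
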