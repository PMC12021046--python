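import numpy as np
import pytest

from lcimpute import popsim, seqsim
from lcimpute.types import HaplotypePanel


@pytest.fixture(scope="session")
def small_panel() -> HaplotypePanel:
    """100 haplotypes x 800 sites over 400 kb; complete."""
    return popsim.simulate_panel(n_hap=100, n_sites=800, region_len=400_000,
                                 founder_count=20, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return popsim.sample_offspring(small_panel, n_ind=6, seed=12)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return seqsim.simulate_reads(small_truth, depth=0.1, error_rate=0.001, seed=13)


def random_tiny_panel(rng: np.random.Generator, n_hap: int, n_sites: int) -> HaplotypePanel:
    """A tiny random panel guaranteed polymorphic at every site."""
    while True:
        alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
        if np.all(alleles.min(axis=0) != alleles.max(axis=0)):
            break
    positions = np.sort(rng.choice(10_000, size=n_sites, replace=False)) + 1
    return HaplotypePanel(chrom="1", positions=positions, alleles=alleles)
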