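import numpy as np
import pytest

from staract import counts as counts_mod
from staract import design as design_mod
from staract import simlib


@pytest.fixture(scope="session")
def toy_genome_snps():
    """A small random genome with 12 plus-strand SNPs placed on it."""
    return simlib.random_genome_and_snps(12, seed=11)


@pytest.fixture(scope="session")
def toy_designs(toy_genome_snps):
    genome, snps = toy_genome_snps
    return design_mod.build_library(snps, genome)


@pytest.fixture(scope="session")
def toy_index(toy_designs):
    return counts_mod.InsertIndex(toy_designs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
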