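import numpy as np
import pytest

from edgepop.datatypes import MISSING, GenotypeMatrix, LocusMeta, PopulationMap


@pytest.fixture
def two_allele_locus():
    return LocusMeta("L1", 2, (8, 15))


@pytest.fixture
def toy_matrix(two_allele_locus):
    """Four individuals, one locus: AA, AB, AB, BB (A=10, B=11)."""
    calls = np.array([[[10, 10]], [[10, 11]], [[10, 11]], [[11, 11]]])
    return GenotypeMatrix(["i1", "i2", "i3", "i4"], [two_allele_locus], calls)


@pytest.fixture
def toy_popmap():
    return PopulationMap({"i1": "p1", "i2": "p1", "i3": "p2", "i4": "p2"})


def random_matrix(rng, n_ind=12, n_loci=4, n_pops=2, missing_rate=0.1):
    """Seeded random genotype matrix + popmap for oracle comparisons."""
    loci = [LocusMeta(f"L{j}", 2, (5, 30)) for j in range(n_loci)]
    calls = rng.integers(8, 18, size=(n_ind, n_loci, 2))
    drop = rng.random((n_ind, n_loci)) < missing_rate
    calls[drop] = MISSING
    # keep each locus observed somewhere
    calls[0][calls[0, :, 0] == MISSING] = 9
    inds = [f"ind{i}" for i in range(n_ind)]
    g = GenotypeMatrix(inds, loci, calls)
    pops = PopulationMap({ind: f"pop{i % n_pops}" for i, ind in enumerate(inds)})
    return g, pops


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
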