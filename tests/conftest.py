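import numpy as np
import pytest
from hypothesis import settings

from msatpop.io_genotypes import GenotypeDataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_ds(genotypes_by_pop, loci=None, species=None):
    """Build a GenotypeDataset from {pop: [[(a1, a2), ...], ...]}:
    one list of per-locus allele pairs per individual."""
    individuals, populations, rows = [], [], []
    n_loci = None
    for pop, inds in genotypes_by_pop.items():
        for i, row in enumerate(inds):
            individuals.append(f"{pop}{i + 1}")
            populations.append(pop)
            rows.append(row)
            n_loci = len(row)
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    species = species or ["sp"] * len(individuals)
    if isinstance(species, str):
        species = [species] * len(individuals)
    return GenotypeDataset(individuals, populations, species, loci,
                           np.array(rows, dtype=np.int32))


@pytest.fixture
def toy_two_pop():
    """Two populations, two loci, three individuals each."""
    return make_ds({
        "A": [[(100, 102), (200, 200)],
              [(100, 100), (200, 202)],
              [(102, 102), (202, 202)]],
        "B": [[(104, 104), (200, 200)],
              [(104, 102), (200, 200)],
              [(102, 102), (200, 202)]],
    })


@pytest.fixture
def fixed_diff_pops():
    """Two populations fixed for different alleles at one locus."""
    return make_ds({
        "A": [[(100, 100)]] * 6,
        "B": [[(120, 120)]] * 6,
    })
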