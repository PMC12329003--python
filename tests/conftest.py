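import numpy as np
import pandas as pd
import pytest

from popsplit.genotype_io import GenotypeMatrix, PopulationMap, SiteMeta


def make_matrix(calls, locus_ids=None, mean_depths=None, individuals=None):
    """Build a GenotypeMatrix from a (individuals x sites) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    individuals = individuals or [f"ind{i}" for i in range(n_ind)]
    locus_ids = locus_ids or [f"locus{j}" for j in range(n_sites)]
    mean_depths = mean_depths if mean_depths is not None else [10.0] * n_sites
    sites = [
        SiteMeta(
            locus_id=locus_ids[j],
            chrom=locus_ids[j],
            pos=100 + j,
            ref_allele="A",
            alt_allele="G",
            mean_depth=mean_depths[j],
        )
        for j in range(n_sites)
    ]
    return GenotypeMatrix(individuals, sites, calls)


def make_popmap(assignment, region=None):
    """PopulationMap from {individual: locality}; region defaults to locality."""
    rows = [
        (ind, loc, (region or {}).get(ind, loc)) for ind, loc in assignment.items()
    ]
    return PopulationMap(
        pd.DataFrame(rows, columns=["individual", "locality", "region"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_matrix(rng):
    """A 10-individual x 20-site matrix with some missing calls."""
    calls = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = -1
    return make_matrix(calls)
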