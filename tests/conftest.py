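import numpy as np
import pytest

from msatpop.genotypes import GenotypeTable
from msatpop.simulate import SimulationConfig, simulate_hierarchical_fmodel


def table_from_calls(calls, sites=None, loci=None, ids=None):
    """Build a GenotypeTable from a nested list (n, L, 2) of allele codes."""
    arr = np.asarray(calls, dtype=np.int64)
    n, L, _ = arr.shape
    return GenotypeTable(
        ids=ids or [f"ind{i+1}" for i in range(n)],
        sites=sites or ["s1"] * n,
        loci=loci or [f"L{j+1}" for j in range(L)],
        alleles=arr,
    )


@pytest.fixture
def small_structured_table():
    """Two seas x three sites, moderate differentiation, some missing data."""
    cfg = SimulationConfig(seed=11, n_seas=2, sites_per_sea=3, n_per_site=20,
                           n_loci=8, alleles_per_locus=8,
                           theta_between_seas=0.2, theta_within_sea=0.05,
                           fis_target=0.0, miss_rate=0.05)
    table, hierarchy, truth = simulate_hierarchical_fmodel(cfg)
    return table, hierarchy, truth
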