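import numpy as np
import pandas as pd
import pytest

from divscape.windows import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def worked_example_gm():
    """4 haplotypes at 3 SNPs: S=3, mean pairwise differences 2.0, D ~ 2.012."""
    calls = np.array([[0, 0, 0],
                      [0, 1, 1],
                      [1, 0, 1],
                      [1, 1, 0]], dtype=np.int8)
    return GenotypeMatrix("chr1", np.array([10, 20, 30]), calls)


def random_genotype_matrix(rng, n_hap=None, n_sites=None, missing_frac=0.0):
    n_hap = n_hap or int(rng.integers(4, 12))
    n_sites = n_sites or int(rng.integers(1, 40))
    calls = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(calls.shape) < missing_frac
        calls[mask] = -1
    pos = np.sort(rng.choice(5000, size=n_sites, replace=False))
    return GenotypeMatrix("chr1", pos, calls)


@pytest.fixture
def diversity_table_pair(rng):
    """Two small correlated diversity tables sharing a window grid."""
    n = 60
    base = rng.poisson(20, n).astype(float)
    tabs = {}
    for pop in ("p1", "p2"):
        S = base + rng.poisson(5, n)
        tabs[pop] = pd.DataFrame({
            "population": pop, "contig": "chr1",
            "start": np.arange(n) * 5000, "end": np.arange(1, n + 1) * 5000,
            "S": S.astype(int), "pi": S / 5000.0,
            "tajima_d": rng.normal(size=n),
        })
    return tabs
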