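import numpy as np
import pytest

import msatland as m
from msatland import synthetic as sy

LADDER = 100 + 2 * np.arange(8)


def matrix_from_indices(idx_calls, coords=None, motif=2, ids=None):
    """Build a GenotypeMatrix from (n, L, 2) allele-index calls."""
    idx_calls = np.asarray(idx_calls)
    n, L, _ = idx_calls.shape
    loci = [m.Locus(f"L{l + 1:02d}", motif) for l in range(L)]
    ids = ids or [f"i{i + 1:03d}" for i in range(n)]
    return m.GenotypeMatrix(ids, loci, LADDER[idx_calls], coordinates=coords)


def two_group_sample(F, n_per_group, n_loci=15, n_alleles=8, seed=0):
    """Two groups drawn from Balding-Nichols frequencies at divergence F."""
    rng = np.random.default_rng(seed)
    p_anc = sy._ancestral_freqs(rng, n_loci, n_alleles, 1.0)
    fa = m.balding_nichols(rng, p_anc, F)
    fb = m.balding_nichols(rng, p_anc, F)
    calls = np.concatenate([
        sy._draw_genotypes(rng, fa, n_per_group),
        sy._draw_genotypes(rng, fb, n_per_group),
    ])
    gm = matrix_from_indices(calls)
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    return gm, labels


@pytest.fixture(scope="session")
def landscape():
    """The default synthetic study landscape (168 x 15, 4 groups, island)."""
    gm, q, truth = m.generate_dataset(m.SimConfig(seed=1))
    return gm, q, truth


@pytest.fixture(scope="session")
def panmictic_small():
    return m.generate_panmictic(80, n_loci=10, seed=11)
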