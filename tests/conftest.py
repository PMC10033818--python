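import numpy as np
import pytest

import selfscan as ss


@pytest.fixture(scope="session")
def neutral_pair():
    """Small neutral selfing pair shared by read-only tests."""
    cfg = ss.SimConfig(
        n_loci=400, ne=300, selfing_rate=0.95, tau=31, n0=60, n_tau=60, seed=101
    )
    return ss.simulate_temporal_population(cfg)


@pytest.fixture(scope="session")
def filtered_neutral_pair(neutral_pair):
    pair, _ = ss.filter_pair(neutral_pair)
    return pair


def pair_from_counts(counts0, counts1, tau=31):
    """Build a two-sample pair from genotype count triples (one per locus).

    counts are lists of (nAA, nAa, naa) with AA = hom-ref (dosage 0).
    """
    def expand(counts):
        cols = []
        for nAA, nAa, naa in counts:
            cols.append(np.array([0] * nAA + [1] * nAa + [2] * naa, dtype=np.int8))
        n = max(len(c) for c in cols)
        assert all(len(c) == n for c in cols), "equal sample sizes per locus required"
        return np.stack(cols, axis=1)

    g0, g1 = expand(counts0), expand(counts1)
    L = g0.shape[1]
    chrom = np.array(["chr01"] * L, dtype=object)
    pos = np.arange(1, L + 1, dtype=np.int64) * 1000
    m0 = ss.GenotypeMatrix(g0, chrom, pos, [f"a{i}" for i in range(g0.shape[0])])
    m1 = ss.GenotypeMatrix(g1, chrom, pos, [f"b{i}" for i in range(g1.shape[0])])
    return ss.TemporalSamplePair(m0, m1, tau=tau)
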