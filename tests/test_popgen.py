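"""Locus filtering, identity probabilities, Weir-Cockerham components, FIS and
LD statistics, each checked against an independent direct computation."""

import numpy as np
import pytest

import selfscan as ss
from selfscan.popgen import MISSING, EmptyOutputError, NotEstimableError, wc_components_from_counts

from conftest import pair_from_counts


def make_matrix(genotypes, pos=None):
    g = np.asarray(genotypes, dtype=np.int8)
    L = g.shape[1]
    chrom = np.array(["chr01"] * L, dtype=object)
    pos = np.arange(1, L + 1) * 1000 if pos is None else np.asarray(pos)
    return ss.GenotypeMatrix(g, chrom, pos, [f"s{i}" for i in range(g.shape[0])])


# ---------------------------------------------------------------------------
# filtering


class TestFilterLoci:
    def test_monomorphic_removed(self):
        m = make_matrix([[0, 0], [0, 1], [0, 2], [0, 1]])
        kept, rep = ss.filter_loci(m, het_max=1.0)
        assert kept.n_loci == 1 and rep.n_loci_dropped == 1

    def test_missing_threshold_is_strict(self):
        # 1 of 4 samples missing = 25% >= 20% threshold -> removed
        m = make_matrix([[0, 0], [2, MISSING], [0, 2], [2, 0]])
        kept, _ = ss.filter_loci(m, miss_max=0.20, het_max=1.0)
        assert kept.n_loci == 1

    def test_exact_survivor_set_on_known_fixture(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(40, 100)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        m = make_matrix(g)
        kept, rep = ss.filter_loci(m, maf_min=0.1, miss_max=0.15, het_max=0.4)
        # direct recount per locus
        expected = []
        for j in range(100):
            col = g[:, j]
            obs = col[col != MISSING]
            miss = 1 - len(obs) / 40
            p = obs.mean() / 2
            maf = min(p, 1 - p)
            het = (obs == 1).mean()
            expected.append(maf > 0.1 and miss < 0.15 and het < 0.4)
        assert kept.n_loci == sum(expected)
        np.testing.assert_array_equal(kept.pos, m.pos[np.array(expected)])
        assert rep.n_loci_dropped == 100 - sum(expected)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.integers(0, 3, size=(30, 50)).astype(np.int8))
        once, _ = ss.filter_loci(m, het_max=1.0)
        twice, rep = ss.filter_loci(once, het_max=1.0)
        assert rep.n_loci_dropped == 0
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)

    def test_all_removed_raises(self):
        m = make_matrix([[0, 0], [0, 0]])
        with pytest.raises(EmptyOutputError):
            ss.filter_loci(m)


# ---------------------------------------------------------------------------
# identity probabilities


def brute_force_identity(counts0, counts1):
    """Oracle: enumerate ordered gene pairs from explicit gene lists."""
    def genes(c):
        nAA, nAa, naa = c
        return ["A"] * (2 * nAA + nAa) + ["a"] * (nAa + 2 * naa)

    g0, g1 = genes(counts0), genes(counts1)

    def within(g):
        same = sum(1 for i in range(len(g)) for j in range(len(g)) if i != j and g[i] == g[j])
        return same / (len(g) * (len(g) - 1))

    between = sum(1 for x in g0 for y in g1 if x == y) / (len(g0) * len(g1))
    return (within(g0) + within(g1)) / 2, between


class TestLocusSummaries:
    def test_both_fixed_same_allele(self):
        pair = pair_from_counts([(10, 0, 0)], [(10, 0, 0)])
        s = ss.locus_summaries(pair).iloc[0]
        assert s.f0_hat == 1.0 and s.f1_hat == 1.0 and np.isnan(s.fst_bn)

    def test_fixed_for_alternative_alleles(self):
        pair = pair_from_counts([(10, 0, 0)], [(0, 0, 10)])
        s = ss.locus_summaries(pair).iloc[0]
        assert s.f0_hat == 1.0 and s.f1_hat == 0.0 and s.fst_bn == 1.0

    @pytest.mark.parametrize(
        "c0,c1",
        [((25, 50, 25), (81, 18, 1)), ((40, 20, 40), (90, 0, 10)), ((5, 3, 2), (1, 4, 5))],
    )
    def test_matches_gene_pair_enumeration(self, c0, c1):
        pair = pair_from_counts([c0], [c1])
        s = ss.locus_summaries(pair).iloc[0]
        f0, f1 = brute_force_identity(c0, c1)
        assert s.f0_hat == pytest.approx(f0)
        assert s.f1_hat == pytest.approx(f1)
        assert s.fst_bn == pytest.approx((f0 - f1) / (1 - f1))

    def test_h0_equals_direct_gene_diversity(self):
        # on small fixtures, 1 - f0 equals the average within-sample
        # probability that two distinct genes differ, counted directly
        rng = np.random.default_rng(3)
        for _ in range(20):
            c0 = tuple(rng.integers(0, 5, size=3) + np.array([1, 0, 1]))
            c1 = tuple(rng.integers(0, 5, size=3) + np.array([1, 0, 1]))
            pair = pair_from_counts([c0], [c1])
            s = ss.locus_summaries(pair).iloc[0]
            f0, _ = brute_force_identity(c0, c1)
            assert s.h0_hat == pytest.approx(1 - f0)


# ---------------------------------------------------------------------------
# Weir-Cockerham


def wc_anova_oracle(counts1, counts2):
    """Independent mean-squares formulation of the two-population
    Weir-Cockerham theta, from explicit per-individual allele counts."""
    def expand(c):
        nAA, nAa, naa = c
        return np.array([2] * nAA + [1] * nAa + [0] * naa, dtype=float)

    y1, y2 = expand(counts1), expand(counts2)
    n1, n2 = len(y1), len(y2)
    p1, p2 = y1.mean() / 2, y2.mean() / 2
    pbar = (2 * n1 * p1 + 2 * n2 * p2) / (2 * (n1 + n2))
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    ssp = 2 * n1 * (p1 - pbar) ** 2 + 2 * n2 * (p2 - pbar) ** 2
    ssi = ((y1 / 2 - p1) ** 2).sum() * 2 + ((y2 / 2 - p2) ** 2).sum() * 2
    ssw = (y1 == 1).sum() / 2 + (y2 == 1).sum() / 2
    msp = ssp / 1
    msi = ssi / (n1 + n2 - 2)
    msw = ssw / (n1 + n2)
    s2_w = msw
    s2_i = (msi - msw) / 2
    s2_p = (msp - msi) / (2 * nc)
    return s2_p / (s2_p + s2_i + s2_w)


class TestWeirCockerham:
    def test_identical_counts_nonpositive(self):
        pair = pair_from_counts([(8, 2, 0)], [(8, 2, 0)])
        per, _ = ss.fst_weir_cockerham(pair)
        assert per[0] <= 0

    def test_fixed_difference_is_one(self):
        pair = pair_from_counts([(10, 0, 0)], [(0, 0, 10)])
        per, _ = ss.fst_weir_cockerham(pair)
        assert per[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "c1,c2",
        [((8, 2, 0), (2, 2, 6)), ((5, 5, 0), (0, 5, 5)), ((9, 0, 1), (3, 4, 3))],
    )
    def test_matches_anova_oracle(self, c1, c2):
        a, b, c = wc_components_from_counts(np.array(c1), np.array(c2))
        assert a / (a + b + c) == pytest.approx(wc_anova_oracle(c1, c2))

    def test_identity_and_anova_fst_agree_on_balanced_fixture(self):
        # two estimators of the same quantity: within 0.05 at n=60 per sample
        rng = np.random.default_rng(11)
        counts0, counts1 = [], []
        for _ in range(50):
            p, q = rng.uniform(0.2, 0.8, size=2)
            counts0.append(tuple(rng.multinomial(60, [p**2, 2 * p * (1 - p), (1 - p) ** 2])))
            counts1.append(tuple(rng.multinomial(60, [q**2, 2 * q * (1 - q), (1 - q) ** 2])))
        pair = pair_from_counts(counts0, counts1)
        s = ss.locus_summaries(pair)
        ok = np.isfinite(s.fst_bn) & np.isfinite(s.fst_wc)
        diff = (s.fst_bn - s.fst_wc)[ok]
        assert np.abs(diff).max() < 0.05
        assert (np.sign(s.fst_bn[ok]) == np.sign(s.fst_wc[ok])).mean() > 0.9


class TestFis:
    def test_all_homozygous_gives_one(self):
        pair = pair_from_counts([(6, 0, 4)], [(5, 0, 5)])
        assert ss.multilocus_fis(pair) == pytest.approx(1.0)

    def test_hardy_weinberg_near_zero(self):
        # exact HWE proportions at p=0.5 in both samples
        pair = pair_from_counts([(25, 50, 25)] * 20, [(25, 50, 25)] * 20)
        assert abs(ss.multilocus_fis(pair)) < 0.02

    def test_no_polymorphism_raises(self):
        pair = pair_from_counts([(10, 0, 0)], [(10, 0, 0)])
        with pytest.raises(NotEstimableError):
            ss.multilocus_fis(pair)

    def test_selfing_equilibrium(self):
        # FIS -> s/(2-s) = 0.9/1.1 = 0.818 for selfing rate 0.9
        cfg = ss.SimConfig(n_loci=500, ne=300, selfing_rate=0.9, tau=5,
                           n0=100, n_tau=100, seed=17)
        pair = ss.simulate_temporal_population(cfg)
        assert ss.multilocus_fis(pair) == pytest.approx(0.9 / 1.1, abs=0.05)


# ---------------------------------------------------------------------------
# linkage disequilibrium


class TestLD:
    def test_locus_against_itself(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]])
        assert ss.ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_complement_dosage(self):
        g = np.array([[0, 2], [1, 1], [2, 0], [0, 2], [1, 1]], dtype=np.int8)
        m = make_matrix(g)
        assert ss.ld_r2(m, 0, 1) == pytest.approx(1.0)

    def test_matches_pearson_squared(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(8, 2)).astype(np.int8)
        m = make_matrix(g)
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert ss.ld_r2(m, 0, 1) == pytest.approx(r**2)

    def test_monomorphic_is_missing(self):
        m = make_matrix([[0, 0], [0, 1], [0, 2]])
        assert np.isnan(ss.ld_r2(m, 0, 1))

    def test_profile_of_exact_copies(self):
        col = np.array([0, 1, 2, 0, 1, 2, 0, 0], dtype=np.int8)
        g = np.tile(col[:, None], (1, 10))
        m = make_matrix(g, pos=np.arange(1, 11) * 30_000)
        prof = ss.ld_decay_profile(m)
        occupied = prof.n_pairs > 0
        assert np.allclose(prof.mean_r2[occupied], 1.0)
        assert prof.decay_distance(0.2) is None

    def test_independent_loci_r2_near_one_over_n(self):
        rng = np.random.default_rng(5)
        n = 40
        g = rng.integers(0, 3, size=(n, 60)).astype(np.int8)
        m = make_matrix(g, pos=np.arange(1, 61) * 40_000)
        prof = ss.ld_decay_profile(m)
        occupied = prof.n_pairs > 20
        # E[r^2] ~ 1/n under independence; well below 0.2 for n=40
        assert np.nanmax(prof.mean_r2[occupied]) < 0.2
        assert np.nanmean(prof.mean_r2[occupied]) == pytest.approx(1 / n, abs=0.03)

    def test_recovers_programmed_decay_scale(self):
        from selfscan.simulate import linked_dosage_matrix

        decay_bp = 150_000.0
        m = linked_dosage_matrix(150, 300, spacing_bp=10_000, decay_bp=decay_bp, seed=9)
        prof = ss.ld_decay_profile(m, bin_width_kb=50.0)
        # r^2(d) ~ exp(-2d/decay): r^2 < 0.2 beyond ~ -ln(0.2)*decay/2 = 121 kb
        d = prof.decay_distance(0.2)
        expected_kb = -np.log(0.2) * decay_bp / 2 / 1000
        assert d is not None and abs(d - expected_kb) <= 50.0
        assert prof.initial_ld > 0.75
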