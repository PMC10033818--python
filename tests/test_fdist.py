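"""FDist-style machinery: weighted global FST, island-model coalescent null,
kernel p-values and quantile envelopes. The coalescent engine is cross-checked
against the classic island-model expectation and against msprime on a small
configuration."""

import numpy as np
import pandas as pd
import pytest

import selfscan as ss
from selfscan.fdist import (
    IslandModelConfig,
    JointNullCloud,
    _simulate_cloud_kernel,
    _weighted_mean_fst,
    kernel_pvalue,
    quantile_envelope,
)

from conftest import pair_from_counts


def make_summaries(fst, h1):
    return pd.DataFrame({"fst_bn": fst, "h1_hat": h1})


class TestGlobalFst:
    def test_constant_fst(self):
        s = make_summaries([0.3, 0.3, 0.3], [0.1, 0.5, 0.9])
        assert ss.global_fst_weighted(s) == pytest.approx(0.3)

    def test_zero_weight_locus_dropped(self):
        s = make_summaries([0.2, 0.0], [0.5, 0.0])
        assert ss.global_fst_weighted(s) == pytest.approx(0.2)

    def test_hand_computed_weighted_mean(self):
        fst = [0.1, 0.2, 0.0, 0.4, -0.05]
        h1 = [0.2, 0.1, 0.3, 0.05, 0.15]
        s = make_summaries(fst, h1)
        expected = np.dot(fst, h1) / np.sum(h1)
        assert ss.global_fst_weighted(s) == pytest.approx(expected)

    def test_all_zero_weights_raise(self):
        with pytest.raises(ValueError):
            ss.global_fst_weighted(make_summaries([0.1], [0.0]))


class TestInferH1:
    @pytest.mark.parametrize("h0,fst,expected", [(0.3, 0.0, 0.3), (0.02, 0.5, 0.04), (0.0, 0.2, 0.0)])
    def test_formula(self, h0, fst, expected):
        assert ss.infer_h1(h0, fst) == pytest.approx(expected)

    def test_fst_one_raises(self):
        with pytest.raises(ValueError):
            ss.infer_h1(0.1, 1.0)


class TestCoalescentNull:
    def test_deterministic_under_fixed_seed(self):
        cfg = IslandModelConfig(n_sim=200, sample_sizes=(40, 40), seed=5)
        a = ss.simulate_island_null(cfg, (10.0, 1.0))
        b = ss.simulate_island_null(cfg, (10.0, 1.0))
        np.testing.assert_array_equal(a.fst, b.fst)
        np.testing.assert_array_equal(a.h1, b.h1)

    def test_all_points_retained_and_in_range(self):
        cfg = IslandModelConfig(n_sim=500, sample_sizes=(40, 40), seed=6)
        cloud = ss.simulate_island_null(cfg, (10.0, 1.0))
        assert len(cloud.h1) == 500
        assert np.all((cloud.h1 > 0) & (cloud.h1 <= 1))
        assert np.all(cloud.fst <= 1.0)

    def test_panmixia_limit_centred_at_zero(self):
        # small island configuration so the very high migration rate stays cheap
        cfg = IslandModelConfig(k_groups=2, d_demes=2, n_sim=1500, sample_sizes=(50, 50), seed=7)
        cloud = ss.simulate_island_null(cfg, (500.0, 500.0))
        assert abs(_weighted_mean_fst(cloud)) < 0.01
        assert (cloud.fst < 0).any()  # negative estimates allowed

    def test_classic_island_model_expectation(self):
        # single group of d=10 demes (between-group rate 0): FST ~
        # 1/(1 + 4Nm (d/(d-1))^2) with 4Nm = 2 * per-lineage scaled rate
        mig_w = 10.0
        h1, fst = _simulate_cloud_kernel(4000, 50, 50, 1, 10, mig_w, 0.0, 99)
        expected = 1.0 / (1.0 + 2 * mig_w * (10 / 9) ** 2)
        observed = float(np.sum(h1 * fst) / np.sum(h1))
        assert observed == pytest.approx(expected, rel=0.2)

    def test_doubling_migration_decreases_fst(self):
        cfg = IslandModelConfig(n_sim=2000, sample_sizes=(50, 50), seed=8)
        low = _weighted_mean_fst(ss.simulate_island_null(cfg, (5.0, 0.5)))
        high = _weighted_mean_fst(ss.simulate_island_null(cfg, (10.0, 1.0)))
        assert high < low

    def test_agrees_with_msprime_island_model(self):
        # 4-island symmetric model: our k=2 x d=2 kernel with mig_b = 2*mig_w
        # gives per-deme rate mig_w to each of the 3 other demes; msprime with
        # migration m = rate/N per generation has the same rate ratio
        msprime = pytest.importorskip("msprime")
        rate = 4.0
        h1, fst = _simulate_cloud_kernel(3000, 30, 30, 2, 2, rate, 2 * rate, 1234)
        mine = float(np.sum(h1 * fst) / np.sum(h1))

        N = 500
        demography = msprime.Demography.isolated_model([N] * 4)
        for i in range(4):
            for j in range(4):
                if i != j:
                    # ploidy-1 deme of size N: pair-coalescence rate is 1/N per
                    # generation, so per-deme scaled rate r maps to m = r/N
                    demography.migration_matrix[i][j] = rate / N
        rng = np.random.default_rng(55)
        f_sum = h_sum = 0.0
        reps = msprime.sim_ancestry(
            samples={0: 30, 1: 30}, demography=demography, ploidy=1,
            num_replicates=1500, random_seed=2024,
        )
        for ts in reps:
            tree = ts.first(tracked_samples=ts.samples(population=0))
            lengths = np.array([tree.branch_length(v) for v in range(ts.num_nodes)])
            v = rng.choice(len(lengths), p=lengths / lengths.sum())
            da = tree.num_tracked_samples(v)
            dtot = tree.num_samples(v)
            db = dtot - da
            p1, p2 = da / 30, db / 30
            fa = (da * (da - 1) + (30 - da) * (29 - da)) / (30 * 29)
            fb = (db * (db - 1) + (30 - db) * (29 - db)) / (30 * 29)
            f0 = (fa + fb) / 2
            f1 = p1 * p2 + (1 - p1) * (1 - p2)
            h_sum += 1 - f1
            f_sum += (f0 - f1) / (1 - f1) * (1 - f1)
        theirs = f_sum / h_sum
        assert mine == pytest.approx(theirs, rel=0.25, abs=0.01)


class TestCalibration:
    def test_reaches_target(self):
        cfg = IslandModelConfig(n_sim=1000, sample_sizes=(60, 60), seed=9,
                                target_fst=0.10, pilot_n=2000)
        rates = ss.calibrate_migration(cfg)
        cloud = ss.simulate_island_null(cfg, rates, n_loci=3000, seed=10)
        assert _weighted_mean_fst(cloud) == pytest.approx(0.10, rel=0.15)

    def test_near_zero_target_gives_high_migration(self):
        cfg = IslandModelConfig(k_groups=5, d_demes=4, n_sim=500, sample_sizes=(60, 60),
                                seed=11, target_fst=0.004, pilot_n=1500)
        rates = ss.calibrate_migration(cfg)
        assert rates[0] > 50
        cloud = ss.simulate_island_null(cfg, rates, n_loci=1500, seed=12)
        assert _weighted_mean_fst(cloud) < 0.006


def synthetic_cloud(n=20000, seed=13):
    rng = np.random.default_rng(seed)
    h1 = rng.uniform(0.02, 0.6, size=n)
    fst = rng.normal(0.03, 0.01 + 0.08 * h1)
    return JointNullCloud(h1=h1, fst=fst, n_requested=n)


class TestKernelPvalue:
    def test_extremes(self):
        cloud = synthetic_cloud(5000)
        assert kernel_pvalue(cloud, 0.3, -10.0) == pytest.approx(1.0)
        assert kernel_pvalue(cloud, 0.3, 10.0) == pytest.approx(1 / 5001)

    def test_outside_support_missing_with_warning(self):
        cloud = synthetic_cloud(2000)
        with pytest.warns(UserWarning):
            assert np.isnan(kernel_pvalue(cloud, 0.99, 0.1))

    def test_matches_binned_tail_count(self):
        # plain tail count within a narrow heterozygosity band, +-0.02
        cloud = synthetic_cloud(30000)
        for h_obs, f_obs in [(0.2, 0.05), (0.4, 0.08), (0.1, 0.03)]:
            band = np.abs(cloud.h1 - h_obs) < 0.02
            direct = np.mean(cloud.fst[band] >= f_obs)
            assert kernel_pvalue(cloud, h_obs, f_obs) == pytest.approx(direct, abs=0.02)

    def test_median_of_band_near_half(self):
        cloud = synthetic_cloud(30000)
        band = np.abs(cloud.h1 - 0.3) < 0.01
        med = np.median(cloud.fst[band])
        assert kernel_pvalue(cloud, 0.3, med) == pytest.approx(0.5, abs=0.05)


class TestEnvelope:
    def test_alpha_half_gives_medians(self):
        cloud = synthetic_cloud(10000)
        env = quantile_envelope(cloud, 0.5, n_bins=10)
        edges = np.linspace(cloud.h1.min(), cloud.h1.max(), 11)
        for b in range(10):
            sel = (cloud.h1 >= edges[b]) & (cloud.h1 <= edges[b + 1]) if b == 9 else (
                (cloud.h1 >= edges[b]) & (cloud.h1 < edges[b + 1])
            )
            if sel.sum() >= 50:
                assert env.quantile[b] == pytest.approx(np.median(cloud.fst[sel]), abs=1e-9)

    def test_stricter_envelope_lies_above(self):
        cloud = synthetic_cloud(10000)
        e99 = quantile_envelope(cloud, 0.01)
        e95 = quantile_envelope(cloud, 0.05)
        ok = np.isfinite(e99.quantile) & np.isfinite(e95.quantile)
        assert np.all(e99.quantile[ok] >= e95.quantile[ok])

    def test_sparse_bin_missing(self):
        cloud = synthetic_cloud(300)
        env = quantile_envelope(cloud, 0.05, n_bins=30, min_points=50)
        assert np.isnan(env.quantile).any()


class TestFdistScan:
    def test_identical_duplicated_sample_yields_no_outliers(self):
        rng = np.random.default_rng(20)
        counts = []
        for _ in range(500):
            p = rng.uniform(0.05, 0.95)
            f = 0.9
            g = [p**2 + f * p * (1 - p), 2 * p * (1 - p) * (1 - f), 0]
            g[2] = 1 - g[0] - g[1]
            counts.append(tuple(rng.multinomial(60, g)))
        pair = pair_from_counts(counts, counts)
        # small island configuration: the near-zero calibration target implies
        # very high migration, which is cheap only with few demes
        cfg = IslandModelConfig(k_groups=5, d_demes=4, n_sim=1500, seed=21, pilot_n=1000)
        res = ss.FdistScan(pair, cfg).fit()
        assert (res.table["class"] == "sig1").sum() == 0

    def test_sig1_implies_small_p_and_above_envelopes(self, filtered_neutral_pair):
        cfg = IslandModelConfig(n_sim=1500, seed=23, pilot_n=1000)
        res = ss.FdistScan(filtered_neutral_pair, cfg).fit()
        t = res.table
        sig1 = t[t["class"] == "sig1"]
        assert np.all(sig1["p"] <= 0.01)
        if len(sig1):
            e95 = res.envelope_95.at(sig1["h1_hat"].to_numpy())
            assert np.all(sig1["fst"].to_numpy() > e95)
        sig5 = t[t["class"] == "sig5"]
        assert np.all((sig5["p"] > 0.01) | (sig5["p"] <= 0.05))
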