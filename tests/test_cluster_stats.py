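"""Cluster-based permutation test, t-tests with effect sizes, correlations."""

import numpy as np
import pytest

from tmreeg.cluster_stats import (
    Neighborhood,
    cluster_permutation_test,
    pearson_correlation,
    ttest_effsize,
)
from tmreeg.montage import CHANNELS_19, montage_adjacency


class TestNeighborhood:
    def test_montage_adjacency_is_symmetric_irreflexive_connected(self):
        adj = montage_adjacency()
        for ch, nbrs in adj.items():
            assert ch not in nbrs
            assert len(nbrs) >= 1
            for nb in nbrs:
                assert ch in adj[nb]

    def test_validation_rejects_bad_matrices(self):
        with pytest.raises(ValueError, match="symmetric"):
            Neighborhood(["a", "b"], np.array([[False, True], [False, False]]))
        with pytest.raises(ValueError, match="irreflexive"):
            Neighborhood(["a", "b"], np.array([[True, True], [True, False]]))
        with pytest.raises(ValueError, match="neighbour"):
            Neighborhood(["a", "b", "c"], np.array([
                [False, True, False], [True, False, False], [False, False, False],
            ]))


class TestClusterPermutation:
    def test_identical_paired_data_has_no_clusters(self, montage_neighborhood):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((12, 19, 2, 8))
        res = cluster_permutation_test(a, a.copy(), paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=100, seed=0)
        assert res.clusters == []

    def test_constant_data_yields_no_clusters(self, montage_neighborhood):
        a = np.ones((10, 19, 1, 5))
        res = cluster_permutation_test(a, np.zeros_like(a), paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=64, seed=0)
        assert res.clusters == []

    def test_single_channel_effect_blocked_by_min_chan(self, montage_neighborhood):
        rng = np.random.default_rng(1)
        b = rng.standard_normal((14, 19, 1, 6))
        a = b.copy()  # differences identically zero except at Cz
        cz = CHANNELS_19.index("Cz")
        a[:, cz] += 5.0 + rng.normal(0.0, 0.5, size=(14, 1, 6))
        res = cluster_permutation_test(a, b, paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=100, min_chan=2, seed=1)
        assert res.clusters == []
        res1 = cluster_permutation_test(a, b, paired=True,
                                        neighborhood=montage_neighborhood,
                                        n_perm=100, min_chan=1, seed=1)
        assert any("Cz" in c.channels for c in res1.clusters)

    def test_adjacent_alpha_band_effect_recovered(self):
        from tmreeg.validation import cluster_effect_recovery

        res = cluster_effect_recovery(seed=1)
        assert res["n_significant"] >= 1
        assert res["effect_channels_recovered"] >= 2

    def test_seed_reproducibility(self, montage_neighborhood):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10, 19, 1, 6))
        b = rng.standard_normal((10, 19, 1, 6))
        r1 = cluster_permutation_test(a, b, paired=False,
                                      neighborhood=montage_neighborhood,
                                      n_perm=200, seed=42)
        r2 = cluster_permutation_test(a, b, paired=False,
                                      neighborhood=montage_neighborhood,
                                      n_perm=200, seed=42)
        assert [(c.stat, c.p) for c in r1.clusters] == [(c.stat, c.p) for c in r2.clusters]

    def test_sign_relabeling_mirrors_clusters(self, montage_neighborhood):
        # swapping conditions negates t; with full sign-flip enumeration the
        # mirrored clusters get identical statistics and p-values
        rng = np.random.default_rng(6)
        a = rng.standard_normal((7, 19, 1, 4))
        b = rng.standard_normal((7, 19, 1, 4))
        b[:, 5:8] -= 1.5
        fwd = cluster_permutation_test(a, b, paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=128, seed=0)  # 2^7 = 128: exact
        rev = cluster_permutation_test(b, a, paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=128, seed=0)
        assert sorted(round(c.stat, 9) for c in fwd.clusters) == \
            sorted(round(-c.stat, 9) for c in rev.clusters)
        assert sorted(c.p for c in fwd.clusters) == sorted(c.p for c in rev.clusters)

    def test_p_floor_respected(self, montage_neighborhood):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((10, 19, 1, 5)) + 3.0
        b = rng.standard_normal((10, 19, 1, 5))
        res = cluster_permutation_test(a, b, paired=True,
                                       neighborhood=montage_neighborhood,
                                       n_perm=200, seed=0)
        assert res.clusters
        assert all(c.p >= 1.0 / (res.n_perm + 1) for c in res.clusters)

    def test_cluster_points_are_connected(self, montage_neighborhood):
        import networkx as nx

        rng = np.random.default_rng(8)
        a = rng.standard_normal((12, 19, 2, 6))
        b = rng.standard_normal((12, 19, 2, 6))
        a[:, [6, 7, 18], :, 2:5] += 1.2  # P3/P4/Pz block
        res = cluster_permutation_test(a, b, paired=False,
                                       neighborhood=montage_neighborhood,
                                       n_perm=100, seed=3)
        adj = montage_neighborhood.matrix
        for cl in res.clusters:
            g = nx.Graph()
            pts = [tuple(p) for p in cl.points]
            g.add_nodes_from(pts)
            for c, f, t in pts:
                for other in pts:
                    oc, of, ot = other
                    grid_nb = c == oc and ((abs(f - of) == 1 and t == ot)
                                           or (f == of and abs(t - ot) == 1))
                    chan_nb = f == of and t == ot and adj[c, oc]
                    if grid_nb or chan_nb:
                        g.add_edge((c, f, t), other)
            assert nx.is_connected(g)

    def test_cross_check_against_mne_on_adjacency_free_data(self):
        # independent route: mne's one-sample sign-flip cluster test on a
        # single-channel time series (pure temporal clustering)
        from mne.stats import permutation_cluster_1samp_test
        from scipy.stats import t as tdist

        rng = np.random.default_rng(9)
        d = rng.standard_normal((10, 30))
        d[:, 10:16] += 1.0
        thresh = float(tdist.ppf(0.975, 9))
        _, mne_clusters, mne_p, _ = permutation_cluster_1samp_test(
            d, threshold=thresh, n_permutations=1024, tail=0, seed=0,
            out_type="indices", verbose="error",
        )
        nbh = Neighborhood(["Cz"], np.zeros((1, 1), dtype=bool))
        res = cluster_permutation_test(d[:, None, None, :], np.zeros_like(d)[:, None, None, :],
                                       paired=True, neighborhood=nbh,
                                       n_perm=2048, min_chan=1, seed=0)
        mne_sets = {frozenset(int(i) for i in c[0]) for c in mne_clusters}
        our_sets = {frozenset(int(i) for i in c.points[:, 2]) for c in res.clusters}
        assert our_sets == mne_sets
        # the strongest cluster should agree in significance
        assert (min(mne_p) < 0.05) == (min(c.p for c in res.clusters) < 0.05)

    def test_invalid_inputs(self, montage_neighborhood):
        a = np.zeros((5, 19, 1, 4))
        with pytest.raises(ValueError):
            cluster_permutation_test(a, a, paired=True,
                                     neighborhood=montage_neighborhood, n_perm=0)
        with pytest.raises(ValueError):
            cluster_permutation_test(a, np.zeros((4, 19, 1, 4)), paired=True,
                                     neighborhood=montage_neighborhood, n_perm=10)


class TestTTestEffsize:
    def test_identical_paired_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p, d = ttest_effsize(x, x, paired=True)
        assert (t, d) == (0.0, 0.0)
        assert df == 3

    def test_unit_cohens_d_by_construction(self):
        # differences constructed with mean 1 and SD(ddof=1) exactly 1
        y = np.zeros(4)
        diffs = np.array([0.0, 1.0, 1.0, 2.0])
        diffs = 1.0 + (diffs - diffs.mean()) / diffs.std(ddof=1)
        t, df, p, d_val = ttest_effsize(y + diffs, y, paired=True)
        assert d_val == pytest.approx(1.0, rel=1e-12)
        assert t == pytest.approx(1.0 * np.sqrt(4), rel=1e-12)

    def test_matches_hand_computed_t(self):
        # arithmetic oracle from the definition, two fixed 5-element samples
        x = np.array([2.1, 3.4, 1.9, 2.8, 3.0])
        y = np.array([1.5, 2.2, 2.0, 1.7, 2.4])
        n = 5
        sp2 = ((n - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / (2 * n - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / n))
        t, df, p, d = ttest_effsize(x, y, paired=False)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert df == 8
        assert d == pytest.approx((x.mean() - y.mean()) / np.sqrt(sp2), rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_effsize([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], paired=True)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_mean_r_near_zero(self):
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(1000):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            rs.append(pearson_correlation(x, y)[0])
        assert abs(np.mean(rs)) < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
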