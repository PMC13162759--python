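"""Spatial clustering, sign-flip permutation, effect sizes, FDR."""

import itertools

import numpy as np
import pytest

from narousal import (build_adjacency, channel_ttest, cohens_d_from_t,
                      fdr_correct, form_clusters, signflip_permutation)
from narousal.clusterstats import (_max_cluster_mass, _neighbor_lists,
                                   chain_adjacency)
from narousal.montage import Montage


class TestChannelTtest:
    def test_matches_closed_form(self, rng):
        maps = 0.1 + 0.25 * rng.standard_normal((25, 8))
        stat = channel_ttest(maps)
        expected = maps.mean(0) / (maps.std(0, ddof=1) / np.sqrt(25))
        assert np.allclose(stat.t, expected, atol=1e-12)
        assert stat.df == 24

    def test_constant_channel_across_subjects_symmetry(self, rng):
        col = rng.standard_normal(10)
        maps = np.tile(col[:, None], (1, 5))
        stat = channel_ttest(maps)
        assert np.allclose(stat.t, stat.t[0])

    def test_all_zero_maps_rejected(self):
        with pytest.raises(ValueError):
            channel_ttest(np.zeros((5, 4)))


class TestAdjacency:
    def test_square_side_vs_diagonal(self):
        # unit square of side 0.3: sides < 0.4 < diagonal (~0.424)
        pos = np.array([[0, 0, 1.0], [0.3, 0, 1.0],
                        [0.3, 0.3, 1.0], [0, 0.3, 1.0]])
        pos /= np.linalg.norm(pos, axis=1).max()
        side = 0.3 / np.linalg.norm([0.3, 0.3, 1.0])
        mont = Montage(["a", "b", "c", "d"], pos)
        adj = build_adjacency(mont, threshold=side * 1.1)
        assert adj.sum() == 8  # the 4 sides, both directions
        assert not adj[0, 2] and not adj[1, 3]

    def test_threshold_extremes(self, montage32):
        assert build_adjacency(montage32, threshold=1e-9).sum() == 0
        full = build_adjacency(montage32, threshold=3.0)
        n = montage32.n_channels
        assert full.sum() == n * (n - 1)

    def test_unnormalized_positions_rejected(self):
        mont = Montage(["a", "b"], np.array([[0, 0, 2.0], [0, 0.5, 1.0]]))
        with pytest.raises(ValueError, match="normalized"):
            build_adjacency(mont)

    def test_posterior_region_is_connected(self, montage32):
        # at 32-channel density the 0.4 threshold leaves outer frontal
        # electrodes isolated; the parieto-occipital region, where the
        # simulated couplings live, must form a single component
        import networkx as nx
        from narousal.montage import POSTERIOR_32
        adj = build_adjacency(montage32)
        post = montage32.index(POSTERIOR_32)
        g = nx.from_numpy_array(adj[np.ix_(post, post)])
        assert nx.is_connected(g)


class TestFormClusters:
    def test_chain_example_with_sign_break(self):
        t = np.array([3.0, 3.0, -3.0, 3.0, 3.0])
        clusters = form_clusters(t, chain_adjacency(5), t_crit=2.0)
        member_sets = [c.members.tolist() for c in clusters]
        assert member_sets == [[0, 1], [2], [3, 4]]
        assert [c.sign for c in clusters] == [1, -1, 1]

    def test_mass_and_peak(self):
        t = np.array([-3.0, -4.0, -5.0])
        (cl,) = form_clusters(t, chain_adjacency(3), t_crit=2.0)
        assert cl.mass == pytest.approx(12.0)
        assert cl.peak_t == pytest.approx(-5.0)
        assert cl.mass >= abs(cl.peak_t)

    def test_nothing_supra_threshold(self, rng):
        t = 0.1 * rng.standard_normal(6)
        assert form_clusters(t, chain_adjacency(6), t_crit=2.0) == []

    def test_clusters_partition_supra_set(self, rng, montage32):
        t = 3.0 * rng.standard_normal(montage32.n_channels)
        adj = build_adjacency(montage32)
        clusters = form_clusters(t, adj, t_crit=2.0)
        members = np.concatenate([c.members for c in clusters]) if clusters \
            else np.array([], dtype=int)
        assert len(members) == len(set(members.tolist()))
        assert set(members.tolist()) == set(
            np.flatnonzero(np.abs(t) > 2.0).tolist())


class TestSignflipPermutation:
    def test_injected_posterior_effect_detected(self, montage32):
        g = np.random.default_rng(61)
        post = montage32.index(["PO7", "PO3", "POz", "PO4", "PO8",
                                "O1", "Oz", "O2"])
        adj = build_adjacency(montage32)
        maps = 0.1 * g.standard_normal((25, montage32.n_channels))
        maps[:, post] -= 0.15
        clusters = signflip_permutation(maps, adj, n_perm=1000, seed=62)
        sig = [c for c in clusters if c.p_corrected < 0.05 and c.sign < 0]
        assert any(set(post.tolist()) <= set(c.members.tolist())
                   for c in sig)

    def test_sampled_null_matches_exhaustive_enumeration(self, rng):
        # n = 8 subjects: all 2^8 sign patterns enumerable
        n, n_ch = 8, 6
        maps = rng.standard_normal((n, n_ch))
        adj = chain_adjacency(n_ch)
        neighbors = _neighbor_lists(adj)
        from scipy import stats as st
        t_crit = float(st.t.ppf(0.975, n - 1))
        exhaustive = []
        for signs in itertools.product([-1.0, 1.0], repeat=n):
            flipped = np.array(signs)[:, None] * maps
            t = flipped.mean(0) / (flipped.std(0, ddof=1) / np.sqrt(n))
            exhaustive.append(_max_cluster_mass(t, neighbors, t_crit))
        exhaustive = np.array(exhaustive)
        from narousal.clusterstats import max_null_masses
        sampled = max_null_masses(maps, adj, n_perm=4000, seed=63)
        sem = exhaustive.std() / np.sqrt(4000)
        assert sampled.mean() == pytest.approx(exhaustive.mean(),
                                               abs=5 * sem)
        assert sampled.var() == pytest.approx(exhaustive.var(), rel=0.2)

    def test_invariant_to_channel_relabeling(self, rng):
        n_ch = 10
        maps = rng.standard_normal((12, n_ch))
        maps[:, :4] += 0.8
        adj = chain_adjacency(n_ch)
        perm = rng.permutation(n_ch)
        clusters_a = signflip_permutation(maps, adj, n_perm=500, seed=64)
        clusters_b = signflip_permutation(maps[:, perm],
                                          adj[np.ix_(perm, perm)],
                                          n_perm=500, seed=64)
        ps_a = sorted(c.p_corrected for c in clusters_a)
        ps_b = sorted(c.p_corrected for c in clusters_b)
        assert np.allclose(ps_a, ps_b)


class TestEffectSize:
    @pytest.mark.parametrize("t,n,expected", [
        (-4.47, 25, -0.89), (2.24, 25, 0.45), (0.0, 25, 0.0),
    ])
    def test_one_sample_d(self, t, n, expected):
        assert cohens_d_from_t(t, n) == pytest.approx(expected, abs=0.005)

    def test_linear_in_t(self):
        assert cohens_d_from_t(6.0, 25) == pytest.approx(
            2 * cohens_d_from_t(3.0, 25))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0)


class TestFdr:
    def test_hand_computed_bh_example(self):
        reject, p_adj = fdr_correct([0.01, 0.02, 0.03, 0.9], q=0.05)
        # BH: 0.03 <= (3/4) * 0.05, so the first three are rejected
        assert reject.tolist() == [True, True, True, False]

    def test_all_tiny_p_rejected(self):
        reject, _ = fdr_correct(np.full(68, 0.001), q=0.05)
        assert reject.all()

    def test_single_p_identity(self):
        _, p_adj = fdr_correct([0.04])
        assert p_adj[0] == pytest.approx(0.04)

    def test_adjusted_p_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(size=30))
        _, p_adj = fdr_correct(p)
        assert np.all(np.diff(p_adj) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.1, 1.2])
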