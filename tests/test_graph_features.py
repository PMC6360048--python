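import itertools

import numpy as np
import pytest

from motifeeg.graph_features import (_rewired_null, band_graph_features,
                                     clustering_features, degree_features,
                                     direction_of_flow,
                                     extract_motif_features,
                                     motif_feature_names, path_features,
                                     small_world_features, threshold_graph,
                                     transitivity)
from motifeeg.motif_connectivity import SyncConfig, SyncResult


def complete(n, w=1.0):
    g = np.full((n, n), w)
    np.fill_diagonal(g, 0.0)
    return g


def er_graph(n, p, rng):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


# ---------------------------------------------------------------------------
# brute-force oracles (independent enumeration; no matrix powers)
# ---------------------------------------------------------------------------

def brute_clustering(a):
    n = len(a)
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j] > 0]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        e = sum(1 for x, y in itertools.combinations(nb, 2) if a[x, y] > 0)
        vals.append(2.0 * e / (k * (k - 1)))
    return float(np.mean(vals))


def brute_weighted_clustering(w):
    n = len(w)
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            vals.append(0.0)
            continue
        t = 0.5 * sum((w[i, j] * w[j, h] * w[h, i]) ** (1 / 3)
                      for j in range(n) for h in range(n))
        kw = w[i].sum()
        vals.append(2.0 * t / (kw * (kw - 1)) if kw * (kw - 1) > 0 else 0.0)
    return float(np.mean(vals))


def brute_transitivity(a):
    n = len(a)
    triangles = sum(1 for i, j, h in itertools.combinations(range(n), 3)
                    if a[i, j] and a[j, h] and a[h, i])
    triplets = sum(k * (k - 1) / 2 for k in a.sum(axis=1))
    return 3.0 * triangles / triplets if triplets else 0.0


def brute_paths(g, weighted):
    """All-pairs shortest paths by Floyd-Warshall relaxation."""
    n = len(g)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if g[i, j] > 0:
                d[i, j] = 1.0 / g[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    off = ~np.eye(n, dtype=bool)
    dd = d[off]
    finite = np.isfinite(dd)
    L = float(dd[finite].mean()) if finite.any() else 0.0
    G = float(np.where(finite, 1.0 / np.where(dd > 0, dd, 1), 0.0).mean())
    return L, G


class TestThresholdGraph:
    def test_all_equal_weights_give_empty_graph(self):
        assert threshold_graph(complete(5, 0.3)).sum() == 0

    def test_single_strong_pair_survives(self):
        w = complete(4, 0.1)
        w[0, 1] = w[1, 0] = 0.9
        a = threshold_graph(w)
        assert a[0, 1] == 1 and a.sum() == 2

    def test_scale_invariance(self, rng):
        w = er_graph(8, 0.5, rng) * rng.random((8, 8))
        w = (w + w.T) / 2
        np.testing.assert_array_equal(threshold_graph(w),
                                      threshold_graph(3.7 * w))

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            threshold_graph(rng.random((4, 4)))


class TestDegree:
    def test_complete_graph(self):
        k, kw = degree_features(complete(5), complete(5))
        assert k == pytest.approx(4.0)

    def test_empty_graph(self):
        z = np.zeros((5, 5))
        assert degree_features(z, z) == (0.0, 0.0)

    def test_uniform_half_weights(self):
        _, kw = degree_features(complete(5), complete(5, 0.5))
        assert kw == pytest.approx(2.0)


class TestClustering:
    def test_complete_graph_fully_clustered(self):
        C, Cw = clustering_features(complete(6), complete(6))
        assert C == pytest.approx(1.0)
        assert Cw == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1
        C, _ = clustering_features(a, a)
        assert C == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(5):
            a = er_graph(9, 0.5, rng)
            w = a * rng.uniform(0.1, 1.0, size=a.shape)
            w = (w + w.T) / 2
            C, Cw = clustering_features(a, w)
            assert C == pytest.approx(brute_clustering(a))
            assert Cw == pytest.approx(brute_weighted_clustering(w))


class TestTransitivity:
    def test_complete_graph(self):
        assert transitivity(complete(6)) == pytest.approx(1.0)

    def test_bipartite_triangle_free(self):
        a = np.zeros((6, 6))
        a[:3, 3:] = 1
        a[3:, :3] = 1
        assert transitivity(a) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a = er_graph(10, 0.4, rng)
            assert transitivity(a) == pytest.approx(brute_transitivity(a))

    def test_weighted_reduces_to_unweighted_on_unit_weights(self, rng):
        a = er_graph(8, 0.6, rng)
        assert transitivity(a, weighted=True) == \
            pytest.approx(transitivity(a, weighted=False))


class TestPaths:
    def test_complete_graph(self):
        L, G = path_features(complete(5))
        assert (L, G) == (1.0, 1.0)

    def test_path_graph_hand_enumeration(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
        L, G = path_features(a)
        assert L == pytest.approx(4 / 3)
        assert G == pytest.approx((1 + 1 + 0.5) * 2 / 6)

    def test_disconnected_pairs_excluded_from_L(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1  # plus two isolated nodes
        L, G = path_features(a)
        assert L == pytest.approx(1.0)
        assert G == pytest.approx(2 / 12)

    def test_matches_brute_force_weighted(self, rng):
        for _ in range(4):
            a = er_graph(8, 0.45, rng)
            w = a * rng.uniform(0.2, 1.0, size=a.shape)
            w = (w + w.T) / 2
            for weighted, g in ((False, a), (True, w)):
                L, G = path_features(g, weighted=weighted)
                Lb, Gb = brute_paths(g, weighted)
                assert L == pytest.approx(Lb)
                assert G == pytest.approx(Gb)


class TestSmallWorld:
    def test_rewiring_preserves_degree_sequence(self, rng):
        a = er_graph(12, 0.4, rng)
        null = _rewired_null(a, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(null.sum(axis=1)),
                                      np.sort(a.sum(axis=1)))
        assert np.all(np.diag(null) == 0)
        np.testing.assert_array_equal(null, null.T)

    def test_ring_lattice_more_clustered_than_null(self):
        # each node linked to its 2 neighbours on each side: C = 0.5
        n = 20
        a = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                a[i, (i + d) % n] = a[(i + d) % n, i] = 1
        Ls, Cs, S = small_world_features(a, n_null=10, seed=3)
        assert Cs > 1.0
        assert S == pytest.approx(Cs / Ls)

    def test_deterministic_given_seed(self, rng):
        a = er_graph(10, 0.5, rng)
        assert small_world_features(a, seed=11) == \
            small_world_features(a, seed=11)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            small_world_features(np.zeros((4, 4)))


class TestDirectionOfFlow:
    def test_zero_matrix(self):
        assert direction_of_flow(np.zeros((6, 6))) == 0.0

    def test_saturated_upper_triangle(self):
        n = 6
        q = np.triu(np.ones((n, n)), 1)
        q -= q.T
        assert direction_of_flow(q) == n * (n - 1) / 2

    def test_odd_symmetry(self, rng):
        q = np.sign(rng.standard_normal((7, 7)))
        q = np.triu(q, 1)
        q -= q.T
        assert direction_of_flow(-q) == -direction_of_flow(q)

    def test_non_antisymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="antisymmetric"):
            direction_of_flow(np.abs(rng.standard_normal((4, 4))) + 1)


class TestExtractMotifFeatures:
    def test_feature_names_and_counts(self, mini_montage):
        names = motif_feature_names(mini_montage)
        # 14 graph-family x 4 bands + 4 PE + (2 pairs x 4 bands) Dm
        assert len(names) == 56 + 4 + 8

    def test_deterministic_given_seed(self, mini_montage, rng):
        trial = rng.standard_normal((6, 700))
        a = extract_motif_features(trial, 128.0, mini_montage, seed=5)
        b = extract_motif_features(trial, 128.0, mini_montage, seed=5)
        assert a.equals(b)

    def test_identical_channels_degenerate_limits(self, mini_montage, rng):
        x = rng.standard_normal(700)
        trial = np.tile(x, (6, 1))
        feats = extract_motif_features(trial, 128.0, mini_montage)
        for band in ("theta", "alpha", "beta", "gamma"):
            assert feats[f"Dm(A1,A2)({band})"] == pytest.approx(0.0)
            assert feats[f"DoF({band})"] == 0.0
            # all-ones Q thresholds to an empty graph
            assert feats[f"k({band})"] == 0.0
            assert feats[f"kw({band})"] == pytest.approx(5.0)

    def test_band_graph_features_on_synthetic_sync(self, rng):
        w = np.abs(rng.random((10, 10)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        q = np.sign(np.triu(rng.standard_normal((10, 10)), 1))
        q -= q.T
        feats = band_graph_features(SyncResult(Q=w, q=q), seed=2)
        assert set(feats) == {"k", "kw", "C", "Cw", "Tr", "Trw", "L", "Lw",
                              "G", "Gw", "Ls", "Cs", "S", "DoF"}
        assert feats["S"] == pytest.approx(
            feats["Cs"] / feats["Ls"]) or feats["Ls"] == 0
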