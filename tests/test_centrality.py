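"""Strength, bridge statistics and z-standardization."""

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.data import SchemaError

from oracles import brute_force_bridge_betweenness


def _net(W, item_ids=None):
    from symptomnet.ggm import GGMNetwork

    p = W.shape[0]
    item_ids = item_ids or tuple(f"v{j}" for j in range(p))
    iu = np.triu_indices(p, 1)
    return GGMNetwork(
        W=W, item_ids=item_ids, lam=0.1, ebic=0.0, gamma=0.5,
        n_edges=int(np.count_nonzero(W[iu])),
    )


def _random_partition(p, k, rng):
    labels = np.array([f"c{i % k}" for i in range(p)])
    rng.shuffle(labels)
    return sn.CommunityMap({f"v{j}": labels[j] for j in range(p)})


class TestStrength:
    def test_zero_network(self):
        assert np.all(sn.strength(np.zeros((4, 4))) == 0)

    def test_signed_edges_sum_in_absolute_value(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.2
        np.testing.assert_allclose(sn.strength(W), [0.7, 0.5, 0.2])

    def test_matches_brute_force_row_sums(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(21, 21)) * (rng.random((21, 21)) < 0.3)
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        expected = [sum(abs(W[i, j]) for j in range(21) if j != i)
                    for i in range(21)]
        np.testing.assert_allclose(sn.strength(W), expected)


class TestBridgeStrength:
    def test_single_community_all_zero(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        cm = sn.CommunityMap({f"v{j}": "All" for j in range(6)})
        assert np.all(sn.bridge_strength(W, cm, tuple(f"v{j}" for j in range(6))) == 0)

    def test_single_cross_edge(self):
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = -0.3
        cm = sn.CommunityMap({"v0": "A", "v1": "A", "v2": "B", "v3": "B"})
        ids = ("v0", "v1", "v2", "v3")
        np.testing.assert_allclose(
            sn.bridge_strength(W, cm, ids), [0.3, 0.0, 0.3, 0.0]
        )

    def test_decomposition_identity_on_random_networks(self):
        """strength = within + bridge exactly, on 100 random (W, partition)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.integers(4, 15)
            A = rng.normal(size=(p, p)) * (rng.random((p, p)) < 0.4)
            W = (A + A.T) / 2
            np.fill_diagonal(W, 0.0)
            ids = tuple(f"v{j}" for j in range(p))
            cm = _random_partition(p, rng.integers(1, 4), rng)
            s = sn.strength(W)
            b = sn.bridge_strength(W, cm, ids)
            w = sn.within_strength(W, cm, ids)
            np.testing.assert_allclose(b + w, s, rtol=0, atol=1e-12)
            assert np.all(b >= 0) and np.all(w >= 0)

    def test_missing_node_raises(self):
        W = np.zeros((2, 2))
        cm = sn.CommunityMap({"v0": "A"})
        with pytest.raises(SchemaError):
            sn.bridge_strength(W, cm, ("v0", "v1"))


class TestBridgeBetweenness:
    def test_three_node_path(self):
        """a - b - c with comm(a) != comm(c): b scores 1, ends 0."""
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        cm = sn.CommunityMap({"v0": "A", "v1": "A", "v2": "B"})
        ids = ("v0", "v1", "v2")
        np.testing.assert_allclose(
            sn.bridge_betweenness(W, cm, ids), [0.0, 1.0, 0.0]
        )

    def test_empty_network_all_zero(self):
        cm = sn.CommunityMap({f"v{j}": ("A" if j < 2 else "B") for j in range(4)})
        ids = tuple(f"v{j}" for j in range(4))
        assert np.all(sn.bridge_betweenness(np.zeros((4, 4)), cm, ids) == 0)

    def test_tied_shortest_paths_share_credit(self):
        """Diamond: two equal-length routes; each middle node gets 0.5."""
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            W[i, j] = W[j, i] = 0.5
        cm = sn.CommunityMap({"v0": "A", "v1": "A", "v2": "A", "v3": "B"})
        ids = tuple(f"v{j}" for j in range(4))
        bb = sn.bridge_betweenness(W, cm, ids)
        np.testing.assert_allclose(bb, [0.0, 0.5, 0.5, 0.0])

    def test_matches_exhaustive_enumeration(self):
        """Brandes-style counting equals brute-force path enumeration on
        50 random weighted graphs with p <= 6."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = int(rng.integers(4, 7))
            mask = rng.random((p, p)) < 0.5
            A = rng.uniform(0.1, 0.9, size=(p, p)) * mask
            W = np.triu(A, 1)
            W = W + W.T
            k = int(rng.integers(2, 4))
            labels = np.array([f"c{i % k}" for i in range(p)])
            rng.shuffle(labels)
            ids = tuple(f"v{j}" for j in range(p))
            cm = sn.CommunityMap({ids[j]: labels[j] for j in range(p)})
            ours = sn.bridge_betweenness(W, cm, ids)
            ref = brute_force_bridge_betweenness(W, labels)
            np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_leaves_score_zero(self):
        rng = np.random.default_rng(4)
        W = np.zeros((5, 5))
        # star: node 0 center, all others leaves
        for j in range(1, 5):
            w = rng.uniform(0.2, 0.8)
            W[0, j] = W[j, 0] = w
        cm = _random_partition(5, 2, rng)
        ids = tuple(f"v{j}" for j in range(5))
        bb = sn.bridge_betweenness(W, cm, ids)
        assert np.all(bb[1:] == 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = 8
        A = rng.normal(size=(p, p)) * (rng.random((p, p)) < 0.4)
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0.0)
        ids = tuple(f"v{j}" for j in range(p))
        cm = _random_partition(p, 3, rng)
        perm = rng.permutation(p)
        Wp = W[np.ix_(perm, perm)]
        ids_p = tuple(ids[k] for k in perm)
        for fn in (sn.strength,):
            np.testing.assert_allclose(fn(W)[perm], fn(Wp))
        np.testing.assert_allclose(
            sn.bridge_strength(W, cm, ids)[perm],
            sn.bridge_strength(Wp, cm, ids_p),
        )
        np.testing.assert_allclose(
            sn.bridge_betweenness(W, cm, ids)[perm],
            sn.bridge_betweenness(Wp, cm, ids_p),
            atol=1e-12,
        )


class TestZStandardize:
    def test_simple_example(self):
        np.testing.assert_allclose(sn.zstandardize([0, 1, 2]), [-1, 0, 1])

    def test_constant_vector_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            z = sn.zstandardize([3.0, 3.0, 3.0])
        np.testing.assert_array_equal(z, 0.0)

    def test_output_moments(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 30)) * rng.uniform(0.1, 5)
            z = sn.zstandardize(x)
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0)


class TestNodeMetricsTable:
    def test_columns_and_identity(self, dass_model, responses_318):
        r = sn.correlation_matrix(sn.npn_transform(responses_318))
        net = sn.select_network(r)
        cm = dass_model.communities
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # possible constant bb vector
            tbl = sn.node_metrics(net, cm)
        assert list(tbl.node) == list(net.item_ids)
        np.testing.assert_allclose(
            tbl.strength, tbl.bridge_strength + tbl.within_strength
        )
        assert tbl.strength_z.mean() == pytest.approx(0.0, abs=1e-12)
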