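"""Density-matched binarisation and multiplex participation metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroplex import (
    ConnectivityMatrix,
    MultiplexNetwork,
    TooSparseError,
    binarize_to_density,
    build_multiplex,
    layer_degree,
    matrix_density,
    min_group_density,
    participation,
)


def _cm(values, modality="FA", **kw):
    return ConnectivityMatrix(values=np.asarray(values, float), modality=modality, **kw)


def _symmetric(rng, n, zero_frac=0.0):
    w = rng.random((n, n))
    w = np.triu(w, 1)
    if zero_frac:
        mask = rng.random((n, n)) < zero_frac
        w[mask] = 0.0
    return w + w.T


class TestMatrixDensity:
    def test_counts_positive_upper_triangle(self, rng):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 2] = w[2, 3] = 0.5
        w = w + w.T
        assert matrix_density(_cm(w)) == pytest.approx(0.5)

    def test_empty_matrix_is_zero(self):
        assert matrix_density(_cm(np.zeros((5, 5)))) == 0.0

    def test_full_matrix_is_one(self, rng):
        assert matrix_density(_cm(_symmetric(rng, 6))) == 1.0

    def test_directed_uses_ordered_pairs(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        m = ConnectivityMatrix(values=w, modality="TE", directed=True)
        assert matrix_density(m) == pytest.approx(1 / 6)


class TestMinGroupDensity:
    def test_takes_the_minimum(self, rng):
        mats = []
        for target in (0.31, 0.22, 0.40):
            n = 68
            w = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            e = int(round(target * len(iu[0])))
            pick = rng.choice(len(iu[0]), e, replace=False)
            w[iu[0][pick], iu[1][pick]] = rng.uniform(0.2, 0.8, e)
            mats.append(_cm(w + w.T))
        assert min_group_density(mats) == pytest.approx(0.22, abs=1e-3)

    def test_single_matrix_returns_own_density(self, rng):
        m = _cm(_symmetric(rng, 10, zero_frac=0.5))
        assert min_group_density([m]) == matrix_density(m)

    def test_mixed_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            min_group_density([_cm(_symmetric(rng, 5)), _cm(_symmetric(rng, 6))])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            min_group_density([])


class TestBinarizeToDensity:
    def test_keeps_the_strongest_edges(self):
        w = np.zeros((4, 4))
        weights = {(0, 1): 6, (0, 2): 5, (0, 3): 4, (1, 2): 3, (1, 3): 2, (2, 3): 1}
        for (i, j), v in weights.items():
            w[i, j] = w[j, i] = v
        adj = binarize_to_density(_cm(w), 0.5)
        assert adj.sum() // 2 == 3
        assert adj[0, 1] == adj[0, 2] == adj[0, 3] == 1
        assert adj[1, 2] == adj[1, 3] == adj[2, 3] == 0

    def test_study_density_on_68_nodes_keeps_501_edges(self, rng):
        w = _symmetric(rng, 68)
        adj = binarize_to_density(_cm(w), 0.22)
        assert adj.sum() // 2 == 501  # floor(0.22 * 68 * 67 / 2)

    def test_zero_density_rejected(self, rng):
        with pytest.raises(ValueError):
            binarize_to_density(_cm(_symmetric(rng, 4)), 0.0)

    def test_too_sparse_matrix_rejected(self):
        w = np.zeros((10, 10))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(TooSparseError):
            binarize_to_density(_cm(w), 0.5)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(99)
        w = _symmetric(rng, 12)
        a = binarize_to_density(_cm(w), 0.3)
        b = binarize_to_density(_cm(w * scale), 0.3)
        assert np.array_equal(a, b)

    def test_tie_break_is_lexicographic_and_deterministic(self):
        w = np.ones((4, 4)) - np.eye(4)  # all weights tie
        adj = binarize_to_density(_cm(w), 0.5)
        # the 3 lexicographically first pairs win: (0,1), (0,2), (0,3)
        assert adj[0, 1] == adj[0, 2] == adj[0, 3] == 1
        assert adj[1, 2] == adj[1, 3] == adj[2, 3] == 0


def _random_multiplex(rng, n=10, density=0.3):
    a = binarize_to_density(_cm(_symmetric(rng, n)), density)
    b = binarize_to_density(
        _cm(_symmetric(rng, n), modality="PLV", band="8-12Hz"), density
    )
    return MultiplexNetwork(
        layers=[a, b], layer_tags=["FA", "PLV"], density=density
    )


def _participation_bruteforce(layers):
    """Direct evaluation of the printed participation formula."""
    m = len(layers)
    n = layers[0].shape[0]
    p = np.zeros(n)
    for i in range(n):
        k = [layer[i].sum() for layer in layers]
        o = sum(k)
        if o == 0:
            p[i] = 0.0
        else:
            p[i] = m / (m - 1) * (1 - sum((ki / o) ** 2 for ki in k))
    return p


class TestParticipation:
    def test_equal_degrees_give_full_participation(self):
        # M=2, k1=k2=2 -> p = 2 * (1 - (1/4 + 1/4)) = 1
        a = np.zeros((5, 5), dtype=np.int8)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1
        mx = MultiplexNetwork(layers=[a, a.copy()], layer_tags=["s", "f"], density=0.2)
        res = participation(mx)
        assert res.p[0] == pytest.approx(1.0)
        assert res.o[0] == 4

    def test_single_layer_node_has_zero_participation(self):
        a = np.zeros((5, 5), dtype=np.int8)
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = a[0, 3] = a[3, 0] = 1
        b = np.zeros((5, 5), dtype=np.int8)
        mx = MultiplexNetwork(layers=[a, b], layer_tags=["s", "f"], density=0.3)
        assert participation(mx).p[0] == pytest.approx(0.0)

    def test_three_one_split_evaluates_printed_formula(self):
        # M=2, k1=3, k2=1 -> p = 2 * (1 - (9/16 + 1/16)) = 0.75
        a = np.zeros((6, 6), dtype=np.int8)
        for j in (1, 2, 3):
            a[0, j] = a[j, 0] = 1
        b = np.zeros((6, 6), dtype=np.int8)
        b[0, 4] = b[4, 0] = 1
        mx = MultiplexNetwork(layers=[a, b], layer_tags=["s", "f"], density=0.2)
        assert participation(mx).p[0] == pytest.approx(0.75)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_equals_bruteforce_formula_on_random_multiplexes(self, seed):
        rng = np.random.default_rng(seed)
        mx = _random_multiplex(rng, n=int(rng.integers(5, 15)))
        res = participation(mx)
        expected = _participation_bruteforce(mx.layers)
        assert np.allclose(res.p, expected, atol=1e-12)
        assert np.all(res.p >= 0.0) and np.all(res.p <= 1.0)
        assert np.array_equal(res.o, res.k.sum(axis=0))

    def test_node_relabelling_permutes_participation(self, rng):
        mx = _random_multiplex(rng, n=9)
        perm = rng.permutation(9)
        permuted = MultiplexNetwork(
            layers=[layer[np.ix_(perm, perm)] for layer in mx.layers],
            layer_tags=mx.layer_tags,
            density=mx.density,
        )
        assert np.allclose(participation(permuted).p, participation(mx).p[perm])


class TestBuildMultiplex:
    def test_identical_layers_give_unit_participation(self, rng):
        w = _symmetric(rng, 10)
        s = _cm(w)
        f = _cm(w.copy(), modality="PLV", band="8-12Hz")
        mx = build_multiplex(s, f, density=0.3)
        res = participation(mx)
        connected = res.o > 0
        assert np.allclose(res.p[connected], 1.0)

    def test_layers_share_the_edge_budget(self, rng):
        mx = build_multiplex(
            _cm(_symmetric(rng, 15)),
            _cm(_symmetric(rng, 15), modality="PLV", band="8-12Hz"),
            density=0.22,
        )
        counts = [layer.sum() // 2 for layer in mx.layers]
        assert counts[0] == counts[1] == int(np.floor(0.22 * 15 * 14 / 2))

    def test_all_zero_functional_layer_fails_loudly(self, rng):
        with pytest.raises(TooSparseError):
            build_multiplex(
                _cm(_symmetric(rng, 8)),
                _cm(np.zeros((8, 8)), modality="PLV", band="8-12Hz"),
                density=0.25,
            )

    def test_inward_mode_rewards_a_strong_te_column(self, rng):
        n = 8
        w = rng.random((n, n)) * 0.1
        w[:, 3] = 0.9  # node 3 is a strong receiver
        np.fill_diagonal(w, 0.0)
        te = ConnectivityMatrix(values=w, modality="TE", directed=True)
        mx = build_multiplex(_cm(_symmetric(rng, n)), te, density=0.22,
                             direction_mode="inward")
        k_func = mx.degrees()[1]
        assert k_func[3] == k_func.max()

    def test_direction_mode_must_match_directedness(self, rng):
        s = _cm(_symmetric(rng, 6))
        f = _cm(_symmetric(rng, 6), modality="PLV", band="8-12Hz")
        te = ConnectivityMatrix(values=rng.random((6, 6)), modality="TE", directed=True)
        with pytest.raises(ValueError):
            build_multiplex(s, te, density=0.3, direction_mode="undirected")
        with pytest.raises(ValueError):
            build_multiplex(s, f, density=0.3, direction_mode="inward")


class TestLayerDegree:
    def test_triangle_layer(self):
        a = np.zeros((3, 3), dtype=np.int8)
        a[[0, 1, 2], [1, 2, 0]] = 1
        a |= a.T
        mx = MultiplexNetwork(layers=[a, np.zeros_like(a)], layer_tags=["s", "f"],
                              density=1.0)
        assert np.array_equal(layer_degree(mx, 0), [2, 2, 2])
        assert np.array_equal(layer_degree(mx, 1), [0, 0, 0])

    def test_matches_row_sum_oracle(self, rng):
        mx = _random_multiplex(rng, n=12)
        for m, layer in enumerate(mx.layers):
            assert np.array_equal(layer_degree(mx, m), np.asarray(layer).sum(axis=1))

    def test_bad_index_rejected(self, rng):
        with pytest.raises(IndexError):
            layer_degree(_random_multiplex(rng), 5)
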