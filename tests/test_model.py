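"""Per-edge operations, closed forms, and batched/unbatched agreement."""

import itertools

import numpy as np
import pytest

from hyperfill.errors import ContractError, DimensionError
from hyperfill.model import (
    AblationFlags,
    Hyperedge,
    ModelConfig,
    build_batch,
    decompose_hyperedge,
    forward_scores,
    fuse_attention,
    init_params,
    inter_message_passing,
    intra_message_passing,
    load_checkpoint,
    normalize_adjacency,
    pool_maxmin,
    pool_norm,
    save_checkpoint,
    score_edge_reference,
    score_hyperedge,
)
from conftest import random_edges


def brute_force_conv(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-vertex neighbor sum with explicit 1/sqrt(d_i d_j) factors."""
    deg = A.sum(axis=1)
    out = np.zeros_like(X)
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if A[i, j] and deg[i] > 0 and deg[j] > 0:
                out[i] += X[j] / np.sqrt(deg[i] * deg[j])
    return out


class TestDecomposition:
    def test_two_substrates_one_product(self):
        dec = decompose_hyperedge(Hyperedge(substrates=(5, 9), products=(2,)))
        assert np.array_equal(dec.A_S, [[0, 1], [1, 0]])
        assert np.array_equal(dec.A_P, [[0]])
        assert np.array_equal(dec.A_SP, [[1], [1]])
        assert np.array_equal(dec.A, [[0, 0, 1], [0, 0, 1], [1, 1, 0]])

    def test_smallest_edge(self):
        dec = decompose_hyperedge(Hyperedge(substrates=(0,), products=(1,)))
        assert np.array_equal(dec.A, [[0, 1], [1, 0]])
        assert dec.A_S.item() == 0 and dec.A_P.item() == 0

    def test_subgraphs_partition_complete_graph(self):
        rng = np.random.default_rng(0)
        for edge in random_edges(rng, 50, 100):
            dec = decompose_hyperedge(edge)
            k = edge.k
            full = np.zeros((edge.size, edge.size))
            full[:k, :k] = dec.A_S
            full[k:, k:] = dec.A_P
            union = full + dec.A
            assert np.array_equal(union, np.ones((edge.size, edge.size)) - np.eye(edge.size))

    def test_invariants(self):
        with pytest.raises(ContractError):
            Hyperedge(substrates=(1, 2), products=(2, 3))
        with pytest.raises(ContractError):
            Hyperedge(substrates=(), products=())
        # exchange-style edges with one empty side are allowed
        e = Hyperedge(substrates=(4,), products=())
        assert decompose_hyperedge(e).A.shape == (1, 1)


class TestNormalization:
    @pytest.mark.parametrize("k", range(2, 11))
    def test_complete_graph_closed_form(self, k):
        A = np.ones((k, k)) - np.eye(k)
        assert np.array_equal(normalize_adjacency(A), A / (k - 1))

    def test_isolated_vertex_guard(self):
        A = np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 0]])
        N = normalize_adjacency(A)
        assert np.all(N[2] == 0) and np.all(N[:, 2] == 0)
        assert N[0, 1] == 1.0


class TestMessagePassing:
    @pytest.fixture()
    def weights(self):
        rng = np.random.default_rng(11)
        d = 8
        return rng.normal(size=(d, d)), rng.normal(size=(d, d)), rng.normal(size=(d, d))

    def test_single_substrate_gets_zero_intra(self, weights):
        W_S, W_P, _ = weights
        e = Hyperedge(substrates=(0,), products=(1, 2))
        dec = decompose_hyperedge(e)
        rng = np.random.default_rng(0)
        X_S, X_P = rng.normal(size=(1, 8)), rng.normal(size=(2, 8))
        out = intra_message_passing(X_S, X_P, dec, W_S, W_P)
        assert np.all(out[0] == 0.0)
        assert np.all(np.abs(out) <= 1.0)

    def test_identical_rows_give_identical_outputs(self, weights):
        W_S, W_P, _ = weights
        e = Hyperedge(substrates=(0, 1, 2), products=(3,))
        dec = decompose_hyperedge(e)
        X_S = np.tile(np.linspace(-1, 1, 8), (3, 1))
        out = intra_message_passing(X_S, np.ones((1, 8)), dec, W_S, W_P)
        assert np.allclose(out[0], out[1]) and np.allclose(out[1], out[2])

    def test_inter_swaps_sides_for_unit_edge(self):
        e = Hyperedge(substrates=(0,), products=(1,))
        dec = decompose_hyperedge(e)
        X_S, X_P = np.array([[0.3, -0.7]]), np.array([[0.9, 0.1]])
        out = inter_message_passing(X_S, X_P, dec, np.eye(2))
        assert np.allclose(out[0], X_P[0])
        assert np.allclose(out[1], X_S[0])

    def test_substrate_rows_independent_of_each_other(self, weights):
        _, _, W = weights
        e = Hyperedge(substrates=(0, 1), products=(2, 3))
        dec = decompose_hyperedge(e)
        rng = np.random.default_rng(1)
        X_S, X_P = rng.normal(size=(2, 8)), rng.normal(size=(2, 8))
        base = inter_message_passing(X_S, X_P, dec, W)
        X_S2 = X_S.copy()
        X_S2[1] += 10.0
        pert = inter_message_passing(X_S2, X_P, dec, W)
        assert np.allclose(base[0], pert[0])  # substrate 0 unaffected by substrate 1

    def test_matches_brute_force_oracle_small_edges(self, weights):
        """For k+l <= 4 the vectorised convolutions equal the explicit
        neighbor-sum with 1/sqrt(d_i d_j) factors."""
        W_S, W_P, W_I = weights
        rng = np.random.default_rng(5)
        for k, l in [(1, 1), (1, 2), (2, 1), (2, 2), (1, 3), (3, 1)]:
            e = Hyperedge(substrates=tuple(range(k)), products=tuple(range(k, k + l)))
            dec = decompose_hyperedge(e)
            X_S, X_P = rng.normal(size=(k, 8)), rng.normal(size=(l, 8))
            X = np.vstack([X_S, X_P])
            intra = intra_message_passing(X_S, X_P, dec, W_S, W_P)
            expect_S = np.clip(brute_force_conv(dec.A_S, X_S) @ W_S, -1, 1)
            expect_P = np.clip(brute_force_conv(dec.A_P, X_P) @ W_P, -1, 1)
            assert np.allclose(intra, np.vstack([expect_S, expect_P]), atol=1e-6)
            inter = inter_message_passing(X_S, X_P, dec, W_I)
            assert np.allclose(inter, np.clip(brute_force_conv(dec.A, X) @ W_I, -1, 1), atol=1e-6)

    def test_shape_errors(self, weights):
        W_S, W_P, _ = weights
        e = Hyperedge(substrates=(0, 1), products=(2,))
        dec = decompose_hyperedge(e)
        with pytest.raises(DimensionError):
            intra_message_passing(np.ones((2, 5)), np.ones((1, 5)), dec, W_S, W_P)


class TestFusionAndPooling:
    def _weights(self, d=6, identity_premap=False):
        rng = np.random.default_rng(2)
        return {
            "W_attn_pre": np.eye(d) if identity_premap else rng.normal(size=(d, d)),
            "b_attn_pre": np.zeros(d),
            "attn_a": rng.normal(size=(3, d)),
            "attn_b": np.zeros(3),
        }

    def test_betas_form_convex_combination(self):
        rng = np.random.default_rng(3)
        Xs = [rng.normal(size=(4, 6)) for _ in range(3)]
        _, betas = fuse_attention(*Xs, self._weights())
        assert betas.shape == (3,)
        assert np.all(betas >= 0) and np.isclose(betas.sum(), 1.0)

    def test_degenerate_attention_recovers_single_view(self):
        rng = np.random.default_rng(4)
        Xs = [rng.normal(size=(3, 6)) for _ in range(3)]
        w = self._weights(identity_premap=True)
        w["attn_b"] = np.array([1e3, 0.0, 0.0])  # force beta = (1, 0, 0)
        X, betas = fuse_attention(*Xs, w)
        assert np.isclose(betas[0], 1.0)
        assert np.allclose(X, Xs[0])

    def test_identical_views_identity_premap(self):
        rng = np.random.default_rng(5)
        T = rng.normal(size=(4, 6))
        X, _ = fuse_attention(T, T, T, self._weights(identity_premap=True))
        assert np.allclose(X, T)

    def test_pool_norm_values(self):
        single = np.array([[3.0, 4.0, -2.0]])
        assert np.allclose(pool_norm(single), [3.0, 4.0, 2.0], atol=1e-6)
        two = np.array([[0.0, 1.0], [2.0, 1.0]])
        assert np.allclose(pool_norm(two), [np.sqrt(2.0), 1.0], atol=1e-6)

    def test_pool_maxmin_values(self):
        assert np.allclose(pool_maxmin(np.array([[1.0, 5.0], [3.0, 2.0]])), [2.0, 3.0])
        assert np.allclose(pool_maxmin(np.array([[7.0, -1.0]])), [0.0, 0.0])

    def test_pooling_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 7))
        for _ in range(20):
            P = rng.permutation(5)
            assert np.allclose(pool_norm(X), pool_norm(X[P]))
            assert np.allclose(pool_maxmin(X), pool_maxmin(X[P]))

    def test_pooling_rejects_empty(self):
        with pytest.raises(ContractError):
            pool_norm(np.zeros((0, 4)))
        with pytest.raises(ContractError):
            pool_maxmin(np.zeros((0, 4)))


class TestScoring:
    def test_score_range_and_zero_weights(self, toy_params):
        y1, y2 = np.ones(256), np.zeros(256)
        s = score_hyperedge(y1, y2, toy_params)
        assert 0.0 < s < 1.0
        zeros = {k: np.zeros_like(v) for k, v in toy_params.items()}
        assert score_hyperedge(y1, y2, zeros) == pytest.approx(0.5)

    def test_batched_equals_reference_all_variants(self, toy_params):
        rng = np.random.default_rng(9)
        X_init = rng.normal(size=(40, 256))
        edges = random_edges(rng, 12, 40) + [
            Hyperedge(substrates=(0, 1), products=()),  # exchange-style edges
            Hyperedge(substrates=(), products=(2,)),
        ]
        for flags in itertools.product([False, True], repeat=3):
            cfg = ModelConfig(ablation=AblationFlags(*flags))
            batch_scores = np.asarray(forward_scores(toy_params, X_init, build_batch(edges), cfg))
            ref = np.array([score_edge_reference(toy_params, X_init, e, cfg) for e in edges])
            assert np.allclose(batch_scores, ref, atol=1e-9), flags

    def test_end_to_end_permutation_invariance(self, toy_params):
        rng = np.random.default_rng(10)
        X_init = rng.normal(size=(60, 256))
        cfg = ModelConfig()
        edges = random_edges(rng, 20, 60)
        base = np.asarray(forward_scores(toy_params, X_init, build_batch(edges), cfg))
        shuffled = [
            Hyperedge(
                substrates=tuple(rng.permutation(e.substrates)),
                products=tuple(rng.permutation(e.products)),
            )
            for e in edges
        ]
        again = np.asarray(forward_scores(toy_params, X_init, build_batch(shuffled), cfg))
        assert np.allclose(base, again, atol=1e-9)


def test_checkpoint_round_trip(tmp_path, toy_params):
    cfg = ModelConfig(ablation=AblationFlags(no_attention=True))
    p = tmp_path / "ckpt.npz"
    save_checkpoint(p, toy_params, cfg, seed=123)
    params, cfg2, seed = load_checkpoint(p)
    assert seed == 123
    assert cfg2 == cfg
    assert all(np.array_equal(params[k], toy_params[k]) for k in toy_params)
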