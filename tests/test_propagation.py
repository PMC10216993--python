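"""Attention message passing: logits, softmax, aggregation, full sweeps."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import dense_propagation_oracle
from fkgm import embedding as emb
from fkgm import graph as g
from fkgm import propagation as prop


class TestAttentionLogit:
    def test_zero_tail_projection_gives_zero(self, small_params):
        p = small_params
        p.ent_emb[1] = 0.0
        p.ent_proj[1] = 0.0
        assert prop.attention_logit(p, 0, 1, 0) == pytest.approx(0.0)

    def test_cancelling_head_and_relation_give_zero(self, small_params):
        p = small_params
        p.ent_proj[0] = 0.0  # head projection = identity
        p.rel_proj[0] = 0.0
        p.rel_emb[0] = -p.ent_emb[0]
        assert prop.attention_logit(p, 0, 1, 0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_oracle(self, small_params):
        p, e, t, r = small_params, 0, 6, 0
        v_rp = p.rel_proj[r]
        M_e = np.outer(v_rp, p.ent_proj[e]) + np.eye(3)
        M_t = np.outer(v_rp, p.ent_proj[t]) + np.eye(3)
        expected = (M_t @ p.ent_emb[t]) @ np.tanh(M_e @ p.ent_emb[e] + p.rel_emb[r])
        assert prop.attention_logit(p, e, t, r) == pytest.approx(expected, rel=1e-10)


class TestNormalizeAttention:
    def test_singleton(self):
        assert np.allclose(prop.normalize_attention(np.array([3.7])), [1.0])

    def test_symmetry(self):
        assert np.allclose(prop.normalize_attention(np.array([2.0, 2.0])), [0.5, 0.5])

    def test_direct_softmax_values(self):
        out = prop.normalize_attention(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(np.round(out, 4), [0.0900, 0.2447, 0.6652])

    def test_empty_neighborhood(self):
        assert prop.normalize_attention(np.array([])).size == 0

    def test_segment_softmax_sums_to_one(self, small_crkg, small_params):
        logits = prop.attention_logits(small_params, small_crkg)
        coeffs = prop.normalize_attention(logits, small_crkg.edges[:, 0], small_crkg.n_entities)
        assert (coeffs >= 0).all()
        sums = np.zeros(small_crkg.n_entities)
        np.add.at(sums, small_crkg.edges[:, 0], coeffs)
        with_nbrs = np.diff(small_crkg.indptr) > 0
        assert np.allclose(sums[with_nbrs], 1.0, atol=1e-6)


class TestAggregation:
    def test_single_neighbor_passthrough(self):
        w = np.array([1.0, 2.0])
        assert np.allclose(prop.aggregate_neighborhood([1.0], w[None]), w)

    def test_two_neighbor_average(self):
        vecs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(prop.aggregate_neighborhood([0.5, 0.5], vecs), [0.5, 0.5])

    def test_three_neighbor_weighted_sum_oracle(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(3, 4))
        co = prop.normalize_attention(rng.normal(size=3))
        expected = sum(c * v for c, v in zip(co, vecs))
        assert np.allclose(prop.aggregate_neighborhood(co, vecs), expected)


class TestBiInteraction:
    def test_zero_neighborhood_keeps_leaky_self(self):
        v = np.array([1.0, -2.0])
        out = prop.bi_interaction(v, np.zeros(2), np.eye(2), np.eye(2))
        assert np.allclose(out, np.where(v > 0, v, 0.2 * v))

    def test_all_zero(self):
        assert np.allclose(prop.bi_interaction(np.zeros(2), np.zeros(2), np.eye(2), np.eye(2)), 0.0)

    def test_dense_oracle(self):
        rng = np.random.default_rng(1)
        v, n = rng.normal(size=2), rng.normal(size=2)
        W1, W2 = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        lrelu = lambda x: np.where(x > 0, x, 0.2 * x)
        expected = lrelu(W1 @ (v + n)) + lrelu(W2 @ (v * n))
        assert np.allclose(prop.bi_interaction(v, n, W1, W2), expected)


class TestPropagate:
    def test_edgeless_graph_reduces_to_leaky_chain(self, small_params):
        N = small_params.n_entities
        A = sp.csr_matrix((N, N))
        cache = prop.propagate(small_params, A, 2)
        v = small_params.ent_emb
        lrelu = lambda x: np.where(x > 0, x, 0.2 * x)
        for layer in range(2):
            v = lrelu(v @ small_params.W1[layer].T) + lrelu(np.zeros_like(v))
            assert np.allclose(cache.states[layer + 1], v, atol=1e-12)

    def test_matches_dense_per_entity_oracle(self, small_crkg, small_params):
        A = prop.attention_matrix(small_crkg, small_params)
        cache = prop.propagate(small_params, A, 2)
        oracle = dense_propagation_oracle(small_params, small_crkg, 2)
        for got, want in zip(cache.states, oracle):
            assert np.abs(got - want).max() < 1e-8

    def test_dropout_zero_is_noop(self, small_crkg, small_params):
        A = prop.attention_matrix(small_crkg, small_params)
        a = prop.propagate(small_params, A, 2, message_dropout=0.0, training=True,
                           rng=np.random.default_rng(0))
        b = prop.propagate(small_params, A, 2, message_dropout=0.0, training=False)
        for x, y in zip(a.states, b.states):
            assert np.array_equal(x, y)

    def test_uniform_logits_reduce_to_neighborhood_mean(self, small_crkg, small_params):
        p = small_params
        p.ent_proj[:] = 0.0
        p.rel_proj[:] = 0.0
        p.rel_emb[:] = 0.0
        # every logit is v_t . tanh(v_e); force them equal by zeroing v_e effect
        p.ent_emb[:] = 1.0  # all entities identical -> equal logits per edge
        A = prop.attention_matrix(small_crkg, p)
        deg = np.diff(small_crkg.indptr)
        for e in range(small_crkg.n_entities):
            row = A[e].toarray().ravel()
            if deg[e]:
                nbr_counts = np.zeros(small_crkg.n_entities)
                for _, t in small_crkg.neighborhood(e):
                    nbr_counts[t] += 1
                assert np.allclose(row, nbr_counts / deg[e])

    def test_entity_permutation_equivariance(self, small_crkg, small_params):
        """Relabeling entities consistently permutes all layer states."""
        rng = np.random.default_rng(7)
        perm = rng.permutation(small_crkg.n_entities)
        inv = np.argsort(perm)
        # permuted graph: entity i becomes perm[i]
        edges = small_crkg.edges.copy()
        edges[:, 0] = perm[edges[:, 0]]
        edges[:, 2] = perm[edges[:, 2]]
        order = np.lexsort((edges[:, 2], edges[:, 1], edges[:, 0]))
        edges = edges[order]
        indptr = np.zeros(small_crkg.n_entities + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(np.bincount(edges[:, 0], minlength=small_crkg.n_entities))
        crkg_p = g.CRKG(
            n_entities=small_crkg.n_entities, n_relations=small_crkg.n_relations,
            n_kg_entities=small_crkg.n_kg_entities, n_users=small_crkg.n_users,
            n_base_relations=small_crkg.n_base_relations,
            interact_relation=small_crkg.interact_relation,
            edges=edges, indptr=indptr, roles=small_crkg.roles[inv],
        )
        params_p = small_params.copy()
        params_p.ent_emb = small_params.ent_emb[inv]
        params_p.ent_proj = small_params.ent_proj[inv]
        base = prop.propagate(small_params, prop.attention_matrix(small_crkg, small_params), 2)
        permuted = prop.propagate(params_p, prop.attention_matrix(crkg_p, params_p), 2)
        for s_base, s_perm in zip(base.states, permuted.states):
            assert np.allclose(s_perm, s_base[inv], atol=1e-10)


class TestFinalRepresentation:
    def test_zero_layer_edge_case(self, small_params):
        out = prop.final_representation([small_params.ent_emb])
        assert np.array_equal(out, small_params.ent_emb)

    def test_slices_recover_layers(self, small_crkg, small_params):
        A = prop.attention_matrix(small_crkg, small_params)
        cache = prop.propagate(small_params, A, 2)
        F = prop.final_representation(cache.states)
        d = small_params.d
        assert F.shape[1] == 3 * d
        for layer in range(3):
            assert np.array_equal(F[:, layer * d : (layer + 1) * d], cache.states[layer])

    def test_empty_states_rejected(self):
        with pytest.raises(ValueError):
            prop.final_representation([])


class TestPredictScore:
    def test_orthogonal_and_self(self):
        assert prop.predict_score(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        v = np.array([1.0, 2.0, 2.0])
        assert prop.predict_score(v, v) == pytest.approx(9.0)

    def test_arithmetic(self):
        assert prop.predict_score(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == 32.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            prop.predict_score(np.ones(3), np.ones(4))
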