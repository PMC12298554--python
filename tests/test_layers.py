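"""Relational convolution and graph attention against dense oracles.

The sparse edge-list implementations are checked against explicit dense
adjacency-matrix formulas on small random instances, plus the structural
invariants: normalisation, permutation equivariance and window locality.
"""

import numpy as np
import pytest

from mignn._tensor import Tensor
from mignn.graph import (BFC, FFC, SELF, EdgeInitParams, build_edges,
                         init_edge_weights)
from mignn.layers import (GATParams, MHAParams, RGCNParams, gat_forward,
                          gat_reweight, mha_forward, rgcn_forward)


def weighted_graph(n, nw, d, seed):
    rng = np.random.default_rng(seed)
    g = build_edges(n, nw)
    C = Tensor(rng.standard_normal((n, d)))
    g = init_edge_weights(g, C, EdgeInitParams.init(d, rng=rng))
    return g, C, rng


def dense_alpha(g, relation):
    A = np.zeros((g.n_nodes, g.n_nodes))
    idx = g.rel == relation
    A[g.dst[idx], g.src[idx]] = g.alpha.data[idx]
    return A


def dense_rgcn(g, C, params, degree_norm=True):
    """Dense-matrix evaluation of the relational convolution."""
    n = g.n_nodes
    out = np.zeros((n, params.W_self.shape[1]))
    for r, W in params.W_rel.items():
        A = dense_alpha(g, r)
        deg = (np.abs(A) > 0).sum(axis=1, keepdims=True)
        coef = np.divide(A, deg, out=np.zeros_like(A), where=deg > 0) \
            if degree_norm else A
        out += coef @ (C.data @ W.data)
    alpha_self = np.diag(dense_alpha(g, SELF))
    out += alpha_self[:, None] * (C.data @ params.W_self.data)
    if params.activation == "relu":
        out = np.maximum(out, 0.0)
    elif params.activation == "tanh":
        out = np.tanh(out)
    return out


def dense_gat_head(g, H1, params, k):
    """Dense evaluation of one attention head over the union neighborhood."""
    n = g.n_nodes
    W, a = params.W[k].data, params.a[k].data
    wh = H1.data @ W
    lrelu = np.where(wh > 0, wh, params.leaky_slope * wh)
    d_head = W.shape[1]
    s_dst, s_src = lrelu @ a[:d_head], lrelu @ a[d_head:]
    adj = np.zeros((n, n), dtype=bool)
    adj[g.dst, g.src] = True
    logits = np.where(adj, s_dst[:, None] + s_src[None, :], -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    alpha = e / e.sum(axis=1, keepdims=True)
    return alpha @ wh, alpha


class TestRGCN:
    def test_single_node_self_term_only(self):
        g, C, rng = weighted_graph(1, 4, 3, seed=0)
        params = RGCNParams.init(3, 2, rng=rng)
        out = rgcn_forward(g, C, params)
        expected = np.maximum(C.data @ params.W_self.data, 0.0)  # alpha_00 = 1
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_zero_weights_give_activation_of_zero(self):
        g, C, rng = weighted_graph(4, 2, 3, seed=1)
        params = RGCNParams.init(3, 2, rng=rng)
        for t in [params.W_self, *params.W_rel.values()]:
            t.data[...] = 0.0
        assert np.all(rgcn_forward(g, C, params).data == 0.0)

    def test_identity_weights_uniform_alpha_equal_neighborhood_mean(self):
        """With W = I, uniform α and identity activation, each node gets the
        per-relation mean of its neighborhood features plus its own."""
        n, d = 5, 3
        rng = np.random.default_rng(2)
        g = build_edges(n, 4)
        C = Tensor(rng.standard_normal((n, d)))
        ep = EdgeInitParams.init(d, rng=rng)
        for t in ep.W.values():
            t.data[...] = 0.0  # uniform softmax
        g = init_edge_weights(g, C, ep)
        params = RGCNParams.init(d, d, activation="identity", rng=rng)
        for t in [params.W_self, *params.W_rel.values()]:
            t.data[...] = np.eye(d)
        out = rgcn_forward(g, C, params).data
        for i in range(n):
            expected = C.data[i].copy()  # alpha_ii = 1 (singleton softmax)
            for r in (FFC, BFC):
                idx = (g.dst == i) & (g.rel == r)
                k = idx.sum()
                if k:
                    # uniform alpha 1/k, degree norm 1/k again
                    expected += C.data[g.src[idx]].sum(axis=0) / k ** 2
            np.testing.assert_allclose(out[i], expected, atol=1e-10)

    @pytest.mark.parametrize("degree_norm", [True, False])
    def test_matches_dense_oracle(self, degree_norm):
        for seed in range(6):
            n = 2 + seed % 5
            g, C, rng = weighted_graph(n, 4, 4, seed=seed)
            params = RGCNParams.init(4, 3, rng=rng)
            out = rgcn_forward(g, C, params, degree_norm=degree_norm)
            np.testing.assert_allclose(
                out.data, dense_rgcn(g, C, params, degree_norm), atol=1e-5)

    def test_unweighted_graph_rejected(self):
        rng = np.random.default_rng(0)
        g = build_edges(3, 2)
        with pytest.raises(ValueError, match="weights"):
            rgcn_forward(g, Tensor(rng.standard_normal((3, 3))),
                         RGCNParams.init(3, 2, rng=rng))


class TestGAT:
    def test_singleton_neighborhood_weight_one(self):
        g, C, rng = weighted_graph(1, 2, 3, seed=0)
        params = GATParams.init(3, 2, heads=1, rng=rng)
        alpha = gat_reweight(g, C, params, 0)
        np.testing.assert_allclose(alpha.data, [1.0], atol=1e-12)

    def test_zero_logit_vector_gives_uniform_weights(self):
        g, C, rng = weighted_graph(5, 4, 3, seed=1)
        params = GATParams.init(3, 2, heads=1, rng=rng)
        params.a[0].data[...] = 0.0
        alpha = gat_reweight(g, C, params, 0)
        for i in range(5):
            idx = g.dst == i
            np.testing.assert_allclose(alpha.data[idx], 1.0 / idx.sum(),
                                       atol=1e-12)

    def test_matches_dense_oracle(self):
        for seed in range(6):
            n = 2 + seed % 5
            g, C, rng = weighted_graph(n, 4, 4, seed=10 + seed)
            params = GATParams.init(4, 3, heads=2, rng=rng)
            H2 = gat_forward(g, C, params)
            for k in range(2):
                dense_out, dense_a = dense_gat_head(g, C, params, k)
                alpha = gat_reweight(g, C, params, k)
                np.testing.assert_allclose(
                    alpha.data, dense_a[g.dst, g.src], atol=1e-6)
                np.testing.assert_allclose(
                    H2.data[:, 3 * k: 3 * (k + 1)], dense_out, atol=1e-5)

    def test_normalization_per_destination_and_head(self):
        g, C, rng = weighted_graph(7, 6, 3, seed=2)
        params = GATParams.init(3, 2, heads=3, rng=rng)
        for k in range(3):
            alpha = gat_reweight(g, C, params, k)
            sums = np.zeros(7)
            np.add.at(sums, g.dst, alpha.data)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert np.all(alpha.data > 0) and np.all(alpha.data <= 1)

    def test_per_relation_normalization_mode(self):
        g, C, rng = weighted_graph(6, 4, 3, seed=4)
        params = GATParams.init(3, 2, heads=1, rng=rng)
        alpha = gat_reweight(g, C, params, 0, per_relation=True)
        for i in range(6):
            for r in (FFC, BFC, SELF):
                idx = (g.dst == i) & (g.rel == r)
                if idx.any():
                    assert abs(alpha.data[idx].sum() - 1.0) < 1e-6

    def test_single_head_reduces_to_head_output(self):
        g, C, rng = weighted_graph(4, 2, 3, seed=5)
        params = GATParams.init(3, 2, heads=1, rng=rng)
        out = gat_forward(g, C, params)
        dense_out, _ = dense_gat_head(g, C, params, 0)
        assert out.shape == (4, 2)
        np.testing.assert_allclose(out.data, dense_out, atol=1e-5)

    def test_head_concatenation_width(self):
        g, C, rng = weighted_graph(3, 2, 8, seed=6)
        params = GATParams.init(8, 40, heads=4, rng=rng)
        assert gat_forward(g, C, params).shape == (3, 160)

    def test_heads_must_be_positive(self):
        with pytest.raises(ValueError):
            GATParams.init(3, 2, heads=0)


class TestEquivarianceAndLocality:
    def test_permutation_equivariance(self):
        """Relabeling nodes and edge endpoints together permutes both
        layers' outputs identically."""
        n, d = 6, 4
        g, C, rng = weighted_graph(n, 4, d, seed=8)
        rgcn = RGCNParams.init(d, 3, rng=rng)
        gat = GATParams.init(3, 2, heads=2, rng=rng)
        H1 = rgcn_forward(g, C, rgcn)
        H2 = gat_forward(g, H1, gat)
        perm = np.random.default_rng(0).permutation(n)
        inv = np.argsort(perm)
        # permuted graph: node i -> inv[i] keeps alpha attached to edges
        g_p = type(g)(n_nodes=n, src=inv[g.src], dst=inv[g.dst], rel=g.rel,
                      nw=g.nw, alpha=g.alpha, degree=g.degree)
        C_p = Tensor(C.data[perm])
        H1_p = rgcn_forward(g_p, C_p, rgcn)
        np.testing.assert_allclose(H1_p.data, H1.data[perm], atol=1e-10)
        np.testing.assert_allclose(gat_forward(g_p, H1_p, gat).data,
                                   H2.data[perm], atol=1e-10)

    def test_two_hop_locality(self):
        """h^(2) of node 0 ignores features outside its 2-hop window."""
        n, nw, d = 12, 4, 3
        rng = np.random.default_rng(9)
        base = rng.standard_normal((n, d))
        ep_rng = np.random.default_rng(10)
        ep = EdgeInitParams.init(d, rng=ep_rng)
        rgcn = RGCNParams.init(d, 3, rng=ep_rng)
        gat = GATParams.init(3, 2, heads=1, rng=ep_rng)

        def node0_h2(features):
            g = build_edges(n, nw)
            g = init_edge_weights(g, Tensor(features), ep)
            H1 = rgcn_forward(g, Tensor(features), rgcn)
            return gat_forward(g, H1, gat).data[0]

        ref = node0_h2(base)
        far = base.copy()
        far[6:] += 3.0  # nodes beyond 2 hops of node 0 (2 * nw/2 = 4)
        np.testing.assert_allclose(node0_h2(far), ref, atol=1e-10)
        near = base.copy()
        near[1] += 1.0
        assert not np.allclose(node0_h2(near), ref)


class TestMHABaseline:
    def test_attention_spans_whole_session_only(self):
        rng = np.random.default_rng(11)
        C = Tensor(rng.standard_normal((6, 4)))
        ids = np.array([0, 0, 0, 1, 1, 1])
        params = MHAParams.init(4, 2, heads=2, rng=rng)
        out = mha_forward(C, ids, params)
        assert out.shape == (6, 4)
        # perturbing session 1 must not change session 0's rows
        C2 = Tensor(np.concatenate([C.data[:3], C.data[3:] + 5.0]))
        out2 = mha_forward(C2, ids, params)
        np.testing.assert_allclose(out2.data[:3], out.data[:3], atol=1e-12)
        assert not np.allclose(out2.data[3:], out.data[3:])
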