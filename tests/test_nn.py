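"""Network layers vs dense oracles, gradient correctness, invariances."""

import numpy as np
import pytest

import rhopocket as rp
from rhopocket.autodiff import Tensor
from rhopocket.graphs import MolecularGraph
from rhopocket.nn import (
    GraphBatch,
    LayerDims,
    batch_norm,
    forward_tensor,
    gat_layer,
    gcn_layer,
    init_params,
    param_count,
)
from conftest import random_graph


def dense_gcn_oracle(x, edges, weights, W, b):
    """D^{-1/2} A D^{-1/2} X W + b with weighted degrees, no self-loops."""
    n = x.shape[0]
    A = np.zeros((n, n))
    for (i, j), w in zip(edges, weights):
        A[j, i] = w  # message i -> j
    deg = A.sum(axis=1)
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        for j in range(n):
            if A[i, j] > 0:
                out[i] += A[i, j] / np.sqrt(deg[i] * deg[j]) * (x[j] @ W)
    return out + b


def dense_gat_oracle(x, edges, weights, W, a_src, a_dst, a_edge, b, slope=0.2):
    """Dense single-head attention with LeakyReLU logits and per-row softmax."""
    n = x.shape[0]
    hw = x @ W
    out = np.tile(b, (n, 1)).astype(float)
    incoming: dict[int, list[tuple[int, float]]] = {}
    for (src, dst), w in zip(edges, weights):
        incoming.setdefault(dst, []).append((src, w))
    for i, nbrs in incoming.items():
        logits = []
        for j, w in nbrs:
            e = a_dst @ hw[i] + a_src @ hw[j] + a_edge * w
            logits.append(e if e > 0 else slope * e)
        logits = np.array(logits)
        alpha = np.exp(logits - logits.max())
        alpha /= alpha.sum()
        out[i] = sum(a * hw[j] for a, (j, _) in zip(alpha, nbrs)) + b
    return out


@pytest.mark.parametrize("seed", range(25))
def test_gcn_layer_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    g = random_graph(rng, int(rng.integers(2, 9)), 3)
    W = rng.normal(size=(3, 4))
    b = rng.normal(size=4)
    batch = GraphBatch.from_graphs([g])
    out = gcn_layer(
        Tensor(g.node_features), batch.src, batch.dst, batch.w,
        g.n_nodes, Tensor(W), Tensor(b),
    ).value
    oracle = dense_gcn_oracle(g.node_features, g.edges, g.edge_weights, W, b)
    np.testing.assert_allclose(out, oracle, atol=1e-9)


@pytest.mark.parametrize("seed", range(25))
def test_gat_layer_matches_dense_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    g = random_graph(rng, int(rng.integers(2, 9)), 3)
    W = rng.normal(size=(3, 4))
    b = rng.normal(size=4)
    a_src, a_dst = rng.normal(size=4), rng.normal(size=4)
    a_edge = float(rng.normal())
    batch = GraphBatch.from_graphs([g])
    out = gat_layer(
        Tensor(g.node_features), batch.src, batch.dst, batch.w, g.n_nodes,
        Tensor(W), Tensor(b), Tensor(a_src), Tensor(a_dst), Tensor(np.array(a_edge)),
    ).value
    oracle = dense_gat_oracle(
        g.node_features, g.edges, g.edge_weights, W, a_src, a_dst, a_edge, b
    )
    np.testing.assert_allclose(out, oracle, atol=1e-9)


def test_gat_attention_rows_sum_to_one():
    rng = np.random.default_rng(3)
    g = random_graph(rng, 5, 3, p_edge=0.9)
    batch = GraphBatch.from_graphs([g])
    hw = g.node_features @ rng.normal(size=(3, 4))
    a_src, a_dst = rng.normal(size=4), rng.normal(size=4)
    logits = np.array([
        a_dst @ hw[d] + a_src @ hw[s] for s, d in zip(batch.src, batch.dst)
    ])
    logits = np.where(logits > 0, logits, 0.2 * logits)
    for i in set(batch.dst.tolist()):
        sel = batch.dst == i
        alpha = np.exp(logits[sel] - logits[sel].max())
        alpha /= alpha.sum()
        assert alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(alpha >= 0)


def test_single_neighbor_attention_is_identity():
    x = np.array([[1.0, 2.0], [0.5, -1.0]])
    g = MolecularGraph(x, [[0, 1], [1, 0]], [0.8, 0.8])
    batch = GraphBatch.from_graphs([g])
    W = np.eye(2)
    b = np.array([0.1, 0.2])
    out = gat_layer(
        Tensor(x), batch.src, batch.dst, batch.w, 2,
        Tensor(W), Tensor(b), Tensor(np.ones(2)), Tensor(np.ones(2)),
        Tensor(np.array(0.5)),
    ).value
    # α = 1 exactly: output is the neighbour's features + bias
    np.testing.assert_allclose(out[0], x[1] + b)
    np.testing.assert_allclose(out[1], x[0] + b)


def test_gcn_zero_edges_gives_bias_rows():
    x = np.random.default_rng(0).normal(size=(4, 3))
    g = MolecularGraph(x, np.empty((0, 2)), np.empty(0))
    batch = GraphBatch.from_graphs([g])
    b = np.array([1.0, -2.0])
    out = gcn_layer(Tensor(x), batch.src, batch.dst, batch.w, 4,
                    Tensor(np.zeros((3, 2))), Tensor(b)).value
    np.testing.assert_allclose(out, np.tile(b, (4, 1)))


class TestBatchNorm:
    def test_eval_identity_with_unit_running_stats(self):
        h = np.random.default_rng(0).normal(size=(6, 3))
        out = batch_norm(
            Tensor(h), Tensor(np.ones(3)), Tensor(np.zeros(3)),
            (np.zeros(3), np.ones(3) - 1e-5), "eval",
        ).value
        np.testing.assert_allclose(out, h, atol=1e-9)

    def test_train_normalizes_columns(self):
        h = np.random.default_rng(1).normal(size=(50, 4)) * 3 + 7
        out = batch_norm(
            Tensor(h), Tensor(np.ones(4)), Tensor(np.zeros(4)),
            (np.zeros(4), np.ones(4)), "train",
        ).value
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0), 1, atol=1e-2)

    def test_train_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            batch_norm(
                Tensor(np.ones((1, 3))), Tensor(np.ones(3)), Tensor(np.zeros(3)),
                (np.zeros(3), np.ones(3)), "train",
            )

    def test_eval_is_deterministic_and_stateless(self):
        h = np.random.default_rng(2).normal(size=(5, 2))
        rm, rv = np.array([0.3, -0.1]), np.array([1.2, 0.8])
        out1 = batch_norm(Tensor(h), Tensor(np.ones(2)), Tensor(np.zeros(2)),
                          (rm, rv), "eval").value
        out2 = batch_norm(Tensor(h), Tensor(np.ones(2)), Tensor(np.zeros(2)),
                          (rm, rv), "eval").value
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_array_equal(rm, [0.3, -0.1])  # untouched


class TestForward:
    def _graph_and_params(self, seed=0, n=6, f=5):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, n, f, p_edge=0.6)
        params = init_params(LayerDims(f, 7, 6, 5), seed=seed + 1)
        return g, params

    def test_permutation_invariance(self):
        g, params = self._graph_and_params()
        rng = np.random.default_rng(9)
        for _ in range(20):
            perm = rng.permutation(g.n_nodes)
            inv = np.argsort(perm)
            edges = np.array([[inv[i], inv[j]] for i, j in g.edges])
            gp = MolecularGraph(g.node_features[perm], edges, g.edge_weights)
            assert rp.forward(gp, params)[0] == pytest.approx(
                rp.forward(g, params)[0], abs=1e-6
            )

    def test_duplicated_graph_prediction_unchanged(self):
        g, params = self._graph_and_params()
        n = g.n_nodes
        doubled = MolecularGraph(
            np.vstack([g.node_features, g.node_features]),
            np.vstack([g.edges, g.edges + n]),
            np.concatenate([g.edge_weights, g.edge_weights]),
        )
        assert rp.forward(doubled, params)[0] == pytest.approx(
            rp.forward(g, params)[0], abs=1e-6
        )

    def test_zero_parameters_give_constant_zero_output(self):
        g, params = self._graph_and_params()
        for k in params.trainable_keys():
            params.arrays[k][...] = 0.0
        for k in ("g1", "g2", "g3"):
            params.arrays[k][...] = 1.0
        out1 = rp.forward(g, params)[0]
        g2 = random_graph(np.random.default_rng(77), 8, 5, p_edge=0.4)
        out2 = rp.forward(g2, params)[0]
        assert out1 == 0.0 and out2 == 0.0

    def test_feature_width_mismatch_rejected(self):
        g, params = self._graph_and_params()
        bad = init_params(LayerDims(g.node_features.shape[1] + 1), seed=0)
        with pytest.raises(ValueError, match="F_in"):
            rp.forward(g, bad)

    def test_label_scaling_applied(self):
        g, params = self._graph_and_params()
        base = rp.forward(g, params)[0]
        params.label_mean, params.label_std = 550.0, 40.0
        scaled = rp.forward(g, params)[0]
        assert scaled == pytest.approx(550.0 + 40.0 * base, rel=1e-12)


class TestGradients:
    def test_analytic_matches_central_finite_differences(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 5, 4, p_edge=0.7)
        batch = GraphBatch.from_graphs([g])
        params = init_params(LayerDims(4, 6, 5, 4), seed=1)
        y = np.array([5.0])
        keys = params.trainable_keys()

        def loss_and_leaves(arrays):
            p = params.copy()
            p.arrays.update({k: v.copy() for k, v in arrays.items()})
            leaves = {k: Tensor(p.arrays[k], requires_grad=True) for k in keys}
            pred = forward_tensor(batch, p, mode="train", leaves=leaves)
            return (pred - Tensor(y)).abs().mean(), leaves

        loss, leaves = loss_and_leaves(params.arrays)
        loss.backward()
        eps = 1e-6
        for k in keys:
            flat_ids = rng.choice(
                params.arrays[k].size, size=min(3, params.arrays[k].size),
                replace=False,
            )
            for fi in flat_ids:
                arrays = {kk: params.arrays[kk].copy() for kk in keys}
                arrays[k].reshape(-1)[fi] += eps
                lp, _ = loss_and_leaves(arrays)
                arrays[k].reshape(-1)[fi] -= 2 * eps
                lm, _ = loss_and_leaves(arrays)
                fd = (lp.value - lm.value) / (2 * eps)
                an = leaves[k].grad.reshape(-1)[fi]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-8), k


class TestInitAndCount:
    def test_same_seed_bit_identical(self):
        p1 = init_params(LayerDims(10), seed=5)
        p2 = init_params(LayerDims(10), seed=5)
        for k in p1.arrays:
            np.testing.assert_array_equal(p1.arrays[k], p2.arrays[k])

    def test_different_seeds_differ(self):
        p1 = init_params(LayerDims(10), seed=5)
        p2 = init_params(LayerDims(10), seed=6)
        assert any(
            not np.array_equal(p1.arrays[k], p2.arrays[k]) for k in p1.arrays
        )

    @pytest.mark.parametrize("attention", [True, False])
    def test_param_count_matches_formula(self, attention):
        dims = LayerDims(33, 32, 32, 32)
        params = init_params(dims, seed=0, attention=attention)
        assert params.n_trainable() == param_count(dims, attention=attention)

    def test_attention_count_difference_is_attention_vectors(self):
        dims = LayerDims(33, 32, 32, 32)
        diff = param_count(dims, True) - param_count(dims, False)
        assert diff == 2 * (2 * 32 + 1)  # a_src + a_dst + a_edge per GAT layer

    def test_architecture_report(self):
        on = init_params(LayerDims(4), seed=0, attention=True)
        off = init_params(LayerDims(4), seed=0, attention=False)
        assert on.architecture_report() == ["GCN", "GAT", "GAT", "GCN"]
        assert off.architecture_report() == ["GCN", "GCN", "GCN", "GCN"]


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, normalized_graphs):
        graphs, stats = normalized_graphs
        params = init_params(LayerDims(graphs[0].node_features.shape[1]), seed=2)
        params.label_mean, params.label_std = 550.0, 42.0
        path = tmp_path / "ckpt.json"
        rp.save_checkpoint(params, path, feature_columns=["a", "b"],
                           norm_stats=stats, target_units="nm")
        back, info = rp.load_checkpoint(path)
        preds0 = rp.forward(graphs[0], params)
        preds1 = rp.forward(graphs[0], back)
        np.testing.assert_allclose(preds0, preds1)
        assert info["target_units"] == "nm"
        assert info["feature_columns"] == ["a", "b"]
        np.testing.assert_array_equal(
            info["norm_stats"].retained_mask, stats.retained_mask
        )

    def test_corrupted_checkpoint_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="corrupted"):
            rp.load_checkpoint(p)
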