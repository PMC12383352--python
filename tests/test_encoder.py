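"""Graph layers and readouts: hand-checked algebra, attention
normalization, permutation symmetry."""

import numpy as np
import pytest

import connstage as cs
from connstage.encoder import EncoderModel

from conftest import random_binary_graph

PATH_3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)


class TestGINLayer:
    def test_path_graph_by_hand(self):
        x = np.array([[1.0], [2.0], [3.0]])
        out = cs.gin_layer(x, PATH_3, cs.GINLayerParams())
        assert np.allclose(out.ravel(), [3, 6, 5])

    def test_isolated_node_scales_by_one_plus_eps(self):
        x = np.array([[2.0, -1.0]])
        out = cs.gin_layer(x, np.zeros((1, 1)),
                           cs.GINLayerParams(epsilon=0.5))
        assert np.allclose(out, 1.5 * x)

    def test_triangle_one_hot_sums_all(self):
        out = cs.gin_layer(np.eye(3), TRIANGLE, cs.GINLayerParams())
        assert np.allclose(out, np.ones((3, 3)))

    def test_identity_phi_equals_matrix_oracle(self):
        # GIN with ε=0, φ=identity is exactly (A + I)·X
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            a = random_binary_graph(rng, n)
            x = rng.standard_normal((n, 3))
            out = cs.gin_layer(x, a, cs.GINLayerParams())
            assert np.allclose(out, (a + np.eye(n)) @ x, atol=1e-12)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.gin_layer(np.zeros((2, 1)), np.zeros((3, 3)),
                         cs.GINLayerParams())


class TestGATLayer:
    def test_isolated_node_passes_through_transform(self):
        w = np.array([[2.0, 0.0], [0.0, 3.0]])
        params = cs.GATLayerParams(weight=w, attn_kernel=np.ones(4))
        x = np.array([[1.0, 1.0]])
        out = cs.gat_layer(x, np.zeros((1, 1)), params)
        assert np.allclose(out, x @ w)

    def test_zero_kernel_gives_uniform_attention(self):
        params = cs.GATLayerParams(weight=np.eye(2),
                                   attn_kernel=np.zeros(4))
        x = np.array([[0.5, -1.0], [0.5, -1.0]])
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        alpha = cs.gat_attention(x, adj, params)
        assert np.allclose(alpha, 0.25 + np.zeros((2, 2)) + 0.25)
        out = cs.gat_layer(x, adj, params)
        assert np.allclose(out, x)

    def test_engineered_logits_give_two_thirds_one_third(self):
        # identical unit features make z·a constant; bias the self term
        # via the source half of the kernel so logits are (ln 2, 0)
        w = np.eye(1)
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        x = np.array([[np.log(2.0)], [0.0]])
        params = cs.GATLayerParams(weight=w,
                                   attn_kernel=np.array([1.0, 0.0]))
        alpha = cs.gat_attention(x, adj, params)
        # column 0: softmax over logits (self=ln2, neighbor=0)
        assert np.allclose(alpha[:, 0], [2 / 3, 1 / 3])

    def test_kernel_length_validated(self):
        with pytest.raises(ValueError):
            cs.GATLayerParams(weight=np.eye(2), attn_kernel=np.zeros(3))


class TestGCNLayer:
    def test_isolated_node_identity(self):
        out = cs.gcn_layer(np.array([[3.0]]), np.zeros((1, 1)), np.eye(1))
        assert np.allclose(out, [[3.0]])

    def test_two_identical_nodes_unchanged(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0]])
        adj = np.array([[0, 1], [1, 0]], dtype=float)
        out = cs.gcn_layer(x, adj, np.eye(2))
        assert np.allclose(out, x)

    def test_star_graph_normalization_coefficient(self):
        adj = np.zeros((4, 4))
        adj[0, 1:] = adj[1:, 0] = 1.0
        from connstage._nn import GCNBlock

        m = GCNBlock.normalized_adjacency(adj)
        assert np.isclose(m[0, 1], 1 / (np.sqrt(4) * np.sqrt(2)))


class TestReadouts:
    def test_constant_gate_averages(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        params = cs.ReadoutParams(gate_weight=np.zeros(2), gate_bias=3.0)
        assert np.allclose(cs.attention_readout(x, params), x.mean(axis=0))

    def test_saturated_gate_selects_node(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        # gate scores differ by 50: softmax concentrates on node 0
        params = cs.ReadoutParams(gate_weight=np.array([50.0, 0.0]))
        assert np.abs(cs.attention_readout(x, params) - x[0]).max() < 1e-6

    def test_log_two_gate_weights(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        params = cs.ReadoutParams(gate_weight=np.array([np.log(2.0), 0.0]))
        assert np.allclose(cs.attention_readout(x, params), [2 / 3, 1 / 3])

    def test_sum_readout(self):
        assert np.allclose(cs.sum_readout(np.array([[1.0, 2.0],
                                                    [3.0, 4.0]])), [4, 6])
        assert np.allclose(cs.sum_readout(np.array([[5.0, 6.0]])), [5, 6])
        assert np.allclose(cs.sum_readout(np.zeros((3, 2))), [0, 0])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cs.sum_readout(np.zeros((0, 2)))
        with pytest.raises(ValueError):
            cs.attention_readout(np.zeros((0, 2)),
                                 cs.ReadoutParams(np.zeros(2)))


def test_identity_parameterized_stack_on_triangle():
    """Composing the hand examples: GIN(φ=id) → GAT(W=id, a=0) →
    uniform readout on the triangle gives the all-ones mean vector."""
    x = np.eye(3)
    h = cs.gin_layer(x, TRIANGLE, cs.GINLayerParams())
    assert np.allclose(h, np.ones((3, 3)))
    gat = cs.GATLayerParams(weight=np.eye(3), attn_kernel=np.zeros(6))
    h2 = cs.gat_layer(h, TRIANGLE, gat)
    assert np.allclose(h2, np.ones((3, 3)))
    out = cs.attention_readout(h2, cs.ReadoutParams(np.zeros(3)))
    assert np.allclose(out, [1.0, 1.0, 1.0])


class TestAttentionNormalization:
    def test_gat_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            a = random_binary_graph(rng, n)
            params = cs.GATLayerParams(
                weight=rng.standard_normal((4, 3)),
                attn_kernel=rng.standard_normal(6))
            alpha = cs.gat_attention(rng.standard_normal((n, 4)), a, params)
            assert alpha.min() >= 0
            assert np.abs(alpha.sum(axis=0) - 1).max() < 1e-8
            # non-neighbors get exactly zero attention
            mask = (a + np.eye(n)) == 0
            assert np.all(alpha[mask] == 0)

    def test_readout_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(1, 12))
            x = rng.standard_normal((n, 5))
            params = cs.ReadoutParams(rng.standard_normal(5),
                                      float(rng.standard_normal()))
            from connstage.encoder import readout_weights

            w = readout_weights(x, params)
            assert w.min() >= 0
            assert abs(w.sum() - 1) < 1e-8


class TestEncoderModel:
    def test_variant_embedding_dims(self):
        for variant, dim in [("baseline", 64), ("sum_pool", 64),
                             ("gin_only", 128), ("gcn_variant", 64),
                             ("gat_only", 64)]:
            model = EncoderModel(variant, n_nodes=10, seed=0)
            assert model.embedding_dim == dim
            rng = np.random.default_rng(1)
            emb = model.embed_arrays(random_binary_graph(rng, 10)[None])
            assert emb.shape == (1, dim)

    def test_empty_edge_graph_is_defined(self):
        model = EncoderModel("baseline", n_nodes=6, seed=0)
        emb = model.embed_arrays(np.zeros((1, 6, 6)))
        assert np.isfinite(emb).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        model = EncoderModel("baseline", n_nodes=8, seed=2)
        for _ in range(20):
            a = random_binary_graph(rng, 8)
            perm = rng.permutation(8)
            p = np.eye(8)[perm]
            base = model.embed_arrays(a[None], np.eye(8)[None])[0]
            permuted = model.embed_arrays((p @ a @ p.T)[None], p[None])[0]
            assert np.abs(base - permuted).max() < 1e-6

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            EncoderModel("transformer", n_nodes=5)

    def test_node_count_mismatch_rejected(self):
        model = EncoderModel("baseline", n_nodes=5)
        with pytest.raises(ValueError):
            model.embed_arrays(np.zeros((1, 6, 6)))

    def test_save_load_roundtrip(self, tmp_path, toy_task_small):
        graphs, labels = toy_task_small
        model = cs.train_classifier(graphs, labels,
                                    cs.TrainConfig(epochs=5))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = EncoderModel.load(path)
        assert loaded.classes_ == model.classes_
        a = model.embed(graphs)
        b = loaded.embed(graphs)
        assert np.abs(a - b).max() < 1e-12

    def test_embed_graph_matches_batch_path(self, toy_task_small):
        graphs, _ = toy_task_small
        model = EncoderModel("baseline", n_nodes=graphs[0].n_nodes, seed=0)
        single = cs.embed_graph(graphs[0], model)
        batch = model.embed(graphs[:1])[0]
        assert np.allclose(single, batch)
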