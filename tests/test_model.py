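import numpy as np
import pytest

from plantgraphnet.autograd import Tensor
from plantgraphnet.graph_construction import GraphBatch, ImageGraph
from plantgraphnet.layers import dropout, global_add_pool
from plantgraphnet.model import HybridModel, ModelConfig
from plantgraphnet.training import Adam, Sample, TrainConfig, train_epoch


def tiny_config(**overrides):
    base = dict(
        in_features=4,
        d=3,
        C=2,
        gnn_hidden=(4, 4, 3),
        backbone_channels=(2, 3, 4),
        image_size=8,
        norm_type="none",
        p_drop=0.0,
    )
    base.update(overrides)
    return ModelConfig(**base)


def make_graph(rng, n_nodes=5, f=4, label=0):
    if n_nodes > 1:
        und = [(i, (i + 1) % n_nodes) for i in range(n_nodes)]
        edges = np.array(und + [(j, i) for i, j in und], dtype=np.int64)
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
    return ImageGraph(
        node_features=rng.normal(size=(n_nodes, f)),
        node_positions=rng.uniform(0, 20, size=(n_nodes, 2)),
        edge_index=edges,
        edge_attr=np.ones(len(edges)),
        label=label,
        method="grid",
    )


def make_images(rng, n, size=12):
    return rng.integers(0, 256, size=(n, size, size, 3)).astype(np.uint8)


class TestGnnLayer:
    def test_two_node_layer_matches_hand_computation(self):
        cfg = ModelConfig(
            in_features=1, d=1, C=2, gnn_hidden=(1, 1, 1), backbone_channels=(2, 2, 2),
            image_size=8, norm_type="none", activation="identity", p_drop=0.0,
        )
        model = HybridModel(cfg, seed=0)
        layer = model.gnn_layers[0]
        layer.W_self.data = np.array([[2.0]])
        layer.W_neigh.data = np.array([[3.0]])
        layer.b.data = np.array([0.0])
        g = ImageGraph(
            node_features=[[2.0], [5.0]],
            node_positions=[[0.0, 0.0], [1.0, 0.0]],
            edge_index=[[0, 1], [1, 0]],
            edge_attr=[1.0, 1.0],
        )
        batch = GraphBatch.from_graphs([g])
        out = model.gnn_layer_forward(Tensor(batch.node_features), batch, 1, training=False)
        # node 0: 2*2 + 3*mean({5}) = 19; node 1: 2*5 + 3*mean({2}) = 16
        np.testing.assert_allclose(out.data, [[19.0], [16.0]])

    def test_isolated_nodes_depend_only_on_self(self):
        cfg = tiny_config(activation="identity")
        model = HybridModel(cfg, seed=1)
        rng = np.random.default_rng(0)
        g1 = make_graph(rng, n_nodes=3)
        g1.edge_index = np.zeros((0, 2), dtype=np.int64)
        g1.edge_attr = np.zeros(0)
        batch = GraphBatch.from_graphs([g1])
        h = Tensor(batch.node_features)
        out = model.gnn_layer_forward(h, batch, 1, training=False)
        layer = model.gnn_layers[0]
        expected = batch.node_features @ layer.W_self.data + layer.b.data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_permutation_equivariance(self):
        model = HybridModel(tiny_config(), seed=2)
        rng = np.random.default_rng(3)
        g = make_graph(rng, n_nodes=6)
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g_perm = ImageGraph(
            node_features=g.node_features[perm],
            node_positions=g.node_positions[perm],
            edge_index=inv[g.edge_index],
            edge_attr=g.edge_attr,
        )
        b1, b2 = GraphBatch.from_graphs([g]), GraphBatch.from_graphs([g_perm])
        o1 = model.gnn_layer_forward(Tensor(b1.node_features), b1, 1, training=False)
        o2 = model.gnn_layer_forward(Tensor(b2.node_features), b2, 1, training=False)
        np.testing.assert_allclose(o2.data, o1.data[perm], atol=1e-10)

    def test_invalid_layer_index(self):
        model = HybridModel(tiny_config(), seed=0)
        rng = np.random.default_rng(0)
        batch = GraphBatch.from_graphs([make_graph(rng)])
        with pytest.raises(ValueError):
            model.gnn_layer_forward(Tensor(batch.node_features), batch, 4)


class TestGlobalAddPool:
    def test_single_node_graph_pools_to_itself(self):
        h = Tensor(np.array([[1.5, -2.0]]))
        out = global_add_pool(h, np.array([0]), 1)
        np.testing.assert_array_equal(out.data, [[1.5, -2.0]])

    def test_manual_sums_for_two_graphs(self):
        h = Tensor(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]]))
        out = global_add_pool(h, np.array([0, 0, 1, 1]), 2)
        np.testing.assert_array_equal(out.data, [[4.0, 6.0], [12.0, 14.0]])

    def test_zero_embeddings_pool_to_zero(self):
        out = global_add_pool(Tensor(np.zeros((3, 4))), np.array([0, 0, 1]), 2)
        np.testing.assert_array_equal(out.data, np.zeros((2, 4)))


class TestGnnEncode:
    def test_exactly_three_message_passing_layers(self):
        model = HybridModel(tiny_config(), seed=0)
        assert model.num_message_passing_layers == 3
        assert len(model.gnn_layers) == 3

    def test_identical_graphs_get_identical_embeddings(self):
        model = HybridModel(tiny_config(), seed=4)
        rng = np.random.default_rng(5)
        g = make_graph(rng)
        batch = GraphBatch.from_graphs([g, g])
        z = model.gnn_encode(batch, training=False).data
        np.testing.assert_array_equal(z[0], z[1])

    def test_permutation_invariance_of_graph_embedding(self):
        model = HybridModel(tiny_config(norm_type="batch"), seed=6)
        rng = np.random.default_rng(7)
        g = make_graph(rng, n_nodes=7)
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        g_perm = ImageGraph(
            node_features=g.node_features[perm],
            node_positions=g.node_positions[perm],
            edge_index=inv[g.edge_index],
            edge_attr=g.edge_attr,
        )
        z1 = model.gnn_encode(GraphBatch.from_graphs([g]), training=False).data
        z2 = model.gnn_encode(GraphBatch.from_graphs([g_perm]), training=False).data
        np.testing.assert_allclose(z1, z2, atol=1e-5)

    def test_attention_layer_variant_runs_and_is_permutation_invariant(self):
        model = HybridModel(tiny_config(layer_type="attention"), seed=8)
        rng = np.random.default_rng(9)
        g = make_graph(rng, n_nodes=6)
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g_perm = ImageGraph(
            node_features=g.node_features[perm],
            node_positions=g.node_positions[perm],
            edge_index=inv[g.edge_index],
            edge_attr=g.edge_attr,
        )
        z1 = model.gnn_encode(GraphBatch.from_graphs([g]), training=False).data
        z2 = model.gnn_encode(GraphBatch.from_graphs([g_perm]), training=False).data
        np.testing.assert_allclose(z1, z2, atol=1e-5)


class TestImageEncode:
    def test_identical_images_identical_rows(self):
        model = HybridModel(tiny_config(), seed=0)
        rng = np.random.default_rng(1)
        img = make_images(rng, 1)[0]
        z = model.image_encode(np.stack([img, img]), training=False).data
        np.testing.assert_array_equal(z[0], z[1])

    def test_zero_projection_gives_zero_embeddings(self):
        model = HybridModel(tiny_config(), seed=0)
        model.image_proj.W.data[:] = 0.0
        model.image_proj.b.data[:] = 0.0
        rng = np.random.default_rng(2)
        z = model.image_encode(make_images(rng, 3), training=False).data
        np.testing.assert_array_equal(z, np.zeros_like(z))

    @pytest.mark.parametrize("d,channels", [(2, (2, 2, 3)), (5, (2, 3, 4)), (7, (3, 4, 6))])
    def test_output_width_is_d_for_any_backbone_width(self, d, channels):
        model = HybridModel(tiny_config(d=d, backbone_channels=channels, gnn_hidden=(4, 4, d)), seed=0)
        rng = np.random.default_rng(3)
        z = model.image_encode(make_images(rng, 2), training=False).data
        assert z.shape == (2, d)

    def test_wrong_channel_count_raises(self):
        model = HybridModel(tiny_config(), seed=0)
        with pytest.raises(ValueError):
            model.image_encode(np.zeros((2, 8, 8, 4), dtype=np.uint8))


class TestForward:
    def test_zero_classifier_gives_uniform_softmax(self):
        model = HybridModel(tiny_config(C=4, p_drop=0.2), seed=0)
        model.fusion_head.W.data[:] = 0.0
        rng = np.random.default_rng(4)
        batch = GraphBatch.from_graphs([make_graph(rng), make_graph(rng)])
        logits = model.forward_hybrid(batch, make_images(rng, 2), training=False).data
        np.testing.assert_array_equal(logits, np.zeros((2, 4)))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs, 0.25)

    def test_fusion_classifier_width_is_2d(self):
        model = HybridModel(tiny_config(), seed=0)
        assert model.fusion_head.W.data.shape == (2 * model.config.d, model.config.C)
        assert model.graph_head.W.data.shape == (model.config.d, model.config.C)

    def test_hybrid_equals_manual_fusion_of_encoders(self):
        model = HybridModel(tiny_config(), seed=1)
        rng = np.random.default_rng(5)
        graphs = [make_graph(rng), make_graph(rng, n_nodes=3)]
        images = make_images(rng, 2)
        batch = GraphBatch.from_graphs(graphs)
        logits = model.forward_hybrid(batch, images, training=False).data
        zg = model.gnn_encode(batch, training=False).data
        zi = model.image_encode(images, training=False).data
        manual = np.concatenate([zg, zi], axis=1) @ model.fusion_head.W.data + model.fusion_head.b.data
        np.testing.assert_allclose(logits, manual, atol=1e-12)

    def test_dropout_zeroing_rate_matches_p(self):
        rng = np.random.default_rng(0)
        x = Tensor(np.ones(10_000))
        dropped = dropout(x, 0.2, rng, training=True).data
        rate = float(np.mean(dropped == 0.0))
        assert abs(rate - 0.2) < 0.02
        # surviving units are rescaled by 1/(1-p)
        np.testing.assert_allclose(dropped[dropped != 0], 1.25)

    def test_unimodal_graph_fallback_with_zero_head_gives_zero_logits(self):
        model = HybridModel(tiny_config(in_features=128, gnn_hidden=(4, 4, 3)), seed=0)
        model.graph_head.W.data[:] = 0.0
        fallback = ImageGraph(
            node_features=np.zeros((1, 128)),
            node_positions=np.zeros((1, 2)),
            edge_index=np.zeros((0, 2), dtype=np.int64),
            edge_attr=np.zeros(0),
        )
        logits = model.forward_unimodal(GraphBatch.from_graphs([fallback]), "graph_only").data
        np.testing.assert_array_equal(logits, np.zeros((1, model.config.C)))

    def test_unimodal_mode_input_mismatch_raises(self):
        model = HybridModel(tiny_config(), seed=0)
        rng = np.random.default_rng(6)
        with pytest.raises(TypeError):
            model.forward_unimodal(make_images(rng, 1), "graph_only")
        with pytest.raises(TypeError):
            model.forward_unimodal(GraphBatch.from_graphs([make_graph(rng)]), "image_only")

    def test_unimodal_deterministic_in_eval_mode(self):
        model = HybridModel(tiny_config(p_drop=0.2), seed=0)
        rng = np.random.default_rng(7)
        batch = GraphBatch.from_graphs([make_graph(rng), make_graph(rng)])
        a = model.forward_unimodal(batch, "graph_only", training=False).data
        b = model.forward_unimodal(batch, "graph_only", training=False).data
        np.testing.assert_array_equal(a, b)

    def test_misaligned_batch_sizes_raise(self):
        model = HybridModel(tiny_config(), seed=0)
        rng = np.random.default_rng(8)
        batch = GraphBatch.from_graphs([make_graph(rng)])
        with pytest.raises(ValueError):
            model.forward_hybrid(batch, make_images(rng, 3))


class TestInitialization:
    def test_biases_zero_and_weights_xavier_bounded(self):
        cfg = tiny_config(norm_type="batch")
        model = HybridModel(cfg, seed=0)
        for name, p in model.parameters().items():
            leaf = name.rsplit(".", 1)[-1]
            if leaf in ("b", "beta"):
                np.testing.assert_array_equal(p.data, np.zeros_like(p.data))
        checks = [
            (model.graph_proj.W, cfg.gnn_hidden[-1], cfg.d),
            (model.image_proj.W, cfg.d_img, cfg.d),
            (model.fusion_head.W, 2 * cfg.d, cfg.C),
            (model.graph_head.W, cfg.d, cfg.C),
            (model.image_head.W, cfg.d, cfg.C),
            (model.gnn_layers[0].W_self, cfg.in_features, cfg.gnn_hidden[0]),
        ]
        for tensor, fan_in, fan_out in checks:
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            assert np.all(np.abs(tensor.data) <= bound)
            assert tensor.data.std() > 0

    def test_evaluation_forward_is_bit_identical(self):
        model = HybridModel(tiny_config(p_drop=0.2, norm_type="batch"), seed=0)
        rng = np.random.default_rng(9)
        batch = GraphBatch.from_graphs([make_graph(rng), make_graph(rng)])
        images = make_images(rng, 2)
        a = model.forward_hybrid(batch, images, training=False).data
        b = model.forward_hybrid(batch, images, training=False).data
        assert np.array_equal(a, b)

    def test_frozen_backbone_unchanged_by_training_step(self):
        model = HybridModel(tiny_config(backbone_frozen=True, p_drop=0.0), seed=0)
        rng = np.random.default_rng(10)
        samples = [
            Sample(graph=make_graph(rng, label=i % 2), image=make_images(rng, 1)[0], label=i % 2)
            for i in range(4)
        ]
        before_backbone = {
            k: v.data.copy() for k, v in model.backbone.parameters().items()
        }
        before_proj = model.image_proj.W.data.copy()
        before_cls = model.fusion_head.W.data.copy()
        opt = Adam(model.parameters(trainable_only=True), learning_rate=1e-2)
        cfg = TrainConfig(learning_rate=1e-2, epochs=1, batch_size=4, seed=0, mode="hybrid")
        train_epoch(model, samples, opt, cfg)
        for k, v in model.backbone.parameters().items():
            np.testing.assert_array_equal(v.data, before_backbone[k])
        assert not np.array_equal(model.image_proj.W.data, before_proj)
        assert not np.array_equal(model.fusion_head.W.data, before_cls)


class TestCheckpoint:
    def test_checkpoint_roundtrip_restores_eval_behaviour(self, tmp_path):
        model = HybridModel(tiny_config(norm_type="batch", p_drop=0.1), seed=3)
        rng = np.random.default_rng(11)
        batch = GraphBatch.from_graphs([make_graph(rng), make_graph(rng, n_nodes=4)])
        images = make_images(rng, 2)
        # perturb running stats so they must round-trip too
        model.forward_hybrid(batch, images, training=True)
        ref = model.forward_hybrid(batch, images, training=False).data
        path = tmp_path / "ckpt.npz"
        model.save_checkpoint(path, extra={"mode": "hybrid"})
        restored, extra = HybridModel.load_checkpoint(path)
        assert extra["mode"] == "hybrid"
        out = restored.forward_hybrid(batch, images, training=False).data
        assert np.array_equal(ref, out)
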