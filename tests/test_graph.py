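"""Graph convolution: dense oracle agreement, neighbour sampling, training."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gdec import (
    GcnConfig,
    GcnLayerParams,
    GeneGraph,
    NodeFeatures,
    forward_on_blocks,
    gcn_layer_forward,
    sample_blocks,
    train_gene_embeddings,
)

from .conftest import random_graph


def dense_oracle(graph: GeneGraph, h: np.ndarray, params: GcnLayerParams) -> np.ndarray:
    """Straightforward D^{-1/2} A D^{-1/2} (h W) + b, dense."""
    n = graph.n_genes
    A = np.zeros((n, n))
    idx = graph.index()
    for u, v in graph.edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    deg = A.sum(axis=1)
    inv = np.where(deg > 0, 1 / np.sqrt(np.where(deg > 0, deg, 1)), 0.0)
    out = (np.diag(inv) @ A @ np.diag(inv)) @ (h @ params.W) + params.b
    return np.maximum(out, 0) if params.activation == "relu" else out


class TestGcnLayerForward:
    def test_isolated_node_outputs_activation_of_bias(self):
        g = GeneGraph(["A", "B", "C"], {("A", "B")})
        p = GcnLayerParams(np.ones((2, 2)), np.array([-1.0, 2.0]), "relu")
        out = gcn_layer_forward(np.ones((3, 2)), g, p)
        assert np.allclose(out[2], [0.0, 2.0])

    def test_path_graph_hand_values(self, path_graph):
        p = GcnLayerParams(np.array([[1.0]]), np.array([0.0]), "identity")
        out = gcn_layer_forward(np.ones((3, 1)), path_graph, p)
        s = 1 / np.sqrt(2)
        assert np.allclose(out.ravel(), [s, 2 * s, s], atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(int(rng.integers(2, 21)), 0.3, seed)
        h = rng.normal(size=(g.n_genes, 3))
        p = GcnLayerParams(rng.normal(size=(3, 4)), rng.normal(size=4),
                           "relu" if seed % 2 else "identity")
        assert np.allclose(gcn_layer_forward(h, g, p), dense_oracle(g, h, p), atol=1e-6)

    def test_shape_mismatch(self, path_graph):
        p = GcnLayerParams(np.ones((2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="does not match"):
            gcn_layer_forward(np.ones((3, 1)), path_graph, p)

    @given(st.integers(0, 500))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(8, 0.4, seed)
        h = rng.normal(size=(8, 2))
        p = GcnLayerParams(rng.normal(size=(2, 2)), rng.normal(size=2), "relu")
        perm = rng.permutation(8)
        genes_p = [g.gene_ids[i] for i in perm]
        g_p = GeneGraph(genes_p, set(g.edges))
        out = gcn_layer_forward(h, g, p)
        out_p = gcn_layer_forward(h[perm], g_p, p)
        assert np.allclose(out_p, out[perm], atol=1e-9)


class TestSampleBlocks:
    def test_full_fanout_keeps_entire_neighborhoods(self):
        g = random_graph(15, 0.4, seed=2)
        blocks = sample_blocks(g, list(range(5)), [None, None], seed=0)
        nbrs = {i: set() for i in range(15)}
        idx = g.index()
        for u, v in g.edges:
            nbrs[idx[u]].add(idx[v])
            nbrs[idx[v]].add(idx[u])
        top = blocks.blocks[-1]
        for spos, dpos in top["edges"]:
            assert top["src"][spos] in nbrs[top["dst"][dpos]]
        for dpos, node in enumerate(top["dst"]):
            sampled = {top["src"][s] for s, d in top["edges"] if d == dpos}
            assert sampled == nbrs[node]

    def test_fanout_one_contained_in_neighborhood(self):
        g = GeneGraph(["a", "b", "c", "d"], {("a", "b"), ("a", "c"), ("a", "d")})
        blocks = sample_blocks(g, ["a"], [1], seed=3)
        blk = blocks.blocks[0]
        assert len(blk["edges"]) == 1
        src = blk["src"][blk["edges"][0][0]]
        assert g.gene_ids[src] in {"b", "c", "d"}

    def test_determinism(self):
        g = random_graph(30, 0.2, seed=9)
        b1 = sample_blocks(g, list(range(6)), [2, 2], seed=42)
        b2 = sample_blocks(g, list(range(6)), [2, 2], seed=42)
        assert b1.blocks == b2.blocks

    def test_unknown_seed_node(self):
        g = random_graph(5, 0.5, seed=1)
        with pytest.raises(KeyError):
            sample_blocks(g, ["nope"], [None], seed=0)

    def test_destinations_are_prefix_of_sources(self):
        g = random_graph(40, 0.15, seed=4)
        blocks = sample_blocks(g, list(range(8)), [3, 3], seed=7)
        for blk in blocks.blocks:
            assert blk["src"][: len(blk["dst"])] == blk["dst"]


class TestForwardOnBlocks:
    def _layers(self, rng, dims=(3, 4, 2)):
        return [
            GcnLayerParams(rng.normal(size=(dims[0], dims[1])), rng.normal(size=dims[1]), "relu"),
            GcnLayerParams(rng.normal(size=(dims[1], dims[2])), rng.normal(size=dims[2]), "identity"),
        ]

    @pytest.mark.parametrize("seed", range(8))
    def test_full_fanout_equals_full_graph_forward(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(int(rng.integers(10, 200)), 0.05, seed)
        h0 = rng.normal(size=(g.n_genes, 3))
        layers = self._layers(rng)
        seeds = rng.choice(g.n_genes, size=5, replace=False).tolist()
        blocks = sample_blocks(g, seeds, [None, None], seed=seed)
        batch = forward_on_blocks(blocks, h0, layers, g)
        full = gcn_layer_forward(gcn_layer_forward(h0, g, layers[0]), g, layers[1])
        assert np.allclose(batch, full[seeds], atol=1e-6)

    def test_single_seed_one_layer_reduces_to_layer_forward(self):
        rng = np.random.default_rng(0)
        g = random_graph(10, 0.4, seed=0)
        h0 = rng.normal(size=(10, 3))
        layer = GcnLayerParams(rng.normal(size=(3, 2)), rng.normal(size=2), "identity")
        blocks = sample_blocks(g, [4], [None], seed=0)
        out = forward_on_blocks(blocks, h0, [layer], g)
        assert np.allclose(out, gcn_layer_forward(h0, g, layer)[[4]], atol=1e-9)

    def test_zero_features_zero_bias_gives_zero(self):
        rng = np.random.default_rng(1)
        g = random_graph(10, 0.4, seed=1)
        layers = [
            GcnLayerParams(rng.normal(size=(3, 3)), np.zeros(3), "relu"),
            GcnLayerParams(rng.normal(size=(3, 2)), np.zeros(2), "identity"),
        ]
        blocks = sample_blocks(g, [0, 1], [None, None], seed=0)
        out = forward_on_blocks(blocks, np.zeros((10, 3)), layers, g)
        assert np.allclose(out, 0.0)

    def test_layer_count_mismatch(self):
        g = random_graph(5, 0.5, seed=2)
        blocks = sample_blocks(g, [0], [None], seed=0)
        with pytest.raises(ValueError, match="block count"):
            forward_on_blocks(blocks, np.zeros((5, 3)), self._layers(np.random.default_rng(0)), g)


class TestTrainGeneEmbeddings:
    def test_epochs_zero_equals_untrained_forward(self):
        g = random_graph(20, 0.3, seed=5)
        m0 = train_gene_embeddings(g, GcnConfig(epochs=0, seed=7))
        m1 = train_gene_embeddings(g, GcnConfig(epochs=0, seed=7))
        assert np.array_equal(m0.values, m1.values)

    def test_edgeless_graph_warns_and_returns_untrained(self, caplog):
        g = GeneGraph(["a", "b"], set())
        with caplog.at_level("WARNING", logger="gdec"):
            m = train_gene_embeddings(g, GcnConfig(epochs=5, seed=0))
        assert "no edges" in caplog.text
        assert m.values.shape == (2, 16)

    def test_two_cliques_embed_apart(self):
        genes = [f"g{i}" for i in range(40)]
        edges = set()
        for block in (range(20), range(20, 40)):
            block = list(block)
            for i in block:
                for j in block:
                    if i < j:
                        edges.add((genes[i], genes[j]))
        edges.add((genes[0], genes[20]))  # single bridge
        g = GeneGraph(genes, edges)
        m = train_gene_embeddings(g, GcnConfig(embed_dim=8, epochs=80, seed=0))
        v = m.values / np.linalg.norm(m.values, axis=1, keepdims=True)
        sim = v @ v.T
        within = (sim[:20, :20].sum() - 20) / (20 * 19)
        across = sim[:20, 20:].mean()
        assert within > across

    def test_loss_decreases(self):
        from gdec import SimulationConfig, simulate_gene_graph

        sim = SimulationConfig(n_genes=100, k_types=2, markers_per_type=30,
                               graph_within_module_p=0.3,
                               graph_between_module_p=0.03, seed=4)
        g = simulate_gene_graph(sim)
        m = train_gene_embeddings(g, GcnConfig(epochs=60, seed=1))
        assert m.loss_history[-1] <= m.loss_history[0]
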