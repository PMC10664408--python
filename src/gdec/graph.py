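"""Gene-graph convolution with mini-batch neighbour sampling.

Each convolution layer computes, for gene ``i``,

    h_i^(l+1) = act( b + sum_{j in N(i)} h_j^(l) W / (sqrt(deg j) sqrt(deg i)) )

i.e. a symmetric degree-normalised neighbour aggregation with no self-loop
term: an isolated gene's neighbour sum is empty and its output is ``act(b)``.
Two stacked layers (ReLU then identity) produce the per-gene embedding
matrix M used downstream for feature fusion.

For large graphs the forward pass can be restricted to sampled blocks: from
the output layer down, each destination node samples up to ``fanout``
neighbours uniformly without replacement; the normaliser always uses
full-graph degrees, so sampling approximates the neighbour sum, never the
normalisation.

The embedding is trained with a self-supervised link-prediction objective
(logistic loss on dot-product scores of observed edges against uniformly
sampled non-edges).  An ``objective="none"`` mode propagates the seeded
random input features through untrained layers, for ablation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import GeneGraph
from .nn import Adam, relu, sigmoid

log = logging.getLogger("gdec")

__all__ = [
    "GcnLayerParams",
    "NodeFeatures",
    "GeneEmbeddingMatrix",
    "SampledBlockSet",
    "GcnConfig",
    "gcn_layer_forward",
    "sample_blocks",
    "forward_on_blocks",
    "train_gene_embeddings",
]


@dataclass
class GcnLayerParams:
    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[1],):
            raise ValueError("inconsistent GCN layer shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite GCN parameters")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")

    def apply_activation(self, x: np.ndarray) -> np.ndarray:
        return relu(x) if self.activation == "relu" else x


@dataclass
class NodeFeatures:
    """Initial per-gene feature rows (seeded standard normal)."""

    values: np.ndarray
    generation_seed: int

    @classmethod
    def random(cls, graph: GeneGraph, dim: int, seed: int) -> "NodeFeatures":
        rng = np.random.default_rng(seed)
        return cls(rng.standard_normal((graph.n_genes, dim)), seed)


@dataclass
class GeneEmbeddingMatrix:
    """g x d embedding matrix M, row order matching ``gene_ids``."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError("one embedding row required per gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embeddings")

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class SampledBlockSet:
    """Per-layer sampled computation blocks, input layer first.

    ``blocks[l]`` is a dict with ``src`` (node indices whose layer-l features
    are needed), ``dst`` (node indices computed by layer l) and ``edges``
    (pairs of positions ``(src_pos, dst_pos)`` into those lists).  The
    destinations of each block are a prefix of its source list, and the final
    block's destinations are the requested seed nodes.
    """

    blocks: list[dict]
    fanouts: list[int | None]
    seed: int


def gcn_layer_forward(h: np.ndarray, graph: GeneGraph, params: GcnLayerParams) -> np.ndarray:
    """Full-graph single-layer convolution (see module docstring)."""
    h = np.asarray(h, dtype=float)
    if h.shape[0] != graph.n_genes:
        raise ValueError("feature rows must match graph genes")
    if h.shape[1] != params.W.shape[0]:
        raise ValueError(
            f"feature dim {h.shape[1]} does not match W rows {params.W.shape[0]}"
        )
    agg = graph.normalized_adjacency() @ (h @ params.W)
    return params.apply_activation(agg + params.b)


def _neighbor_lists(graph: GeneGraph) -> list[list[int]]:
    idx = graph.index()
    nbrs: list[list[int]] = [[] for _ in range(graph.n_genes)]
    for u, v in sorted(graph.edges):
        nbrs[idx[u]].append(idx[v])
        nbrs[idx[v]].append(idx[u])
    return [sorted(n) for n in nbrs]


def sample_blocks(
    graph: GeneGraph,
    seed_nodes: list[str] | list[int],
    fanouts: list[int | None],
    seed: int = 0,
) -> SampledBlockSet:
    """Build per-layer neighbour-sampled blocks for ``seed_nodes``.

    ``fanouts`` is listed input-layer-first and must have one entry per
    layer; ``None`` (or any value >= the node degree) keeps the full
    neighbourhood.  Sampling is uniform without replacement and
    deterministic in ``seed``.
    """
    if not len(seed_nodes):
        raise ValueError("seed_nodes must be nonempty")
    idx = graph.index()
    ids: list[int] = []
    for s in seed_nodes:
        if isinstance(s, (int, np.integer)):
            if not 0 <= s < graph.n_genes:
                raise KeyError(f"node index {s} out of range")
            ids.append(int(s))
        else:
            if s not in idx:
                raise KeyError(f"unknown seed node {s!r}")
            ids.append(idx[s])
    nbrs = _neighbor_lists(graph)
    rng = np.random.default_rng(seed)
    blocks_top_down = []
    dst = list(dict.fromkeys(ids))
    for fanout in reversed(fanouts):
        src = list(dst)  # destinations are a prefix of sources
        pos = {n: i for i, n in enumerate(src)}
        edges = []
        for d_pos, node in enumerate(dst):
            cand = nbrs[node]
            if fanout is None or fanout >= len(cand):
                chosen = cand
            else:
                chosen = [cand[i] for i in sorted(rng.choice(len(cand), size=fanout, replace=False))]
            for c in chosen:
                if c not in pos:
                    pos[c] = len(src)
                    src.append(c)
                edges.append((pos[c], d_pos))
        blocks_top_down.append({"src": src, "dst": dst, "edges": edges})
        dst = src
    return SampledBlockSet(list(reversed(blocks_top_down)), list(fanouts), seed)


def _block_matrix(block: dict, graph: GeneGraph) -> sparse.csr_matrix:
    """Sparse dst x src aggregation matrix with full-graph degree normalisation."""
    deg = np.array([graph.degree[g] for g in graph.gene_ids], dtype=float)
    src, dst, edges = block["src"], block["dst"], block["edges"]
    if not edges:
        return sparse.csr_matrix((len(dst), len(src)))
    rows = [d for _, d in edges]
    cols = [s for s, _ in edges]
    data = [
        1.0 / (np.sqrt(deg[src[s]]) * np.sqrt(deg[dst[d]]))
        for s, d in edges
    ]
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(dst), len(src)))


def forward_on_blocks(
    blocks: SampledBlockSet,
    h0: NodeFeatures | np.ndarray,
    layers: list[GcnLayerParams],
    graph: GeneGraph,
) -> np.ndarray:
    """Layered forward pass restricted to sampled edges.

    Returns one embedding row per seed node (the destinations of the final
    block).  With unlimited fanout this equals the corresponding rows of the
    full-graph forward pass.
    """
    if len(blocks.blocks) != len(layers):
        raise ValueError("block count must equal layer count")
    feats = h0.values if isinstance(h0, NodeFeatures) else np.asarray(h0, dtype=float)
    h = feats[blocks.blocks[0]["src"], :]
    for block, params in zip(blocks.blocks, layers):
        agg = _block_matrix(block, graph) @ (h @ params.W)
        h = params.apply_activation(agg + params.b)
    return h


@dataclass(frozen=True)
class GcnConfig:
    feature_dim: int = 32
    embed_dim: int = 16
    epochs: int = 60
    lr: float = 1e-2
    negative_samples: int = 1
    objective: str = "link_prediction"  # or "none"
    hidden_dim: int | None = None  # default: embed_dim
    seed: int = 0


def train_gene_embeddings(graph: GeneGraph, cfg: GcnConfig) -> GeneEmbeddingMatrix:
    """Train the two-layer convolution on a link-prediction objective.

    Returns the g x d matrix M of final-layer gene embeddings.  A graph with
    no edges cannot be trained; the seeded random features are propagated
    through the untrained layers with a warning.  ``loss_history`` is
    attached to the returned matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    h0 = NodeFeatures.random(graph, cfg.feature_dim, int(rng.integers(2**31 - 1)))
    hidden = cfg.hidden_dim or cfg.embed_dim
    p1 = GcnLayerParams(
        rng.normal(0, np.sqrt(2.0 / cfg.feature_dim), size=(cfg.feature_dim, hidden)),
        np.zeros(hidden), "relu",
    )
    p2 = GcnLayerParams(
        rng.normal(0, np.sqrt(1.0 / hidden), size=(hidden, cfg.embed_dim)),
        np.zeros(cfg.embed_dim), "identity",
    )
    layers = [p1, p2]
    losses: list[float] = []

    def full_forward():
        a = graph.normalized_adjacency()
        pre1 = a @ (h0.values @ p1.W) + p1.b
        h1 = p1.apply_activation(pre1)
        m = a @ (h1 @ p2.W) + p2.b
        return a, pre1, h1, m

    if graph.n_edges == 0 or cfg.objective == "none" or cfg.epochs == 0:
        if graph.n_edges == 0 and cfg.objective != "none" and cfg.epochs > 0:
            log.warning("graph has no edges; returning untrained embeddings")
        m = full_forward()[3]
        out = GeneEmbeddingMatrix(m, list(graph.gene_ids))
        out.loss_history = losses
        out.layers = layers
        out.node_features = h0
        return out

    idx = graph.index()
    edge_arr = np.array([[idx[u], idx[v]] for u, v in sorted(graph.edges)])
    adj_set = {(int(u), int(v)) for u, v in edge_arr} | {(int(v), int(u)) for u, v in edge_arr}
    opt = Adam([p1.W, p1.b, p2.W, p2.b], lr=cfg.lr)

    for _ in range(cfg.epochs):
        a, pre1, h1, m = full_forward()
        pos = edge_arr
        n_neg = cfg.negative_samples * len(pos)
        neg = rng.integers(0, graph.n_genes, size=(int(1.5 * n_neg) + 8, 2))
        keep = [(u != v) and ((int(u), int(v)) not in adj_set) for u, v in neg]
        neg = neg[np.flatnonzero(keep)[:n_neg]]
        pairs = np.vstack([pos, neg])
        y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        s = sigmoid((m[pairs[:, 0]] * m[pairs[:, 1]]).sum(axis=1))
        eps = 1e-12
        losses.append(float(-np.mean(y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps))))
        # gradient of mean logistic loss wrt embedding rows
        coef = (s - y)[:, None] / len(pairs)
        g_m = np.zeros_like(m)
        np.add.at(g_m, pairs[:, 0], coef * m[pairs[:, 1]])
        np.add.at(g_m, pairs[:, 1], coef * m[pairs[:, 0]])
        # back through layer 2 (identity activation)
        ah1 = a @ h1
        g_w2 = ah1.T @ g_m
        g_b2 = g_m.sum(axis=0)
        g_h1 = a.T @ (g_m @ p2.W.T)
        g_h1 *= pre1 > 0
        ah0 = a @ h0.values
        g_w1 = ah0.T @ g_h1
        g_b1 = g_h1.sum(axis=0)
        opt.step([g_w1, g_b1, g_w2, g_b2])

    m = full_forward()[3]
    out = GeneEmbeddingMatrix(m, list(graph.gene_ids))
    out.loss_history = losses
    out.layers = layers
    out.node_features = h0
    return out
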