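"""Seeded synthetic scRNA-seq data with planted cluster and graph structure.

The generator emulates the statistical features the clustering method relies
on: multi-cluster count data (log-normal gene means, Poisson sampling),
zero-inflation through independent dropout, a per-gene multiplicative batch
effect between a paired source/target dataset, cell types present in the
target but absent from the source, and a gene-interaction graph whose edges
are enriched within per-type marker modules.

All randomness flows from ``SimulationConfig.seed``; child streams for the
gene panel, the source cells, the target cells, the batch factors and the
graph are derived at fixed offsets so each piece is independently
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneGraph, LabelTable

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_pair",
    "simulate_gene_graph",
    "marker_modules",
    "batch_factors",
    "sample_prior_labels",
]

# fixed child-seed offsets (documented contract; keeps every stream < 2^31)
_OFF_PANEL = 0
_OFF_SOURCE = 1
_OFF_TARGET = 2
_OFF_BATCH = 3
_OFF_GRAPH = 4
_SEED_MOD = 2**31 - 1


def _child(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 7 + offset) % _SEED_MOD)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset (or source/target pair).

    ``separation`` is the between-cluster mean shift, in log-space units, on
    each type's marker genes.  ``batch_scale`` is the standard deviation of
    the per-gene log batch factor applied to the target half of a pair.
    ``dropout_rate`` is the probability an observed count is zeroed.
    """

    n_cells: int = 800
    n_genes: int = 200
    k_types: int = 4
    separation: float = 4.0
    batch_scale: float = 0.5
    dropout_rate: float = 0.35
    missing_types_in_source: tuple[int, ...] = ()
    markers_per_type: int = 15
    base_log_mean: float = 0.7
    base_log_sd: float = 0.4
    library_log_sd: float = 0.2
    graph_within_module_p: float = 0.25
    graph_between_module_p: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.k_types < 1:
            raise ValueError("n_cells, n_genes, k_types must be positive")
        if self.k_types > self.n_cells:
            raise ValueError("k_types cannot exceed n_cells")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.separation < 0 or self.batch_scale < 0:
            raise ValueError("separation and batch_scale must be nonnegative")
        for p in (self.graph_within_module_p, self.graph_between_module_p):
            if not 0 <= p <= 1:
                raise ValueError("graph probabilities must be in [0, 1]")
        bad = [t for t in self.missing_types_in_source if not 0 <= t < self.k_types]
        if bad:
            raise ValueError(f"missing types {bad} outside 0..{self.k_types - 1}")
        if self.k_types * self.markers_per_type > self.n_genes:
            raise ValueError("marker modules do not fit into n_genes")


def marker_modules(cfg: SimulationConfig) -> list[np.ndarray]:
    """Per-type disjoint marker gene index sets (deterministic in cfg.seed)."""
    rng = _child(cfg.seed, _OFF_PANEL)
    perm = rng.permutation(cfg.n_genes)
    m = cfg.markers_per_type
    return [np.sort(perm[t * m : (t + 1) * m]) for t in range(cfg.k_types)]


def _gene_panel(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(baseline log-means, k x g per-type log-mean matrix)."""
    rng = _child(cfg.seed, _OFF_PANEL)
    rng.permutation(cfg.n_genes)  # keep stream aligned with marker_modules
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    means = np.tile(base, (cfg.k_types, 1))
    for t, idx in enumerate(marker_modules(cfg)):
        means[t, idx] += cfg.separation
    return base, means


def _even_types(n_cells: int, types: list[int], rng: np.random.Generator) -> np.ndarray:
    reps = np.array([len(chunk) for chunk in np.array_split(np.arange(n_cells), len(types))])
    assignment = np.repeat(types, reps)
    rng.shuffle(assignment)
    return assignment


def _draw_counts(
    log_means: np.ndarray,
    types: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_factors: np.ndarray | None = None,
) -> np.ndarray:
    mu = np.exp(log_means[types])  # cells x genes expected counts
    if gene_factors is not None:
        mu = mu * gene_factors[None, :]
    lib = np.exp(rng.normal(0.0, cfg.library_log_sd, size=(mu.shape[0], 1)))
    counts = rng.poisson(mu * lib).astype(float)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts *= keep
    return counts


def _make_dataset(
    cfg: SimulationConfig,
    offset: int,
    prefix: str,
    types_present: list[int],
    gene_factors: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, LabelTable]:
    rng = _child(cfg.seed, offset)
    _, means = _gene_panel(cfg)
    assignment = _even_types(cfg.n_cells, types_present, rng)
    counts = _draw_counts(means, assignment, cfg, rng, gene_factors)
    cells = [f"{prefix}{i:05d}" for i in range(cfg.n_cells)]
    genes = [f"G{j:04d}" for j in range(cfg.n_genes)]
    labels = [f"type{t}" for t in assignment]
    return ExpressionMatrix(counts, cells, genes), LabelTable(cells, labels)


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, LabelTable]:
    """One dataset: cells split evenly (+-1) across all k types."""
    return _make_dataset(cfg, _OFF_SOURCE, "cell", list(range(cfg.k_types)))


def batch_factors(cfg: SimulationConfig) -> np.ndarray:
    """Per-gene multiplicative factors applied to the target dataset."""
    rng = _child(cfg.seed, _OFF_BATCH)
    return np.exp(rng.normal(0.0, cfg.batch_scale, size=cfg.n_genes))


def simulate_pair(cfg: SimulationConfig):
    """Paired source/target datasets sharing genes and type definitions.

    The target receives per-gene multiplicative batch factors with log-sd
    ``batch_scale`` (see :func:`batch_factors`); types listed in
    ``missing_types_in_source`` are excluded from the source only.
    """
    source_types = [t for t in range(cfg.k_types) if t not in cfg.missing_types_in_source]
    if not source_types:
        raise ValueError("all types missing from source")
    source = _make_dataset(cfg, _OFF_SOURCE, "src", source_types)
    factors = batch_factors(cfg)
    target = _make_dataset(cfg, _OFF_TARGET, "tgt", list(range(cfg.k_types)), factors)
    return source, target


def simulate_gene_graph(
    cfg: SimulationConfig, marker_module_sets: list[np.ndarray] | None = None
) -> GeneGraph:
    """Planted-partition gene graph enriched within marker modules.

    Edge probability is ``graph_within_module_p`` between genes of the same
    module and ``graph_between_module_p`` otherwise (genes outside every
    module are background).  Requires within > between so modules are
    genuinely enriched.
    """
    if cfg.graph_within_module_p <= cfg.graph_between_module_p:
        raise ValueError("graph_within_module_p must exceed graph_between_module_p")
    modules = marker_modules(cfg) if marker_module_sets is None else marker_module_sets
    flat = np.concatenate([np.asarray(m) for m in modules]) if modules else np.array([], int)
    if len(set(flat.tolist())) != len(flat):
        raise ValueError("marker modules must be disjoint")
    g = cfg.n_genes
    module_of = np.full(g, -1)
    for t, idx in enumerate(modules):
        module_of[np.asarray(idx)] = t
    rng = _child(cfg.seed, _OFF_GRAPH)
    iu, ju = np.triu_indices(g, k=1)
    same = (module_of[iu] >= 0) & (module_of[iu] == module_of[ju])
    p = np.where(same, cfg.graph_within_module_p, cfg.graph_between_module_p)
    draw = rng.random(len(iu)) < p
    genes = [f"G{j:04d}" for j in range(g)]
    edges = {(genes[i], genes[j]) for i, j in zip(iu[draw], ju[draw])}
    return GeneGraph(genes, edges)


def sample_prior_labels(labels: LabelTable, fraction: float, seed: int = 0) -> LabelTable:
    """Uniform random subset of labelled cells ("prior knowledge").

    Used to emulate the small labelled fraction of a target dataset that the
    transfer stage may exploit during fine-tuning.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n = len(labels)
    m = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(n, size=m, replace=False))
    return LabelTable([labels.cell_ids[i] for i in pick], [labels.labels[i] for i in pick])
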