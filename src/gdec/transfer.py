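"""Source pretraining, cross-dataset transfer with fine-tuning, and
unknown-type rejection.

The full pipeline on a labelled source dataset is: align genes with the
interaction graph, library-normalise, train gene embeddings on the graph,
fuse them with the expression profile, pretrain the autoencoder, initialise
one centroid per source cell type by K-means, and run KL self-training.
Each final cluster is mapped to the majority source label among its members.

Transfer copies the trained encoder and centroids to the target dataset
(aligned to the bundle's gene space) and fine-tunes with KL self-training;
if a small fraction of target cells carries labels ("prior knowledge"),
those cells contribute a cross-entropy term anchoring them to their mapped
source clusters.  Cells whose final maximum soft assignment falls below the
rejection threshold ``tau`` are labelled ``"unknown"`` instead of being
forced into a known type.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dec import (
    DecFitConfig,
    DecState,
    EncoderSpec,
    PretrainConfig,
    SoftAssignment,
    dec_fit,
    encode,
    init_centroids,
    pretrain_autoencoder,
)
from .fusion import FusedFeatures, fuse
from .graph import GcnConfig, GeneEmbeddingMatrix, train_gene_embeddings
from .io import (
    AlignmentError,
    ExpressionMatrix,
    GeneGraph,
    LabelTable,
    align_genes,
    normalize,
    select_top_variable_genes,
)
from .nn import MLP, Dense

log = logging.getLogger("gdec")

UNKNOWN = "unknown"

__all__ = [
    "GdecConfig",
    "TransferConfig",
    "ClusterResult",
    "ModelBundle",
    "pretrain_source",
    "transfer_and_finetune",
    "assign_with_rejection",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class GdecConfig:
    """End-to-end pipeline hyperparameters for source pretraining."""

    normalize_mode: str = "log1p_cpm"
    n_top_genes: int | None = None
    use_gcn: bool = True
    fusion_mode: str = "summed"
    gcn: GcnConfig = field(default_factory=GcnConfig)
    encoder_hidden: tuple[int, ...] = (500, 500, 2000)
    latent_dim: int = 20
    alpha: float = 1.0
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    dec: DecFitConfig = field(default_factory=DecFitConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "GdecConfig":
        from dataclasses import replace

        return replace(
            self,
            seed=seed,
            gcn=replace(self.gcn, seed=seed + 11),
            pretrain=replace(self.pretrain, seed=seed + 13),
            dec=replace(self.dec, seed=seed + 17),
        )

    @classmethod
    def compact(cls, **overrides) -> "GdecConfig":
        """Configuration sized for inputs of a few hundred genes.

        The default encoder widths (500/500/2000) are matched to
        thousand-gene panels; for small feature spaces a narrower encoder
        trains faster and embeds just as well.
        """
        base = dict(
            encoder_hidden=(128, 128, 512),
            n_top_genes=80,
            pretrain=PretrainConfig(epochs=200, lr=3e-4),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class TransferConfig:
    """Fine-tuning and rejection settings for the target dataset.

    ``confidence_gate`` restricts KL self-training to cells whose current
    maximum soft assignment reaches the gate, so clusters sharpen without
    absorbing far-from-centroid cells (the usual pseudo-label threshold);
    ``None`` disables the gate.  ``rejection_tau`` is the final assignment
    threshold below which a cell is labelled unknown.
    """

    finetune_iters: int = 90
    finetune_lr: float = 1e-4
    update_interval: int = 30
    tol: float = 1e-3
    frozen_layers: tuple[int, ...] = ()
    prior_fraction: float = 0.1
    prior_weight: float = 1.0
    rejection_tau: float = 0.6
    confidence_gate: float | None = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prior_fraction <= 1:
            raise ValueError("prior_fraction must be in [0, 1]")
        if not 0 < self.rejection_tau <= 1:
            raise ValueError("rejection_tau must be in (0, 1]")

    @classmethod
    def open_set(cls, n_encoder_layers: int = 4, **overrides) -> "TransferConfig":
        """Preset for targets that may contain types absent from the source.

        Freezes the encoder so fine-tuning adapts only the centroids: encoder
        updates driven by confidently assigned cells otherwise drag
        novel-type cells toward known centroids and erase the low-confidence
        signal that rejection relies on.
        """
        base = dict(frozen_layers=tuple(range(n_encoder_layers)))
        base.update(overrides)
        return cls(**base)


@dataclass
class ClusterResult:
    """Per-cell cluster assignment with confidence and mapped type.

    ``cluster`` holds the assigned cluster index, or -1 where the cell was
    rejected; ``mapped_type`` then holds ``"unknown"``.
    """

    cell_ids: list[str]
    cluster: np.ndarray
    mapped_type: list[str]
    max_q: np.ndarray
    Q: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "cluster": self.cluster,
                "mapped_type": self.mapped_type,
                "max_q": self.max_q,
            }
        )

    def as_label_table(self) -> LabelTable:
        return LabelTable(list(self.cell_ids), list(self.mapped_type))

    @property
    def n_unknown(self) -> int:
        return int((self.cluster < 0).sum())


@dataclass
class ModelBundle:
    """Everything needed to apply a pretrained model to a new dataset."""

    gene_ids: list[str]
    embeddings: GeneEmbeddingMatrix | None
    state: DecState
    cluster_to_type: dict[int, str]
    config: GdecConfig
    source_result: ClusterResult | None = None

    def manifest(self) -> dict:
        enc = self.state.encoder
        return {
            "genes": self.gene_ids,
            "encoder_sizes": enc.sizes,
            "k": self.state.k,
            "alpha": self.state.alpha,
            "cluster_to_type": {str(k): v for k, v in sorted(self.cluster_to_type.items())},
            "config": _config_dict(self.config),
            "weight_sha256": _weights_hash(self),
        }

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest(), sort_keys=True).encode()
        ).hexdigest()


def _config_dict(cfg) -> dict:
    d = asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return clean(d)


def _weights_hash(bundle: ModelBundle) -> str:
    h = hashlib.sha256()
    arrays = []
    for net in (bundle.state.encoder, bundle.state.decoder):
        arrays += net.params()
    if bundle.state.centroids is not None:
        arrays.append(bundle.state.centroids)
    if bundle.embeddings is not None:
        arrays.append(bundle.embeddings.values)
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _prepare_features(
    expr: ExpressionMatrix,
    embeddings: GeneEmbeddingMatrix | None,
    cfg: GdecConfig,
) -> FusedFeatures:
    norm = normalize(expr, cfg.normalize_mode)
    if cfg.use_gcn and embeddings is not None:
        return fuse(norm, embeddings, mode=cfg.fusion_mode)
    return FusedFeatures(
        norm.values, "none", list(norm.cell_ids), list(norm.gene_ids), norm.n_genes
    )


def _majority_map(hard: np.ndarray, labels: list[str], k: int,
                  centroids: np.ndarray) -> dict[int, str]:
    mapping: dict[int, str] = {}
    empty = []
    arr = np.asarray(labels, dtype=object)
    for c in range(k):
        members = arr[hard == c]
        if len(members) == 0:
            empty.append(c)
            continue
        vals, counts = np.unique(members.astype(str), return_counts=True)
        mapping[c] = str(vals[counts.argmax()])
    for c in empty:
        others = [j for j in range(k) if j in mapping]
        d = ((centroids[c] - centroids[others]) ** 2).sum(axis=1)
        nearest = others[int(d.argmin())]
        mapping[c] = mapping[nearest]
        log.warning("cluster %d empty; inheriting type %r from nearest centroid", c, mapping[c])
    return mapping


def pretrain_source(
    source_expr: ExpressionMatrix,
    source_labels: LabelTable,
    graph: GeneGraph,
    cfg: GdecConfig = GdecConfig(),
) -> ModelBundle:
    """Run the full pipeline on a labelled source dataset.

    The number of clusters k equals the number of distinct source types;
    after self-training each cluster is mapped to its majority source label.
    """
    label_map = source_labels.as_dict()
    missing = [c for c in source_expr.cell_ids if c not in label_map]
    if missing:
        raise ValueError(f"{len(missing)} source cells lack labels")
    types = sorted(set(label_map.values()))
    if len(types) < 2:
        raise ValueError("source labels must cover at least 2 types")
    expr, agraph = align_genes(source_expr, graph)
    if cfg.n_top_genes is not None and cfg.n_top_genes < expr.n_genes:
        keep = select_top_variable_genes(normalize(expr, cfg.normalize_mode), cfg.n_top_genes)
        expr = expr.subset_genes(keep)
        agraph = agraph.subgraph(keep)
    embeddings = train_gene_embeddings(agraph, cfg.gcn) if cfg.use_gcn else None
    feats = _prepare_features(expr, embeddings, cfg)
    spec = EncoderSpec(feats.width, cfg.encoder_hidden, cfg.latent_dim)
    state = pretrain_autoencoder(feats, spec, cfg.pretrain)
    state.alpha = cfg.alpha
    Z = encode(state, feats)
    k = len(types)
    if cfg.pretrain.epochs == 0 and cfg.dec.max_iters == 0:
        # degenerate smoke configuration: untrained embeddings may collapse
        state.centroids = init_centroids(Z, min(k, np.unique(Z, axis=0).shape[0]),
                                         seed=cfg.seed)
    else:
        state.centroids = init_centroids(Z, k, seed=cfg.seed)
    state, Q = dec_fit(state, feats, cfg.dec)
    hard = Q.hard()
    labels = [label_map[c] for c in expr.cell_ids]
    mapping = _majority_map(hard, labels, state.k, state.centroids)
    result = ClusterResult(
        list(expr.cell_ids),
        hard,
        [mapping[int(c)] for c in hard],
        Q.max_q(),
        Q.Q,
    )
    return ModelBundle(list(expr.gene_ids), embeddings, state, mapping, cfg, result)


def _align_target(bundle: ModelBundle, target: ExpressionMatrix) -> ExpressionMatrix:
    lut = {g.upper(): i for i, g in enumerate(target.gene_ids)}
    cols = []
    missing = []
    for g in bundle.gene_ids:
        if g.upper() in lut:
            cols.append(lut[g.upper()])
        else:
            missing.append(g)
            cols.append(-1)
    if len(missing) == len(bundle.gene_ids):
        raise AlignmentError("target shares no genes with the model bundle")
    if missing:
        log.warning("%d bundle genes absent from target; filled with zeros", len(missing))
    values = np.zeros((target.n_cells, len(bundle.gene_ids)))
    for j, c in enumerate(cols):
        if c >= 0:
            values[:, j] = target.values[:, c]
    return ExpressionMatrix(values, list(target.cell_ids), list(bundle.gene_ids))


def transfer_and_finetune(
    bundle: ModelBundle,
    target_expr: ExpressionMatrix,
    target_prior_labels: LabelTable | None = None,
    tcfg: TransferConfig = TransferConfig(),
) -> tuple[DecState, ClusterResult]:
    """Adapt a pretrained bundle to a target dataset and cluster it.

    The encoder and centroids are initialised from the bundle; fine-tuning
    is KL self-training on the target, optionally with a cross-entropy prior
    on the labelled target cells (labels naming types unknown to the bundle
    are dropped with a warning).  Assignment uses the bundle's cluster-to-
    type map with rejection at ``tcfg.rejection_tau``.
    """
    expr = _align_target(bundle, target_expr)
    cfg = bundle.config
    feats = _prepare_features(expr, bundle.embeddings, cfg)
    prior = None
    if target_prior_labels is not None and len(target_prior_labels):
        type_to_cluster: dict[str, int] = {}
        for c, t in sorted(bundle.cluster_to_type.items()):
            type_to_cluster.setdefault(t, c)
        cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
        rows, targets = [], []
        dropped = 0
        for cell, lab in zip(target_prior_labels.cell_ids, target_prior_labels.labels):
            if cell not in cell_pos:
                continue
            if lab not in type_to_cluster:
                dropped += 1
                continue
            rows.append(cell_pos[cell])
            targets.append(type_to_cluster[lab])
        if dropped:
            log.warning("%d prior cells name types unknown to the bundle; excluded", dropped)
        if rows:
            onehot = np.zeros((len(rows), bundle.state.k))
            onehot[np.arange(len(rows)), targets] = 1.0
            prior = (np.asarray(rows), onehot)
    dcfg = DecFitConfig(
        max_iters=tcfg.finetune_iters,
        update_interval=tcfg.update_interval,
        lr=tcfg.finetune_lr,
        tol=tcfg.tol,
        seed=tcfg.seed,
        prior_weight=tcfg.prior_weight,
        confidence_gate=tcfg.confidence_gate,
    )
    state, Q = dec_fit(bundle.state, feats, dcfg, prior=prior,
                       frozen_layers=tcfg.frozen_layers)
    result = assign_with_rejection(Q, bundle.cluster_to_type, tcfg.rejection_tau,
                                   cell_ids=list(expr.cell_ids))
    return state, result


def assign_with_rejection(
    Q: SoftAssignment,
    cluster_to_type: dict[int, str],
    tau: float = 0.6,
    cell_ids: list[str] | None = None,
) -> ClusterResult:
    """Hard-assign each cell, rejecting low-confidence cells as unknown.

    A cell receives its argmax cluster (ties broken by lowest index) and the
    mapped type when ``max_q >= tau``; otherwise the sentinel ``"unknown"``.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    hard = Q.hard()
    maxq = Q.max_q()
    n = len(hard)
    if cell_ids is None:
        cell_ids = [f"cell{i:05d}" for i in range(n)]
    cluster = np.where(maxq >= tau, hard, -1)
    mapped = [
        cluster_to_type.get(int(c), UNKNOWN) if c >= 0 else UNKNOWN for c in cluster
    ]
    return ClusterResult(cell_ids, cluster, mapped, maxq, Q.Q)


# ---------------------------------------------------------------------------
# bundle persistence: a single .npz archive of weight tensors + JSON manifest
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for prefix, net in (("enc", bundle.state.encoder), ("dec", bundle.state.decoder)):
        for i, layer in enumerate(net.layers):
            arrays[f"{prefix}_{i}_W"] = layer.W
            arrays[f"{prefix}_{i}_b"] = layer.b
    if bundle.state.centroids is not None:
        arrays["centroids"] = bundle.state.centroids
    if bundle.embeddings is not None:
        arrays["gene_embeddings"] = bundle.embeddings.values
    manifest = bundle.manifest()
    manifest["encoder_activations"] = [l.activation for l in bundle.state.encoder.layers]
    manifest["decoder_activations"] = [l.activation for l in bundle.state.decoder.layers]
    arrays["manifest_json"] = np.frombuffer(
        json.dumps(manifest, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_bundle(path: str | Path) -> ModelBundle:
    data = np.load(path)
    manifest = json.loads(bytes(data["manifest_json"]).decode())

    def read_net(prefix: str, acts: list[str]) -> MLP:
        layers = []
        i = 0
        while f"{prefix}_{i}_W" in data:
            layers.append(Dense(data[f"{prefix}_{i}_W"], data[f"{prefix}_{i}_b"], acts[i]))
            i += 1
        return MLP(layers)

    encoder = read_net("enc", manifest["encoder_activations"])
    decoder = read_net("dec", manifest["decoder_activations"])
    sizes = encoder.sizes
    spec = EncoderSpec(sizes[0], tuple(sizes[1:-1]), sizes[-1])
    state = DecState(encoder, decoder, spec, alpha=manifest["alpha"],
                     centroids=data["centroids"] if "centroids" in data else None)
    genes = manifest["genes"]
    embeddings = (
        GeneEmbeddingMatrix(data["gene_embeddings"], genes)
        if "gene_embeddings" in data
        else None
    )
    c2t = {int(k): v for k, v in manifest["cluster_to_type"].items()}
    cfgd = manifest["config"]
    cfg = GdecConfig(
        normalize_mode=cfgd["normalize_mode"],
        use_gcn=cfgd["use_gcn"],
        fusion_mode=cfgd["fusion_mode"],
        gcn=GcnConfig(**cfgd["gcn"]),
        encoder_hidden=tuple(cfgd["encoder_hidden"]),
        latent_dim=cfgd["latent_dim"],
        alpha=cfgd["alpha"],
        pretrain=PretrainConfig(**cfgd["pretrain"]),
        dec=DecFitConfig(**cfgd["dec"]),
        seed=cfgd["seed"],
    )
    return ModelBundle(genes, embeddings, state, c2t, cfg)
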