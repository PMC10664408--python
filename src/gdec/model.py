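"""Model/Results interface over the clustering pipeline.

:class:`GDEC` is constructed from data (expression matrix, gene graph and,
for a labelled source dataset, a label table); :meth:`GDEC.fit` runs the
full pipeline and returns a :class:`GDECResults` carrying the fitted state,
per-cell assignments, loss diagnostics and a ``summary()`` table.
Cross-dataset transfer hangs off the results object:
``results.transfer(target_expr, prior_labels)`` returns a
:class:`TransferResults` for the target dataset.
"""
from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import metrics
from .io import ExpressionMatrix, GeneGraph, LabelTable, read_expression, read_gene_graph, read_labels
from .transfer import (
    ClusterResult,
    GdecConfig,
    ModelBundle,
    TransferConfig,
    pretrain_source,
    transfer_and_finetune,
)

__all__ = ["GDEC", "GDECResults", "TransferResults"]


class GDEC:
    """Graph-based deep embedded clustering model.

    Parameters
    ----------
    expr : ExpressionMatrix
        Cells x genes expression values (counts or normalised).
    graph : GeneGraph
        Gene-interaction network; ignored when ``config.use_gcn`` is False.
    labels : LabelTable
        Cell-type labels for the (source) dataset; determines the number of
        clusters and the cluster-to-type map.
    config : GdecConfig, optional
        Pipeline hyperparameters.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        graph: GeneGraph,
        labels: LabelTable,
        config: GdecConfig | None = None,
    ):
        self.expr = expr
        self.graph = graph
        self.labels = labels
        self.config = config or GdecConfig()

    @classmethod
    def from_files(cls, expr_path, graph_path, labels_path,
                   config: GdecConfig | None = None) -> "GDEC":
        return cls(
            read_expression(expr_path),
            read_gene_graph(graph_path),
            read_labels(labels_path),
            config,
        )

    def fit(self, seed: int | None = None) -> "GDECResults":
        cfg = self.config if seed is None else self.config.with_seed(seed)
        bundle = pretrain_source(self.expr, self.labels, self.graph, cfg)
        return GDECResults(self, bundle)


class GDECResults:
    """Fitted source model: weights, centroids, assignments, diagnostics."""

    def __init__(self, model: GDEC, bundle: ModelBundle):
        self.model = model
        self.bundle = bundle

    @property
    def assignments(self) -> ClusterResult:
        return self.bundle.source_result

    @property
    def cluster_to_type(self) -> dict[int, str]:
        return self.bundle.cluster_to_type

    @property
    def kl_history(self) -> list[float]:
        return self.bundle.state.kl_history

    @property
    def pretrain_loss(self) -> list[float]:
        return self.bundle.state.pretrain_loss

    def training_accuracy(self) -> float:
        return metrics.hungarian_accuracy(self.model.labels, self.assignments)

    def summary(self) -> str:
        b = self.bundle
        res = self.assignments
        sizes = pd.Series(res.cluster).value_counts().sort_index()
        lines = [
            "GDEC source model",
            "=" * 46,
            f"cells: {len(res.cell_ids)}    genes: {len(b.gene_ids)}",
            f"clusters (k): {b.state.k}    alpha: {b.state.alpha}",
            f"encoder: {' -> '.join(map(str, b.state.encoder.sizes))}",
            f"gene embedding: "
            + (f"d={b.embeddings.d}" if b.embeddings is not None else "disabled"),
            f"final pretrain MSE: "
            + (f"{b.state.pretrain_loss[-1]:.5f}" if b.state.pretrain_loss else "n/a"),
            f"final KL(P||Q): "
            + (f"{b.state.kl_history[-1]:.5f}" if b.state.kl_history else "n/a"),
            f"training accuracy (Hungarian): {self.training_accuracy():.4f}",
            "-" * 46,
            "cluster  size  mapped type",
        ]
        for c, n in sizes.items():
            lines.append(f"{c:>7d}  {n:>4d}  {b.cluster_to_type[int(c)]}")
        return "\n".join(lines)

    def transfer(
        self,
        target_expr: ExpressionMatrix,
        prior_labels: LabelTable | None = None,
        config: TransferConfig | None = None,
        seed: int | None = None,
    ) -> "TransferResults":
        tcfg = config or TransferConfig()
        if seed is not None:
            tcfg = replace(tcfg, seed=seed)
        state, result = transfer_and_finetune(self.bundle, target_expr, prior_labels, tcfg)
        return TransferResults(self, target_expr, state, result, tcfg)


class TransferResults:
    """Target-dataset clustering produced by transfer + fine-tuning."""

    def __init__(self, source: GDECResults, target_expr, state, result: ClusterResult, tcfg):
        self.source = source
        self.target_expr = target_expr
        self.state = state
        self.result = result
        self.config = tcfg

    @property
    def assignments(self) -> ClusterResult:
        return self.result

    def evaluate(self, true_labels: LabelTable, unknown_policy: str = "exclude") -> dict:
        """Accuracy/ARI/NMI of the target assignment against ground truth."""
        return {
            "accuracy": metrics.hungarian_accuracy(true_labels, self.result, unknown_policy),
            "ari": metrics.ari(true_labels, self.result),
            "nmi": metrics.nmi(true_labels, self.result),
        }

    def confusion(self, true_labels: LabelTable) -> metrics.ConfusionMatrix:
        return metrics.confusion(true_labels, self.result)

    def summary(self) -> str:
        res = self.result
        known = res.cluster >= 0
        lines = [
            "GDEC transfer results",
            "=" * 46,
            f"target cells: {len(res.cell_ids)}",
            f"rejection tau: {self.config.rejection_tau}",
            f"assigned: {int(known.sum())}    unknown: {res.n_unknown}",
            f"mean max_q (assigned): "
            + (f"{res.max_q[known].mean():.4f}" if known.any() else "n/a"),
            "-" * 46,
            "type            cells",
        ]
        counts = pd.Series(res.mapped_type).value_counts()
        for t, n in counts.items():
            lines.append(f"{t:<15s} {n:>5d}")
        return "\n".join(lines)
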