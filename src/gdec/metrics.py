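"""Clustering evaluation: optimally matched accuracy, ARI/NMI and
row-normalised confusion matrices.

Hungarian-matched accuracy maximises the number of correctly labelled cells
over one-to-one assignments of predicted clusters to true types (optimal
assignment on the contingency table); surplus clusters remain unmatched and
all their cells count as errors.  Rejected (``"unknown"``) cells are either
excluded from the denominator or counted as wrong, per policy.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io import LabelTable
from .transfer import UNKNOWN, ClusterResult

log = logging.getLogger("gdec")

__all__ = ["ConfusionMatrix", "hungarian_accuracy", "confusion", "ari", "nmi"]


@dataclass
class ConfusionMatrix:
    """Row-normalised true x predicted proportions (rows sum to 1)."""

    values: np.ndarray
    true_labels: list[str]
    pred_labels: list[str]

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        nonempty = sums > 0
        if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
            raise ValueError("nonempty confusion rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.true_labels, columns=self.pred_labels)

    def plot(self, ax=None, cmap: str = "viridis"):
        """Heatmap with true types on the vertical axis, predictions on the
        horizontal axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.6 * len(self.pred_labels),
                                          1 + 0.5 * len(self.true_labels)))
        im = ax.imshow(self.values, cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks(range(len(self.pred_labels)), self.pred_labels, rotation=45, ha="right")
        ax.set_yticks(range(len(self.true_labels)), self.true_labels)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax, label="row proportion")
        return ax


def _paired(true: LabelTable, pred) -> tuple[list[str], list[str]]:
    """Common-cell (true, predicted) label pairs; predictions may be a
    LabelTable, ClusterResult or array aligned with ``true``."""
    if isinstance(pred, ClusterResult):
        pred = pred.as_label_table()
    if isinstance(pred, LabelTable):
        pmap = pred.as_dict()
        tmap = true.as_dict()
        common = [c for c in true.cell_ids if c in pmap]
        if not common:
            raise ValueError("no common cells between true and predicted labels")
        return [tmap[c] for c in common], [pmap[c] for c in common]
    pred = [str(p) for p in np.asarray(pred).ravel()]
    if len(pred) != len(true):
        raise ValueError("prediction length does not match label table")
    return list(true.labels), pred


def hungarian_accuracy(
    true: LabelTable, pred, unknown_policy: str = "exclude"
) -> float:
    """Clustering accuracy under the optimal cluster-to-type matching."""
    if unknown_policy not in ("exclude", "count_wrong"):
        raise ValueError(f"unknown policy {unknown_policy!r}")
    t, p = _paired(true, pred)
    t = np.asarray(t, dtype=object)
    p = np.asarray(p, dtype=object)
    known = p != UNKNOWN
    denom = int(known.sum()) if unknown_policy == "exclude" else len(p)
    if denom == 0:
        return 0.0
    t_k, p_k = t[known], p[known]
    if len(t_k) == 0:
        return 0.0
    tcats = sorted(set(t_k))
    pcats = sorted(set(p_k))
    table = np.zeros((len(tcats), len(pcats)))
    ti = {c: i for i, c in enumerate(tcats)}
    pi = {c: i for i, c in enumerate(pcats)}
    for a, b in zip(t_k, p_k):
        table[ti[a], pi[b]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / denom


def confusion(true: LabelTable, pred) -> ConfusionMatrix:
    """Row-normalised confusion matrix; ``unknown`` is its own column."""
    t, p = _paired(true, pred)
    df = pd.crosstab(pd.Series(t, name="true"), pd.Series(p, name="pred"))
    values = df.to_numpy(dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    return ConfusionMatrix(values, [str(x) for x in df.index], [str(x) for x in df.columns])


def _checked_partition_metric(true: LabelTable, pred, fn) -> float:
    t, p = _paired(true, pred)
    if len(set(t)) < 2 or len(set(p)) < 2:
        warnings.warn("single-cluster partition: metric defined as 0", stacklevel=3)
        return 0.0
    return float(fn(t, p))


def ari(true: LabelTable, pred) -> float:
    """Adjusted Rand index (0 with a warning for single-cluster input)."""
    return _checked_partition_metric(true, pred, adjusted_rand_score)


def nmi(true: LabelTable, pred) -> float:
    """Normalised mutual information (0 with a warning for single-cluster input)."""
    return _checked_partition_metric(true, pred, normalized_mutual_info_score)
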