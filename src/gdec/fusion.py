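"""Fusion of the expression profile with gene embeddings.

The per-cell gene-interaction features are the matrix product ``D = S @ M``
(cells x d); ``summed`` mode collapses D to a single column ``D' = sum_i
D_i``.  The DEC input is the column-wise concatenation ``I = [S, D]`` (or
``[S, D']``).  Optionally the appended block is standardised to zero mean /
unit variance per column so its scale cannot dominate the expression block.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import GeneEmbeddingMatrix
from .io import AlignmentError, ExpressionMatrix

__all__ = ["FusedFeatures", "fuse"]


@dataclass
class FusedFeatures:
    """Cells x (g+d) or cells x (g+1) DEC input matrix."""

    values: np.ndarray
    mode: str
    cell_ids: list[str]
    gene_ids: list[str]
    n_genes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite fused features")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def expression_block(self) -> np.ndarray:
        return self.values[:, : self.n_genes]

    @property
    def embedding_block(self) -> np.ndarray:
        return self.values[:, self.n_genes :]


def fuse(
    S: ExpressionMatrix,
    M: GeneEmbeddingMatrix,
    mode: str = "summed",
    standardize: bool = True,
) -> FusedFeatures:
    """Fuse expression with gene embeddings; gene orders must match exactly.

    A mismatch in gene order is an error, never silently reordered — run
    :func:`gdec.io.align_genes` first.
    """
    if mode not in ("full", "summed"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    if S.gene_ids != M.gene_ids:
        raise AlignmentError("expression and embedding gene orders differ")
    D = S.values @ M.values
    if mode == "summed":
        D = D.sum(axis=1, keepdims=True)
    if standardize:
        mu = D.mean(axis=0, keepdims=True)
        sd = D.std(axis=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        D = (D - mu) / sd
    values = np.hstack([S.values, D])
    return FusedFeatures(values, mode, list(S.cell_ids), list(S.gene_ids), S.n_genes)
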