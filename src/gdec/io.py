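"""On-disk formats and gene alignment.

Expression matrices are cells x genes (cells are rows). Supported formats:

* dense CSV/TSV with a header row of gene symbols and cell IDs in the first
  column;
* Matrix Market coordinate (``.mtx``) with sidecar newline-delimited name
  files ``<stem>.cells.txt`` and ``<stem>.genes.txt``.

Gene graphs are two-column TSV edge lists over gene symbols (no header).
Labels are two-column TSV ``cell_id<TAB>label``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger("gdec")

__all__ = [
    "ExpressionMatrix",
    "GeneGraph",
    "LabelTable",
    "AlignmentError",
    "ValidationError",
    "read_expression",
    "write_expression",
    "read_gene_graph",
    "write_gene_graph",
    "read_labels",
    "write_labels",
    "align_genes",
    "normalize",
    "select_top_variable_genes",
]


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class AlignmentError(ValueError):
    """Gene sets cannot be aligned (empty intersection or order mismatch)."""


@dataclass
class ExpressionMatrix:
    """Nonnegative cells x genes expression matrix with row/column names."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        a, g = self.values.shape
        if a < 1 or g < 1:
            raise ValidationError("expression matrix must be at least 1x1")
        if len(self.cell_ids) != a or len(self.gene_ids) != g:
            raise ValidationError("id lists do not match matrix shape")
        if len(set(self.cell_ids)) != a:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if (self.values < 0).any():
            raise ValidationError("negative expression values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(self.values[:, idx], list(self.cell_ids), list(genes))


@dataclass
class GeneGraph:
    """Undirected gene-interaction network.

    Edges are stored as sorted ``(gene_a, gene_b)`` tuples; self-loops and
    duplicates are never present.  ``degree`` maps each gene to its
    incident-edge count.
    """

    gene_ids: list[str]
    edges: set[tuple[str, str]]
    degree: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in graph")
        known = set(self.gene_ids)
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if u not in known or v not in known:
                raise ValidationError(f"edge ({u!r}, {v!r}) references unknown gene")
            canon.add((u, v) if u <= v else (v, u))
        self.edges = canon
        deg = {g: 0 for g in self.gene_ids}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        if self.degree and self.degree != deg:
            raise ValidationError("stated degrees disagree with incident edges")
        self.degree = deg

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def adjacency(self) -> sparse.csr_matrix:
        """Binary symmetric adjacency matrix in ``gene_ids`` order."""
        idx = self.index()
        if not self.edges:
            return sparse.csr_matrix((self.n_genes, self.n_genes))
        rows, cols = [], []
        for u, v in self.edges:
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_genes, self.n_genes))

    def normalized_adjacency(self) -> sparse.csr_matrix:
        """Symmetric degree-normalised adjacency D^{-1/2} A D^{-1/2}.

        Rows/columns of isolated genes are zero, so the neighbour sum for a
        degree-0 gene is empty and no division by zero is ever evaluated.
        """
        a = self.adjacency()
        deg = np.array([self.degree[g] for g in self.gene_ids], dtype=float)
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        d = sparse.diags(inv_sqrt)
        return (d @ a @ d).tocsr()

    def neighbors(self, gene: str) -> list[str]:
        out = []
        for u, v in self.edges:
            if u == gene:
                out.append(v)
            elif v == gene:
                out.append(u)
        return sorted(out)

    def subgraph(self, genes: list[str]) -> "GeneGraph":
        keep = set(genes)
        edges = {(u, v) for u, v in self.edges if u in keep and v in keep}
        return GeneGraph(list(genes), edges)


@dataclass
class LabelTable:
    """Per-cell string labels (ground truth or predictions)."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = [str(l) for l in self.labels]
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in label table")
        if any(l == "" for l in self.labels):
            raise ValidationError("empty label string")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def __len__(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(str(stem) + ".cells.txt"), Path(str(stem) + ".genes.txt")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or MTX (+ sidecar name files)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "mtx":
        cells_f, genes_f = _mtx_sidecars(path)
        for f in (cells_f, genes_f):
            if not f.exists():
                raise ValidationError(f"missing MTX companion file {f}")
        mat = spio.mmread(path)
        values = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float)
        cell_ids = cells_f.read_text().splitlines()
        gene_ids = genes_f.read_text().splitlines()
        return ExpressionMatrix(values, cell_ids, gene_ids)
    if format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "csv"
    if format == "mtx":
        cells_f, genes_f = _mtx_sidecars(path)
        spio.mmwrite(str(path), sparse.coo_matrix(expr.values))
        cells_f.write_text("\n".join(expr.cell_ids) + "\n")
        genes_f.write_text("\n".join(expr.gene_ids) + "\n")
    elif format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.gene_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_gene_graph(path: str | Path) -> GeneGraph:
    """Read a two-column TSV edge list; dedup, drop self-loops with a warning."""
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            u, v = fields[0].strip(), fields[1].strip()
            for g in (u, v):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
            if u == v:
                log.warning("dropping self-loop on %r (%s:%d)", u, path, lineno)
                continue
            edges.add((u, v) if u <= v else (v, u))
    return GeneGraph(genes, edges)


def write_gene_graph(graph: GeneGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated genes are not representable in an edge list; note them
        isolated = [g for g in graph.gene_ids if graph.degree[g] == 0]
        if isolated:
            log.warning("%d isolated genes not written to edge list %s", len(isolated), path)


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    return LabelTable(list(df["cell_id"]), list(df["label"]))


def write_labels(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(table.cell_ids, table.labels):
            fh.write(f"{c}\t{l}\n")


# ---------------------------------------------------------------------------
# alignment and normalization
# ---------------------------------------------------------------------------

def _apply_ortholog_map(gene_ids: list[str], ortholog_map: dict[str, str] | None) -> list[str]:
    if not ortholog_map:
        return gene_ids
    lut = {k.upper(): v for k, v in ortholog_map.items()}
    return [lut.get(g.upper(), g) for g in gene_ids]


def align_genes(
    expr: ExpressionMatrix,
    graph: GeneGraph,
    other: ExpressionMatrix | None = None,
    ortholog_map: dict[str, str] | None = None,
):
    """Restrict expression matrices and graph to their common gene set.

    Matching is by case-normalised symbol (optionally after renaming genes
    through ``ortholog_map``, e.g. mouse -> human symbols).  All outputs use
    one canonical gene order: the sorted upper-cased symbols of the
    intersection.  Graph degrees are recomputed on the induced subgraph.
    Returns ``(expr, graph)`` or ``(expr, graph, other)``.
    """

    def canon(ids: list[str]) -> dict[str, str]:
        renamed = _apply_ortholog_map(ids, ortholog_map)
        return {r.upper(): orig for r, orig in zip(renamed, ids)}

    maps = [canon(expr.gene_ids), canon(graph.gene_ids)]
    if other is not None:
        maps.append(canon(other.gene_ids))
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        raise AlignmentError("no genes shared between inputs")
    order = sorted(common)

    def restrict_expr(e: ExpressionMatrix, m: dict[str, str]) -> ExpressionMatrix:
        idx = {g: i for i, g in enumerate(e.gene_ids)}
        cols = [idx[m[u]] for u in order]
        return ExpressionMatrix(e.values[:, cols], list(e.cell_ids), list(order))

    gmap = maps[1]
    rename = {gmap[u]: u for u in order}
    keep = set(rename)
    edges = {
        tuple(sorted((rename[u], rename[v])))
        for u, v in graph.edges
        if u in keep and v in keep
    }
    out_graph = GeneGraph(list(order), edges)
    out_expr = restrict_expr(expr, maps[0])
    if other is None:
        return out_expr, out_graph
    return out_expr, out_graph, restrict_expr(other, maps[2])


def normalize(
    expr: ExpressionMatrix, mode: str = "log1p_cpm", target_sum: float = 1e4
) -> ExpressionMatrix:
    """Library-size normalisation.

    ``none`` is the identity.  ``log1p_cpm`` scales each cell to a fixed
    library size (``target_sum`` total counts) and applies log(1+x); all-zero
    cells are left as zeros with a warning.
    """
    if mode == "none":
        return ExpressionMatrix(expr.values.copy(), list(expr.cell_ids), list(expr.gene_ids))
    if mode != "log1p_cpm":
        raise ValueError(f"unknown normalization mode {mode!r}")
    sums = expr.values.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        log.warning("%d all-zero cells left unnormalised", int(zero.sum()))
    safe = np.where(sums > 0, sums, 1.0)
    scaled = expr.values / safe * target_sum
    scaled[zero, :] = 0.0
    return ExpressionMatrix(np.log1p(scaled), list(expr.cell_ids), list(expr.gene_ids))


def select_top_variable_genes(expr: ExpressionMatrix, n_top: int) -> list[str]:
    """Gene symbols of the ``n_top`` most variable genes (ties by symbol).

    Variance is taken over the matrix as given, so apply the intended
    normalisation first.  Standard highly-variable-gene screening: informative
    (e.g. marker) genes vary across cell types while most genes contribute
    only technical noise.
    """
    if n_top < 1:
        raise ValueError("n_top must be positive")
    n_top = min(n_top, expr.n_genes)
    var = expr.values.var(axis=0)
    order = sorted(range(expr.n_genes), key=lambda j: (-var[j], expr.gene_ids[j]))
    return sorted(expr.gene_ids[j] for j in order[:n_top])
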