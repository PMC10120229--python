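"""Recover relative expression from the detection pattern of neighbours.

Highly expressed genes are detected in almost every cell of a
neighbourhood, lowly expressed genes in few.  Averaging the detection
indicator of a gene over a cell's k nearest neighbours (found in a
binary-only embedding) therefore yields a [0, 1] value that tracks the
gene's relative expression in that region of the manifold, even though
the counts were discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import NeighborGraph, jaccard_eigenmap, knn_graph
from .matrix import BinaryMatrix, NormalizedMatrix

__all__ = ["RecoveredMatrix", "recover_expression", "evaluate_recovery"]


@dataclass
class RecoveredMatrix:
    values: np.ndarray  # genes x cells, neighbourhood detection rates in [0,1]
    k_used: int
    gene_ids: np.ndarray
    cell_ids: np.ndarray


def recover_expression(
    b: BinaryMatrix,
    g: NeighborGraph | None = None,
    include_self: bool = False,
    k: int = 15,
    n_components: int = 10,
) -> RecoveredMatrix:
    """Neighbourhood detection rate per gene per cell.

    When no neighbour graph is supplied one is built from a Jaccard
    eigenmap of the binary matrix itself (the count-free default).
    """
    if g is None:
        emb = jaccard_eigenmap(b, n_components=min(n_components, b.n_cells - 1))
        g = knn_graph(emb, k=min(k, b.n_cells - 1))
    if g.k == 0:
        raise ValueError("neighbour graph has k = 0")
    if g.neighbor_ids.shape[0] != b.n_cells:
        raise ValueError("neighbour graph does not match the matrix cells")
    dense = b.to_dense().astype(np.float64)
    # genes x cells x k gather, averaged over neighbours
    neigh = dense[:, g.neighbor_ids]  # genes x cells x k
    sums = neigh.sum(axis=2)
    denom = g.k
    if include_self:
        sums = sums + dense
        denom += 1
    return RecoveredMatrix(
        values=sums / denom,
        k_used=g.k,
        gene_ids=b.gene_ids,
        cell_ids=b.cell_ids,
    )


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((am**2).sum(axis=1))
    sb = np.sqrt((bm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (am * bm).sum(axis=1) / (sa * sb)
    return np.where((sa == 0) | (sb == 0), np.nan, r)


def evaluate_recovery(
    r: RecoveredMatrix, truth: NormalizedMatrix, scope: str = "per_gene"
) -> tuple[pd.Series, float]:
    """Pearson correlation of recovered vs normalized values.

    ``per_gene`` correlates across cells for each gene, ``per_cell``
    across genes for each cell; the summary is the median over defined
    correlations.  Constant vectors are skipped with a warning.
    """
    if r.values.shape != truth.values.shape:
        raise ValueError("recovered and truth matrices differ in shape")
    if scope == "per_gene":
        cors = _rowwise_pearson(r.values, truth.values)
        index = pd.Index(r.gene_ids, name="gene_id")
    elif scope == "per_cell":
        cors = _rowwise_pearson(r.values.T, truth.values.T)
        index = pd.Index(r.cell_ids, name="cell_id")
    else:
        raise ValueError("scope must be 'per_gene' or 'per_cell'")
    n_bad = int(np.isnan(cors).sum())
    if n_bad == cors.size:
        raise ValueError("no non-constant vectors; recovery cannot be evaluated")
    if n_bad:
        warnings.warn(f"{n_bad} constant vector(s) skipped")
    series = pd.Series(cors, index=index, name="pearson_r")
    return series, float(np.nanmedian(cors))
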