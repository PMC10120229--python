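"""Linear embeddings of binary / normalized matrices and quality metrics.

Two embeddings are provided: PCA (gene-wise centered, unscaled) applied
to either log-normalized values or the 0/1 detection matrix treated as
reals, and an eigenvector embedding of the Jaccard cell-cell similarity
matrix computed from detection patterns alone.  Quality is assessed by
per-cell-type silhouette scores, a fixed-k inverse Simpson mixing index
(iLISI) over batch labels, and the Pearson correlation of pairwise
cell-cell distances between two embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_samples

from .matrix import BinaryMatrix, NormalizedMatrix

__all__ = [
    "Embedding",
    "NeighborGraph",
    "pca_embed",
    "jaccard_eigenmap",
    "knn_graph",
    "silhouette_by_label",
    "ilisi",
    "distance_correlation",
]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x k
    method: str
    n_components: int
    cell_ids: np.ndarray | None = None
    explained: np.ndarray | None = None  # eigenvalues, non-increasing

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"dim{i + 1}" for i in range(self.coords.shape[1])],
        )
        if self.cell_ids is not None:
            df.insert(0, "cell_id", self.cell_ids)
        return df


@dataclass
class NeighborGraph:
    neighbor_ids: np.ndarray  # cells x k int indices, self excluded
    distances: np.ndarray  # cells x k, non-decreasing per row

    @property
    def k(self) -> int:
        return self.neighbor_ids.shape[1]


def _fix_signs(loadings: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
            coords[:, j] = -coords[:, j]
    return loadings, coords


def _dense_cells_by_genes(m) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(m, BinaryMatrix):
        return m.to_dense().T.astype(np.float64), m.cell_ids
    if isinstance(m, NormalizedMatrix):
        return m.values.T.astype(np.float64), m.cell_ids
    arr = np.asarray(m, dtype=np.float64)
    return arr.T, None


def pca_embed(m, n_components: int) -> Embedding:
    """PCA with gene-wise centering and no scaling.

    Components are eigenvectors of the cell covariance matrix; scores are
    the centered data projected on them.  The sign of each component is
    fixed so that its largest-magnitude gene loading is positive.  If
    ``n_components`` exceeds the matrix rank the returned embedding is
    truncated to the rank with a warning.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x, cell_ids = _dense_cells_by_genes(m)  # cells x genes
    n_cells = x.shape[0]
    if n_cells < 2:
        raise ValueError("PCA requires at least 2 cells")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating"
        )
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T  # genes x k
    _, coords = _fix_signs(loadings, coords)
    explained = (s[:k] ** 2) / (n_cells - 1)
    method = "pca_binary" if isinstance(m, BinaryMatrix) else "pca_counts"
    return Embedding(
        coords=coords, method=method, n_components=k,
        cell_ids=cell_ids, explained=explained,
    )


def jaccard_matrix(b: BinaryMatrix) -> np.ndarray:
    """Pairwise Jaccard similarity of cell detection patterns (diag 1)."""
    d = b.to_dense().astype(np.float64)  # genes x cells
    sizes = d.sum(axis=0)
    if np.any(sizes == 0):
        bad = b.cell_ids[np.flatnonzero(sizes == 0)][:10]
        raise ValueError(
            "Jaccard similarity undefined for cells with zero detected genes; "
            f"remove: {', '.join(map(str, bad))}"
        )
    inter = d.T @ d
    union = sizes[:, None] + sizes[None, :] - inter
    s = inter / union
    np.fill_diagonal(s, 1.0)
    return s


def jaccard_eigenmap(b: BinaryMatrix, n_components: int) -> Embedding:
    """Embedding from top eigenvectors of the Jaccard similarity matrix.

    Eigenvectors are scaled by the square root of their eigenvalues
    (negative eigenvalues truncated to zero) and sign-fixed like PCA
    components.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    s = jaccard_matrix(b)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    k = min(n_components, s.shape[0])
    evals, evecs = evals[order[:k]], evecs[:, order[:k]]
    coords = evecs * np.sqrt(np.maximum(evals, 0.0))
    _, coords = _fix_signs(evecs.copy(), coords)
    return Embedding(
        coords=coords, method="jaccard_eig", n_components=k,
        cell_ids=b.cell_ids, explained=evals,
    )


def _sorted_neighbors(dist_row: np.ndarray, self_idx: int, k: int) -> np.ndarray:
    order = np.lexsort((np.arange(dist_row.size), dist_row))
    return order[order != self_idx][:k]


def knn_graph(e: Embedding, k: int) -> NeighborGraph:
    """Euclidean k-nearest neighbours, ties broken by lower cell index."""
    if k <= 0:
        raise ValueError("k must be positive")
    n = e.coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    dist = squareform(pdist(e.coords))
    ids = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        ids[i] = _sorted_neighbors(dist[i], i, k)
    return NeighborGraph(neighbor_ids=ids, distances=np.take_along_axis(dist, ids, 1))


def silhouette_by_label(e: Embedding, labels) -> tuple[pd.Series, float]:
    """Per-label mean silhouette and the overall mean (Euclidean distance)."""
    labels = np.asarray(labels)
    if labels.shape[0] != e.coords.shape[0]:
        raise ValueError("labels length must match number of cells")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two labels")
    s = silhouette_samples(e.coords, labels, metric="euclidean")
    per_label = pd.Series(s).groupby(labels).mean()
    per_label.index.name = "label"
    return per_label, float(s.mean())


def ilisi(e: Embedding, batch_labels, k: int) -> float:
    """Mean inverse Simpson index of batch proportions among k neighbours.

    1 means each cell's neighbourhood is a single batch; the number of
    batches means perfect mixing.  A simplified fixed-k variant of LISI.
    """
    batch_labels = np.asarray(batch_labels)
    graph = knn_graph(e, k)
    codes = pd.factorize(batch_labels)[0]
    n_batches = codes.max() + 1
    neigh_codes = codes[graph.neighbor_ids]  # cells x k
    counts = np.stack(
        [(neigh_codes == b).sum(axis=1) for b in range(n_batches)], axis=1
    )
    props = counts / k
    scores = 1.0 / (props**2).sum(axis=1)
    return float(scores.mean())


def distance_correlation(a: Embedding, b: Embedding) -> float:
    """Pearson r between the condensed pairwise-distance vectors of a and b."""
    if a.coords.shape[0] != b.coords.shape[0]:
        raise ValueError("embeddings must contain the same cells")
    da, db = pdist(a.coords), pdist(b.coords)
    if da.std() == 0 or db.std() == 0:
        raise ValueError("constant distance vector; correlation undefined")
    return float(pearsonr(da, db)[0])
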