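"""Per-cell concordance between the binary and normalized representations.

For every cell we compute the point-biserial correlation ``p`` between its
log-normalized expression vector and its 0/1 detection vector, and the
predictor ``q`` = detection rate x variance of the non-zero normalized
values.  Cells with many zeros and little spread among their detected
values have ``p`` close to 1 — for such cells the detection pattern
carries nearly all of the normalized signal.  The dataset-level summary
``alpha`` is the Pearson correlation of ``p`` against ``q`` across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix, NormalizedMatrix

__all__ = ["CellDiagnostics", "cell_concordance", "alpha_statistic"]


@dataclass
class CellDiagnostics:
    cell_ids: np.ndarray
    p: np.ndarray  # point-biserial correlation, NaN where undefined
    q: np.ndarray  # detection_rate * var_nonzero
    detection_rate: np.ndarray
    var_nonzero: np.ndarray
    alpha: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "p": self.p,
                "q": self.q,
                "detection_rate": self.detection_rate,
                "var_nonzero": self.var_nonzero,
            }
        )


def cell_concordance(norm: NormalizedMatrix, b: BinaryMatrix) -> CellDiagnostics:
    """Per-cell p, q, detection rate and non-zero variance.

    ``p`` is the Pearson correlation across genes between a cell's
    normalized values and its detections.  ``var_nonzero`` is the unbiased
    (n-1) sample variance of the cell's non-zero normalized values, zero
    when the cell has exactly one detected gene.  Cells with a constant
    vector on either side get ``p`` = NaN with a warning.
    """
    if (norm.n_genes, norm.n_cells) != (b.n_genes, b.n_cells):
        raise ValueError("normalized and binary matrices differ in shape")
    x = norm.values  # genes x cells
    y = b.to_dense().astype(np.float64)
    n = x.shape[0]
    mean_x = x.mean(axis=0)
    det = y.mean(axis=0)
    # population covariance/std per cell; x*y == x because zeros align
    cov = (x * y).mean(axis=0) - mean_x * det
    sx = x.std(axis=0)
    sy = y.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = cov / (sx * sy)
    undefined = (sx == 0) | (sy == 0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} cell(s) have a constant vector; "
            "their concordance p is undefined"
        )
        p = np.where(undefined, np.nan, p)

    n_det = y.sum(axis=0)
    sum_x = x.sum(axis=0)
    sum_x2 = (x**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_nz = sum_x / n_det
        var_nz = (sum_x2 - n_det * mean_nz**2) / (n_det - 1)
    var_nz = np.where(n_det <= 1, 0.0, var_nz)
    var_nz = np.maximum(var_nz, 0.0)  # guard tiny negative rounding
    q = det * var_nz
    return CellDiagnostics(
        cell_ids=norm.cell_ids,
        p=np.asarray(p, dtype=np.float64),
        q=q,
        detection_rate=det,
        var_nonzero=var_nz,
    )


def alpha_statistic(d: CellDiagnostics) -> float:
    """Pearson correlation of p against q across cells (pairwise-complete)."""
    mask = np.isfinite(d.p) & np.isfinite(d.q)
    if mask.sum() < 3:
        raise ValueError("alpha requires at least 3 cells with defined p")
    p, q = d.p[mask], d.q[mask]
    if p.std() == 0 or q.std() == 0:
        raise ValueError("alpha undefined: constant p or q vector")
    alpha = float(np.corrcoef(p, q)[0, 1])
    d.alpha = alpha
    return alpha
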