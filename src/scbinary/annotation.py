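"""Marker-detection cell-type annotation of binarized data.

A cell is scored against each cell type by the fraction of that type's
marker genes it detects; the label is the unique best-scoring type with a
positive score, otherwise "unassigned".  Agreement with reference labels
is summarized by per-type F1 and its median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix

__all__ = [
    "UNASSIGNED",
    "AnnotationResult",
    "read_markers",
    "annotate_by_markers",
    "f1_scores",
]

UNASSIGNED = "unassigned"


@dataclass
class AnnotationResult:
    labels: np.ndarray  # per cell, a type name or UNASSIGNED
    scores: pd.DataFrame  # cells x types, fraction of markers detected
    cell_ids: np.ndarray


def read_markers(path: str | Path) -> dict[str, list[str]]:
    """Marker sets from a 2-column TSV (cell_type, gene_id) or a JSON mapping."""
    path = Path(path)
    if path.suffix == ".json":
        mapping = json.loads(path.read_text())
        return {str(k): [str(g) for g in v] for k, v in mapping.items()}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("marker TSV needs columns cell_type and gene_id")
    ct_col, gene_col = df.columns[:2]
    return {
        str(ct): sub[gene_col].astype(str).tolist()
        for ct, sub in df.groupby(ct_col, sort=True)
    }


def annotate_by_markers(b: BinaryMatrix, markers: dict[str, list[str]]) -> AnnotationResult:
    """Label each cell by the fraction of each type's markers it detects.

    Marker genes absent from the matrix are dropped with a warning; a type
    whose marker list becomes empty is an error.  Ties for the best score,
    or an all-zero score vector, yield "unassigned".
    """
    gene_index = {g: i for i, g in enumerate(b.gene_ids)}
    usable: dict[str, list[int]] = {}
    for ct, genes in markers.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        missing = [g for g in genes if g not in gene_index]
        if missing:
            warnings.warn(
                f"{ct}: {len(missing)} marker(s) absent from matrix, dropped"
            )
        if not idx:
            raise ValueError(f"cell type {ct!r} has no usable markers")
        usable[ct] = idx

    dense = b.to_dense()
    types = list(usable)
    score = np.stack(
        [dense[usable[ct], :].mean(axis=0) for ct in types], axis=1
    )  # cells x types
    best = score.max(axis=1)
    n_best = (score == best[:, None]).sum(axis=1)
    labels = np.where(
        (best > 0) & (n_best == 1),
        np.asarray(types, dtype=object)[score.argmax(axis=1)],
        UNASSIGNED,
    ).astype(object)
    scores = pd.DataFrame(score, columns=types)
    scores.insert(0, "cell_id", b.cell_ids)
    scores = scores.set_index("cell_id")
    return AnnotationResult(labels=labels, scores=scores, cell_ids=b.cell_ids)


def f1_scores(pred_labels, true_labels) -> tuple[pd.Series, float]:
    """Per-type F1 against reference labels, plus the median over types.

    Types are those present in the reference.  An "unassigned" prediction
    is never a true positive; it counts as a miss for the cell's true
    type.
    """
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("label vectors must be equal-length and non-empty")
    out = {}
    for ct in sorted(set(true.tolist())):
        tp = int(((pred == ct) & (true == ct)).sum())
        fp = int(((pred == ct) & (true != ct)).sum())
        fn = int(((pred != ct) & (true == ct)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        out[ct] = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
    per_type = pd.Series(out, name="f1")
    per_type.index.name = "cell_type"
    return per_type, float(per_type.median())
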