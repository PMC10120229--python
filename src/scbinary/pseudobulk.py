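"""Pseudobulk aggregation and the two differential-expression routes.

Single cells are collapsed to one profile per sample, either as the mean
log-normalized expression of each gene or as the gene's detection rate
(fraction of non-zero cells).  Differential expression between two
conditions is then tested per gene with

* ``detection_t`` — a two-sided Welch t-test on the per-sample detection
  rates (the count-free route), or
* ``moderated_trend`` — a linear model on the per-sample means with
  empirical-Bayes variance shrinkage toward an intensity-dependent trend
  (the limma-trend style count route): the posterior variance is
  s~^2 = (d0*s0^2 + d*s^2) / (d0 + d), the moderated t uses d0 + d
  degrees of freedom, the prior s0^2(A) is a quadratic fit of log s^2 on
  mean abundance A, and the prior df d0 is moment-matched on the
  log-variance residuals.

Both routes are Benjamini-Hochberg adjusted; a gene is called DE when its
adjusted p is at or below the FDR level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .matrix import BinaryMatrix, NormalizedMatrix, binarize

__all__ = [
    "PseudobulkTable",
    "DEResult",
    "ConfusionSummary",
    "aggregate_pseudobulk",
    "de_test",
    "bh_adjust",
    "evaluate_de",
]

DEFAULT_BINS = np.round(np.arange(0.0, 1.01, 0.1), 10)


@dataclass
class PseudobulkTable:
    values: np.ndarray  # samples x genes
    mode: str  # "mean" | "detection_rate"
    sample_ids: np.ndarray
    condition: np.ndarray  # per sample
    n_cells: np.ndarray  # per sample
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "detection_rate"):
            raise ValueError("mode must be 'mean' or 'detection_rate'")
        if self.mode == "detection_rate":
            if self.values.size and (
                self.values.min() < 0 or self.values.max() > 1
            ):
                raise ValueError("detection rates must lie in [0, 1]")
        if np.any(self.n_cells < 1):
            raise ValueError("every sample needs at least one cell")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.gene_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "condition", self.condition)
        return df


@dataclass
class DEResult:
    gene_ids: np.ndarray
    effect: np.ndarray  # difference of group means (first - second condition)
    stat: np.ndarray
    p: np.ndarray
    padj: np.ndarray
    call: np.ndarray  # boolean at the stated FDR level
    route: str
    alpha: float
    df: np.ndarray | None = None
    d0: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "effect": self.effect,
                "stat": self.stat,
                "p": self.p,
                "padj": self.padj,
                "call": self.call,
            }
        )


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    fn_by_detection_bin: pd.Series = field(repr=False, default=None)


def aggregate_pseudobulk(
    m: NormalizedMatrix | BinaryMatrix,
    sample_of_cell=None,
    mode: str = "detection_rate",
) -> PseudobulkTable:
    """Collapse cells to per-sample profiles (mean or detection rate).

    ``detection_rate`` mode is exactly ``mean`` mode applied to the
    binarized matrix.
    """
    if sample_of_cell is None:
        sample_of_cell = m.sample_of_cell
    if sample_of_cell is None:
        raise ValueError("sample_of_cell annotation required")
    sample_of_cell = np.asarray(sample_of_cell, dtype=object)
    if mode == "detection_rate":
        dense = binarize(m).to_dense().astype(np.float64)
    elif mode == "mean":
        dense = (
            m.to_dense().astype(np.float64)
            if isinstance(m, BinaryMatrix)
            else m.values
        )
    else:
        raise ValueError("mode must be 'mean' or 'detection_rate'")

    sample_ids = pd.unique(sample_of_cell)
    groups = {s: np.flatnonzero(sample_of_cell == s) for s in sample_ids}
    values = np.stack([dense[:, idx].mean(axis=1) for idx in groups.values()])
    n_cells = np.array([len(idx) for idx in groups.values()])
    if m.condition_of_cell is not None:
        condition = np.array(
            [m.condition_of_cell[idx[0]] for idx in groups.values()], dtype=object
        )
    else:
        condition = np.array([None] * len(sample_ids), dtype=object)
    return PseudobulkTable(
        values=values,
        mode=mode,
        sample_ids=np.asarray(sample_ids, dtype=object),
        condition=condition,
        n_cells=n_cells,
        gene_ids=m.gene_ids,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1 or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized two-sample t on samples x genes blocks.

    Welch by default; genes where one group is constant fall back to the
    pooled-variance statistic (with a warning).  Genes constant in both
    groups get t = 0, p = 1 when the effect is zero and p = 0 otherwise.
    """
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    effect = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        se2_w = v1 / n1 + v2 / n2
        df_w = se2_w**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2_p = sp2 * (1 / n1 + 1 / n2)
        df_p = np.full_like(se2_p, float(n1 + n2 - 2))

    one_const = ((v1 == 0) ^ (v2 == 0))
    both_const = (v1 == 0) & (v2 == 0)
    if one_const.any():
        warnings.warn(
            f"{int(one_const.sum())} gene(s) constant in one group; "
            "using pooled-variance t for them"
        )
    se2 = np.where(one_const, se2_p, se2_w)
    df = np.where(one_const, df_p, df_w)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        p = 2 * stats.t.sf(np.abs(t), df)
    # no within-group variance at all: the t-test is undefined (p = 1, no
    # call) — matching the behaviour of refusing essentially-constant data
    t = np.where(both_const, 0.0, t)
    p = np.where(both_const, 1.0, p)
    df = np.where(both_const, np.nan, df)
    return effect, t, p, df


def _inv_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    lo, hi = 1e-8, 1e8
    f = lambda x: special.polygamma(1, x) - y
    if f(lo) < 0:  # y above trigamma range -> tiny x
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-12)


def _moderated_trend(
    x1: np.ndarray, x2: np.ndarray, d0_override: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    n1, n2 = x1.shape[0], x2.shape[0]
    d = n1 + n2 - 2
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    effect = m1 - m2
    v = 1.0 / n1 + 1.0 / n2
    s2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)) / d
    abundance = np.concatenate([x1, x2]).mean(axis=0)

    ok = s2 > 0
    if d0_override is not None and d0_override == 0:
        d0, s0 = 0.0, np.ones_like(s2)  # prior irrelevant at weight 0
    else:
        if ok.sum() < 10:
            raise ValueError("too few genes with positive variance to fit a trend")
        # quadratic trend of log s^2 on abundance; the digamma/log terms
        # correct for E[log chi2_d / d] so s0^2 is on the variance scale
        coef = np.polyfit(abundance[ok], np.log(s2[ok]), deg=2)
        fitted = np.polyval(coef, abundance)
        resid = np.log(s2[ok]) - fitted[ok]
        excess = resid.var(ddof=1) - special.polygamma(1, d / 2)
        if d0_override is not None:
            d0 = float(d0_override)
        elif excess > 0:
            d0 = 2.0 * _inv_trigamma(float(excess))
        else:
            d0 = 1e8  # residual spread below sampling noise: shrink fully
        s0 = np.exp(fitted - special.digamma(d / 2) + np.log(d / 2))

    st2 = (d0 * s0 + d * s2) / (d0 + d)
    df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(st2 * v)
        p = 2 * stats.t.sf(np.abs(t), df_total)
    degenerate = (st2 == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    df = np.full_like(p, df_total)
    return effect, t, p, df, d0


def de_test(
    pb: PseudobulkTable,
    route: str = "detection_t",
    alpha: float = 0.05,
    d0_override: float | None = None,
) -> DEResult:
    """Per-gene two-condition test on a pseudobulk table.

    Conditions are taken in sorted order; ``effect`` is mean(first) -
    mean(second).  ``d0_override=0`` turns the moderated test into the
    ordinary pooled t-test (no shrinkage).
    """
    conds = sorted(set(pb.condition.tolist()))
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    g1 = pb.values[pb.condition == conds[0]]
    g2 = pb.values[pb.condition == conds[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each condition needs at least 2 samples")

    d0 = None
    if route == "detection_t":
        effect, t, p, df = _welch(g1, g2)
    elif route == "moderated_trend":
        effect, t, p, df, d0 = _moderated_trend(g1, g2, d0_override)
    else:
        raise ValueError("route must be 'detection_t' or 'moderated_trend'")

    padj = bh_adjust(p)
    return DEResult(
        gene_ids=pb.gene_ids,
        effect=effect,
        stat=t,
        p=p,
        padj=padj,
        call=padj <= alpha,
        route=route,
        alpha=alpha,
        df=df,
        d0=d0,
    )


def evaluate_de(
    r: DEResult,
    is_de_true: np.ndarray,
    gene_detection: np.ndarray | None = None,
    bins: np.ndarray = DEFAULT_BINS,
) -> ConfusionSummary:
    """Confusion counts and F1 against simulation truth.

    When per-gene overall detection rates are supplied, false negatives
    are additionally binned on them (left-closed bins, last bin closed).
    """
    truth = np.asarray(is_de_true, dtype=bool)
    if truth.shape[0] != r.call.shape[0]:
        raise ValueError("truth length does not match result genes")
    call = np.asarray(r.call, dtype=bool)
    tp = int((call & truth).sum())
    fp = int((call & ~truth).sum())
    fn = int((~call & truth).sum())
    tn = int((~call & ~truth).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    fn_bins = None
    if gene_detection is not None:
        det = np.asarray(gene_detection, dtype=np.float64)
        fn_mask = ~call & truth
        cats = pd.cut(det[fn_mask], bins=bins, include_lowest=True)
        fn_bins = cats.value_counts().sort_index()
    return ConfusionSummary(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        fn_by_detection_bin=fn_bins,
    )
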