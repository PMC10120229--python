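"""Synthetic scRNA-seq generators with known ground truth.

Two generators cover the statistical structure the analyses assume:

* :func:`simulate_multisample` — a hierarchical negative-binomial
  simulator of a two-condition, multi-sample experiment.  Gene baseline
  means are log-normal, dispersions uniform, each sample perturbs every
  gene by a log-normal factor (inter-individual variability), and a
  known fraction of genes carries a condition effect of fixed log2
  magnitude with random sign.  This is the standard hierarchical design
  used by pseudobulk DE benchmarks.

* :func:`simulate_celltypes` — a multi-population generator with marker
  genes (high detection in their own type, near-absent elsewhere),
  housekeeping genes (identical NB in every type) and low-level
  background genes, for annotation, embedding and zero-inflation
  analyses.

:func:`setting_grid` spans 96 unique multi-sample settings
(4 sample sizes x 4 cell counts x 2 DE fractions x 3 effect sizes); run
with 10 seeds each this yields 960 simulated datasets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_multisample",
    "simulate_celltypes",
    "setting_grid",
]


@dataclass(frozen=True)
class SimConfig:
    """Multi-sample simulation settings.

    Defaults describe a mid-sized population study: 1,000 genes, two
    conditions with 5 samples each, 100 cells per sample, 10% DE genes
    with |log2FC| = 1, log-normal baseline means (median ~0.37 counts per
    cell, a realistically zero-rich regime), NB dispersions theta in
    [0.5, 3], and 20% log-scale inter-sample variability.
    """

    n_genes: int = 1000
    samples_per_group: int = 5
    cells_per_sample: int = 100
    p_de: float = 0.1
    lfc: float = 1.0
    baseline_loc: float = -1.0
    baseline_scale: float = 1.5
    theta_range: tuple[float, float] = (0.5, 3.0)
    sample_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.samples_per_group < 1 or self.cells_per_sample < 1:
            raise ValueError("sizes must be positive")
        if not 0 <= self.p_de <= 1:
            raise ValueError("p_de must lie in [0, 1]")
        if self.lfc < 0 or self.sample_effect_sd < 0 or self.baseline_scale <= 0:
            raise ValueError("scales must be non-negative")
        if not 0 < self.theta_range[0] <= self.theta_range[1]:
            raise ValueError("theta_range must be positive and ordered")


@dataclass(frozen=True)
class SimTruth:
    is_de: np.ndarray  # boolean per gene
    lfc: np.ndarray  # signed log2 fold change, 0 for null genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """NB(mean, size=theta) via the gamma-Poisson mixture (vectorized)."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate_multisample(c: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Hierarchical NB counts for two conditions with per-sample effects."""
    rng = np.random.default_rng(c.seed)
    g = c.n_genes
    mu = np.exp(rng.normal(c.baseline_loc, c.baseline_scale, size=g))
    theta = rng.uniform(*c.theta_range, size=g)
    is_de = rng.random(g) < c.p_de
    sign = rng.choice([-1.0, 1.0], size=g)
    lfc = np.where(is_de, sign * c.lfc, 0.0)

    n_samples = 2 * c.samples_per_group
    conditions = np.array(
        ["A"] * c.samples_per_group + ["B"] * c.samples_per_group, dtype=object
    )
    sample_factor = np.exp(
        rng.normal(0.0, c.sample_effect_sd, size=(g, n_samples))
    )

    blocks, cell_ids, sample_of_cell, condition_of_cell = [], [], [], []
    for s in range(n_samples):
        cond_mult = 2.0**lfc if conditions[s] == "B" else np.ones(g)
        mean_gene = mu * sample_factor[:, s] * cond_mult
        mean = np.broadcast_to(
            mean_gene[:, None], (g, c.cells_per_sample)
        )
        theta_b = np.broadcast_to(theta[:, None], mean.shape)
        blocks.append(_nb_draw(rng, mean, theta_b))
        sid = f"s{s:02d}"
        for j in range(c.cells_per_sample):
            cell_ids.append(f"{sid}_c{j:04d}")
            sample_of_cell.append(sid)
            condition_of_cell.append(conditions[s])

    values = np.concatenate(blocks, axis=1)
    m = CountMatrix(
        values=values,
        gene_ids=np.array([f"g{i:05d}" for i in range(g)], dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        sample_of_cell=np.array(sample_of_cell, dtype=object),
        condition_of_cell=np.array(condition_of_cell, dtype=object),
    )
    return m, SimTruth(is_de=is_de, lfc=lfc)


def _mean_for_detection(detection: float, theta: float) -> float:
    """NB mean whose zero probability is 1 - detection (at size theta)."""
    return theta * ((1 - detection) ** (-1.0 / theta) - 1.0)


def simulate_celltypes(
    n_types: int = 3,
    cells_per_type: int = 200,
    markers_per_type: int = 10,
    n_housekeeping: int = 50,
    n_background: int = 140,
    detection_high: float = 0.9,
    detection_low: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Multi-population counts with marker / housekeeping / background genes.

    Marker genes of a type have NB means targeting ``detection_high`` in
    that type and ``detection_low`` elsewhere; housekeeping genes share
    one NB across all types (per-gene detection drawn in [0.5, 0.9]);
    background genes are uniformly low (detection in [0.05, 0.4]).
    Returns the labelled matrix and a per-gene truth table (gene_id,
    gene_class, marker_type).
    """
    if not 0 <= detection_low < detection_high < 1:
        raise ValueError("need 0 <= detection_low < detection_high < 1")
    if n_types < 1 or cells_per_type < 1 or markers_per_type < 0:
        raise ValueError("degenerate configuration")
    rng = np.random.default_rng(seed)
    n_markers = n_types * markers_per_type
    g = n_markers + n_housekeeping + n_background
    theta = rng.uniform(1.0, 3.0, size=g)

    # per-gene per-type target detection rates
    target = np.empty((g, n_types))
    gene_class = np.empty(g, dtype=object)
    marker_type = np.full(g, "", dtype=object)
    row = 0
    for t in range(n_types):
        for _ in range(markers_per_type):
            target[row] = detection_low
            target[row, t] = detection_high
            gene_class[row] = "marker"
            marker_type[row] = f"type{t}"
            row += 1
    for _ in range(n_housekeeping):
        target[row] = rng.uniform(0.5, 0.9)
        gene_class[row] = "housekeeping"
        row += 1
    for _ in range(n_background):
        target[row] = rng.uniform(0.05, 0.4)
        gene_class[row] = "background"
        row += 1

    blocks, labels = [], []
    for t in range(n_types):
        mean = np.array(
            [_mean_for_detection(target[i, t], theta[i]) for i in range(g)]
        )
        mean = np.maximum(mean, 1e-8)
        mb = np.broadcast_to(mean[:, None], (g, cells_per_type))
        tb = np.broadcast_to(theta[:, None], mb.shape)
        blocks.append(_nb_draw(rng, mb, tb))
        labels.extend([f"type{t}"] * cells_per_type)

    values = np.concatenate(blocks, axis=1)
    gene_ids = np.array([f"g{i:05d}" for i in range(g)], dtype=object)
    m = CountMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=np.array(
            [f"c{i:05d}" for i in range(values.shape[1])], dtype=object
        ),
        celltype_of_cell=np.array(labels, dtype=object),
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "gene_class": gene_class, "marker_type": marker_type}
    )
    return m, truth


def setting_grid(base: SimConfig | None = None) -> list[SimConfig]:
    """The 96-setting benchmark grid (4 x 4 x 2 x 3 Cartesian product)."""
    base = base or SimConfig()
    grid = []
    for spg, cps, p_de, lfc in itertools.product(
        (2, 3, 5, 8), (25, 50, 100, 200), (0.05, 0.1), (0.5, 1.0, 2.0)
    ):
        grid.append(
            replace(
                base,
                samples_per_group=spg,
                cells_per_sample=cps,
                p_de=p_de,
                lfc=lfc,
            )
        )
    return grid
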