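"""Trajectory-informative ("TRAINing") gene selection.

A trajectory branch is summarised per gene by the sample covariance between
the gene's expression and pseudotime; genes whose expression barely tracks
pseudotime carry no trajectory information and are filtered out by rank
before any ligand scoring. Pearson correlation is available as an
alternative, scale-free metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import TrajectoryBranch

METRICS = ("covariance", "correlation")


@dataclass
class CovarianceVector:
    """Per-gene association with pseudotime on one branch."""

    values: np.ndarray
    gene_ids: list
    branch: str
    metric: str = "covariance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.gene_ids):
            raise ValidationError("values must align 1:1 with gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("covariance vector contains non-finite values")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")


@dataclass
class TrainingGeneSet:
    """Outcome of the rank filter: retained and dropped gene ids."""

    retained: list
    dropped: list
    drop_fraction: float

    def __post_init__(self):
        if set(self.retained) & set(self.dropped):
            raise ValidationError("retained and dropped gene sets overlap")


def branch_covariance(branch: TrajectoryBranch,
                      metric: str = "covariance") -> CovarianceVector:
    """Compute per-gene covariance (or Pearson correlation) between
    expression and pseudotime on one branch.

    Covariance uses the unbiased n-1 denominator. In the correlation
    variant, genes with zero variance are assigned 0 (they cannot order
    cells along the trajectory).
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got '{metric}'")
    tau = branch.tau
    n = branch.n_cells
    if n < 3:
        raise ValidationError("covariance requires at least 3 cells")
    tau_c = tau - tau.mean()
    if np.all(tau_c == 0):
        raise ValidationError(
            f"pseudotime is constant on branch '{branch.label}'; it carries "
            "no ordering information")
    x_c = branch.matrix - branch.matrix.mean(axis=0, keepdims=True)
    cov = x_c.T @ tau_c / (n - 1)
    if metric == "correlation":
        sd_x = np.sqrt((x_c ** 2).sum(axis=0) / (n - 1))
        sd_t = math.sqrt(float(tau_c @ tau_c) / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(sd_x > 0, cov / (sd_x * sd_t), 0.0)
    else:
        vals = cov
    return CovarianceVector(vals, list(branch.gene_ids), branch.label, metric)


def select_training_genes(cov: CovarianceVector,
                          drop_fraction: float = 0.05,
                          signed: bool = False) -> TrainingGeneSet:
    """Drop the floor(drop_fraction * n_genes) genes least associated with
    pseudotime; the rest are the TRAINing genes.

    Ranking uses |value| by default so that strongly negatively covarying
    genes — equally informative about the trajectory — are kept; pass
    ``signed=True`` to rank by the raw signed value instead. Ties at the
    cut are broken lexicographically by gene id (smaller id dropped first),
    making the selection deterministic.
    """
    if not 0 <= drop_fraction < 1:
        raise ValidationError(
            f"drop_fraction must lie in [0, 1), got {drop_fraction}")
    n = len(cov.gene_ids)
    if n == 0:
        raise ValidationError("empty covariance vector")
    n_drop = math.floor(drop_fraction * n)
    key = cov.values if signed else np.abs(cov.values)
    order = sorted(range(n), key=lambda i: (key[i], cov.gene_ids[i]))
    dropped = sorted(cov.gene_ids[i] for i in order[:n_drop])
    keep = {cov.gene_ids[i] for i in order[n_drop:]}
    retained = [g for g in cov.gene_ids if g in keep]
    return TrainingGeneSet(retained, dropped, drop_fraction)
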