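"""Core in-memory containers shared by every analysis mode.

Conventions
-----------
* Expression-like matrices are always cells (or spots) x genes in memory,
  whatever their on-disk orientation.
* Identifiers are plain strings, matched case-sensitively everywhere.
* Containers validate their structural invariants at construction time and
  raise :class:`~entrain.errors.ValidationError` on violation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("entrain")


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    return arr


def _check_unique(ids: Sequence[str], what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression matrix with identifiers.

    Parameters
    ----------
    values
        Non-negative matrix, one row per cell, one column per gene. Raw
        counts and normalized expression are both accepted; the choice is
        up to the caller and is logged, not enforced.
    cell_ids, gene_ids
        Unique string identifiers aligned to rows / columns.
    cell_types
        Optional per-cell type label (senders vs receivers etc.).
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    cell_types: Optional[list] = None

    def __post_init__(self):
        self.values = _as_float_matrix(self.values, "expression")
        if np.any(self.values < 0):
            raise ValidationError("expression matrix contains negative entries")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite entries")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if self.cell_types is not None and len(self.cell_types) != n:
            raise ValidationError("cell_types length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.cell_index()
        missing = [c for c in cell_ids if c not in idx]
        if missing:
            raise ValidationError(f"unknown cell id(s): {missing[:5]}")
        rows = [idx[c] for c in cell_ids]
        types = None
        if self.cell_types is not None:
            types = [self.cell_types[i] for i in rows]
        return ExpressionMatrix(self.values[rows], list(cell_ids),
                                list(self.gene_ids), types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids,
                            columns=self.gene_ids)


@dataclass
class TrajectoryAnnotation:
    """Per-cell pseudotime and branch labels for cells on a trajectory.

    Cells not on any branch (e.g. niche/sender cells) are simply absent.
    """

    cell_ids: list
    pseudotime: np.ndarray
    branch: list
    root_cell: Optional[str] = None

    def __post_init__(self):
        self.cell_ids = _check_unique(self.cell_ids, "annotated cell ids")
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.pseudotime.ndim != 1 or len(self.pseudotime) != len(self.cell_ids):
            raise ValidationError("pseudotime must align 1:1 with cell ids")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValidationError("pseudotime contains non-finite values")
        if np.any(self.pseudotime < 0):
            raise ValidationError("pseudotime must be >= 0")
        self.branch = [str(b) for b in self.branch]
        if len(self.branch) != len(self.cell_ids):
            raise ValidationError("branch labels must align 1:1 with cell ids")

    def branches(self) -> list:
        return sorted(set(self.branch))

    def cells_on_branch(self, label: str) -> list:
        return [c for c, b in zip(self.cell_ids, self.branch) if b == label]


@dataclass
class TrajectoryBranch:
    """Expression submatrix for one branch, rows ordered as given, with
    pseudotime aligned to rows. Needs at least 3 cells: covariance needs two
    and a floor of three keeps degenerate fits out."""

    matrix: np.ndarray
    tau: np.ndarray
    cell_ids: list
    gene_ids: list
    label: str = "branch"

    def __post_init__(self):
        self.matrix = _as_float_matrix(self.matrix, "branch matrix")
        self.tau = np.asarray(self.tau, dtype=float)
        if self.matrix.shape[0] != len(self.tau):
            raise ValidationError("tau must align with branch matrix rows")
        if self.matrix.shape[0] < 3:
            raise ValidationError(
                f"branch '{self.label}' has {self.matrix.shape[0]} cells; "
                "at least 3 are required")
        if not np.all(np.isfinite(self.tau)):
            raise ValidationError("tau contains non-finite values")
        self.cell_ids = _check_unique(self.cell_ids, "branch cell ids")
        if len(self.cell_ids) != self.matrix.shape[0]:
            raise ValidationError("cell ids must align with branch matrix rows")
        if len(self.gene_ids) != self.matrix.shape[1]:
            raise ValidationError("gene ids must align with branch matrix columns")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def subset_cells(self, row_indices) -> "TrajectoryBranch":
        rows = np.asarray(row_indices, dtype=int)
        return TrajectoryBranch(self.matrix[rows], self.tau[rows],
                                [self.cell_ids[i] for i in rows],
                                list(self.gene_ids), self.label)


def make_branch(expr: ExpressionMatrix, ann: TrajectoryAnnotation,
                label: str) -> TrajectoryBranch:
    """Assemble a :class:`TrajectoryBranch` for one branch label."""
    cells = ann.cells_on_branch(label)
    if not cells:
        raise ValidationError(f"no cells annotated with branch '{label}'")
    sub = expr.subset_cells(cells)
    tau_by_cell = dict(zip(ann.cell_ids, ann.pseudotime))
    tau = np.array([tau_by_cell[c] for c in cells])
    return TrajectoryBranch(sub.values, tau, cells, list(expr.gene_ids), label)


@dataclass
class LigandTargetPrior:
    """Target genes x ligands matrix of regulatory-potential edge weights.

    Each entry w quantifies prior evidence that the ligand regulates the
    target gene. Weights are non-negative; all-zero ligand columns carry no
    information and are dropped with a logged warning at construction.
    """

    weights: np.ndarray
    target_gene_ids: list = field(default_factory=list)
    ligand_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = _as_float_matrix(self.weights, "prior weights")
        if np.any(self.weights < 0):
            bad = np.argwhere(self.weights < 0)[0]
            raise ValidationError(
                "regulatory-potential weights must be non-negative; found "
                f"{self.weights[tuple(bad)]} at row {bad[0]}, column {bad[1]}")
        self.target_gene_ids = _check_unique(self.target_gene_ids, "target gene ids")
        self.ligand_ids = _check_unique(self.ligand_ids, "ligand ids")
        g, l = self.weights.shape
        if len(self.target_gene_ids) != g:
            raise ValidationError("target gene ids must align with prior rows")
        if len(self.ligand_ids) != l:
            raise ValidationError("ligand ids must align with prior columns")
        keep = self.weights.sum(axis=0) > 0
        if not np.all(keep):
            dropped = [lig for lig, k in zip(self.ligand_ids, keep) if not k]
            logger.warning("dropping %d all-zero ligand column(s): %s",
                           len(dropped), dropped[:5])
            warnings.warn(f"dropping {len(dropped)} all-zero ligand column(s)",
                          stacklevel=2)
            self.weights = self.weights[:, keep]
            self.ligand_ids = [lig for lig, k in zip(self.ligand_ids, keep) if k]

    @property
    def n_targets(self) -> int:
        return self.weights.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.target_gene_ids,
                            columns=self.ligand_ids)


@dataclass
class LigandReceptorNetwork:
    """Set of known (ligand gene, receptor gene) pairs."""

    pairs: list

    def __post_init__(self):
        seen = set()
        cleaned = []
        for pair in self.pairs:
            lig, rec = pair
            lig, rec = str(lig), str(rec)
            if not lig or not rec:
                raise ValidationError("ligand and receptor ids must be non-empty")
            if (lig, rec) in seen:
                continue
            seen.add((lig, rec))
            cleaned.append((lig, rec))
        if len(cleaned) < len(self.pairs):
            logger.warning("removed %d duplicate ligand-receptor pair(s)",
                           len(self.pairs) - len(cleaned))
        self.pairs = cleaned

    def ligands(self) -> list:
        return sorted({l for l, _ in self.pairs})

    def receptors_for(self, ligand: str) -> list:
        return sorted({r for l, r in self.pairs if l == ligand})


@dataclass
class SpotGrid:
    """Visium spots on the hexagonal array with their expression.

    Array coordinates follow the 10x convention: columns alternate parity by
    row, so (array_row + array_col) is even for every real spot and each spot
    has up to six equidistant neighbours.
    """

    spot_ids: list
    array_row: np.ndarray
    array_col: np.ndarray
    expression: np.ndarray
    gene_ids: list
    labels: Optional[list] = None

    def __post_init__(self):
        self.spot_ids = _check_unique(self.spot_ids, "spot ids")
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        n = len(self.spot_ids)
        if len(self.array_row) != n or len(self.array_col) != n:
            raise ValidationError("array coordinates must align with spot ids")
        if np.any((self.array_row + self.array_col) % 2 != 0):
            bad = int(np.argmax((self.array_row + self.array_col) % 2 != 0))
            raise ValidationError(
                f"spot '{self.spot_ids[bad]}' violates Visium parity: "
                f"row+col must be even, got ({self.array_row[bad]}, "
                f"{self.array_col[bad]})")
        coords = list(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(set(coords)) != n:
            raise ValidationError("duplicate (array_row, array_col) pairs")
        self.expression = _as_float_matrix(self.expression, "spot expression")
        if np.any(self.expression < 0):
            raise ValidationError("spot expression contains negative entries")
        if self.expression.shape[0] != n:
            raise ValidationError("spot expression rows must align with spot ids")
        if self.expression.shape[1] != len(self.gene_ids):
            raise ValidationError("spot expression columns must align with gene ids")
        if self.labels is not None and len(self.labels) != n:
            raise ValidationError("labels must align with spot ids")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def coord_index(self) -> dict:
        return {(int(r), int(c)): i for i, (r, c) in
                enumerate(zip(self.array_row, self.array_col))}

    def spot_index(self) -> dict:
        return {s: i for i, s in enumerate(self.spot_ids)}

    def subset(self, spot_indices) -> "SpotGrid":
        rows = np.asarray(spot_indices, dtype=int)
        labels = None
        if self.labels is not None:
            labels = [self.labels[i] for i in rows]
        return SpotGrid([self.spot_ids[i] for i in rows],
                        self.array_row[rows], self.array_col[rows],
                        self.expression[rows], list(self.gene_ids), labels)


@dataclass
class VelocityMatrix:
    """Cells x genes matrix of RNA-velocity estimates (entries may be
    negative: a velocity is a time derivative of expression)."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = _as_float_matrix(self.values, "velocity matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("velocity matrix contains non-finite entries")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValidationError("cell ids must align with velocity rows")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValidationError("gene ids must align with velocity columns")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class VelocityClusterLikelihoods:
    """Per-gene dynamical-model fit likelihoods for one velocity cluster.

    Likelihoods live in [0, 1] and usually cover only a subset of genes,
    because not every gene has a confident velocity fit.
    """

    cluster: str
    gene_ids: list
    likelihoods: np.ndarray

    def __post_init__(self):
        self.cluster = str(self.cluster)
        self.gene_ids = _check_unique(self.gene_ids, "likelihood gene ids")
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.ndim != 1 or len(self.likelihoods) != len(self.gene_ids):
            raise ValidationError("likelihoods must align 1:1 with gene ids")
        if not np.all(np.isfinite(self.likelihoods)):
            raise ValidationError("likelihoods contain non-finite values")
        if np.any(self.likelihoods < 0) or np.any(self.likelihoods > 1):
            raise ValidationError("likelihoods must lie in [0, 1]")
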