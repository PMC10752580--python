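"""Readers and writers for the plain-text exchange formats.

Supported formats
-----------------
expression / velocity
    Matrix Market ``.mtx`` with sidecar ``barcodes.tsv`` / ``features.tsv``
    (genes as MTX rows, cells as columns — the 10x convention), or a dense
    CSV with cells as rows, a header row of gene ids and the first column
    holding cell ids. In memory everything is cells x genes.
metadata
    TSV with a ``cell`` column plus any of ``cell_type``, ``pseudotime``,
    ``branch``, ``velocity_cluster``.
ligand-target prior
    CSV, rows = target genes, columns = ligands, non-negative body.
ligand-receptor network
    CSV with ``ligand`` and ``receptor`` columns.
spot table
    CSV with ``spot``, ``array_row``, ``array_col`` columns; expression for
    spots uses the same matrix dialects as cells.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, MissingColumnError, ValidationError
from .types import (ExpressionMatrix, LigandReceptorNetwork, LigandTargetPrior,
                    SpotGrid, TrajectoryAnnotation, VelocityClusterLikelihoods,
                    VelocityMatrix)

logger = logging.getLogger("entrain")

METADATA_COLUMNS = ("cell", "cell_type", "pseudotime", "branch", "velocity_cluster")


def _dedupe_gene_ids(ids: Sequence[str]) -> list:
    """Disambiguate duplicate gene symbols by suffixing .1, .2, ..."""
    seen: dict = {}
    out = []
    for g in ids:
        g = str(g)
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def _read_id_file(path: str) -> list:
    with open(path) as fh:
        # features.tsv may carry extra columns (id, symbol, type); keep col 0
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression(path: str, barcodes: Optional[str] = None,
                    features: Optional[str] = None,
                    allow_negative: bool = False):
    """Read an expression (or velocity) matrix into cells x genes form.

    ``path`` is either a dense CSV, an ``.mtx`` file (with ``barcodes`` and
    ``features`` sidecars), or a directory containing ``matrix.mtx``,
    ``barcodes.tsv`` and ``features.tsv``.
    """
    if os.path.isdir(path):
        return read_expression(os.path.join(path, "matrix.mtx"),
                               os.path.join(path, "barcodes.tsv"),
                               os.path.join(path, "features.tsv"),
                               allow_negative=allow_negative)
    if path.endswith(".mtx"):
        if barcodes is None or features is None:
            raise FormatError("MTX input requires barcodes and features files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        gene_ids = _dedupe_gene_ids(_read_id_file(features))
        cell_ids = _read_id_file(barcodes)
        # 10x orientation: genes are MTX rows, cells are columns
        if mat.shape != (len(gene_ids), len(cell_ids)):
            offender = features if mat.shape[0] != len(gene_ids) else barcodes
            raise FormatError(
                f"matrix {path} has shape {mat.shape} (genes x cells) but "
                f"identifier file {offender} lists "
                f"{len(gene_ids)} genes / {len(cell_ids)} cells")
        values = mat.T
    else:
        try:
            df = pd.read_csv(path, index_col=0,
                             float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"could not parse {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has no gene columns")
        values = df.to_numpy(dtype=float)
        cell_ids = [str(c) for c in df.index]
        gene_ids = _dedupe_gene_ids(df.columns)
    if allow_negative:
        return VelocityMatrix(values, cell_ids, gene_ids)
    return ExpressionMatrix(values, cell_ids, gene_ids)


def read_velocity(path: str, barcodes: Optional[str] = None,
                  features: Optional[str] = None) -> VelocityMatrix:
    return read_expression(path, barcodes, features, allow_negative=True)


def write_expression_csv(expr, path: str) -> None:
    # %.17g keeps float64 round-trips lossless
    pd.DataFrame(expr.values, index=expr.cell_ids,
                 columns=expr.gene_ids).to_csv(path, float_format="%.17g")


def write_expression_mtx(expr, directory: str) -> None:
    """Write the 10x trio (genes x cells on disk)."""
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"),
                     scipy.sparse.csr_matrix(expr.values.T), precision=17)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(expr.cell_ids) + "\n")
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        fh.write("\n".join(expr.gene_ids) + "\n")


def read_prior(path: str) -> LigandTargetPrior:
    """Read a genes x ligands regulatory-potential matrix from CSV."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValidationError(f"duplicate ligand column(s) in {path}: {dupes}")
    try:
        df = pd.read_csv(path, index_col=0,
                             float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path} has no ligand columns")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise FormatError(f"{path} has a non-numeric body")
    if df.columns.duplicated().any():
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValidationError(f"duplicate ligand column(s) in {path}: {dupes}")
    return LigandTargetPrior(df.to_numpy(dtype=float),
                             [str(g) for g in df.index],
                             [str(c) for c in df.columns])


def write_prior(prior: LigandTargetPrior, path: str) -> None:
    prior.to_frame().to_csv(path, float_format="%.17g")


@dataclass
class CellMetadata:
    """Parsed per-cell metadata table, keyed by cell id."""

    frame: pd.DataFrame

    def annotation(self) -> TrajectoryAnnotation:
        df = self.frame.dropna(subset=["pseudotime", "branch"])
        return TrajectoryAnnotation(list(df.index),
                                    df["pseudotime"].to_numpy(dtype=float),
                                    list(df["branch"]))

    def cell_types(self) -> dict:
        if "cell_type" not in self.frame.columns:
            return {}
        return {c: t for c, t in self.frame["cell_type"].items() if pd.notna(t)}

    def velocity_clusters(self) -> dict:
        if "velocity_cluster" not in self.frame.columns:
            return {}
        return {c: v for c, v in self.frame["velocity_cluster"].items()
                if pd.notna(v)}


def read_metadata(path: str, expr=None,
                  required: Sequence[str] = ("cell",)) -> CellMetadata:
    """Read the per-cell metadata TSV and validate against an expression
    matrix when given."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path} is missing required column(s) {missing}; this mode "
            f"requires {sorted(set(required))} (recognised columns: "
            f"{', '.join(METADATA_COLUMNS)})")
    if "cell" not in df.columns:
        raise MissingColumnError(f"{path} is missing the 'cell' column")
    df["cell"] = df["cell"].astype(str)
    if df["cell"].duplicated().any():
        raise ValidationError(f"duplicate cell ids in {path}")
    if "pseudotime" in df.columns:
        # NaN marks cells off the trajectory; any stated value must be finite
        tau = pd.to_numeric(df["pseudotime"], errors="coerce")
        bad = df["pseudotime"].notna() & (tau.isna() | np.isinf(tau))
        if bad.any():
            cell = df.loc[bad, "cell"].iloc[0]
            raise ValidationError(
                f"non-finite pseudotime for cell '{cell}' in {path}")
        df["pseudotime"] = tau
    if expr is not None:
        known = set(expr.cell_ids)
        unknown = [c for c in df["cell"] if c not in known]
        if unknown:
            raise ValidationError(
                f"metadata references cell id(s) absent from the expression "
                f"matrix: {unknown[:5]}")
    return CellMetadata(df.set_index("cell"))


def read_lr_network(path: str) -> LigandReceptorNetwork:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path} is missing the '{col}' column")
    return LigandReceptorNetwork(list(zip(df["ligand"].astype(str),
                                          df["receptor"].astype(str))))


def write_lr_network(network: LigandReceptorNetwork, path: str) -> None:
    pd.DataFrame(network.pairs, columns=["ligand", "receptor"]).to_csv(
        path, index=False)


def read_likelihoods(path: str) -> list:
    """Read per-cluster fit-likelihood tables from a long-format CSV with
    columns cluster, gene, likelihood."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    for col in ("cluster", "gene", "likelihood"):
        if col not in df.columns:
            raise FormatError(f"{path} is missing the '{col}' column")
    out = []
    for cluster, grp in df.groupby("cluster", sort=True):
        out.append(VelocityClusterLikelihoods(
            str(cluster), [str(g) for g in grp["gene"]],
            grp["likelihood"].to_numpy(dtype=float)))
    return out


def write_likelihoods(tables: Sequence[VelocityClusterLikelihoods],
                      path: str) -> None:
    rows = []
    for tab in tables:
        for g, l in zip(tab.gene_ids, tab.likelihoods):
            rows.append((tab.cluster, g, l))
    pd.DataFrame(rows, columns=["cluster", "gene", "likelihood"]).to_csv(
        path, index=False)


def read_spot_grid(spot_table: str, matrix_path: str,
                   labels_path: Optional[str] = None) -> SpotGrid:
    """Assemble a SpotGrid from a spot coordinate table plus a spots x genes
    matrix (CSV dialect, spot ids as row index)."""
    try:
        spots = pd.read_csv(spot_table)
    except Exception as exc:
        raise FormatError(f"could not parse {spot_table}: {exc}") from exc
    for col in ("spot", "array_row", "array_col"):
        if col not in spots.columns:
            raise FormatError(f"{spot_table} is missing the '{col}' column")
    expr = read_expression(matrix_path)
    sub = expr.subset_cells([str(s) for s in spots["spot"]])
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        for col in ("spot", "velocity_cluster"):
            if col not in lab.columns:
                raise FormatError(f"{labels_path} is missing '{col}'")
        by_spot = dict(zip(lab["spot"].astype(str),
                           lab["velocity_cluster"].astype(str)))
        try:
            labels = [by_spot[s] for s in sub.cell_ids]
        except KeyError as exc:
            raise ValidationError(f"no label for spot {exc}") from exc
    return SpotGrid(sub.cell_ids, spots["array_row"].to_numpy(int),
                    spots["array_col"].to_numpy(int), sub.values,
                    sub.gene_ids, labels)


def write_spot_grid(grid: SpotGrid, spot_table: str, matrix_path: str,
                    labels_path: Optional[str] = None) -> None:
    pd.DataFrame({"spot": grid.spot_ids, "array_row": grid.array_row,
                  "array_col": grid.array_col}).to_csv(spot_table, index=False)
    pd.DataFrame(grid.expression, index=grid.spot_ids,
                 columns=grid.gene_ids).to_csv(matrix_path,
                                               float_format="%.17g")
    if labels_path is not None and grid.labels is not None:
        pd.DataFrame({"spot": grid.spot_ids,
                      "velocity_cluster": grid.labels}).to_csv(
            labels_path, index=False)
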