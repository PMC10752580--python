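"""Spatial mode: Visium hex adjacency, label transfer and spatially
restricted ligand scoring.

Visium spots sit on a hexagonal lattice encoded by integer array
coordinates in which column parity alternates by row; a spot's six
equidistant neighbours are at offsets (0, +/-2), (-1, +/-1), (+1, +/-1).
Secreted and contact ligands act locally, so a candidate ligand is only
credible for a velocity cluster if it is expressed within the seven-spot
neighbourhood (six neighbours plus the spot itself) of some reference spot
carrying that cluster's label. Ligands passing this filter are scored
exactly as in velocity mode.

Velocity-cluster labels reach the spots either from an external mapping
tool's output file, or through the light-weight centroid-correlation
transfer implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .ligand_scoring import LigandModel, build_design, fit_ligand_model
from .types import (ExpressionMatrix, LigandReceptorNetwork,
                    LigandTargetPrior, SpotGrid, VelocityClusterLikelihoods)
from .training_genes import TrainingGeneSet

logger = logging.getLogger("entrain")

# six hex neighbours in 10x array coordinates
HEX_OFFSETS = ((0, 2), (0, -2), (-1, 1), (-1, -1), (1, 1), (1, -1))
MIN_SHARED_GENES = 50


@dataclass
class SpotNeighborhood:
    """A reference spot plus its existing hex neighbours (size 1..7)."""

    reference: str
    members: list

    def __post_init__(self):
        if self.reference not in self.members:
            raise ValidationError("reference spot must be a member")
        if len(set(self.members)) != len(self.members):
            raise ValidationError("duplicate members in neighbourhood")
        if not 1 <= len(self.members) <= 7:
            raise ValidationError(
                f"neighbourhood size {len(self.members)} outside [1, 7]")

    def __len__(self):
        return len(self.members)


def hex_neighbors(grid: SpotGrid, spot_id: str) -> SpotNeighborhood:
    """The seven-spot neighbourhood of ``spot_id``: itself plus any of the
    six hex-adjacent array positions present in the grid."""
    sidx = grid.spot_index()
    if spot_id not in sidx:
        raise ValidationError(f"unknown spot id '{spot_id}'")
    i = sidx[spot_id]
    r, c = int(grid.array_row[i]), int(grid.array_col[i])
    coords = grid.coord_index()
    members = [spot_id]
    for dr, dc in HEX_OFFSETS:
        j = coords.get((r + dr, c + dc))
        if j is not None:
            members.append(grid.spot_ids[j])
    return SpotNeighborhood(spot_id, members)


def transfer_labels(sc_expr: ExpressionMatrix,
                    sc_labels: Sequence,
                    grid: SpotGrid,
                    n_top_genes: int = 500) -> list:
    """Assign each spot the velocity-cluster label of the most correlated
    single-cell cluster centroid.

    Centroids are means over cells of each cluster, restricted to the
    ``n_top_genes`` most variable genes shared between the single-cell and
    spot matrices. Ties go to the smaller cluster label. This is
    deliberately simple plumbing; labels from a dedicated mapping tool can
    be supplied instead wherever a labelled grid is accepted.
    """
    sc_labels = list(sc_labels)
    if len(sc_labels) != sc_expr.n_cells:
        raise ValidationError("sc_labels must align 1:1 with cells")
    shared = sorted(set(sc_expr.gene_ids) & set(grid.gene_ids))
    if len(shared) < MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} genes shared between single-cell and spot "
            f"matrices; at least {MIN_SHARED_GENES} are required")
    sc_gidx = sc_expr.gene_index()
    sc_cols = np.array([sc_gidx[g] for g in shared])
    sc_sub = sc_expr.values[:, sc_cols]
    variances = sc_sub.var(axis=0)
    top = np.sort(np.argsort(-variances, kind="stable")[:n_top_genes])
    genes = [shared[i] for i in top]
    sp_gidx = grid.gene_index() if hasattr(grid, "gene_index") else \
        {g: j for j, g in enumerate(grid.gene_ids)}
    sp = grid.expression[:, [sp_gidx[g] for g in genes]]
    sc_top = sc_sub[:, top]
    clusters = sorted({l for l in sc_labels if l != -1 and l != "-1"},
                      key=lambda l: str(l))
    if not clusters:
        raise ValidationError("no assigned cluster labels among cells")
    centroids = np.stack([
        sc_top[np.array([lab == cl for lab in sc_labels])].mean(axis=0)
        for cl in clusters])

    def _corr(a, b_rows):
        a = a - a.mean()
        na = np.linalg.norm(a)
        out = np.full(len(b_rows), -np.inf)
        if na == 0:
            return out
        for k, b in enumerate(b_rows):
            b = b - b.mean()
            nb = np.linalg.norm(b)
            if nb > 0:
                out[k] = float(a @ b) / (na * nb)
        return out

    labels = []
    for s in range(grid.n_spots):
        corr = _corr(sp[s], centroids)
        # argmax returns the first (smallest) label on exact ties
        labels.append(clusters[int(np.argmax(corr))])
    return labels


def spatially_filter_ligands(grid: SpotGrid,
                             labels: Sequence,
                             cluster,
                             network: LigandReceptorNetwork,
                             all_spots: bool = False):
    """Restrict candidate ligands to those expressed near the cluster.

    Reference spots are the spots whose label equals ``cluster``; the
    analysis subgrid is the union of their seven-spot neighbourhoods. A
    network ligand is a candidate when it is detected (value > 0) in at
    least one spot of that subgrid — or, with ``all_spots=True``, in every
    spot of at least one complete neighbourhood.

    Returns ``(candidates, subgrid, n_spots_detected)`` where
    ``n_spots_detected`` maps each candidate to its number of detected
    subgrid spots.
    """
    labels = [str(l) for l in labels]
    if len(labels) != grid.n_spots:
        raise ValidationError("labels must align 1:1 with spots")
    cluster = str(cluster)
    refs = [grid.spot_ids[i] for i, l in enumerate(labels) if l == cluster]
    if not refs:
        raise ValidationError(f"no spot carries the cluster label '{cluster}'")
    neighborhoods = [hex_neighbors(grid, r) for r in refs]
    member_ids = sorted({m for nb in neighborhoods for m in nb.members})
    sidx = grid.spot_index()
    sub_rows = [sidx[m] for m in member_ids]
    subgrid = grid.subset(sub_rows)
    gidx = {g: j for j, g in enumerate(grid.gene_ids)}
    candidates, n_detected = [], {}
    for lig in network.ligands():
        if lig not in gidx:
            continue
        col = grid.expression[:, gidx[lig]]
        if all_spots:
            ok = any(all(col[sidx[m]] > 0 for m in nb.members)
                     for nb in neighborhoods)
        else:
            ok = any(col[i] > 0 for i in sub_rows)
        if ok:
            candidates.append(lig)
            n_detected[lig] = int(sum(col[i] > 0 for i in sub_rows))
    if not candidates:
        warnings.warn("no candidate ligands near the cluster; scoring will "
                      "refuse an empty candidate set", stacklevel=2)
    logger.info("spatial filter for cluster %s: %d reference spots, "
                "%d subgrid spots, %d candidate ligands",
                cluster, len(refs), len(member_ids), len(candidates))
    return candidates, subgrid, n_detected


def score_spatial_cluster(candidates: Sequence[str],
                          lik: VelocityClusterLikelihoods,
                          prior: LigandTargetPrior,
                          n_trees: int = 500,
                          mtry: Optional[int] = None,
                          seed: int = 0) -> LigandModel:
    """Score spatially filtered candidate ligands against a cluster's
    likelihood vector; identical machinery to velocity mode with the design
    columns restricted to the candidates."""
    if not candidates:
        raise ValidationError(
            "no candidate ligands survived the spatial filter; widen the "
            "neighbourhood (check labels) or supply candidates explicitly")
    training = TrainingGeneSet(list(lik.gene_ids), [], 0.0)
    design = build_design(prior, training, list(candidates), lik)
    return fit_ligand_model(design, n_trees=n_trees, mtry=mtry, seed=seed)
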