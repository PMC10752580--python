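"""Velocity-mode analysis: cluster velocity vectors, score ligands against
per-cluster fit likelihoods.

RNA velocity assigns each cell a vector of expression time-derivatives.
Cells sharing a dynamic regime point in similar directions, so Leiden
community detection on a kNN graph of (L2-normalised) velocity vectors
partitions the population into its major dynamic groups. The per-gene fit
likelihoods of a cluster then play the role the pseudotime covariance plays
in trajectory mode: the regulatory-potential prior is regressed onto them
to score candidate driver ligands.

The dynamical-model fit itself (likelihood estimation from spliced/unspliced
counts) is upstream of this package; likelihood tables are inputs.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Union

import igraph as ig
import leidenalg
import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError
from .ligand_scoring import (ActiveLigandSet, LigandModel, build_design,
                             fit_ligand_model)
from .training_genes import TrainingGeneSet
from .types import LigandTargetPrior, VelocityClusterLikelihoods, VelocityMatrix

logger = logging.getLogger("entrain")

UNASSIGNED = -1
DEFAULT_K_NEIGHBORS = 30
DEFAULT_RESOLUTION = 1.0


def cluster_velocities(vel: VelocityMatrix,
                       k_neighbors: int = DEFAULT_K_NEIGHBORS,
                       resolution: float = DEFAULT_RESOLUTION,
                       seed: int = 0,
                       n_pcs: Optional[int] = None) -> np.ndarray:
    """Leiden clustering of velocity vectors.

    Vectors are L2-normalised (direction matters, magnitude does not), a
    cosine kNN graph is built, and Leiden community detection is run at the
    given resolution. Labels are consecutive integers ordered by descending
    cluster size; cells with an all-zero velocity vector have no direction
    and receive the reserved label ``-1`` with a warning.

    ``n_pcs`` optionally reduces the normalised vectors by PCA before the
    graph is built (useful for very wide matrices); default is gene space.
    """
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    norms = np.linalg.norm(vel.values, axis=1)
    valid = norms > 0
    n_valid = int(valid.sum())
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} cell(s) with all-zero velocity "
                      "assigned the reserved 'unassigned' label (-1)",
                      stacklevel=2)
    if n_valid < k_neighbors + 1:
        raise ValidationError(
            f"{n_valid} cells with nonzero velocity but k_neighbors="
            f"{k_neighbors} requires at least {k_neighbors + 1}")
    X = vel.values[valid] / norms[valid, None]
    if n_pcs is not None and 0 < n_pcs < X.shape[1]:
        X = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, n_valid),
                          metric="cosine").fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i, row in enumerate(idx):
        for j in row:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    graph = ig.Graph(n=n_valid, edges=sorted(edges))
    part = leidenalg.find_partition(graph,
                                    leidenalg.RBConfigurationVertexPartition,
                                    resolution_parameter=resolution, seed=seed)
    raw = np.asarray(part.membership)
    # relabel 0..k-1 by descending size (ties by original label)
    sizes = np.bincount(raw)
    order = sorted(range(len(sizes)), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.full(vel.n_cells, UNASSIGNED, dtype=int)
    labels[valid] = [remap[c] for c in raw]
    logger.info("velocity clustering: %d clusters over %d cells",
                len(sizes), n_valid)
    return labels


def score_velocity_cluster(lik: VelocityClusterLikelihoods,
                           prior: LigandTargetPrior,
                           active: Union[ActiveLigandSet, Sequence[str]],
                           n_trees: int = 500,
                           mtry: Optional[int] = None,
                           seed: int = 0) -> LigandModel:
    """Score ligands for one velocity cluster.

    Every gene with a computed likelihood is a TRAINing gene for this mode;
    the design is the prior restricted to those genes and the active
    ligands, and the response is the likelihood vector. The forest, its
    importance extraction and %E.V.E. are identical to trajectory mode.
    """
    training = TrainingGeneSet(list(lik.gene_ids), [], 0.0)
    design = build_design(prior, training, active, lik)
    return fit_ligand_model(design, n_trees=n_trees, mtry=mtry, seed=seed)
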