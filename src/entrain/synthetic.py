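"""Self-contained synthetic fixtures with planted ground truth.

Every analysis mode can be exercised end-to-end without external downloads:
the generators plant known driver ligands whose regulatory-potential
columns genuinely explain the trajectory (or velocity-likelihood) response,
surrounded by decoy ligands with sparse, uninformative prior columns.

The trajectory generator follows the operating premise of the method
itself: if a ligand drives differentiation, the expression of its prior
targets covaries with pseudotime. Driver-target expression is linear in
pseudotime (x = a * tau + noise) and the planted prior weight is
proportional to the effect size a, so the design column resembles the
covariance response exactly when the ligand is a true driver.

These fixtures are deliberately idealised: noise is Gaussian, effects are
linear, and there is no dropout or library-size variation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import ValidationError
from . import io as eio
from .types import (ExpressionMatrix, LigandReceptorNetwork, LigandTargetPrior,
                    SpotGrid, TrajectoryAnnotation, VelocityClusterLikelihoods,
                    VelocityMatrix)


@dataclass
class GroundTruth:
    """Sidecar describing what was planted, sufficient to score any ligand
    ranking for recall/precision without re-reading generator internals."""

    driver_ligands: list
    targets: dict  # ligand -> list of target gene ids
    effects: dict  # ligand -> {gene: effect size a}
    noise_sd: float
    branch: Optional[str] = None
    cluster_drivers: dict = field(default_factory=dict)  # cluster -> ligand
    sender_placement: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        for lig in self.driver_ligands:
            if lig not in self.targets:
                raise ValidationError(f"driver '{lig}' has no planted targets")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TrajectoryDataset:
    expression: ExpressionMatrix
    annotation: TrajectoryAnnotation
    prior: LigandTargetPrior
    network: LigandReceptorNetwork
    truth: GroundTruth


@dataclass
class VelocityDataset:
    velocity: VelocityMatrix
    cluster_labels: np.ndarray
    likelihoods: list  # one VelocityClusterLikelihoods per cluster
    prior: LigandTargetPrior
    expression: ExpressionMatrix
    network: LigandReceptorNetwork
    truth: GroundTruth


@dataclass
class VisiumDataset:
    grid: SpotGrid
    labels: list
    truth: GroundTruth


def _gene_names(n: int) -> list:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _decoy_prior_column(rng, n_genes: int, sparsity: float = 0.9,
                        max_weight: float = 0.05) -> np.ndarray:
    col = np.zeros(n_genes)
    nz = rng.random(n_genes) >= sparsity
    if not nz.any():  # keep at least one entry so the column is retained
        nz[rng.integers(n_genes)] = True
    col[nz] = rng.uniform(0.0, max_weight, nz.sum())
    return col


def simulate_trajectory_dataset(n_cells: int = 500,
                                n_genes: int = 300,
                                n_ligands: int = 15,
                                n_drivers: int = 3,
                                noise_sd: float = 0.3,
                                seed: int = 0,
                                targets_per_driver: int = 20,
                                sender_fraction: float = 0.25,
                                effect_window: Optional[tuple] = None,
                                ) -> TrajectoryDataset:
    """One branch of differentiating receiver cells plus niche sender cells.

    Pseudotime is uniform on [0, 1]. Each of the first ``n_drivers`` ligands
    gets a disjoint block of ``targets_per_driver`` target genes whose
    receiver expression is ``a * tau + N(0, noise_sd)`` (clipped at zero)
    with per-gene effect a ~ U[0.5, 1]; the prior carries weight a at those
    (target, ligand) entries. Decoy ligand columns are 90%-sparse draws from
    U[0, 0.05]. Sender cells express every ligand gene and receiver cells
    every receptor gene (in ~60% of cells each), so all ligands pass
    expression gating and the contrast is carried entirely by the prior and
    the response. ``effect_window=(t0, t1)`` restricts the driver effect to
    a pseudotime interval, for window-profile tests.
    """
    if n_drivers > n_ligands:
        raise ValidationError("n_drivers must not exceed n_ligands")
    if n_cells < 50:
        raise ValidationError("n_cells must be >= 50")
    if n_drivers * targets_per_driver > n_genes:
        raise ValidationError("too many driver targets for n_genes")
    rng = np.random.default_rng(seed)

    n_senders = math.ceil(sender_fraction * n_cells)
    receiver_ids = [f"RC{i:05d}" for i in range(1, n_cells + 1)]
    sender_ids = [f"SC{i:05d}" for i in range(1, n_senders + 1)]
    target_genes = _gene_names(n_genes)
    ligand_genes = [f"LG{i:02d}" for i in range(1, n_ligands + 1)]
    receptor_genes = [f"RG{i:02d}" for i in range(1, n_ligands + 1)]
    all_genes = target_genes + ligand_genes + receptor_genes

    tau = rng.uniform(0.0, 1.0, n_cells)
    drivers = ligand_genes[:n_drivers]

    # receiver target-gene expression
    recv = np.empty((n_cells, n_genes))
    baseline = rng.uniform(0.5, 1.5, n_genes)
    recv[:] = baseline[None, :]
    effects: dict = {}
    targets: dict = {}
    for d, lig in enumerate(drivers):
        block = target_genes[d * targets_per_driver:(d + 1) * targets_per_driver]
        a = rng.uniform(0.5, 1.0, targets_per_driver)
        targets[lig] = list(block)
        effects[lig] = {g: float(v) for g, v in zip(block, a)}
        cols = slice(d * targets_per_driver, (d + 1) * targets_per_driver)
        signal = np.outer(tau, a)
        if effect_window is not None:
            t0, t1 = effect_window
            signal = signal * ((tau >= t0) & (tau <= t1))[:, None]
        recv[:, cols] = signal
    recv += rng.normal(0.0, noise_sd, recv.shape)
    np.clip(recv, 0.0, None, out=recv)

    # sender target-gene expression: flat background noise
    send = np.abs(rng.normal(0.5, 0.25, (n_senders, n_genes)))

    # ligand / receptor gene expression: senders express ligands,
    # receivers express receptors, each detected in ~60% of cells
    def _detected_block(n_rows, n_cols_):
        mask = rng.random((n_rows, n_cols_)) < 0.6
        return mask * rng.uniform(1.0, 2.0, (n_rows, n_cols_))

    recv_lig = np.zeros((n_cells, n_ligands))
    recv_rec = _detected_block(n_cells, n_ligands)
    send_lig = _detected_block(n_senders, n_ligands)
    send_rec = np.zeros((n_senders, n_ligands))

    values = np.vstack([
        np.hstack([recv, recv_lig, recv_rec]),
        np.hstack([send, send_lig, send_rec]),
    ])
    cell_ids = receiver_ids + sender_ids
    cell_types = ["receiver"] * n_cells + ["sender"] * n_senders
    expr = ExpressionMatrix(values, cell_ids, all_genes, cell_types)
    ann = TrajectoryAnnotation(receiver_ids, tau, ["branch0"] * n_cells)

    # prior: target genes x ligands
    weights = np.zeros((n_genes, n_ligands))
    for d, lig in enumerate(drivers):
        for g in targets[lig]:
            weights[target_genes.index(g), d] = effects[lig][g]
    for j in range(n_drivers, n_ligands):
        weights[:, j] = _decoy_prior_column(rng, n_genes)
    prior = LigandTargetPrior(weights, list(target_genes), list(ligand_genes))

    network = LigandReceptorNetwork(list(zip(ligand_genes, receptor_genes)))
    truth = GroundTruth(drivers, targets, effects, noise_sd,
                        branch="branch0", seed=seed)
    return TrajectoryDataset(expr, ann, prior, network, truth)


def simulate_velocity_dataset(n_cells: int = 300,
                              n_genes: int = 200,
                              n_clusters: int = 2,
                              seed: int = 0,
                              n_ligands: int = 15,
                              velocity_noise_sd: float = 0.05,
                              likelihood_noise_sd: float = 0.05,
                              targets_per_driver: int = 20,
                              ) -> VelocityDataset:
    """Velocity vectors in well-separated directions plus per-cluster
    likelihood tables with one planted driver ligand per cluster.

    Cluster ``i`` points along coordinate axis ``e_i`` with isotropic
    Gaussian noise; its likelihood vector is the planted prior column of
    driver ``i`` rescaled to [0, 1] plus noise. The accompanying expression
    matrix gives each cluster's cells an elevated marker block (its driver's
    targets), supporting label transfer to spots.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    if n_clusters > n_ligands:
        raise ValidationError("need at least one ligand per cluster")
    if n_clusters * targets_per_driver > n_genes:
        raise ValidationError("too many driver targets for n_genes")
    rng = np.random.default_rng(seed)

    cell_ids = [f"VC{i:05d}" for i in range(1, n_cells + 1)]
    target_genes = _gene_names(n_genes)
    ligand_genes = [f"LG{i:02d}" for i in range(1, n_ligands + 1)]
    receptor_genes = [f"RG{i:02d}" for i in range(1, n_ligands + 1)]

    labels = rng.integers(0, n_clusters, n_cells)
    # guarantee every cluster is populated
    labels[:n_clusters] = np.arange(n_clusters)
    vel = rng.normal(0.0, velocity_noise_sd, (n_cells, n_genes))
    for i in range(n_clusters):
        vel[labels == i, i] += 1.0
    velocity = VelocityMatrix(vel, cell_ids, list(target_genes))

    drivers = ligand_genes[:n_clusters]
    weights = np.zeros((n_genes, n_ligands))
    targets: dict = {}
    effects: dict = {}
    for d, lig in enumerate(drivers):
        block = target_genes[d * targets_per_driver:(d + 1) * targets_per_driver]
        a = rng.uniform(0.5, 1.0, targets_per_driver)
        targets[lig] = list(block)
        effects[lig] = {g: float(v) for g, v in zip(block, a)}
        weights[d * targets_per_driver:(d + 1) * targets_per_driver, d] = a
    for j in range(n_clusters, n_ligands):
        weights[:, j] = _decoy_prior_column(rng, n_genes)
    prior = LigandTargetPrior(weights, list(target_genes), list(ligand_genes))

    likelihoods = []
    cluster_drivers = {}
    for i, lig in enumerate(drivers):
        col = weights[:, i]
        lik = col / col.max() + rng.normal(0.0, likelihood_noise_sd, n_genes)
        np.clip(lik, 0.0, 1.0, out=lik)
        likelihoods.append(VelocityClusterLikelihoods(str(i),
                                                      list(target_genes), lik))
        cluster_drivers[str(i)] = lig

    # expression: cluster marker blocks for label transfer
    expr_vals = np.abs(rng.normal(0.2, 0.1, (n_cells, n_genes)))
    for i, lig in enumerate(drivers):
        rows = labels == i
        cols = slice(i * targets_per_driver, (i + 1) * targets_per_driver)
        expr_vals[rows, cols] += 1.5
    expression = ExpressionMatrix(expr_vals, cell_ids, list(target_genes))

    network = LigandReceptorNetwork(list(zip(ligand_genes, receptor_genes)))
    truth = GroundTruth(drivers, targets, effects, velocity_noise_sd,
                        cluster_drivers=cluster_drivers, seed=seed)
    return VelocityDataset(velocity, labels, likelihoods, prior,
                           expression, network, truth)


def simulate_visium_grid(n_rows: int = 8,
                         n_cols: int = 10,
                         velocity_ds: Optional[VelocityDataset] = None,
                         placement: str = "adjacent",
                         seed: int = 0,
                         cluster_of_interest: int = 0,
                         ) -> VisiumDataset:
    """Full-parity Visium array with cluster-banded spots and a placed
    driver ligand.

    Spots are arranged in ``n_rows`` rows of ``n_cols`` spots using the 10x
    parity encoding (array_col = row parity + 2j). Vertical bands of the
    grid carry the velocity-cluster labels and spot expression mixes the
    matching cluster's single-cell profile with noise. The driver ligand of
    ``cluster_of_interest`` is expressed inside the labelled band
    (``placement='adjacent'``) or only in the far edge of the grid, outside
    every seven-spot neighbourhood of the labelled spots
    (``placement='distal'``). Decoy ligands are expressed everywhere so the
    spatial filter, not expression gating, decides the contrast.
    """
    if placement not in ("adjacent", "distal"):
        raise ValidationError("placement must be 'adjacent' or 'distal'")
    if velocity_ds is None:
        velocity_ds = simulate_velocity_dataset(seed=seed)
    rng = np.random.default_rng(seed)
    n_clusters = len(velocity_ds.likelihoods)
    if n_cols < 3 * n_clusters + 2:
        raise ValidationError("grid too narrow for distinct cluster bands")

    spot_ids, rows_, cols_, band = [], [], [], []
    band_width = n_cols // n_clusters
    for r in range(n_rows):
        for j in range(n_cols):
            spot_ids.append(f"SP{r:02d}_{j:02d}")
            rows_.append(r)
            cols_.append(r % 2 + 2 * j)
            band.append(min(j // band_width, n_clusters - 1))
    n_spots = len(spot_ids)
    labels = [str(b) for b in band]

    # spot expression = its band's single-cell centroid + noise
    target_genes = list(velocity_ds.expression.gene_ids)
    centroids = np.stack([
        velocity_ds.expression.values[velocity_ds.cluster_labels == i].mean(axis=0)
        for i in range(n_clusters)])
    expr_t = centroids[band] + np.abs(rng.normal(0.0, 0.05,
                                                 (n_spots, len(target_genes))))

    ligand_genes = [l for l, _ in velocity_ds.network.pairs]
    driver = velocity_ds.truth.cluster_drivers[str(cluster_of_interest)]
    expr_l = np.zeros((n_spots, len(ligand_genes)))
    for j, lig in enumerate(ligand_genes):
        if lig == driver:
            continue
        expr_l[:, j] = rng.uniform(0.1, 0.5, n_spots)  # decoys everywhere

    j_driver = ligand_genes.index(driver)
    ref_band = cluster_of_interest
    in_band = np.array([b == ref_band for b in band])
    if placement == "adjacent":
        expr_l[in_band, j_driver] = rng.uniform(1.0, 2.0, int(in_band.sum()))
    else:
        # far edge: columns beyond hex reach (one j-step) of any labelled band
        band_js = {j for j in range(n_cols)
                   if min(j // band_width, n_clusters - 1) == ref_band}
        reach = {j + d for j in band_js for d in (-1, 0, 1)}
        far_js = sorted(j for j in range(n_cols) if j not in reach)
        if not far_js:
            raise ValidationError("grid too small to place a distal ligand")
        far = np.array([(j in far_js[-2:]) for _ in range(n_rows)
                        for j in range(n_cols)])
        expr_l[far, j_driver] = rng.uniform(1.0, 2.0, int(far.sum()))

    grid = SpotGrid(spot_ids, np.array(rows_), np.array(cols_),
                    np.hstack([expr_t, expr_l]),
                    target_genes + ligand_genes, labels)
    truth = GroundTruth(list(velocity_ds.truth.driver_ligands),
                        dict(velocity_ds.truth.targets),
                        dict(velocity_ds.truth.effects),
                        velocity_ds.truth.noise_sd,
                        cluster_drivers=dict(velocity_ds.truth.cluster_drivers),
                        sender_placement=placement, seed=seed)
    return VisiumDataset(grid, labels, truth)


# ---------------------------------------------------------------------------
# directory writers (used by the `simulate` CLI subcommand and round-trip
# tests; every file goes through the io module's standard formats)

def write_trajectory_dataset(ds: TrajectoryDataset, outdir: str,
                             matrix_format: str = "csv") -> None:
    os.makedirs(outdir, exist_ok=True)
    if matrix_format == "mtx":
        eio.write_expression_mtx(ds.expression, outdir)
    else:
        eio.write_expression_csv(ds.expression, os.path.join(outdir, "expression.csv"))
    import pandas as pd
    tau = dict(zip(ds.annotation.cell_ids, ds.annotation.pseudotime))
    branch = dict(zip(ds.annotation.cell_ids, ds.annotation.branch))
    meta = pd.DataFrame({
        "cell": ds.expression.cell_ids,
        "cell_type": ds.expression.cell_types,
        "pseudotime": [tau.get(c, "") for c in ds.expression.cell_ids],
        "branch": [branch.get(c, "") for c in ds.expression.cell_ids],
    })
    meta.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    eio.write_prior(ds.prior, os.path.join(outdir, "prior.csv"))
    eio.write_lr_network(ds.network, os.path.join(outdir, "lr_network.csv"))
    ds.truth.to_json(os.path.join(outdir, "ground_truth.json"))


def write_velocity_dataset(ds: VelocityDataset, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    import pandas as pd
    pd.DataFrame(ds.velocity.values, index=ds.velocity.cell_ids,
                 columns=ds.velocity.gene_ids).to_csv(
        os.path.join(outdir, "velocity.csv"), float_format="%.17g")
    eio.write_expression_csv(ds.expression, os.path.join(outdir, "expression.csv"))
    pd.DataFrame({"cell": ds.velocity.cell_ids,
                  "velocity_cluster": ds.cluster_labels}).to_csv(
        os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    eio.write_likelihoods(ds.likelihoods, os.path.join(outdir, "likelihoods.csv"))
    eio.write_prior(ds.prior, os.path.join(outdir, "prior.csv"))
    eio.write_lr_network(ds.network, os.path.join(outdir, "lr_network.csv"))
    ds.truth.to_json(os.path.join(outdir, "ground_truth.json"))


def write_visium_dataset(ds: VisiumDataset, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    eio.write_spot_grid(ds.grid,
                        os.path.join(outdir, "spots.csv"),
                        os.path.join(outdir, "spot_expression.csv"),
                        os.path.join(outdir, "spot_labels.csv"))
    ds.truth.to_json(os.path.join(outdir, "ground_truth.json"))
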