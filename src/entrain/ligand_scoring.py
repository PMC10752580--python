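"""Ligand activity scoring by random-forest regression.

The central statistical step: the ligand->target regulatory-potential prior,
restricted to TRAINing genes and actively signalling ligands, is regressed
onto a per-gene trajectory statistic (pseudotime covariance or velocity fit
likelihood) with a regression forest. A ligand whose prior column resembles
the response earns splits in many trees; its importance is the total
residual-sum-of-squares reduction (increase in node purity) over all splits
on that ligand across the forest:

    RSS(node)  = sum_i (y_i - ybar_node)^2
    dRSS(split) = RSS(node) - RSS(left) - RSS(right)

Environmental dependence of the whole branch (or velocity cluster) is the
percentage of response variance the forest explains out-of-bag:

    %E.V.E. = 100 * (1 - MSE_oob / Var(y))

which may be negative when ligand signalling explains nothing. Significance
is assessed by refitting under response permutations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .errors import ValidationError
from .training_genes import CovarianceVector, TrainingGeneSet
from .types import ExpressionMatrix, LigandReceptorNetwork, LigandTargetPrior

logger = logging.getLogger("entrain")

MIN_DESIGN_GENES = 20
MIN_DESIGN_LIGANDS = 2
DEFAULT_N_TREES = 500
DEFAULT_MIN_EXPR_FRACTION = 0.10
MIN_SAMPLES_LEAF = 5


@dataclass
class ActiveLigandSet:
    """Ligands expressed by sender cells whose cognate receptor is expressed
    by the receiver (differentiating) population."""

    ligand_ids: list
    sender_fraction: dict = field(default_factory=dict)
    receptors: dict = field(default_factory=dict)  # ligand -> {receptor: frac}

    def __post_init__(self):
        self.ligand_ids = [str(l) for l in self.ligand_ids]
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValidationError("duplicate active ligand ids")
        for frac in self.sender_fraction.values():
            if not 0 <= frac <= 1:
                raise ValidationError("sender fractions must lie in [0, 1]")
        for recs in self.receptors.values():
            for frac in recs.values():
                if not 0 <= frac <= 1:
                    raise ValidationError("receiver fractions must lie in [0, 1]")

    def __len__(self):
        return len(self.ligand_ids)


@dataclass
class DesignMatrix:
    """TRAINing genes x active ligands slice of the prior, with the aligned
    response vector the forest is fit to."""

    matrix: np.ndarray
    gene_ids: list
    ligand_ids: list
    response: np.ndarray
    response_kind: str = "pseudotime-covariance"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.ligand_ids)):
            raise ValidationError("design shape does not match identifiers")
        if len(self.response) != len(self.gene_ids):
            raise ValidationError("response must align 1:1 with design rows")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LigandModel:
    """Fitted-forest summary: per-ligand importance and %E.V.E."""

    ligand_ids: list
    importance: np.ndarray
    eve_percent: float
    n_trees: int
    mtry: int
    seed: int
    response_kind: str
    oob_mse: float = float("nan")
    response_variance: float = float("nan")

    def ranking(self):
        """Ligands with importance, ranked by descending importance
        (ties broken by ligand id)."""
        import pandas as pd
        order = sorted(range(len(self.ligand_ids)),
                       key=lambda i: (-self.importance[i], self.ligand_ids[i]))
        df = pd.DataFrame({
            "ligand": [self.ligand_ids[i] for i in order],
            "importance": self.importance[order],
        })
        df["importance_rank"] = np.arange(1, len(df) + 1)
        df["eve_percent"] = self.eve_percent
        return df

    def top_ligands(self, k: int = 5) -> list:
        return list(self.ranking()["ligand"].head(k))


@dataclass
class PermutationNullResult:
    """Observed vs permutation-null importances and the empirical FDR."""

    ligand_ids: list
    observed: np.ndarray
    null_importances: np.ndarray  # n_perm x n_ligands
    fdr: np.ndarray

    def __post_init__(self):
        if np.any(self.fdr < 0) or np.any(self.fdr > 1):
            raise ValidationError("FDR values must lie in [0, 1]")


def detect_active_ligands(expr: ExpressionMatrix,
                          network: LigandReceptorNetwork,
                          sender_cells: Sequence[str],
                          receiver_cells: Sequence[str],
                          min_fraction: float = DEFAULT_MIN_EXPR_FRACTION,
                          ) -> ActiveLigandSet:
    """Gate network ligands by expression: a ligand is active when it is
    detected (value > 0) in at least ``min_fraction`` of sender cells AND at
    least one cognate receptor is detected in at least ``min_fraction`` of
    receiver cells."""
    if not sender_cells or not receiver_cells:
        raise ValidationError("sender and receiver cell sets must be non-empty")
    if not 0 < min_fraction <= 1:
        raise ValidationError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    gidx = expr.gene_index()
    cidx = expr.cell_index()

    def rows(cells):
        missing = [c for c in cells if c not in cidx]
        if missing:
            raise ValidationError(f"unknown cell id(s): {missing[:5]}")
        return np.array([cidx[c] for c in cells], dtype=int)

    s_rows, r_rows = rows(sender_cells), rows(receiver_cells)
    ligands_in_data = [l for l in network.ligands() if l in gidx]
    if not ligands_in_data:
        raise ValidationError(
            "no ligand gene from the network is present in the expression matrix")
    active, s_frac, recs = [], {}, {}
    for lig in ligands_in_data:
        frac = float(np.mean(expr.values[s_rows, gidx[lig]] > 0))
        if frac < min_fraction:
            continue
        hits = {}
        for rec in network.receptors_for(lig):
            if rec not in gidx:
                continue
            rfrac = float(np.mean(expr.values[r_rows, gidx[rec]] > 0))
            if rfrac >= min_fraction:
                hits[rec] = rfrac
        if hits:
            active.append(lig)
            s_frac[lig] = frac
            recs[lig] = hits
    if not active:
        warnings.warn("no active ligands detected; downstream fitting will "
                      "refuse an empty ligand set", stacklevel=2)
        logger.warning("no active ligands detected")
    return ActiveLigandSet(active, s_frac, recs)


def _ligand_list(active) -> list:
    if isinstance(active, ActiveLigandSet):
        return list(active.ligand_ids)
    return [str(l) for l in active]


def build_design(prior: LigandTargetPrior,
                 training: TrainingGeneSet,
                 active: Union[ActiveLigandSet, Sequence[str]],
                 response: Union[CovarianceVector, "object"],
                 ) -> DesignMatrix:
    """Assemble the genes x ligands design aligned to the response.

    Rows are the (sorted) intersection of TRAINing genes, prior target genes
    and response genes; columns the active ligands found in the prior.
    Refuses designs with fewer than 20 genes or 2 ligands, where a forest
    fit would be meaningless.
    """
    ligands = _ligand_list(active)
    if not ligands:
        raise ValidationError("active ligand set is empty")
    if not training.retained:
        raise ValidationError("training gene set is empty")
    if isinstance(response, CovarianceVector):
        resp_genes, resp_values = response.gene_ids, response.values
        kind = "pseudotime-covariance"
    else:  # VelocityClusterLikelihoods (duck-typed to avoid import cycle)
        resp_genes, resp_values = response.gene_ids, response.likelihoods
        kind = "velocity-likelihood"
    resp_by_gene = dict(zip(resp_genes, resp_values))
    prior_rows = {g: i for i, g in enumerate(prior.target_gene_ids)}
    genes = sorted(set(training.retained) & set(prior_rows) & set(resp_by_gene))
    logger.info("design gene overlap: %d (training=%d, prior=%d, response=%d)",
                len(genes), len(training.retained), len(prior_rows),
                len(resp_by_gene))
    if len(genes) < MIN_DESIGN_GENES:
        raise ValidationError(
            f"only {len(genes)} genes are shared by the TRAINing set, the "
            f"prior and the response; at least {MIN_DESIGN_GENES} are needed")
    prior_cols = {l: j for j, l in enumerate(prior.ligand_ids)}
    kept = sorted(l for l in ligands if l in prior_cols)
    missing = sorted(set(ligands) - set(kept))
    if missing:
        warnings.warn(f"{len(missing)} active ligand(s) absent from the prior "
                      f"were dropped: {missing[:5]}", stacklevel=2)
        logger.warning("dropped %d active ligand(s) missing from prior", len(missing))
    if len(kept) < MIN_DESIGN_LIGANDS:
        raise ValidationError(
            f"only {len(kept)} active ligand(s) appear in the prior; at "
            f"least {MIN_DESIGN_LIGANDS} are needed")
    rows = [prior_rows[g] for g in genes]
    cols = [prior_cols[l] for l in kept]
    mat = prior.weights[np.ix_(rows, cols)]
    resp = np.array([resp_by_gene[g] for g in genes], dtype=float)
    return DesignMatrix(mat, genes, kept, resp, kind)


def default_mtry(n_ligands: int) -> int:
    """Features tried per split: number of ligands divided by 3, floored,
    with a floor of 1."""
    return max(1, n_ligands // 3)


def _delta_rss_importance(forest: RandomForestRegressor,
                          n_features: int) -> np.ndarray:
    """Total RSS reduction per feature, summed over all splits of all trees.

    For the squared-error criterion a node's impurity is the variance of its
    responses, so RSS(node) = impurity * weighted_n_node_samples.
    """
    total = np.zeros(n_features)
    for est in forest.estimators_:
        t = est.tree_
        rss = t.impurity * t.weighted_n_node_samples
        internal = t.children_left != -1
        for node in np.nonzero(internal)[0]:
            delta = rss[node] - rss[t.children_left[node]] - rss[t.children_right[node]]
            total[t.feature[node]] += max(delta, 0.0)
    return total


def _oob_mse(forest: RandomForestRegressor, X: np.ndarray,
             y: np.ndarray) -> float:
    """Out-of-bag mean squared error, averaging each sample's prediction over
    the trees that did not see it in their bootstrap."""
    n = len(y)
    preds = np.zeros(n)
    counts = np.zeros(n)
    for est, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if oob.any():
            preds[oob] += est.predict(X[oob])
            counts[oob] += 1
    covered = counts > 0
    if not covered.all():
        logger.warning("%d/%d rows never out-of-bag; increase n_trees for a "
                       "better E.V.E. estimate", int((~covered).sum()), n)
    if not covered.any():
        raise ValidationError("no out-of-bag rows; cannot estimate E.V.E.")
    resid = y[covered] - preds[covered] / counts[covered]
    return float(np.mean(resid ** 2))


def fit_ligand_model(design: DesignMatrix,
                     n_trees: int = DEFAULT_N_TREES,
                     mtry: Optional[int] = None,
                     seed: int = 0) -> LigandModel:
    """Fit the regression forest and summarise it as a LigandModel.

    The forest uses bootstrap resampling (sample size = n rows, with
    replacement) and a minimum leaf size of 5. Importance is the summed
    split-wise RSS reduction per ligand; %E.V.E. uses the out-of-bag MSE so
    that a forest memorising noise scores near (or below) zero rather than
    a trivial 100.
    """
    if design.n_genes < MIN_DESIGN_GENES:
        raise ValidationError(
            f"design has {design.n_genes} rows; at least {MIN_DESIGN_GENES} "
            "are required")
    y = design.response
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValidationError(
            "response variance is zero; E.V.E. is undefined for a constant "
            "response")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    if mtry is None:
        mtry = default_mtry(design.n_ligands)
    if not 1 <= mtry <= design.n_ligands:
        raise ValidationError(
            f"mtry must lie in [1, {design.n_ligands}], got {mtry}")
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry,
        min_samples_leaf=MIN_SAMPLES_LEAF, bootstrap=True,
        random_state=seed, n_jobs=1)
    forest.fit(design.matrix, y)
    importance = _delta_rss_importance(forest, design.n_ligands)
    mse = _oob_mse(forest, design.matrix, y)
    eve = 100.0 * (1.0 - mse / var_y)
    return LigandModel(list(design.ligand_ids), importance, eve,
                       n_trees, mtry, seed, design.response_kind,
                       oob_mse=mse, response_variance=var_y)


def permutation_null(design: DesignMatrix,
                     n_perm: int,
                     seed: int = 0,
                     n_trees: int = DEFAULT_N_TREES,
                     mtry: Optional[int] = None) -> PermutationNullResult:
    """Empirical null for ligand importances by permuting the response.

    The design rows stay fixed while the response vector is shuffled and the
    forest refit ``n_perm`` times. The per-ligand FDR is the smoothed
    fraction of null importances at least as large as the observed one:
    (1 + #{null >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    observed = fit_ligand_model(design, n_trees=n_trees, mtry=mtry, seed=seed)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, design.n_ligands))
    for p in range(n_perm):
        perm = DesignMatrix(design.matrix, design.gene_ids, design.ligand_ids,
                            rng.permutation(design.response),
                            design.response_kind)
        forest_seed = int(rng.integers(0, 2 ** 31 - 1))
        null[p] = fit_ligand_model(perm, n_trees=n_trees, mtry=mtry,
                                   seed=forest_seed).importance
    exceed = (null >= observed.importance[None, :]).sum(axis=0)
    fdr = (1.0 + exceed) / (1.0 + n_perm)
    return PermutationNullResult(list(design.ligand_ids),
                                 observed.importance, null, fdr)
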