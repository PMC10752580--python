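# Methods

## Model and assumptions

`entrain` attributes differentiation dynamics to extracellular ligands
under three assumptions: (i) environmental control of a differentiating
population acts through ligand–receptor interactions; (ii) the influence
operates on a time scale resolvable by pseudotime or RNA velocity; and
(iii) the regulatory routes are documented in a prior network whose edge
weight *w*(ℓ, g) ≥ 0 quantifies how strongly ligand ℓ regulates gene g. If
a ligand truly drives the trajectory, the column of prior weights for that
ligand should predict the per-gene trajectory statistic — gene–pseudotime
covariance in trajectory mode, dynamical-fit likelihood in velocity mode.
The package deliberately does not reimplement upstream inference: pseudotime
and branch assignments, velocity matrices, fit-likelihood tables and
(optionally) spot labels are inputs from whichever tools produced them.

The prior does not distinguish activating from repressive regulation, so
both activators and inhibitors of a trajectory can surface; rankings are
evidence of involvement, not of sign.

## Trajectory statistic and TRAINing genes

Per branch, the response is the sample covariance (n−1 denominator)
between each gene's expression and pseudotime. Covariance rather than
correlation is the default so that strongly dynamic genes dominate;
Pearson correlation is available (`metric="correlation"`) when expression
scales differ wildly, with zero-variance genes assigned 0. Genes are
ranked by |covariance| and the bottom 5% (`drop_fraction=0.05`) are
removed. Absolute rather than signed ranking is a deliberate choice: genes
strongly *negatively* covarying with pseudotime are just as informative
about the trajectory, and signed ranking would discard them; a `signed`
flag restores the alternative. Ties at the cut are broken lexicographically
by gene id (smaller id dropped first) so selection is deterministic.
Branches need ≥ 3 cells and non-constant pseudotime.

## Forest fit, importance and %E.V.E.

The design matrix is the prior restricted to rows = sorted intersection of
TRAINing genes, prior targets and response genes (≥ 20 required, otherwise
the fit refuses) and columns = active ligands present in the prior (≥ 2
required). The regression forest uses 500 trees, mtry = max(1, ⌊L/3⌋)
features per split, bootstrap samples of size n with replacement, and
minimum leaf size 5 — conventional regression-forest settings where not
otherwise dictated.

Per-ligand importance is computed from the fitted trees directly as the
summed split-wise reduction in residual sum of squares: for the
squared-error criterion a node's impurity is the variance of its samples,
so RSS = impurity × weighted node size and each split contributes
RSS(parent) − RSS(left) − RSS(right) to its split feature. This is the
"total increase in node purity" convention; scikit-learn's
`feature_importances_` is not used because it renormalises within each
tree before averaging and is therefore only approximately proportional to
the summed ΔRSS.

%E.V.E. = 100 × (1 − MSE/Var(y)) uses the **out-of-bag** MSE (each cell of
the design predicted only by trees whose bootstrap excluded it; Var with
the 1/n denominator, matching the classical out-of-bag "% variance
explained"). Training MSE would be near zero for any forest and would
report ≈100 regardless of signal. The score is not clamped: negative
values mean the ligand programs predict the response worse than its mean,
i.e. no detectable environmental dependence. %E.V.E. ≤ 100 always.

Known numerical behaviour: on a pure-noise response with weak sparse
features, out-of-bag R² has a small negative bias (a few percent) — trees
repeatedly overfit the same spurious split points, their errors correlate,
and bagging cannot fully average the noise away. Null-model %E.V.E. values
of roughly −5 to −10 on such data are expected and should be read as
"no dependence", not as a defect of the data.

## Active-ligand gating and permutation FDR

A ligand is active when detected (> 0) in at least `min_fraction = 0.10`
of sender cells and at least one cognate receptor is detected in at least
the same fraction of receiver cells. These thresholds follow common
ligand–receptor tool practice and are CLI-exposed; a precomputed active
set can be supplied instead (`--active-ligands`) to bypass gating
entirely.

The permutation null shuffles the response vector (design rows fixed),
refits the forest, and records importances. Per-ligand FDR =
(1 + #{null ≥ observed}) / (1 + n_perm); the +1 smoothing prevents zero
estimates at small n_perm, so the smallest attainable FDR is
1/(n_perm + 1) — use ≥ 39 permutations to resolve 0.05.

## Rolling-window profiles

Environmental dependence is rarely uniform along a trajectory. Cells are
sorted by pseudotime (ties broken by cell id), a window spans
max(`min_cells` = 30, ⌈`window_frac` = 0.1 × n⌉) cells, and
`n_windows` = 100 start offsets are evenly spaced over [0, n − width]
(duplicate integer starts collapse). The count of 100 follows the
analysis convention this module mirrors; the width and spacing are this
package's choices and are exposed as flags. TRAINing genes are reselected
inside each window by default (`training=` reuses a branch-level
selection). Windows whose gene overlap falls below the 20-gene floor
yield a missing E.V.E. rather than an error so profiles degrade
gracefully at branch tips. The same forest seed is used in every window,
so a single whole-branch window reproduces the branch-level fit exactly.

## Velocity mode

Velocity vectors are L2-normalised (direction, not magnitude, defines a
dynamic regime), a cosine kNN graph (k = 30) is built, and Leiden
community detection runs at resolution 1.0 with the given seed; labels are
relabelled consecutively by descending cluster size. Cells with all-zero
velocity have no direction and receive the reserved label −1. Clustering
happens in gene space by default; `n_pcs` enables a PCA pre-reduction for
very wide matrices. Note the usual Leiden caveat: a sparse kNN graph of a
single homogeneous population can itself be split into several
communities; only a saturated graph (k ≥ n−1) guarantees one cluster for
one blob.

Scoring a cluster reuses the trajectory machinery verbatim with response =
the cluster's fit-likelihood vector and TRAINing genes = every gene with a
computed likelihood (the upstream fit already restricts to confidently
fitted genes, so no additional rank filter is applied).

## Spatial mode

Visium arrays encode a hex lattice in integer (array_row, array_col) with
column parity alternating by row; the six equidistant neighbours sit at
offsets (0, ±2), (−1, ±1), (+1, ±1). A cluster's reference spots are those
carrying its label; the analysis subgrid is the union of their seven-spot
neighbourhoods. A candidate ligand must be detected in ≥ 1 subgrid spot
(any-spot semantics — requiring all seven would make single dropout spots
veto a ligand; `all_spots=True` provides the strict variant). Scoring is
identical to velocity mode with design columns restricted to candidates,
so for ligands passing the filter the scores equal the unrestricted run on
the same columns.

Label transfer to spots, when labels are not supplied, is a deliberately
simple centroid-correlation assignment: per-cluster mean expression over
the 500 most variable shared genes, each spot labelled by the
highest-Pearson centroid, ties to the smaller label. It is plumbing, not a
contribution — outputs of dedicated mapping tools are accepted wherever a
labelled grid is.

## Synthetic data

The generators produce the fixtures all tests run on, with planted ground
truth written to a sidecar. Trajectory fixture defaults: 500 receiver
cells on one branch, τ ~ U[0,1], 300 genes, 15 ligands of which 3 are
drivers, each driver owning a disjoint block of 20 targets whose receiver
expression is a·τ + N(0, noise_sd = 0.3) clipped at zero, a ~ U[0.5, 1];
the prior carries weight exactly a at planted (target, ligand) edges, so
the design column reproduces the noise-free covariance pattern. Decoy
columns are 90%-sparse U[0, 0.05]. Sender cells (25% extra) express all
ligand genes and receivers all receptor genes in ~60% of cells, so every
ligand passes expression gating and discrimination rests entirely on the
prior-response fit — the planted contrast the validation design needs.
An `effect_window` confines driver action to a pseudotime interval for
window-profile tests.

Velocity fixtures point each cluster along a distinct coordinate axis
(noise sd 0.05) and build its likelihood vector as the driver's prior
column rescaled to [0,1] plus noise; Visium fixtures lay cluster-labelled
vertical bands on a full-parity grid and place the driver ligand either
inside the labelled band (adjacent) or ≥ 2 column steps beyond any
neighbourhood (distal), with decoy ligands everywhere so the spatial
filter, not expression, decides.

These fixtures are idealised: Gaussian noise, linear effects, no dropout,
no library-size variation, no negative-binomial counts, no mixed-kinetics
velocity artefacts. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal — not performance on real
tissue data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — hundreds of cells,
hundreds of genes, tens of ligands, 20 seeds per property, 39
permutations for FDR resolution at 0.05 — sizes at which every claimed
property is measurable in minutes on one CPU. All stochastic operations
take an explicit integer seed (default 0); forest fits, clustering and
permutations are bit-reproducible given (inputs, parameters, seed), and
the CLI writes every resolved parameter plus input checksums to
`manifest.json`.

## Limitations

Results inherit the quality of upstream pseudotime/velocity estimates and
of the regulatory prior; ligands absent from the prior are invisible.
%E.V.E. measures ligand-attributable variance only — nutrient,
mechanical, or other non-ligand environmental influences are out of
frame. Expression inputs are assumed preprocessed (either raw counts or
log-normalised are accepted; the choice affects covariance scale, not
ranks, and is logged rather than enforced). Hybridisation panels that
miss ligand/receptor genes are unsuitable.
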