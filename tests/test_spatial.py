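import math

import numpy as np
import pytest

import entrain as en
from entrain.errors import ValidationError


def _grid(coords, n_genes=2, expr=None, labels=None, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{r}_{c}" for r, c in coords]
    rows = np.array([r for r, _ in coords])
    cols = np.array([c for _, c in coords])
    if expr is None:
        expr = rng.uniform(0, 1, (len(coords), n_genes))
    genes = [f"g{j}" for j in range(expr.shape[1])]
    return en.SpotGrid(ids, rows, cols, expr, genes, labels)


def _full_grid(n_rows, n_cols, **kw):
    coords = [(r, r % 2 + 2 * j) for r in range(n_rows) for j in range(n_cols)]
    return _grid(coords, **kw)


def brute_force_neighbors(coords, r, c):
    """Oracle: neighbours are spots at unit hex distance, using the physical
    embedding x = col, y = sqrt(3) * row (spot pitch = 2 in x units)."""
    out = []
    for (rr, cc) in coords:
        if (rr, cc) == (r, c):
            continue
        d = math.hypot(cc - c, math.sqrt(3) * (rr - r))
        if d <= 2.1:
            out.append((rr, cc))
    return out


class TestHexNeighbors:
    def test_interior_spot_has_seven_spot_neighbourhood(self):
        grid = _full_grid(6, 10)
        nb = en.hex_neighbors(grid, "s3_7")
        assert len(nb) == 7
        assert nb.reference in nb.members

    def test_corner_spot_partial_neighbourhood(self):
        grid = _grid([(0, 0), (0, 2), (1, 1)])
        nb = en.hex_neighbors(grid, "s0_0")
        assert sorted(nb.members) == ["s0_0", "s0_2", "s1_1"]

    def test_isolated_spot_is_its_own_neighbourhood(self):
        grid = _grid([(0, 0), (5, 5)])
        assert en.hex_neighbors(grid, "s0_0").members == ["s0_0"]

    def test_unknown_spot_rejected(self):
        with pytest.raises(ValidationError, match="unknown spot"):
            en.hex_neighbors(_grid([(0, 0)]), "nope")

    def test_matches_bruteforce_on_random_sparse_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lattice = [(r, r % 2 + 2 * j) for r in range(6) for j in range(8)]
            take = rng.random(len(lattice)) < 0.4
            coords = [xy for xy, t in zip(lattice, take) if t]
            if not coords:
                continue
            grid = _grid(coords, seed=1)
            for i, (r, c) in enumerate(coords):
                nb = en.hex_neighbors(grid, grid.spot_ids[i])
                got = sorted(m for m in nb.members if m != grid.spot_ids[i])
                want = sorted(f"s{rr}_{cc}" for rr, cc in
                              brute_force_neighbors(coords, r, c))
                assert got == want

    def test_neighbourhood_symmetry(self):
        rng = np.random.default_rng(5)
        lattice = [(r, r % 2 + 2 * j) for r in range(8) for j in range(8)]
        take = rng.random(len(lattice)) < 0.5
        grid = _grid([xy for xy, t in zip(lattice, take) if t], seed=2)
        for a in grid.spot_ids:
            for b in en.hex_neighbors(grid, a).members:
                assert a in en.hex_neighbors(grid, b).members

    def test_parity_violation_rejected(self):
        with pytest.raises(ValidationError, match="parity"):
            _grid([(0, 1)])


class TestTransferLabels:
    def _sc(self, seed=0, n_genes=60):
        """Two single-cell clusters with disjoint marker blocks."""
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(0.2, 0.05, (40, n_genes)))
        vals[:20, :20] += 2.0
        vals[20:, 20:40] += 2.0
        labels = ["0"] * 20 + ["1"] * 20
        expr = en.ExpressionMatrix(vals, [f"c{i}" for i in range(40)],
                                   [f"g{j}" for j in range(n_genes)])
        return expr, labels

    def test_exact_centroid_recovers_label(self):
        expr, labels = self._sc()
        centroid1 = expr.values[20:].mean(axis=0, keepdims=True)
        grid = _grid([(0, 0)], expr=centroid1)
        assert en.transfer_labels(expr, labels, grid) == ["1"]

    def test_equal_correlation_tie_goes_to_smaller_label(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(0, 1, 60)
        vals = np.vstack([np.tile(profile, (10, 1)),
                          np.tile(profile, (10, 1))])
        expr = en.ExpressionMatrix(np.abs(vals), [f"c{i}" for i in range(20)],
                                   [f"g{j}" for j in range(60)])
        labels = ["2"] * 10 + ["5"] * 10
        grid = _grid([(0, 0)], expr=np.abs(profile)[None, :])
        assert en.transfer_labels(expr, labels, grid) == ["2"]

    def test_banded_grid_high_accuracy(self):
        expr, labels = self._sc(seed=0)
        rng = np.random.default_rng(0)
        coords = [(r, r % 2 + 2 * j) for r in range(4) for j in range(10)]
        truth = ["0" if (c // 2) < 5 else "1" for _, c in coords]
        centroids = {lab: expr.values[np.array(labels) == lab].mean(axis=0)
                     for lab in ("0", "1")}
        spot_vals = np.vstack([centroids[t] for t in truth])
        spot_vals = spot_vals + np.abs(rng.normal(0, 0.05, spot_vals.shape))
        grid = _grid(coords, expr=spot_vals)
        got = en.transfer_labels(expr, labels, grid)
        accuracy = np.mean([a == b for a, b in zip(got, truth)])
        assert accuracy >= 0.95

    def test_too_few_shared_genes_rejected(self):
        expr, labels = self._sc(n_genes=60)
        grid = _grid([(0, 0)], n_genes=10)  # genes g0..g9 only
        grid = en.SpotGrid(grid.spot_ids, grid.array_row, grid.array_col,
                           grid.expression, [f"x{j}" for j in range(10)])
        with pytest.raises(ValidationError, match="shared"):
            en.transfer_labels(expr, labels, grid)


class TestSpatialFilter:
    def _scene(self):
        """5x8 grid, reference label band at columns j<2, one ligand in the
        band, one adjacent, one three rows/columns away, decoy everywhere."""
        coords = [(r, r % 2 + 2 * j) for r in range(5) for j in range(8)]
        n = len(coords)
        genes = ["LREF", "LADJ", "LFAR", "LDEC", "g0"]
        expr = np.zeros((n, 5))
        labels = []
        for i, (r, c) in enumerate(coords):
            j = (c - r % 2) // 2
            labels.append("hit" if j < 2 else "other")
            if labels[-1] == "hit":
                expr[i, 0] = 1.0              # LREF inside reference spots
            if j == 2:
                expr[i, 1] = 1.0              # LADJ in direct neighbours
            if j >= 6:
                expr[i, 2] = 1.0              # LFAR beyond hex reach
            expr[i, 3] = 0.5                  # LDEC everywhere
            expr[i, 4] = 0.1
        grid = _grid(coords, expr=expr)
        grid = en.SpotGrid(grid.spot_ids, grid.array_row, grid.array_col,
                           expr, genes, labels)
        net = en.LigandReceptorNetwork([(l, "R") for l in
                                        ("LREF", "LADJ", "LFAR", "LDEC")])
        return grid, labels, net

    def test_reference_adjacent_and_distal_semantics(self):
        grid, labels, net = self._scene()
        candidates, subgrid, n_det = en.spatially_filter_ligands(
            grid, labels, "hit", net)
        assert "LREF" in candidates   # expressed in the reference spot itself
        assert "LADJ" in candidates   # expressed in a direct neighbour
        assert "LFAR" not in candidates
        assert "LDEC" in candidates
        assert n_det["LDEC"] == subgrid.n_spots

    def test_subgrid_is_union_of_neighbourhoods(self):
        grid, labels, net = self._scene()
        _, subgrid, _ = en.spatially_filter_ligands(grid, labels, "hit", net)
        expected = set()
        for sid, lab in zip(grid.spot_ids, labels):
            if lab == "hit":
                expected.update(en.hex_neighbors(grid, sid).members)
        assert set(subgrid.spot_ids) == expected

    def test_missing_label_rejected(self):
        grid, labels, net = self._scene()
        with pytest.raises(ValidationError, match="cluster label"):
            en.spatially_filter_ligands(grid, labels, "absent", net)

    def test_all_spots_mode_is_stricter(self):
        grid, labels, net = self._scene()
        any_mode, _, _ = en.spatially_filter_ligands(grid, labels, "hit", net)
        strict, _, _ = en.spatially_filter_ligands(grid, labels, "hit", net,
                                                   all_spots=True)
        assert set(strict) <= set(any_mode)
        assert "LDEC" in strict       # detected in every spot

    def test_placement_contrast_on_synthetic_grid(self, velocity_ds):
        driver = velocity_ds.truth.cluster_drivers["0"]
        for placement, expected in (("adjacent", True), ("distal", False)):
            ds = en.simulate_visium_grid(velocity_ds=velocity_ds,
                                         placement=placement, seed=0)
            candidates, _, _ = en.spatially_filter_ligands(
                ds.grid, ds.labels, 0, velocity_ds.network)
            assert (driver in candidates) is expected


class TestScoreSpatialCluster:
    def test_empty_candidates_rejected(self, velocity_ds):
        with pytest.raises(ValidationError, match="candidate"):
            en.score_spatial_cluster([], velocity_ds.likelihoods[0],
                                     velocity_ds.prior)

    def test_scores_match_velocity_mode_on_same_candidates(self, velocity_ds):
        """The spatial filter only removes design columns: scoring the
        filtered candidate set must equal velocity-mode scoring of the same
        ligand set."""
        candidates = list(velocity_ds.prior.ligand_ids)[:6]
        spatial = en.score_spatial_cluster(candidates,
                                           velocity_ds.likelihoods[0],
                                           velocity_ds.prior,
                                           n_trees=150, seed=3)
        velocity = en.score_velocity_cluster(velocity_ds.likelihoods[0],
                                             velocity_ds.prior, candidates,
                                             n_trees=150, seed=3)
        np.testing.assert_array_equal(spatial.importance, velocity.importance)
        assert spatial.eve_percent == velocity.eve_percent

    def test_planted_driver_ranks_first_when_adjacent(self, velocity_ds):
        ds = en.simulate_visium_grid(velocity_ds=velocity_ds,
                                     placement="adjacent", seed=0)
        candidates, _, _ = en.spatially_filter_ligands(
            ds.grid, ds.labels, 0, velocity_ds.network)
        model = en.score_spatial_cluster(candidates,
                                         velocity_ds.likelihoods[0],
                                         velocity_ds.prior,
                                         n_trees=200, seed=0)
        assert model.top_ligands(1) == [velocity_ds.truth.cluster_drivers["0"]]
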