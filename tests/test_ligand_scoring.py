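import numpy as np
import pytest

import entrain as en
from entrain.errors import ValidationError
from entrain.ligand_scoring import default_mtry


class TestActiveLigandDetection:
    def _fixture(self):
        """20 senders, 10 receivers; LIG detected in 10/20 senders, REC in
        4/10 receivers; LOW detected in 1/20 senders (5%); ORPHAN has no
        receptor row."""
        genes = ["LIG", "REC", "LOW", "ORPHAN"]
        cells = [f"s{i}" for i in range(20)] + [f"r{i}" for i in range(10)]
        vals = np.zeros((30, 4))
        vals[:10, 0] = 1.0      # LIG in senders s0..s9
        vals[20:24, 1] = 1.0    # REC in receivers r0..r3
        vals[0, 2] = 1.0        # LOW in one sender (5%)
        vals[:20, 3] = 1.0      # ORPHAN everywhere in senders
        expr = en.ExpressionMatrix(vals, cells, genes)
        net = en.LigandReceptorNetwork([("LIG", "REC"), ("LOW", "REC"),
                                        ("ORPHAN", "NOSUCH")])
        return expr, net, cells[:20], cells[20:]

    def test_fraction_gating(self):
        expr, net, senders, receivers = self._fixture()
        active = en.detect_active_ligands(expr, net, senders, receivers,
                                          min_fraction=0.10)
        assert active.ligand_ids == ["LIG"]
        assert active.sender_fraction["LIG"] == pytest.approx(0.5)
        assert active.receptors["LIG"]["REC"] == pytest.approx(0.4)

    def test_below_threshold_not_active(self):
        expr, net, senders, receivers = self._fixture()
        active = en.detect_active_ligands(expr, net, senders, receivers,
                                          min_fraction=0.10)
        assert "LOW" not in active.ligand_ids

    def test_ligand_without_receptor_not_active(self):
        expr, net, senders, receivers = self._fixture()
        active = en.detect_active_ligands(expr, net, senders, receivers)
        assert "ORPHAN" not in active.ligand_ids

    def test_no_network_ligand_in_matrix_errors(self):
        expr, _, senders, receivers = self._fixture()
        net = en.LigandReceptorNetwork([("ABSENT", "REC")])
        with pytest.raises(ValidationError, match="no ligand gene"):
            en.detect_active_ligands(expr, net, senders, receivers)

    def test_zero_active_warns_and_returns_empty(self):
        expr, net, senders, receivers = self._fixture()
        with pytest.warns(UserWarning, match="no active ligands"):
            active = en.detect_active_ligands(expr, net, senders, receivers,
                                              min_fraction=0.95)
        assert len(active) == 0


class TestBuildDesign:
    def _prior(self, genes, ligands, seed=0):
        rng = np.random.default_rng(seed)
        return en.LigandTargetPrior(rng.uniform(0.1, 1, (len(genes),
                                                         len(ligands))),
                                    genes, ligands)

    def test_set_intersection_oracle(self):
        training_genes = [f"g{i:03d}" for i in range(100)]
        prior = self._prior(training_genes[:80], [f"L{i}" for i in range(10)])
        cov = en.CovarianceVector(np.linspace(-1, 1, 100), training_genes, "b")
        training = en.TrainingGeneSet(training_genes, [], 0.0)
        design = en.build_design(prior, training, [f"L{i}" for i in range(10)],
                                 cov)
        assert design.matrix.shape == (80, 10)
        assert design.gene_ids == sorted(training_genes[:80])

    def test_active_ligand_missing_from_prior_dropped(self):
        genes = [f"g{i}" for i in range(30)]
        prior = self._prior(genes, ["L0", "L1"])
        cov = en.CovarianceVector(np.arange(30, dtype=float), genes, "b")
        training = en.TrainingGeneSet(genes, [], 0.0)
        with pytest.warns(UserWarning, match="absent from the prior"):
            design = en.build_design(prior, training, ["L0", "L1", "LX"], cov)
        assert design.ligand_ids == ["L0", "L1"]

    def test_small_overlap_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        prior = self._prior(genes, ["L0", "L1"])
        cov = en.CovarianceVector(np.arange(5, dtype=float), genes, "b")
        training = en.TrainingGeneSet(genes, [], 0.0)
        with pytest.raises(ValidationError, match="at least 20"):
            en.build_design(prior, training, ["L0", "L1"], cov)

    def test_single_ligand_rejected(self):
        genes = [f"g{i}" for i in range(30)]
        prior = self._prior(genes, ["L0", "L1"])
        cov = en.CovarianceVector(np.arange(30, dtype=float), genes, "b")
        training = en.TrainingGeneSet(genes, [], 0.0)
        with pytest.raises(ValidationError, match="ligand"):
            en.build_design(prior, training, ["L0"], cov)


def _planted_design(seed, n_rows=200, n_decoys=9, noise_frac=0.01):
    """One design column equals the response up to N(0, 0.01*sd) noise."""
    rng = np.random.default_rng(seed)
    response = rng.uniform(0, 1, n_rows)
    signal = response + rng.normal(0, noise_frac * response.std(), n_rows)
    decoys = rng.uniform(0, 1, (n_rows, n_decoys))
    matrix = np.column_stack([np.clip(signal, 0, None), decoys])
    return en.DesignMatrix(matrix, [f"g{i:03d}" for i in range(n_rows)],
                           ["PLANTED"] + [f"D{i}" for i in range(n_decoys)],
                           response)


class TestForestFit:
    def test_constant_response_rejected(self):
        design = _planted_design(0)
        flat = en.DesignMatrix(design.matrix, design.gene_ids,
                               design.ligand_ids,
                               np.full(design.n_genes, 0.7))
        with pytest.raises(ValidationError, match="variance"):
            en.fit_ligand_model(flat)

    def test_planted_column_wins_importance(self):
        hits = 0
        for seed in range(20):
            model = en.fit_ligand_model(_planted_design(seed), seed=seed)
            hits += model.top_ligands(1) == ["PLANTED"]
        assert hits >= 18

    def test_all_zero_design_gives_near_zero_eve(self):
        eves = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            design = en.DesignMatrix(
                np.zeros((100, 3)), [f"g{i}" for i in range(100)],
                ["L0", "L1", "L2"], rng.normal(size=100))
            eves.append(en.fit_ligand_model(design, seed=seed).eve_percent)
        assert all(abs(e) < 5 for e in eves)

    def test_zero_prior_column_gets_zero_importance(self):
        design = _planted_design(1)
        matrix = design.matrix.copy()
        matrix[:, 3] = 0.0
        dead = en.DesignMatrix(matrix, design.gene_ids, design.ligand_ids,
                               design.response)
        model = en.fit_ligand_model(dead, seed=1)
        assert model.importance[3] <= 1e-9 * model.importance.sum()

    def test_deterministic_given_seed(self):
        design = _planted_design(5)
        m1 = en.fit_ligand_model(design, seed=11)
        m2 = en.fit_ligand_model(design, seed=11)
        np.testing.assert_array_equal(m1.importance, m2.importance)
        assert m1.eve_percent == m2.eve_percent

    def test_eve_bounds_and_noise_free_fit(self):
        rng = np.random.default_rng(2)
        response = rng.uniform(0, 1, 500)
        matrix = np.column_stack([response, rng.uniform(0, 1, (500, 4))])
        design = en.DesignMatrix(matrix, [f"g{i}" for i in range(500)],
                                 [f"L{i}" for i in range(5)], response)
        model = en.fit_ligand_model(design, seed=0)
        assert model.eve_percent <= 100
        assert model.eve_percent > 80

    def test_importances_non_negative(self, planted_design):
        model = en.fit_ligand_model(planted_design, seed=0)
        assert np.all(model.importance >= 0)

    def test_mtry_rule(self):
        assert default_mtry(15) == 5
        assert default_mtry(2) == 1
        assert default_mtry(1) == 1


class TestPermutationNull:
    def test_zero_permutations_rejected(self):
        with pytest.raises(ValidationError):
            en.permutation_null(_planted_design(0), n_perm=0)

    def test_planted_driver_has_small_fdr(self):
        fdrs = []
        for seed in range(3):
            design = _planted_design(seed, n_rows=120, n_decoys=7)
            null = en.permutation_null(design, n_perm=39, seed=seed,
                                       n_trees=150)
            fdrs.append(null.fdr[null.ligand_ids.index("PLANTED")])
        assert float(np.median(fdrs)) < 0.05

    def test_fdr_within_unit_interval_and_smoothed(self):
        design = _planted_design(4, n_rows=60, n_decoys=4)
        null = en.permutation_null(design, n_perm=5, seed=0, n_trees=50)
        assert np.all(null.fdr >= 1 / 6) and np.all(null.fdr <= 1.0)
        assert null.null_importances.shape == (5, 5)
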