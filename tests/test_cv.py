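import numpy as np
import pytest

from hippotype import (CVEvaluator, CVReport, ExpressionMatrix, MarkerSet,
                       cv_objective, locto_fold_accuracy, make_folds,
                       simulate_dataset, SimSpec, UNKNOWN_LABEL)


class TestMakeFolds:
    def test_even_split_single_type(self):
        folds = make_folds(["A"] * 10, K=5, seed=0)
        counts = np.bincount(folds.fold_of_cell, minlength=5)
        assert (counts == 2).all()

    def test_reproducible_given_seed(self):
        labels = ["A"] * 7 + ["B"] * 9
        f1 = make_folds(labels, K=3, seed=42)
        f2 = make_folds(labels, K=3, seed=42)
        np.testing.assert_array_equal(f1.fold_of_cell, f2.fold_of_cell)
        f3 = make_folds(labels, K=3, seed=43)
        assert not np.array_equal(f1.fold_of_cell, f3.fold_of_cell)

    def test_small_type_spreads_over_distinct_folds(self):
        labels = ["A"] * 20 + ["B"] * 3
        folds = make_folds(labels, K=5, seed=1)
        b_folds = folds.fold_of_cell[20:]
        assert len(set(b_folds)) == 3

    def test_stratification(self):
        labels = ["A"] * 50 + ["B"] * 25
        folds = make_folds(labels, K=5, seed=0)
        for k in range(5):
            idx = folds.cells_in_fold(k)
            assert (np.asarray(labels, dtype=object)[idx] == "A").sum() == 10


def _noiseless_fixture():
    """Two clean types: each expresses only its own two marker genes."""
    vals = np.array([
        # cells:  a a a a b b b b
        [9.0, 8, 9, 8, 1, 1, 1, 1],   # gA1
        [8.0, 9, 8, 9, 1, 1, 1, 1],   # gA2
        [1.0, 1, 1, 1, 9, 8, 9, 8],   # gB1
        [1.0, 1, 1, 1, 8, 9, 8, 9],   # gB2
        [5.0, 5, 6, 6, 5, 5, 6, 6],   # filler
    ])
    X = ExpressionMatrix(vals, ["gA1", "gA2", "gB1", "gB2", "gf"],
                         [f"c{i}" for i in range(8)], layer_tag="normalized")
    labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
    S = MarkerSet("toy", {"A": ("gA1", "gA2"), "B": ("gB1", "gB2")})
    return X, labels, S


class TestLoctoAccuracy:
    def test_masking_sends_type_to_unknown(self):
        X, labels, S = _noiseless_fixture()
        folds = make_folds(labels, K=2, seed=0)
        for k in range(2):
            acc = locto_fold_accuracy(X, labels, S, "A", folds, k)
            assert acc == 1.0

    def test_masked_cells_can_be_scored_as_incorrect(self):
        X, labels, S = _noiseless_fixture()
        folds = make_folds(labels, K=2, seed=0)
        acc = locto_fold_accuracy(X, labels, S, "A", folds, k=0,
                                  masked_correct_as_unknown=False)
        # the fold's A-cells all predicted unknown, which now counts wrong
        idx = folds.cells_in_fold(0)
        n_a = (labels[idx] == "A").sum()
        assert acc == pytest.approx(1.0 - n_a / len(idx))

    def test_random_markers_near_chance(self):
        sim = simulate_dataset(SimSpec(n_types=4, cells_per_type=50,
                                       n_genes=400, markers_per_type=5, seed=3))
        rng = np.random.default_rng(0)
        nonmarkers = [g for g in sim.X_raw.gene_ids
                      if g not in set(sim.planted.universe)]
        S_rand = MarkerSet("t", {
            ct: tuple(rng.choice(nonmarkers, 5, replace=False))
            for ct in sim.planted.cell_types})
        rep = cv_objective(sim.X_raw, sim.true_labels, S_rand, K=5, seed=0)
        # permutation baseline: chance of a correct label with 4 types plus
        # masked-unknown credit is well below the planted-marker score
        rep_true = cv_objective(sim.X_raw, sim.true_labels, sim.planted, K=5, seed=0)
        assert rep_true.objective - rep.objective > 0.2
        assert rep.objective < 0.6


class TestCVObjective:
    def test_grand_mean_of_stubbed_accuracies(self):
        report = CVReport(per_cell_type_fold=np.array([[1.0, 1.0], [0.5, 0.5]]),
                          cell_types=["A", "B"], K=2)
        assert report.objective == pytest.approx(0.75)
        const = CVReport(per_cell_type_fold=np.full((3, 5), 0.8),
                         cell_types=list("ABC"), K=5)
        assert const.objective == pytest.approx(0.8)

    def test_stubbed_scorer_flows_through(self, monkeypatch):
        X, labels, S = _noiseless_fixture()
        monkeypatch.setattr(CVEvaluator, "type_fold_accuracies",
                            lambda self, S, ct: np.full(self.folds.K, 0.8))
        rep = cv_objective(X, labels, S, K=2, seed=0)
        assert rep.objective == pytest.approx(0.8)

    def test_objective_bounded(self, small_sim):
        rng = np.random.default_rng(0)
        S_rand = MarkerSet("t", {
            ct: tuple(rng.choice(small_sim.X_raw.gene_ids, 4, replace=False))
            for ct in small_sim.planted.cell_types})
        rep = cv_objective(small_sim.X_raw, small_sim.true_labels, S_rand,
                           K=3, seed=0)
        assert np.all((rep.per_cell_type_fold >= 0) & (rep.per_cell_type_fold <= 1))
        assert 0.0 <= rep.objective <= 1.0

    def test_invariant_to_type_enumeration_order(self):
        X, labels, S = _noiseless_fixture()
        S_rev = MarkerSet("toy", {ct: S[ct] for ct in reversed(S.cell_types)})
        r1 = cv_objective(X, labels, S, K=2, seed=0)
        r2 = cv_objective(X, labels, S_rev, K=2, seed=0)
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.per_cell_type_fold, r2.per_cell_type_fold)

    def test_removing_noise_genes_never_hurts_noiseless(self):
        X, labels, S = _noiseless_fixture()
        S_noisy = MarkerSet("toy", {"A": S["A"] + ("gf",), "B": S["B"]})
        f_clean = cv_objective(X, labels, S, K=2, seed=0).objective
        f_noisy = cv_objective(X, labels, S_noisy, K=2, seed=0).objective
        assert f_clean >= f_noisy

    def test_single_type_rejected(self):
        X, labels, S = _noiseless_fixture()
        with pytest.raises(ValueError, match="at least two"):
            cv_objective(X, np.array(["A"] * 8, dtype=object), S.drop_type("B"))

    def test_report_round_trip_frame(self):
        rep = CVReport(per_cell_type_fold=np.array([[0.1, 0.2], [0.3, 0.4]]),
                       cell_types=["A", "B"], K=2)
        df = rep.to_frame()
        assert len(df) == 4
        assert df["accuracy"].mean() == pytest.approx(rep.objective)
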