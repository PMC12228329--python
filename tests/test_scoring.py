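import numpy as np
import pytest

from hippotype import (ExpressionMatrix, MarkerSet, annotate, assign_labels,
                       assign_cluster_labels, enrichment_scores,
                       normalize_counts, specificity_weights, weighted_z,
                       zscore_genes, EnrichmentResult, UNKNOWN_LABEL)


def _weighted(vals, genes, cells):
    return ExpressionMatrix(np.asarray(vals, dtype=float), genes, cells,
                            layer_tag="weighted_zscore")


def naive_enrichment(Z, gene_ids, S, theta):
    """Triple-loop reference implementation of the enrichment score."""
    index = {g: i for i, g in enumerate(gene_ids)}
    cell_types = sorted(S.cell_types)
    n = Z.shape[1]
    E = np.zeros((len(cell_types), n))
    for c, ct in enumerate(cell_types):
        genes = [g for g in S[ct] if g in index]
        for j in range(n):
            total = 0.0
            for g in genes:
                total += Z[index[g], j] * theta[g]
            E[c, j] = total / np.sqrt(len(genes))
    return E


class TestWeightedZ:
    def test_row_scaling(self):
        Z = ExpressionMatrix(np.array([[-1.0, 0.0, 1.0]]), ["g1"],
                             ["c1", "c2", "c3"], layer_tag="zscore")
        W = specificity_weights(MarkerSet("t", {"A": ("g1", "x"), "B": ("g1", "y")}))
        assert W.theta["g1"] == 0.0  # occurs in both types
        out = weighted_z(Z, W)
        np.testing.assert_array_equal(out.values, 0.0)

    @pytest.mark.parametrize("theta,expected", [
        (0.5, [-0.5, 0.0, 0.5]),
        (1.0, [-1.0, 0.0, 1.0]),
    ])
    def test_scalar_weights(self, theta, expected):
        from hippotype.markers import SpecificityWeights
        Z = ExpressionMatrix(np.array([[-1.0, 0.0, 1.0]]), ["g1"],
                             ["c1", "c2", "c3"], layer_tag="zscore")
        W = SpecificityWeights({"g1": theta}, {"g1": 1})
        np.testing.assert_allclose(weighted_z(Z, W).values.ravel(), expected)


class TestEnrichmentScores:
    def test_hand_computed_score(self):
        Zt = _weighted([[1.0], [0.5]], ["g1", "g2"], ["c1"])
        S = MarkerSet("t", {"A": ("g1", "g2")})
        E = enrichment_scores(Zt, S)
        assert E.scores[0, 0] == pytest.approx(1.5 / np.sqrt(2), abs=1e-9)

    def test_all_zero_column_scores_zero(self):
        Zt = _weighted(np.zeros((3, 2)), ["g1", "g2", "g3"], ["c1", "c2"])
        S = MarkerSet("t", {"A": ("g1",), "B": ("g2", "g3")})
        np.testing.assert_array_equal(enrichment_scores(Zt, S).scores, 0.0)

    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_uniform_markers_closed_form(self, k):
        """One type, k markers all at z-tilde = z gives E = z * sqrt(k)."""
        z = 0.7
        genes = [f"g{i}" for i in range(k)]
        Zt = _weighted(np.full((k, 1), z), genes, ["c1"])
        S = MarkerSet("t", {"A": tuple(genes)})
        assert enrichment_scores(Zt, S).scores[0, 0] == pytest.approx(
            z * np.sqrt(k), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_matches_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        m, n, C = rng.integers(20, 100), rng.integers(50, 500), rng.integers(2, 10)
        genes = [f"g{i}" for i in range(m)]
        S = MarkerSet("t", {
            f"T{c}": tuple(rng.choice(genes, size=rng.integers(1, 12), replace=False))
            for c in range(C)})
        universe = S.universe
        theta = specificity_weights(S).theta
        Z = rng.normal(size=(len(universe), n))
        Zt_vals = Z * np.array([theta[g] for g in universe])[:, None]
        Zt = _weighted(Zt_vals, universe, [f"c{j}" for j in range(n)])
        E = enrichment_scores(Zt, S)
        expected = naive_enrichment(Zt_vals, np.array(universe), S,
                                    {g: 1.0 for g in universe})
        assert np.abs(E.scores - expected).max() < 1e-9

    def test_type_without_available_markers_is_nan(self):
        Zt = _weighted([[1.0]], ["g1"], ["c1"])
        S = MarkerSet("t", {"A": ("g1",), "B": ("missing",)})
        with pytest.warns(UserWarning, match="no markers available"):
            E = enrichment_scores(Zt, S)
        assert np.isnan(E.scores[E.cell_types.index("B"), 0])
        assert not np.isnan(E.scores[E.cell_types.index("A"), 0])
        labels = assign_labels(E).labels
        assert labels[0] == "A"  # NaN row can never win


class TestAssignLabels:
    def _result(self, column, types=("A", "B", "C")):
        scores = np.array(column, dtype=float)[:, None]
        return EnrichmentResult(scores=scores, cell_types=list(types),
                                cell_ids=np.array(["c1"], dtype=object))

    def test_argmax_winner(self):
        E = assign_labels(self._result([0.5, 1.2, -0.3]))
        assert E.labels[0] == "B"
        assert E.top_score[0] == pytest.approx(1.2)

    def test_all_nonpositive_is_unknown(self):
        assert assign_labels(self._result([0.0, -1.0, -2.0])).labels[0] == UNKNOWN_LABEL

    def test_exact_tie_breaks_lexicographically(self):
        assert assign_labels(self._result([1.0, 1.0, 0.0])).labels[0] == "A"

    def test_threshold_is_inclusive(self):
        assert assign_labels(self._result([0.4, 0.1, 0.0]),
                             unknown_threshold=0.4).labels[0] == UNKNOWN_LABEL


class TestAnnotate:
    def test_synthetic_accuracy(self, default_sim):
        res = annotate(default_sim.X_raw, default_sim.planted)
        assert (res.labels == default_sim.true_labels).mean() >= 0.95

    def test_gene_order_invariance(self, small_sim):
        X = small_sim.X_raw
        res1 = annotate(X, small_sim.planted)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_genes)
        X2 = ExpressionMatrix(X.values[perm], X.gene_ids[perm], X.cell_ids)
        res2 = annotate(X2, small_sim.planted)
        np.testing.assert_array_equal(res1.labels, res2.labels)

    def test_type_name_order_invariance(self, small_sim):
        S = small_sim.planted
        reversed_S = MarkerSet(S.tissue_tag, {ct: S[ct] for ct in reversed(S.cell_types)})
        res1 = annotate(small_sim.X_raw, S)
        res2 = annotate(small_sim.X_raw, reversed_S)
        np.testing.assert_array_equal(res1.labels, res2.labels)

    def test_duplicating_cells_duplicates_labels(self, small_sim):
        """Doubling every cell leaves per-gene means/sds unchanged up to the
        ddof=1 correction, so labels are preserved and scores shift only
        through the recomputed z statistics."""
        X = small_sim.X_raw
        doubled = ExpressionMatrix(
            np.hstack([np.asarray(X.values)] * 2), X.gene_ids,
            np.array([f"{c}|{r}" for r in (1, 2) for c in X.cell_ids], dtype=object))
        res1 = annotate(X, small_sim.planted)
        res2 = annotate(doubled, small_sim.planted)
        np.testing.assert_array_equal(np.tile(res1.labels, 2), res2.labels)
        # scores differ only by the sd ddof rescaling factor:
        # sd_2n / sd_n = sqrt((2n-1)/(2(n-1))), so z (and E) shrink by its inverse
        n = X.n_cells
        factor = np.sqrt(2 * (n - 1) / (2 * n - 1))
        np.testing.assert_allclose(np.tile(res1.scores, 2),
                                   factor * res2.scores, atol=1e-9)

    def test_affine_transform_invariance(self, small_sim):
        """Per-gene positive-scale affine transforms of the normalized input
        do not change enrichment scores (z-scoring removes them)."""
        from hippotype import normalize_counts
        Xn = normalize_counts(small_sim.X_raw)
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 2.0, size=Xn.n_genes)[:, None]
        b = rng.uniform(-1.0, 1.0, size=Xn.n_genes)[:, None]
        X2 = ExpressionMatrix(np.asarray(Xn.values) * a + b, Xn.gene_ids,
                              Xn.cell_ids, layer_tag="normalized")
        res1 = annotate(Xn, small_sim.planted)
        res2 = annotate(X2, small_sim.planted)
        np.testing.assert_allclose(res1.scores, res2.scores, atol=1e-8)
        np.testing.assert_array_equal(res1.labels, res2.labels)

    def test_missing_markers_warn_then_error(self, small_sim):
        S = small_sim.planted
        mostly_absent = MarkerSet("t", {
            ct: (S[ct][0],) + tuple(f"zz{ct}{i}" for i in range(9))
            for ct in S.cell_types})
        with pytest.warns(UserWarning):
            annotate(small_sim.X_raw, mostly_absent)
        fully_absent = MarkerSet("t", {ct: (f"zz{ct}",) for ct in S.cell_types})
        with pytest.raises(ValueError, match="none of the marker genes"):
            annotate(small_sim.X_raw, fully_absent)

    def test_cluster_mode_assigns_cluster_majority(self, small_sim):
        res = annotate(small_sim.X_raw, small_sim.planted,
                       clusters=small_sim.true_labels)
        assert (res.labels == small_sim.true_labels).all()
        # one label per cluster
        for cl in np.unique(small_sim.true_labels):
            assert len(set(res.labels[small_sim.true_labels == cl])) == 1
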