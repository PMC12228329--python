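"""Leave-one-cell-type-out (LOCTO) x K-fold cross-validated objective.

A candidate marker set S is scored as follows. For each cell type c, the
markers of c are temporarily removed from S, so that cells of type c
should fall below the unknown threshold and be labelled "unknown". The
masked classifier is applied and, for each of K stratified folds, the
accuracy f_{c,k} is the proportion of correctly assigned held-out cells
over *all* cell types: a cell of type != c is correct when it receives
its true label, and a cell of the masked type c is correct when it is
labelled "unknown". The objective is the grand mean

    f(S) = (1 / (C*K)) * sum_c sum_k f_{c,k}(S).

Standardization statistics (per-gene mean/sd) are computed on the full
matrix, as the classifier standardizes across all cells; only the
evaluation is fold-restricted.

:class:`CVEvaluator` caches the normalized matrix, the per-gene moments
and the fold assignment, so that thousands of candidate sets can be
scored during optimization without re-doing the preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .markers import MarkerSet, specificity_weights
from .matrix import ExpressionMatrix, normalize_counts
from .scoring import UNKNOWN_LABEL


@dataclass
class FoldAssignment:
    """Stratified fold index per cell, reproducible from ``seed``."""

    fold_of_cell: np.ndarray
    K: int
    seed: int

    def cells_in_fold(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.fold_of_cell == k)
        if idx.size == 0:
            raise ValueError(f"fold {k} contains no cells")
        return idx


@dataclass
class CVReport:
    """Per-(cell type, fold) accuracies and their grand mean."""

    per_cell_type_fold: np.ndarray   # (C, K)
    cell_types: list[str]
    K: int

    @property
    def C(self) -> int:
        return len(self.cell_types)

    @property
    def objective(self) -> float:
        return float(self.per_cell_type_fold.mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cell_type, fold, accuracy) table."""
        rows = [
            {"cell_type": ct, "fold": k, "accuracy": self.per_cell_type_fold[c, k]}
            for c, ct in enumerate(self.cell_types)
            for k in range(self.K)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"objective": self.objective, "C": self.C, "K": self.K}


def make_folds(true_labels, K: int, seed: int) -> FoldAssignment:
    """Stratified K-fold assignment: each type's cells are spread across
    folds as evenly as possible; deterministic given ``seed``."""
    labels = np.asarray(true_labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    fold_of_cell = np.full(len(labels), -1, dtype=int)
    with warnings.catch_warnings():
        # classes smaller than K are legitimately spread over fewer folds
        warnings.simplefilter("ignore", UserWarning)
        for k, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
            fold_of_cell[test_idx] = k
    return FoldAssignment(fold_of_cell=fold_of_cell, K=K, seed=seed)


def mask_cell_type(S: MarkerSet, cell_type: str) -> MarkerSet:
    """Remove one cell type's marker list from S (LOCTO masking)."""
    return S.drop_type(cell_type)


class CVEvaluator:
    """Reusable LOCTO x K-fold evaluator over one labelled dataset.

    Parameters
    ----------
    X
        Raw counts or normalized expression.
    true_labels
        One label per cell; must cover at least two types.
    K, seed
        Fold count and fold-assignment seed.
    unknown_threshold
        Passed through to label assignment.
    masked_correct_as_unknown
        When True (default), a cell of the masked type counts as correct
        iff predicted "unknown"; when False such cells are always counted
        incorrect (sensitivity analysis).
    """

    def __init__(self, X: ExpressionMatrix, true_labels, K: int = 5, seed: int = 0,
                 unknown_threshold: float = 0.0, scale_factor: float = 1e4,
                 masked_correct_as_unknown: bool = True):
        labels = np.asarray(true_labels, dtype=object)
        if len(labels) != X.n_cells:
            raise ValueError("true_labels must give one label per cell")
        if len(set(labels)) < 2:
            raise ValueError("cross-validation needs at least two cell types")
        if X.layer_tag == "raw":
            X = normalize_counts(X, scale_factor=scale_factor)
        elif X.layer_tag != "normalized":
            raise ValueError("CVEvaluator expects raw or normalized input")
        self.X = X
        self.true_labels = labels
        self.unknown_threshold = unknown_threshold
        self.masked_correct_as_unknown = masked_correct_as_unknown
        self.folds = make_folds(labels, K, seed)
        # per-gene moments across all cells, cached once
        vals = X.dense_rows(np.arange(X.n_genes))
        self._dense = vals
        self._mean = vals.mean(axis=1)
        self._sd = vals.std(axis=1, ddof=1) if X.n_cells > 1 else np.zeros(X.n_genes)
        self._gene_index = dict(X._gene_index)

    # -- scoring with cached moments ------------------------------------
    def _zscores(self, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([self._gene_index[g] for g in genes], dtype=int)
        sd = self._sd[idx]
        z = np.zeros((len(idx), self.X.n_cells))
        nz = sd > 0
        z[nz] = (self._dense[idx[nz]] - self._mean[idx[nz], None]) / sd[nz, None]
        return z, idx

    def predict_labels(self, S: MarkerSet) -> np.ndarray:
        """Annotate all cells with S using the cached moments; equivalent
        to the public :func:`hippotype.annotate` pipeline on this data."""
        universe = [g for g in S.universe if g in self._gene_index]
        if not universe:
            raise ValueError("none of the marker genes are present in the data")
        z, _ = self._zscores(universe)
        theta = specificity_weights(S).vector(universe)
        zt = z * theta[:, None]
        index = {g: i for i, g in enumerate(universe)}
        cell_types = sorted(S.cell_types)
        scores = np.full((len(cell_types), self.X.n_cells), -np.inf)
        any_scored = False
        for r, ct in enumerate(cell_types):
            present = [index[g] for g in S[ct] if g in index]
            if present:
                scores[r] = zt[present].sum(axis=0) / np.sqrt(len(present))
                any_scored = True
        if not any_scored:
            raise ValueError("no cell type has markers available in the data")
        winner = scores.argmax(axis=0)
        top = scores.max(axis=0)
        labels = np.array([cell_types[w] for w in winner], dtype=object)
        labels[top <= self.unknown_threshold] = UNKNOWN_LABEL
        return labels

    def type_fold_accuracies(self, S: MarkerSet, masked_type: str) -> np.ndarray:
        """Accuracies f_{c,k} for one masked type across all K folds."""
        masked = mask_cell_type(S, masked_type)
        pred = self.predict_labels(masked)
        expected = np.where(self.true_labels == masked_type,
                            UNKNOWN_LABEL if self.masked_correct_as_unknown else "__never__",
                            self.true_labels)
        correct = pred == expected
        out = np.empty(self.folds.K)
        for k in range(self.folds.K):
            idx = self.folds.cells_in_fold(k)
            out[k] = correct[idx].mean()
        return out

    def evaluate(self, S: MarkerSet) -> CVReport:
        cell_types = sorted(S.cell_types)
        if len(cell_types) < 2:
            raise ValueError("LOCTO evaluation needs at least two cell types in S")
        acc = np.empty((len(cell_types), self.folds.K))
        for c, ct in enumerate(cell_types):
            acc[c] = self.type_fold_accuracies(S, ct)
        return CVReport(per_cell_type_fold=acc, cell_types=cell_types, K=self.folds.K)

    def objective(self, S: MarkerSet) -> float:
        return self.evaluate(S).objective


def locto_fold_accuracy(X: ExpressionMatrix, true_labels, S: MarkerSet,
                        cell_type: str, fold: FoldAssignment, k: int,
                        unknown_threshold: float = 0.0,
                        masked_correct_as_unknown: bool = True) -> float:
    """Accuracy f_{c,k}: mask ``cell_type``'s markers, annotate, and score
    the held-out fold ``k`` (masked-type cells are correct iff "unknown")."""
    ev = CVEvaluator(X, true_labels, K=fold.K, seed=fold.seed,
                     unknown_threshold=unknown_threshold,
                     masked_correct_as_unknown=masked_correct_as_unknown)
    ev.folds = fold
    return float(ev.type_fold_accuracies(S, cell_type)[k])


def cv_objective(X: ExpressionMatrix, true_labels, S: MarkerSet,
                 K: int = 5, seed: int = 0, **kwargs) -> CVReport:
    """LOCTO x K-fold objective f(S): the grand mean of f_{c,k} over all
    C cell types and K folds. Deterministic given ``seed``."""
    return CVEvaluator(X, true_labels, K=K, seed=seed, **kwargs).evaluate(S)
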