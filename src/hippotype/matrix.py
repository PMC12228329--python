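"""Expression-matrix container and basic preprocessing.

The central container is :class:`ExpressionMatrix`, a genes x cells numeric
matrix with string identifiers on both axes and a ``layer_tag`` recording
which stage of the scoring pipeline the values represent (``raw`` counts,
library-size ``normalized`` log expression, per-gene ``zscore``, or
specificity-``weighted_zscore``).

Values may be a dense :class:`numpy.ndarray` or any scipy sparse matrix;
operations that need dense arithmetic densify only the gene subset they
touch, so restricting to a small marker universe stays cheap even for large
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

LAYER_TAGS = ("raw", "normalized", "zscore", "weighted_zscore")


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell."""


def _as_str_array(ids, name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix.

    Parameters
    ----------
    values
        ``(m, n)`` matrix, dense ndarray or scipy sparse; rows are genes.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    layer_tag
        One of ``raw``, ``normalized``, ``zscore``, ``weighted_zscore``.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer_tag: str = "raw"
    _gene_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        m, n = self.shape
        if m < 1 or n < 1:
            raise ValueError("expression matrix must have >=1 gene and >=1 cell")
        if len(self.gene_ids) != m:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != {m} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"cell_ids length {len(self.cell_ids)} != {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"layer_tag must be one of {LAYER_TAGS}, got {self.layer_tag!r}")
        if self.layer_tag == "raw":
            vmin = self.values.min() if not sp.issparse(self.values) else self.values.data.min(initial=0)
            if vmin < 0:
                raise ValueError("raw layer must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.shape[0]

    @property
    def n_cells(self) -> int:
        return self.shape[1]

    def gene_indices(self, genes) -> np.ndarray:
        """Row indices for ``genes``; raises KeyError listing absent genes."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not present in matrix: {sorted(missing)}")
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def dense_rows(self, idx: np.ndarray) -> np.ndarray:
        """Dense float64 copy of the selected gene rows."""
        sub = self.values[idx, :]
        if sp.issparse(sub):
            sub = sub.toarray()
        return np.asarray(sub, dtype=np.float64)

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        vals = self.values[:, mask_or_idx]
        return replace(self, values=vals, cell_ids=self.cell_ids[mask_or_idx])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])

    # -- per-cell summaries ---------------------------------------------
    def genes_detected(self) -> np.ndarray:
        """Number of genes with nonzero signal per cell."""
        if sp.issparse(self.values):
            return np.asarray((self.values != 0).sum(axis=0)).ravel()
        return (self.values != 0).sum(axis=0)

    def counts_per_cell(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)


def qc_filter(X_raw: ExpressionMatrix, min_genes: int = 200,
              max_umis: float = 20_000) -> ExpressionMatrix:
    """Drop low-complexity and over-sequenced cells.

    Keeps cells with at least ``min_genes`` detected genes and at most
    ``max_umis`` total counts (the defaults are standard nuclear RNA-seq
    thresholds: 200 genes per nucleus, 20,000 nuclear UMIs). Gene set and
    cell order are preserved.
    """
    if X_raw.layer_tag != "raw":
        raise ValueError("qc_filter expects raw counts")
    keep = (X_raw.genes_detected() >= min_genes) & (X_raw.counts_per_cell() <= max_umis)
    if not keep.any():
        raise EmptyResultError(
            f"QC filter (min_genes={min_genes}, max_umis={max_umis}) removed all "
            f"{X_raw.n_cells} cells")
    return X_raw.subset_cells(keep)


def normalize_counts(X_raw: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: scale each cell to ``scale_factor`` total
    counts, then ``log(1 + x)``."""
    if X_raw.layer_tag != "raw":
        raise ValueError("normalize_counts expects raw counts")
    totals = X_raw.counts_per_cell().astype(np.float64)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = list(X_raw.cell_ids[zero[:5]])
        raise ValueError(f"cells with zero total counts cannot be normalized: {names}"
                         + (" ..." if zero.size > 5 else ""))
    scale = scale_factor / totals
    if sp.issparse(X_raw.values):
        vals = X_raw.values.tocsc().astype(np.float64)
        vals = vals.multiply(scale[None, :]).tocsr()
        vals.data = np.log1p(vals.data)
    else:
        vals = np.log1p(np.asarray(X_raw.values, dtype=np.float64) * scale[None, :])
    return replace(X_raw, values=vals, layer_tag="normalized")


def gene_stats(X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and sample standard deviation (ddof=1) across all cells.

    For a single cell the sd is defined as zero.
    """
    n = X.n_cells
    if sp.issparse(X.values):
        v = X.values.tocsr()
        mean = np.asarray(v.mean(axis=1)).ravel()
        sq = np.asarray(v.multiply(v).sum(axis=1)).ravel()
        if n > 1:
            var = (sq - n * mean ** 2) / (n - 1)
            var = np.maximum(var, 0.0)
        else:
            var = np.zeros_like(mean)
        sd = np.sqrt(var)
    else:
        vals = np.asarray(X.values, dtype=np.float64)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)
    return mean, sd


def zscore_genes(X: ExpressionMatrix, restrict_to=None) -> ExpressionMatrix:
    """Standardize each gene across all cells: ``(x - mean) / sd`` with
    sample sd (ddof=1).

    ``restrict_to`` selects a gene subset (typically the marker universe)
    before standardization; means and sds are still computed across all
    cells. Genes with zero variance map to all-zero rows.
    """
    if X.layer_tag not in ("normalized", "raw"):
        raise ValueError(f"zscore_genes expects raw or normalized input, got {X.layer_tag}")
    if restrict_to is None:
        idx = np.arange(X.n_genes)
        genes = X.gene_ids
    else:
        idx = X.gene_indices(restrict_to)
        genes = np.asarray(list(restrict_to), dtype=object)
    sub = X.dense_rows(idx)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1) if X.n_cells > 1 else np.zeros_like(mean)
    nz = sd > 0
    z = np.zeros_like(sub)
    z[nz] = (sub[nz] - mean[nz, None]) / sd[nz, None]
    return ExpressionMatrix(z, genes, X.cell_ids, layer_tag="zscore")
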