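"""Marker-set container and gene specificity weights.

A marker set assigns each cell type an ordered list of marker genes. The
same gene may mark several cell types; its specificity weight theta is then
reduced accordingly, so that promiscuous markers contribute less to the
enrichment score than genes private to one type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SIZE_BOUNDS = (1, 30)


@dataclass(frozen=True)
class MarkerSet:
    """Mapping cell type -> ordered marker gene list for one tissue.

    ``size_bounds`` record the admissible per-type set sizes used during
    optimization (default 1-30 markers per type); they are only enforced
    when :meth:`check_bounds` is called, so hand-written sets of any size
    can still be scored.
    """

    tissue_tag: str
    per_type_markers: dict[str, tuple[str, ...]]
    size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS

    def __post_init__(self):
        if not self.per_type_markers:
            raise ValueError("MarkerSet must contain at least one cell type")
        frozen = {}
        for ct, genes in self.per_type_markers.items():
            genes = tuple(genes)
            if not genes:
                raise ValueError(f"cell type {ct!r} has an empty marker list")
            if len(set(genes)) != len(genes):
                raise ValueError(f"cell type {ct!r} has duplicate marker genes")
            frozen[ct] = genes
        object.__setattr__(self, "per_type_markers", frozen)
        k_min, k_max = self.size_bounds
        if not (1 <= k_min <= k_max):
            raise ValueError(f"invalid size_bounds {self.size_bounds}")

    # -- accessors ------------------------------------------------------
    @property
    def cell_types(self) -> list[str]:
        return list(self.per_type_markers)

    @property
    def n_types(self) -> int:
        return len(self.per_type_markers)

    def __getitem__(self, cell_type: str) -> tuple[str, ...]:
        return self.per_type_markers[cell_type]

    def __contains__(self, cell_type: str) -> bool:
        return cell_type in self.per_type_markers

    @property
    def universe(self) -> list[str]:
        """Sorted union of all per-type marker genes (the tissue universe)."""
        out = set()
        for genes in self.per_type_markers.values():
            out.update(genes)
        return sorted(out)

    def check_bounds(self) -> None:
        k_min, k_max = self.size_bounds
        for ct, genes in self.per_type_markers.items():
            if not (k_min <= len(genes) <= k_max):
                raise ValueError(
                    f"cell type {ct!r} has {len(genes)} markers, outside "
                    f"bounds [{k_min}, {k_max}]")

    # -- editing --------------------------------------------------------
    def drop_type(self, cell_type: str) -> "MarkerSet":
        """Remove one cell type's markers (genes shared with other types
        remain in those types)."""
        if cell_type not in self.per_type_markers:
            raise KeyError(f"cell type {cell_type!r} not in marker set")
        remaining = {ct: g for ct, g in self.per_type_markers.items() if ct != cell_type}
        if not remaining:
            raise ValueError(f"masking {cell_type!r} would leave an empty marker set")
        return MarkerSet(self.tissue_tag, remaining, self.size_bounds)

    def with_type(self, cell_type: str, genes) -> "MarkerSet":
        new = dict(self.per_type_markers)
        new[cell_type] = tuple(genes)
        return MarkerSet(self.tissue_tag, new, self.size_bounds)

    def normalized(self) -> "MarkerSet":
        """Canonical form: types and genes sorted, for order-insensitive
        comparison."""
        return MarkerSet(
            self.tissue_tag,
            {ct: tuple(sorted(self.per_type_markers[ct]))
             for ct in sorted(self.per_type_markers)},
            self.size_bounds)


@dataclass
class SpecificityWeights:
    """Per-gene specificity weights theta in [0, 1] with the underlying
    occurrence counts (number of cell types carrying each gene)."""

    theta: dict[str, float]
    occurrence: dict[str, int]

    def vector(self, genes) -> np.ndarray:
        return np.array([self.theta[g] for g in genes], dtype=np.float64)


def specificity_weights(S: MarkerSet) -> SpecificityWeights:
    """Compute theta_i for every gene in the marker universe of ``S``.

    With n_i the number of cell types whose marker list contains gene i,

        theta_i = (1/n_i - min_j 1/n_j) / (max_j 1/n_j - min_j 1/n_j)

    which rescales to [0, 1] so that genes appearing in fewer cell types
    receive higher weight. When every gene occurs in the same number of
    types the formula is 0/0; all genes are then treated as maximally
    informative (theta = 1).
    """
    occ: dict[str, int] = {}
    for genes in S.per_type_markers.values():
        for g in genes:
            occ[g] = occ.get(g, 0) + 1
    inv = {g: 1.0 / n for g, n in occ.items()}
    lo, hi = min(inv.values()), max(inv.values())
    if hi == lo:
        theta = {g: 1.0 for g in occ}
    else:
        theta = {g: (v - lo) / (hi - lo) for g, v in inv.items()}
    return SpecificityWeights(theta=theta, occurrence=occ)
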