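"""Bayesian optimization of marker gene sets.

The search space is combinatorial: an assignment of between k_min and
k_max genes (from a candidate pool, typically highly variable genes) to
each cell type. Even modest instances are astronomically large --
:func:`count_configurations` computes the exact count -- so the optimizer
navigates with:

* an EM-style proposal step (:func:`em_propose`): annotate cells with the
  current marker set (E-step), rank candidate genes per type by how
  specifically they light up in that type's assigned cells (M-step), and
  mutate the current set toward top-ranked genes;
* a Gaussian-process surrogate over the set kernel, with the Expected
  Improvement acquisition selecting which proposed candidate to spend the
  next cross-validation evaluation on.

The objective is the LOCTO x K-fold accuracy from :mod:`hippotype.cv`.
All randomness flows from a single seed; identical seeds give bit-identical
traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, getcontext

import numpy as np

from .cv import CVEvaluator
from .gp import GPState, gp_fit, ei_closed_form
from .markers import MarkerSet
from .matrix import ExpressionMatrix, normalize_counts


def count_configurations(pool_size: int, k_min: int, k_max: int, n_types: int) -> float:
    """log10 of the exact number of joint marker-set configurations.

    Each of ``n_types`` cell types independently picks between ``k_min``
    and ``k_max`` genes from a pool of ``pool_size``, so the count is
    ``(sum_k C(pool_size, k)) ** n_types``, evaluated in exact integer
    arithmetic before taking log10.
    """
    if not (pool_size >= k_max >= k_min >= 1):
        raise ValueError("need pool_size >= k_max >= k_min >= 1")
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    per_type = sum(math.comb(pool_size, k) for k in range(k_min, k_max + 1))
    total = per_type ** n_types
    getcontext().prec = 50
    return float(Decimal(total).log10())


@dataclass
class OptimizationResult:
    """Outcome of one optimization run."""

    best_set: MarkerSet
    best_objective: float
    trace: list[dict] = field(default_factory=list)
    budget_used: int = 0
    seed: int = 0

    def running_best(self) -> np.ndarray:
        return np.array([rec["f_best"] for rec in self.trace])


# ---------------------------------------------------------------------------
# M-step specificity statistic
# ---------------------------------------------------------------------------

def _group_mean_z(Z: np.ndarray, labels: np.ndarray, cell_types: list[str]) -> np.ndarray:
    """(genes x types) mean z-score within each label group; NaN columns
    for groups with no cells."""
    M = np.full((Z.shape[0], len(cell_types)), np.nan)
    for c, ct in enumerate(cell_types):
        mask = labels == ct
        if mask.any():
            M[:, c] = Z[:, mask].mean(axis=1)
    return M


def marker_statistic(Z: np.ndarray, labels: np.ndarray, cell_types: list[str]) -> np.ndarray:
    """Specificity statistic per (gene, type): mean z within the type's
    cells minus the highest mean z in any other type.

    Positive values flag genes elevated specifically in that type; the
    statistic drives both optimizer initialization and the M-step gene
    ranking.
    """
    M = _group_mean_z(Z, labels, cell_types)
    C = M.shape[1]
    stat = np.full_like(M, np.nan)
    filled = np.where(np.isnan(M), -np.inf, M)
    order = np.argsort(filled, axis=1)
    top_idx = order[:, -1]
    top = filled[np.arange(len(M)), top_idx]
    second = filled[np.arange(len(M)), order[:, -2]] if C > 1 else np.full(len(M), -np.inf)
    for c in range(C):
        if np.isnan(M[:, c]).all():
            continue
        max_other = np.where(top_idx == c, second, top)
        stat[:, c] = M[:, c] - max_other
    return stat


# ---------------------------------------------------------------------------
# EM proposal machinery
# ---------------------------------------------------------------------------

def _top_weighted_choice(rng: np.random.Generator, ranked: list[str],
                         top_k: int = 10, decay: float = 0.6) -> str:
    """Draw from the best-ranked entries with geometrically decaying
    weights, so the top gene is chosen most often but not always."""
    pool = ranked[:top_k]
    w = decay ** np.arange(len(pool))
    return pool[rng.choice(len(pool), p=w / w.sum())]


def _mutate(rng: np.random.Generator, S: MarkerSet, cell_type: str,
            ranked_non_members: list[str], current_order: list[str]) -> MarkerSet:
    """One seeded mutation of a single type's marker list.

    Moves are quality-aware and of variable strength: swap the
    lowest-ranked current markers for highly ranked outsiders, prune a
    block of the weakest markers, or add top outsiders -- always within
    the size bounds. Multi-gene prunes matter: removing several
    uninformative markers at once both helps the 1/sqrt(k)-scaled score
    and moves the candidate far enough in set space for the surrogate to
    consider it.
    """
    k_min, k_max = S.size_bounds
    genes = list(S[cell_type])
    n_edits = min(int(rng.geometric(0.5)), 4)  # 1 w.p. 1/2, 2 w.p. 1/4, ...
    op = rng.choice(["swap", "drop", "add"], p=[0.45, 0.35, 0.2])
    if op == "drop" and len(genes) <= k_min:
        op = "swap"
    if op == "add" and len(genes) >= k_max:
        op = "swap" if ranked_non_members else "drop"
    if not ranked_non_members and op in ("swap", "add"):
        if len(genes) <= k_min:
            return S
        op = "drop"
    if op == "swap":
        r = min(n_edits, len(current_order))
        worst = current_order[-r:]
        new = []
        for _ in range(r):
            g = _top_weighted_choice(rng, [x for x in ranked_non_members
                                           if x not in new])
            new.append(g)
        genes = [g for g in genes if g not in set(worst)] + new
    elif op == "add":
        r = min(n_edits, k_max - len(genes), len(ranked_non_members))
        new = []
        for _ in range(r):
            g = _top_weighted_choice(rng, [x for x in ranked_non_members
                                           if x not in new])
            new.append(g)
        genes = genes + new
    else:
        r = min(n_edits, len(genes) - k_min)
        worst = set(current_order[-r:]) if r > 0 else set()
        genes = [g for g in genes if g not in worst]
    return S.with_type(cell_type, genes)


class _EMContext:
    """Cached z-scores over the candidate pool for repeated EM proposals."""

    def __init__(self, evaluator: CVEvaluator, pool: list[str]):
        self.evaluator = evaluator
        self.pool = list(pool)
        self.Z, _ = evaluator._zscores(self.pool)
        self.pool_index = {g: i for i, g in enumerate(self.pool)}
        self._rank_cache: tuple | None = None  # (incumbent key, rankings)

    def rankings(self, labels: np.ndarray, cell_types: list[str]) -> dict[str, list[str]]:
        """Per-type candidate genes sorted by descending specificity
        statistic under the given cell assignment."""
        stat = marker_statistic(self.Z, labels, cell_types)
        out = {}
        for c, ct in enumerate(cell_types):
            col = stat[:, c]
            if np.isnan(col).all():
                out[ct] = None
                continue
            order = np.argsort(-np.where(np.isnan(col), -np.inf, col), kind="stable")
            out[ct] = [self.pool[i] for i in order]
        return out

    def propose(self, S: MarkerSet, n_candidates: int,
                rng: np.random.Generator) -> list[MarkerSet]:
        if n_candidates == 0:
            return []
        cell_types = sorted(S.cell_types)
        key = tuple((ct, tuple(sorted(S[ct]))) for ct in cell_types)
        if self._rank_cache is not None and self._rank_cache[0] == key:
            ranked = self._rank_cache[1]
        else:
            labels = self.evaluator.predict_labels(S)      # E-step
            ranked = self.rankings(labels, cell_types)     # M-step
            self._rank_cache = (key, ranked)
        mutable = [ct for ct in cell_types if ranked[ct] is not None]
        for ct in cell_types:
            if ranked[ct] is None:
                warnings.warn(f"cell type {ct!r} has no assigned cells; its "
                              "markers are left unchanged", stacklevel=3)
        if not mutable:
            return [S] * n_candidates
        candidates = []
        for _ in range(n_candidates):
            ct = mutable[rng.integers(0, len(mutable))]
            members = set(S[ct])
            non_members = [g for g in ranked[ct] if g not in members]
            cur_order = sorted(S[ct], key=lambda g: ranked[ct].index(g)
                               if g in self.pool_index else len(ranked[ct]))
            candidates.append(_mutate(rng, S, ct, non_members, cur_order))
        return candidates


def em_propose(X: ExpressionMatrix, S_current: MarkerSet, n_candidates: int,
               seed: int, pool=None, true_labels=None) -> list[MarkerSet]:
    """Standalone EM proposal step.

    Annotates ``X`` with ``S_current``, ranks pool genes per cell type by
    the specificity statistic of the induced assignment, and returns
    ``n_candidates`` seeded mutations of ``S_current`` (all respecting its
    size bounds). ``pool`` defaults to all genes of ``X``; ``true_labels``
    is only needed to build the internal evaluator and defaults to the
    induced assignment itself.
    """
    if n_candidates == 0:
        return []
    if X.layer_tag == "raw":
        X = normalize_counts(X)
    pool = list(pool) if pool is not None else list(X.gene_ids)
    if true_labels is None:
        # a label vector is needed for the evaluator's folds; the E-step
        # assignment is what the M-step conditions on anyway
        dummy = np.array(sorted(S_current.cell_types) * (X.n_cells // S_current.n_types + 1))
        true_labels = dummy[:X.n_cells]
    ev = CVEvaluator(X, true_labels, K=2, seed=seed)
    ctx = _EMContext(ev, pool)
    rng = np.random.default_rng(seed)
    return ctx.propose(S_current, n_candidates, rng)


# ---------------------------------------------------------------------------
# Main optimization loop
# ---------------------------------------------------------------------------

def _initial_set(ctx: _EMContext, true_labels: np.ndarray, cell_types: list[str],
                 bounds: tuple[int, int], tissue_tag: str) -> MarkerSet:
    """Data-driven starting point: per type, the top-(k_max // 2) pool
    genes by the specificity statistic computed on the true labels."""
    k_min, k_max = bounds
    k_init = min(k_max, max(k_min, k_max // 2))
    ranked = ctx.rankings(np.asarray(true_labels, dtype=object), cell_types)
    per_type = {}
    for ct in cell_types:
        if ranked[ct] is None:
            raise ValueError(f"cell type {ct!r} has no cells in true_labels")
        per_type[ct] = tuple(ranked[ct][:k_init])
    return MarkerSet(tissue_tag, per_type, size_bounds=bounds)


def _prepare(X, true_labels, pool, bounds, K, cv_seed, unknown_threshold,
             tissue_tag):
    labels = np.asarray(true_labels, dtype=object)
    cell_types = sorted(set(labels))
    k_min, k_max = bounds
    pool = list(pool)
    missing = [g for g in pool if g not in X._gene_index]
    if missing:
        raise KeyError(f"pool genes absent from matrix: {sorted(missing)[:5]}")
    if len(pool) < len(cell_types) * k_min:
        raise ValueError(
            f"pool of {len(pool)} genes cannot fill {len(cell_types)} types "
            f"with at least {k_min} markers each")
    ev = CVEvaluator(X, labels, K=K, seed=cv_seed,
                     unknown_threshold=unknown_threshold)
    ctx = _EMContext(ev, pool)
    S0 = _initial_set(ctx, labels, cell_types, bounds, tissue_tag)
    return ev, ctx, S0, labels


def optimize_markers(X: ExpressionMatrix, true_labels, pool,
                     bounds: tuple[int, int] = (1, 30), budget: int = 300,
                     seed: int = 0, *, K: int = 5, n_candidates: int = 32,
                     gamma: float = 1.0, noise_var: float = 1e-4,
                     unknown_threshold: float = 0.0,
                     tissue_tag: str = "optimized") -> OptimizationResult:
    """Search for the marker set maximizing the LOCTO x K-fold objective.

    Starts from the data-driven initial set, then spends ``budget``
    objective evaluations: each iteration proposes ``n_candidates`` EM
    mutations of the incumbent, scores their Expected Improvement under
    the GP surrogate, and evaluates the acquisition winner.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    rng = np.random.default_rng(seed)
    ev, ctx, S0, labels = _prepare(X, true_labels, pool, bounds, K,
                                   int(rng.integers(2 ** 31)),
                                   unknown_threshold, tissue_tag)
    f0 = ev.objective(S0)
    best_set, f_best = S0, f0
    trace = [{"iteration": 0, "objective": f0, "f_best": f0, "accepted": True}]
    gp: GPState | None = None
    used = 0
    for t in range(1, budget + 1):
        candidates = ctx.propose(best_set, n_candidates, rng)
        if gp is None:
            # no surrogate yet: evaluate a random candidate to seed the GP
            S_next = candidates[rng.integers(0, len(candidates))]
        else:
            ei = np.array([ei_closed_form(*gp.posterior(c), gp.f_best)
                           for c in candidates])
            top = np.flatnonzero(ei == ei.max())
            S_next = candidates[top[rng.integers(0, len(top))]]
        f = ev.objective(S_next)
        used += 1
        if gp is None:
            gp = gp_fit([(S0, f0), (S_next, f)], gamma=gamma, noise_var=noise_var)
        else:
            gp = gp.with_observation(S_next, f)
        accepted = f > f_best
        if accepted:
            best_set, f_best = S_next, f
        trace.append({"iteration": t, "objective": f, "f_best": f_best,
                      "accepted": bool(accepted)})
    return OptimizationResult(best_set=best_set, best_objective=f_best,
                              trace=trace, budget_used=used, seed=seed)


def random_search_markers(X: ExpressionMatrix, true_labels, pool,
                          bounds: tuple[int, int] = (1, 30), budget: int = 300,
                          seed: int = 0, *, K: int = 5,
                          unknown_threshold: float = 0.0,
                          tissue_tag: str = "random-search") -> OptimizationResult:
    """Equal-budget baseline: same initialization, but each iteration
    applies one uniformly random mutation (random type, random swap/add/
    drop with a uniformly random pool gene) and evaluates it directly."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    rng = np.random.default_rng(seed)
    ev, ctx, S0, labels = _prepare(X, true_labels, pool, bounds, K,
                                   int(rng.integers(2 ** 31)),
                                   unknown_threshold, tissue_tag)
    f0 = ev.objective(S0)
    best_set, f_best = S0, f0
    trace = [{"iteration": 0, "objective": f0, "f_best": f0, "accepted": True}]
    k_min, k_max = bounds
    cell_types = sorted(set(np.asarray(true_labels, dtype=object)))
    for t in range(1, budget + 1):
        ct = cell_types[rng.integers(0, len(cell_types))]
        genes = list(best_set[ct])
        op = rng.choice(["swap", "add", "drop"])
        non_members = [g for g in ctx.pool if g not in set(genes)]
        if (op == "add" and len(genes) >= k_max) or not non_members:
            op = "drop"
        if op == "drop" and len(genes) <= k_min:
            op = "swap"
        if op == "swap":
            genes[rng.integers(0, len(genes))] = non_members[rng.integers(0, len(non_members))]
        elif op == "add":
            genes.append(non_members[rng.integers(0, len(non_members))])
        else:
            genes.pop(rng.integers(0, len(genes)))
        S_next = best_set.with_type(ct, genes)
        f = ev.objective(S_next)
        accepted = f > f_best
        if accepted:
            best_set, f_best = S_next, f
        trace.append({"iteration": t, "objective": f, "f_best": f_best,
                      "accepted": bool(accepted)})
    return OptimizationResult(best_set=best_set, best_objective=f_best,
                              trace=trace, budget_used=budget, seed=seed)
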