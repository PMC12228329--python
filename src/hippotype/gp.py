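"""Gaussian-process surrogate over marker sets and Expected Improvement.

Marker sets live in a discrete combinatorial space, so the GP uses a
set-similarity kernel: the mean per-cell-type Jaccard similarity J between
two marker sets, mapped through an exponential,

    k(S, S') = exp(-gamma * (1 - J(S, S'))),

which is symmetric, equals 1 at S = S' and stays positive. Regression is
standard GP with homoskedastic observation noise and a constant prior mean
set to the mean of the observed objectives.

Expected Improvement is the usual closed form

    EI = sigma * (z * Phi(z) + phi(z)),   z = (mu - f_best) / sigma,

reducing to max(0, mu - f_best) when sigma = 0. A stratified Monte-Carlo
integrator of the defining integral E[max(0, f - f_best)] is provided as
an independent numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import ndtr, ndtri

from .markers import MarkerSet

_JITTER = 1e-10


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def mean_jaccard(S: MarkerSet, S2: MarkerSet) -> float:
    """Mean over cell types of the per-type Jaccard marker overlap."""
    if set(S.cell_types) != set(S2.cell_types):
        raise ValueError("marker sets name different cell types")
    return float(np.mean([
        _jaccard(frozenset(S[ct]), frozenset(S2[ct])) for ct in S.cell_types]))


def set_kernel(S: MarkerSet, S2: MarkerSet, gamma: float = 1.0) -> float:
    """Exponential mean-Jaccard kernel; 1 at identity, exp(-gamma) for
    fully disjoint per-type sets."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * (1.0 - mean_jaccard(S, S2))))


def _freeze(S: MarkerSet) -> dict[str, frozenset]:
    return {ct: frozenset(S[ct]) for ct in S.cell_types}


def _kernel_frozen(a: dict, b: dict, gamma: float) -> float:
    j = np.mean([_jaccard(a[ct], b[ct]) for ct in a])
    return float(np.exp(-gamma * (1.0 - j)))


@dataclass
class GPState:
    """Fitted GP over observed (marker set, objective) pairs."""

    sets: list[MarkerSet]
    y: np.ndarray
    kernel_gamma: float = 1.0
    noise_var: float = 1e-4
    prior_mean: float | None = None  # constant mean; None = mean of observed y
    _frozen: list = field(default=None, repr=False)
    _gram: np.ndarray = field(default=None, repr=False)
    _cho: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    _ymean: float = field(default=0.0, repr=False)

    @property
    def f_best(self) -> float:
        return float(self.y.max())

    @property
    def history(self) -> list[tuple[MarkerSet, float]]:
        return list(zip(self.sets, self.y.tolist()))

    def _fit(self, gram: np.ndarray | None = None) -> "GPState":
        t = len(self.sets)
        self._frozen = [_freeze(s) for s in self.sets]
        if gram is None:
            gram = np.empty((t, t))
            for i in range(t):
                gram[i, i] = 1.0
                for j in range(i):
                    gram[i, j] = gram[j, i] = _kernel_frozen(
                        self._frozen[i], self._frozen[j], self.kernel_gamma)
        self._gram = gram
        A = gram + (self.noise_var + _JITTER) * np.eye(t)
        try:
            self._cho = cho_factor(A, lower=True)
        except LinAlgError:
            try:
                self._cho = cho_factor(A + 1e-6 * np.eye(t), lower=True)
            except LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "Gram matrix is singular despite jitter") from err
        self._ymean = float(self.y.mean()) if self.prior_mean is None else self.prior_mean
        self._alpha = cho_solve(self._cho, self.y - self._ymean)
        return self

    def _cross(self, S: MarkerSet) -> np.ndarray:
        fz = _freeze(S)
        return np.array([_kernel_frozen(fz, f, self.kernel_gamma) for f in self._frozen])

    def posterior(self, S: MarkerSet) -> tuple[float, float]:
        """Posterior mean and sd of the latent objective at ``S``."""
        k = self._cross(S)
        mu = self._ymean + k @ self._alpha
        v = cho_solve(self._cho, k)
        var = 1.0 - k @ v
        return float(mu), float(np.sqrt(max(var, 0.0)))

    def with_observation(self, S: MarkerSet, f: float) -> "GPState":
        """New fitted state with one more observation; the Gram matrix is
        extended incrementally rather than recomputed."""
        k = self._cross(S)
        t = len(self.sets)
        gram = np.empty((t + 1, t + 1))
        gram[:t, :t] = self._gram
        gram[t, :t] = gram[:t, t] = k
        gram[t, t] = 1.0
        new = GPState(sets=self.sets + [S], y=np.append(self.y, f),
                      kernel_gamma=self.kernel_gamma, noise_var=self.noise_var,
                      prior_mean=self.prior_mean)
        return new._fit(gram=gram)


def gp_fit(history, gamma: float = 1.0, noise_var: float = 1e-4,
           prior_mean: float | None = None) -> GPState:
    """Fit the set-kernel GP to a history of (MarkerSet, objective) pairs.

    ``prior_mean`` fixes the constant GP mean; by default it tracks the
    mean of the observed objectives.
    """
    history = list(history)
    if len(history) < 2:
        raise ValueError("gp_fit needs at least two observations")
    if noise_var <= 0:
        raise ValueError("noise_var must be positive")
    sets = [s for s, _ in history]
    y = np.array([f for _, f in history], dtype=np.float64)
    return GPState(sets=sets, y=y, kernel_gamma=gamma, noise_var=noise_var,
                   prior_mean=prior_mean)._fit()


def ei_closed_form(mu: float, sigma: float, f_best: float) -> float:
    """Closed-form Expected Improvement of N(mu, sigma^2) over f_best."""
    if sigma <= 0:
        return max(0.0, mu - f_best)
    z = (mu - f_best) / sigma
    phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
    return float(max(0.0, sigma * (z * ndtr(z) + phi)))


def ei_monte_carlo(mu: float, sigma: float, f_best: float,
                   n_samples: int = 1_000_000, seed: int = 0,
                   stratified: bool = True) -> float:
    """Monte-Carlo evaluation of EI = E[max(0, f - f_best)], f ~ N(mu, sigma^2).

    With ``stratified=True`` one uniform draw is taken per equal-probability
    stratum, which collapses the integration error well below the sampling
    noise of plain Monte Carlo at the same sample count.
    """
    if sigma <= 0:
        return max(0.0, mu - f_best)
    rng = np.random.default_rng(seed)
    if stratified:
        u = (np.arange(n_samples) + rng.uniform(size=n_samples)) / n_samples
        f = mu + sigma * ndtri(u)
    else:
        f = mu + sigma * rng.standard_normal(n_samples)
    return float(np.maximum(0.0, f - f_best).mean())


def expected_improvement(gp: GPState, S: MarkerSet) -> float:
    """EI of candidate ``S`` under the fitted GP posterior."""
    mu, sd = gp.posterior(S)
    return ei_closed_form(mu, sd, gp.f_best)
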