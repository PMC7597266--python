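"""Finite-variant population state, Boltzmann selection, and diversity
and genetic-load diagnostics.

A population of K unique variants carries phenotypes ``x_i`` (rows of
X), growth rates (fitness) ``f_i = f(x_i)`` and base frequencies
``p_i(0)``.  Deterministic selection for a time/scale ``t`` multiplies
each frequency by ``exp(t f_i)``; the normalized result is the Boltzmann
distribution over variants.  On the manifold of categorical
distributions this flow is the natural gradient of mean fitness with
respect to the Fisher information metric.

Entropy is reported in bits throughout; the natural-log/bits conversion
lives in :func:`entropy_and_diversity` only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "SelectionState",
    "boltzmann_weights",
    "entropy_and_diversity",
    "weighted_moments",
    "load_diagnostics",
    "replicator_flow",
    "natural_gradient_check",
    "population_table",
]

#: tolerance for accepting an input weight vector as normalized
NORM_TOL = 1e-9


@dataclass
class Population:
    """K variants: K×D phenotypes X, fitness vector f, base frequencies p0."""

    X: np.ndarray
    f: np.ndarray
    p0: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.f = np.asarray(self.f, dtype=float).ravel()
        self.p0 = np.asarray(self.p0, dtype=float).ravel()
        K = self.X.shape[0]
        if self.f.size != K or self.p0.size != K:
            raise ValueError("X rows, f and p0 must have matching length")
        if np.any(np.isnan(self.f)):
            raise ValueError("fitness values must not be NaN")
        if np.any(self.p0 < -NORM_TOL) or abs(self.p0.sum() - 1.0) > NORM_TOL:
            raise ValueError("p0 must be nonnegative and sum to 1")
        self.p0 = np.clip(self.p0, 0.0, None)
        self.p0 = self.p0 / self.p0.sum()

    @classmethod
    def uniform(cls, X: np.ndarray, f: np.ndarray) -> "Population":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = X.shape[0]
        return cls(X=X, f=f, p0=np.full(K, 1.0 / K))

    @property
    def size(self) -> int:
        return self.X.shape[0]

    @property
    def dimension(self) -> int:
        return self.X.shape[1]


@dataclass
class SelectionState:
    """Boltzmann weights at selection scale t, with diversity summaries.

    ``t`` has units of inverse fitness; ``K_eff = 2**entropy_bits`` is
    the effective number of variants, between 1 and K.
    """

    t: float
    p: np.ndarray
    entropy_bits: float
    K_eff: float


def _check_weights(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < -NORM_TOL) or abs(p.sum() - 1.0) > NORM_TOL:
        raise ValueError("weight vector must be normalized and nonnegative")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def entropy_and_diversity(p: np.ndarray) -> tuple[float, float]:
    """Shannon entropy in bits and effective variant count 2**S.

    Uses the convention 0 log 0 = 0.  Rejects unnormalized input.
    """
    p = _check_weights(p)
    nz = p[p > 0.0]
    S = float(-np.sum(nz * np.log2(nz)))
    return S, 2.0 ** S


def boltzmann_weights(pop: Population, t: float) -> SelectionState:
    """Selection weights ``p_i(t) ∝ p_i(0) exp(t f_i)``.

    Computed in log space with the maximum of ``t f`` subtracted before
    exponentiation, so the normalizer is never formed un-shifted and the
    result cannot overflow for any finite t.
    """
    if not np.isfinite(t) or t < 0.0:
        raise ValueError("selection scale t must be finite and >= 0")
    if np.any(np.isnan(pop.f)):
        raise ValueError("fitness values must not be NaN")
    with np.errstate(divide="ignore"):
        logw = np.where(pop.p0 > 0.0, np.log(np.clip(pop.p0, 1e-300, None)), -np.inf)
    logw = logw + t * pop.f
    logw -= logw.max()
    w = np.exp(logw)
    p = w / w.sum()
    S, K_eff = entropy_and_diversity(p)
    return SelectionState(t=float(t), p=p, entropy_bits=S, K_eff=K_eff)


def weighted_moments(
    pop: Population, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Weighted phenotype mean μ, covariance Σ, mean fitness F and
    fitness variance under the weights p."""
    p = _check_weights(p)
    mu = p @ pop.X
    Xc = pop.X - mu
    Sigma = Xc.T @ (Xc * p[:, None])
    F = float(p @ pop.f)
    varF = float(p @ (pop.f - F) ** 2)
    return mu, Sigma, F, varF


def load_diagnostics(pop: Population, state: SelectionState) -> tuple[float, float]:
    """Scaled genetic load ``t (F† − F)`` and scaled fitness variance
    ``t² var(f)``, both unit-less.

    F† is the maximum *observed* fitness in the population.  The scaled
    load vanishes both at t=0 and when selection has concentrated all
    weight on the best variant, and peaks at intermediate selection.
    """
    _, _, F, varF = weighted_moments(pop, state.p)
    scaled_load = state.t * (float(pop.f.max()) - F)
    scaled_varF = state.t ** 2 * varF
    return scaled_load, scaled_varF


def replicator_flow(p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Instantaneous frequency change under selection, p_i (f_i − F)."""
    p = _check_weights(p)
    f = np.asarray(f, dtype=float).ravel()
    F = p @ f
    return p * (f - F)


def natural_gradient_check(p: np.ndarray, f: np.ndarray) -> float:
    """Max deviation between the natural-gradient flow and replicator flow.

    On the (K−1)-simplex the categorical family has Fisher metric
    ``g_ab = δ_ab / p_a + 1 / p_K`` in the coordinates of the first K−1
    frequencies.  The natural gradient ``g⁻¹ ∇_p F`` of mean fitness
    (with ``∇_a F = f_a − f_K`` after eliminating p_K) is computed by an
    explicit solve and compared entrywise to :func:`replicator_flow`
    restricted to the free coordinates.
    """
    p = _check_weights(p)
    f = np.asarray(f, dtype=float).ravel()
    K = p.size
    if K < 2:
        raise ValueError("need at least two variants")
    if np.any(p <= 0.0):
        raise ValueError("Fisher metric is singular when some p_i = 0")
    a = p[:-1]
    g = np.diag(1.0 / a) + 1.0 / p[-1]
    grad = f[:-1] - f[-1]
    nat = np.linalg.solve(g, grad)
    flow = replicator_flow(p, f)[:-1]
    return float(np.max(np.abs(nat - flow)))


def population_table(pop: Population, p: np.ndarray | None = None) -> pd.DataFrame:
    """One row per variant: phenotype coordinates, fitness, weight."""
    cols = {f"x{j+1}": pop.X[:, j] for j in range(pop.dimension)}
    cols["fitness"] = pop.f
    cols["weight"] = _check_weights(p) if p is not None else pop.p0
    return pd.DataFrame(cols)
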