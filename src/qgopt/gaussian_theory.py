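"""Closed-form selection dynamics for Gaussian phenotype distributions
on quadratic fitness landscapes.

If phenotypes are normally distributed with mean μ0 and covariance Σ0
and fitness is quadratic with curvature C (negative fitness Hessian),
the population stays Gaussian under deterministic selection for time t:

    Σ_t⁻¹ = Σ0⁻¹ + t C
    μ_t − μ0 = (Σ0⁻¹ / t + C)⁻¹ ∇f        (∇f evaluated at μ0)

At small t the mean shift reduces to the quantitative-genetics response
``t Σ0 ∇f``; as t → ∞ it tends to the Newton step ``C⁻¹ ∇f``, which on a
quadratic lands exactly on the optimum.  This module also provides the
continuous genetic-load formula for Gaussian populations and the
expected fitness cost of isotropic-in-genotype ("blind") mutation.

Everything here is a theory and diagnostics layer: it factorizes small
matrices freely, which the derivative-free optimizer itself never does.
For non-quadratic landscapes the formulas are local approximations with
∇f and C frozen at μ0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve

from .landscapes import FitnessLandscape

__all__ = [
    "GaussianPopulation",
    "propagate",
    "newton_limit",
    "continuous_load",
    "expected_mutation_cost",
]


@dataclass
class GaussianPopulation:
    """Normal phenotype distribution with mean mu and covariance Sigma."""

    mu: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        D = self.mu.size
        if self.Sigma.shape != (D, D):
            raise ValueError("Sigma shape must match mu")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc

    @property
    def dimension(self) -> int:
        return self.mu.size


def propagate(
    g0: GaussianPopulation, land: FitnessLandscape, t: float
) -> GaussianPopulation:
    """Evolve a Gaussian population under selection for time t.

    ∇f and C are evaluated at the current mean and held fixed, which is
    exact on a pure quadratic.  Raises if ``Σ0⁻¹ + tC`` is not positive
    definite (invalid landscape/time combination).
    """
    if t < 0.0:
        raise ValueError("t must be >= 0")
    if land.gradient is None or land.curvature is None:
        raise ValueError("landscape must provide gradient and curvature")
    if t == 0.0:
        return GaussianPopulation(g0.mu.copy(), g0.Sigma.copy())
    grad = np.asarray(land.gradient(g0.mu), dtype=float)
    C = np.asarray(land.curvature(g0.mu), dtype=float)
    D = g0.dimension
    # Sigma_t = (Sigma0^-1 + t C)^-1 = (I + t Sigma0 C)^-1 Sigma0,
    # computed by linear solve; symmetrized against roundoff.
    B = np.eye(D) + t * g0.Sigma @ C
    Sigma_t = solve(B, g0.Sigma)
    Sigma_t = 0.5 * (Sigma_t + Sigma_t.T)
    try:
        np.linalg.cholesky(Sigma_t)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "propagated covariance not positive definite "
            "(invalid landscape/time combination)"
        ) from exc
    # mean shift (Sigma0^-1/t + C)^-1 grad = t (I + t Sigma0 C)^-1 Sigma0 grad
    shift = t * solve(B, g0.Sigma @ grad)
    return GaussianPopulation(g0.mu + shift, Sigma_t)


def newton_limit(g0: GaussianPopulation, land: FitnessLandscape) -> np.ndarray:
    """Infinite-selection mean shift ``C⁻¹ ∇f`` (one Newton step).

    Requires positive-definite curvature at the current mean; on a
    quadratic, ``μ0 + newton_limit`` is the optimum.
    """
    if land.gradient is None or land.curvature is None:
        raise ValueError("landscape must provide gradient and curvature")
    grad = np.asarray(land.gradient(g0.mu), dtype=float)
    C = np.asarray(land.curvature(g0.mu), dtype=float)
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("curvature must be positive definite") from exc
    return cho_solve(cf, grad)


def continuous_load(g: GaussianPopulation, land: FitnessLandscape) -> float:
    """Genetic load F* − F of a Gaussian population on a quadratic.

    F* is the landscape maximum and F the expected fitness under the
    population:  ``½[(μ−x*)ᵀ C (μ−x*) + tr(C Σ)]``.  When the population
    sits at the optimum with covariance ``C⁻¹/t`` (the selection
    equilibrium at scale t) the load is exactly ``D/(2t)``.
    """
    if land.curvature is None or land.optimum is None:
        raise ValueError("landscape must provide curvature and a known optimum")
    C = np.asarray(land.curvature(g.mu), dtype=float)
    x_star = np.asarray(land.optimum[0], dtype=float)
    d = g.mu - x_star
    return float(0.5 * (d @ C @ d + np.trace(C @ g.Sigma)))


def expected_mutation_cost(
    land: FitnessLandscape, M: np.ndarray, at: np.ndarray | None = None
) -> float:
    """Expected fitness change of a random Gaussian phenotype perturbation.

    For a zero-mean perturbation with covariance M on a quadratic
    landscape the expectation is ``−½ tr(C M)`` regardless of where the
    parent sits: the linear term averages out and every deleterious
    curvature direction contributes in proportion to the mutational
    variance it receives.  M must be symmetric PSD.
    """
    if land.curvature is None:
        raise ValueError("landscape must provide curvature")
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("mutation covariance must be symmetric")
    if M.size and np.linalg.eigvalsh(M).min() < -1e-10:
        raise ValueError("mutation covariance must be positive semi-definite")
    if at is None:
        at = (
            np.asarray(land.optimum[0], dtype=float)
            if land.optimum is not None
            else np.zeros(land.dimension)
        )
    C = np.asarray(land.curvature(np.asarray(at, dtype=float)), dtype=float)
    return float(-0.5 * np.trace(C @ M))
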