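"""Variant-generating recombination operators.

Selection only reweights existing variants; new phenotypes come from
recombination.  Naive coordinate crossover would destroy the covariance
structure the population has learned, so the operators here are built to
*preserve* it:

* pairwise: ``x' = center + (x1 − x2)/√2`` with the two distinct parents
  drawn by weighted sampling — expectation μ_t and covariance Σ_t match
  the weighted parent population (exactly so under with-replacement
  sampling);
* whole-population: ``x' = center + Σ_i η_i c_i (x_i − μ_t)`` with
  independent standard-normal η_i — a stochastic sum over all parents
  whose conditional covariance is ``Σ_i c_i² (x_i−μ_t)(x_i−μ_t)ᵀ``.

With ``c_i = √p_i`` that conditional covariance equals the weighted
population covariance Σ_t exactly, which is the property that makes the
operator a way of sampling an implicit normal distribution without ever
estimating a covariance matrix.  The unbiased variant divides the
radicand by ``1 − Σ_j p_j²``, compensating the downward bias of the
weighted covariance as an estimator when few variants carry weight.

Deviations are always taken about the weighted mean μ_t; the *center*
the deviations are added to is a policy choice (μ_t itself, or the best
phenotype observed so far, which equals the mean at infinite selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .replicator import Population, SelectionState, weighted_moments

__all__ = [
    "RecombinationConfig",
    "recombination_coefficients",
    "recombine_pair",
    "recombine_population",
]

_MODES = ("pairwise", "population")
_CENTER_POLICIES = ("weighted_mean", "best_observed")
_COEFFICIENT_FORMS = ("sqrt", "literal")


@dataclass
class RecombinationConfig:
    """Operator mode, centering policy and coefficient options.

    ``coefficient_form="sqrt"`` (default) uses ``c_i = √p_i``, the unique
    choice reproducing Σ_t as the conditional covariance;
    ``"literal"`` uses ``c_i = p_i`` for comparison experiments.
    """

    mode: str = "population"
    center_policy: str = "best_observed"
    unbiased: bool = True
    rng_seed: int = 0
    coefficient_form: str = "sqrt"

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.center_policy not in _CENTER_POLICIES:
            raise ValueError(f"center_policy must be one of {_CENTER_POLICIES}")
        if self.coefficient_form not in _COEFFICIENT_FORMS:
            raise ValueError(f"coefficient_form must be one of {_COEFFICIENT_FORMS}")


def recombination_coefficients(
    p: np.ndarray, unbiased: bool, form: str = "sqrt"
) -> np.ndarray:
    """Coefficients c_i of the whole-population operator.

    Biased: ``c_i = √p_i`` so that ``Σ c_i² = 1`` and the conditional
    covariance is Σ_t.  Unbiased: ``c_i = √(p_i / (1 − Σ_j p_j²))``,
    inflating the output covariance by ``1/(1 − Σp²)``.  A population
    with a single effective variant (Σp² ≈ 1) cannot be unbiased-
    recombined and raises.
    """
    p = np.asarray(p, dtype=float).ravel()
    sum_p2 = float(p @ p)
    if form == "sqrt":
        c = np.sqrt(p)
    elif form == "literal":
        c = p.copy()
    else:
        raise ValueError(f"unknown coefficient form {form!r}")
    if unbiased:
        denom = 1.0 - sum_p2
        if denom < 1e-12:
            raise ValueError(
                "population has a single effective variant; "
                "unbiased recombination undefined"
            )
        c = c / np.sqrt(denom)
    return c


def recombine_pair(
    pop: Population,
    state: SelectionState,
    center: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pairwise recombinant ``center + (x1 − x2)/√2``.

    The two parents are distinct indices drawn by weighted sampling with
    the current selection weights.  Sampling without replacement biases
    the output covariance down by O(Σp²); the exact moment identity is
    recovered under with-replacement sampling.
    """
    p = state.p
    if int(np.count_nonzero(p > 0.0)) < 2:
        raise ValueError("need at least two positive-weight variants")
    i, j = rng.choice(pop.size, size=2, replace=False, p=p)
    return np.asarray(center, dtype=float) + (pop.X[i] - pop.X[j]) / np.sqrt(2.0)


def recombine_population(
    pop: Population,
    state: SelectionState,
    cfg: RecombinationConfig,
    center: np.ndarray,
    rng: np.random.Generator,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """One recombinant from the whole-population stochastic sum.

    ``x' = center + Σ_i η_i c_i (x_i − μ_t)`` with η_i ~ N(0,1).
    Deviations are about the weighted mean μ_t regardless of the center.
    ``eta`` can be supplied explicitly for deterministic checks.
    """
    mu, _, _, _ = weighted_moments(pop, state.p)
    c = recombination_coefficients(state.p, cfg.unbiased, cfg.coefficient_form)
    if eta is None:
        eta = rng.standard_normal(pop.size)
    else:
        eta = np.asarray(eta, dtype=float).ravel()
        if eta.size != pop.size:
            raise ValueError("eta must have one entry per variant")
    return np.asarray(center, dtype=float) + (eta * c) @ (pop.X - mu)
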