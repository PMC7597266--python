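"""The quantitative genetic algorithm (QGA).

A derivative-free optimizer that keeps a fixed-size population of K0
candidate phenotypes and iterates two moves:

1. *Selection*: give the variants Boltzmann weights
   ``p_i(t) ∝ exp(t f_i)`` and solve for the selection scale t at which
   the population entropy equals a target S (in bits).  Holding
   diversity fixed lets selection strengthen on its own as better
   variants arrive — and weaken when a new variant suddenly dominates.
2. *Recombination*: generate exactly one new variant with the
   whole-population stochastic-sum operator, evaluate it, and replace
   the variant carrying the smallest weight.

The population size is tied to the target entropy, ``K0 = 2^(S+1)``, so
the initial uniform entropy ``S+1`` sits one bit above the target.  The
loop stops when the best objective is within tolerance of a known
optimum, when the evaluation budget is spent, when two distinct
phenotypes collide onto a bit-identical fitness value (a numerical-error
signal typical of premature convergence at diverging t), or when the
entropy target becomes unreachable.

The optimizer performs no matrix factorization or inversion and stores
no covariance matrix; its per-iteration cost is O(K0·D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .landscapes import EvalCounter, FitnessLandscape
from .recombine import (
    RecombinationConfig,
    recombine_pair,
    recombine_population,
)
from .replicator import Population, SelectionState

__all__ = [
    "QGAConfig",
    "RunRecord",
    "BestRegister",
    "DegeneratePopulationError",
    "initialize",
    "solve_selection_scale",
    "step",
    "run",
]


class DegeneratePopulationError(RuntimeError):
    """The entropy target cannot be met by any selection scale."""


@dataclass
class QGAConfig:
    """Hyper-parameters of a QGA run.

    ``target_entropy_bits`` (S) is the only substantive tuning knob.
    ``init_mean``/``init_std`` parameterize the diagonal normal the
    initial population is drawn from.  ``fitness_tolerance`` is the
    objective gap to a *known* optimum that counts as success; leave it
    ``None`` for landscapes without a known optimum (termination is then
    by budget or fitness-collision only).
    """

    target_entropy_bits: float
    init_mean: np.ndarray
    init_std: np.ndarray
    max_evaluations: int = 50_000
    fitness_tolerance: Optional[float] = 1e-8
    rng_seed: int = 0
    recombination: RecombinationConfig = field(default_factory=RecombinationConfig)
    entropy_match_tol: float = 1e-6

    def __post_init__(self):
        if not self.target_entropy_bits > 0:
            raise ValueError("target entropy S must be > 0")
        self.init_mean = np.atleast_1d(np.asarray(self.init_mean, dtype=float))
        self.init_std = np.atleast_1d(np.asarray(self.init_std, dtype=float))
        if self.init_std.size == 1:
            self.init_std = np.full(self.init_mean.size, float(self.init_std[0]))
        if self.init_std.size != self.init_mean.size:
            raise ValueError("init_mean and init_std sizes must match")
        if np.any(self.init_std <= 0):
            raise ValueError("init_std entries must be positive")
        if self.max_evaluations < self.population_size:
            raise ValueError(
                f"budget {self.max_evaluations} smaller than the initial "
                f"population K0={self.population_size}"
            )

    @property
    def population_size(self) -> int:
        """K0 = round(2^(S+1))."""
        return int(round(2.0 ** (self.target_entropy_bits + 1.0)))


@dataclass
class BestRegister:
    """Best (phenotype, fitness) ever evaluated; survives eviction."""

    x: np.ndarray
    fitness: float

    def offer(self, x: np.ndarray, f: float) -> None:
        if f > self.fitness:
            self.x = np.array(x, dtype=float, copy=True)
            self.fitness = float(f)


@dataclass
class RunRecord:
    """Per-iteration trace of a run plus its outcome."""

    evaluations: np.ndarray
    t: np.ndarray
    best_objective: np.ndarray
    entropy_bits: np.ndarray
    K_eff: np.ndarray
    mean_fitness: np.ndarray
    termination_reason: str
    best_x: np.ndarray
    final_best_objective: float
    n_evaluations: int
    seed: int
    config: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "evals": self.evaluations,
                "t": self.t,
                "best_objective": self.best_objective,
                "entropy_bits": self.entropy_bits,
                "K_eff": self.K_eff,
                "mean_fitness": self.mean_fitness,
            }
        )

    def summary(self) -> dict:
        return {
            "termination_reason": self.termination_reason,
            "best_objective": self.final_best_objective,
            "best_x": [float(v) for v in self.best_x],
            "evaluations": int(self.n_evaluations),
            "seed": int(self.seed),
            "config": self.config,
        }

    def write(self, table_path, summary_path=None) -> None:
        """Write the trace as delimited text and the summary as JSON."""
        self.to_dataframe().to_csv(table_path, index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def _config_dict(cfg: QGAConfig) -> dict:
    d = asdict(cfg)
    d["init_mean"] = [float(v) for v in cfg.init_mean]
    d["init_std"] = [float(v) for v in cfg.init_std]
    return d


def initialize(cfg: QGAConfig, land, rng: np.random.Generator) -> Population:
    """Draw K0 phenotypes from the initial diagonal normal and evaluate.

    Base frequencies are uniform 1/K0; every draw costs one evaluation.
    """
    K0 = cfg.population_size
    D = cfg.init_mean.size
    X = cfg.init_mean + cfg.init_std * rng.standard_normal((K0, D))
    f = np.array([land.fitness(x) for x in X], dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite fitness at initialization")
    return Population.uniform(X, f)


def _entropy_bits_of(f: np.ndarray, t: float) -> tuple[float, np.ndarray]:
    """Entropy (bits) and weights of the uniform-base Boltzmann
    distribution at scale t, log-sum-exp stabilized."""
    z = t * f
    z = z - z.max()
    w = np.exp(z)
    p = w / w.sum()
    nz = p[p > 0.0]
    return float(-np.sum(nz * np.log2(nz))), p


_T_CAP = 1e300


def solve_selection_scale(
    pop: Population,
    S_target_bits: float,
    tol: float = 1e-6,
    t_init: float = 1.0,
) -> SelectionState:
    """Find t ≥ 0 whose Boltzmann entropy matches the target (bits).

    With uniform base frequencies the entropy is non-increasing in t, so
    the solver brackets the target geometrically (warm-started at
    ``t_init``) and then bisects.  Conventions: a flat fitness vector or
    a target at or above the uniform entropy returns t = 0; a target
    below the large-t entropy floor (set by ties at the maximum) raises
    :class:`DegeneratePopulationError`.
    """
    f = pop.f
    K = f.size
    S_uniform = np.log2(K)
    if f.max() == f.min():
        S, p = _entropy_bits_of(f, 0.0)
        return SelectionState(t=0.0, p=p, entropy_bits=S, K_eff=2.0 ** S)
    if S_target_bits >= S_uniform - tol:
        S, p = _entropy_bits_of(f, 0.0)
        return SelectionState(t=0.0, p=p, entropy_bits=S, K_eff=2.0 ** S)
    n_max = int(np.count_nonzero(f == f.max()))
    if np.log2(max(n_max, 1)) > S_target_bits + tol:
        raise DegeneratePopulationError(
            "entropy floor from tied maxima exceeds the target"
        )

    t0 = float(t_init) if t_init > 0.0 else 1.0
    S0, _ = _entropy_bits_of(f, t0)
    if S0 > S_target_bits:
        lo, hi = t0, 4.0 * t0
        while True:
            S_hi, _ = _entropy_bits_of(f, hi)
            if S_hi <= S_target_bits:
                break
            lo = hi
            hi *= 4.0
            if hi > _T_CAP:
                raise DegeneratePopulationError(
                    "entropy target unreachable within representable t"
                )
    else:
        hi, lo = t0, t0 / 4.0
        while True:
            S_lo, _ = _entropy_bits_of(f, lo)
            if S_lo >= S_target_bits:
                break
            hi = lo
            lo /= 4.0
            if lo < 1e-300:
                lo = 0.0
                break

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        S_mid, p_mid = _entropy_bits_of(f, mid)
        if abs(S_mid - S_target_bits) <= tol:
            return SelectionState(
                t=mid, p=p_mid, entropy_bits=S_mid, K_eff=2.0 ** S_mid
            )
        if S_mid > S_target_bits:
            lo = mid
        else:
            hi = mid
    # interval collapsed to float resolution; accept the midpoint
    S_mid, p_mid = _entropy_bits_of(f, mid)
    return SelectionState(t=mid, p=p_mid, entropy_bits=S_mid, K_eff=2.0 ** S_mid)


def _has_fitness_collision(X: np.ndarray, f: np.ndarray) -> bool:
    """True if two phenotypes differing in any coordinate share a
    bit-identical fitness value."""
    order = np.argsort(f, kind="stable")
    fs = f[order]
    ties = np.nonzero(fs[1:] == fs[:-1])[0]
    for k in ties:
        i, j = order[k], order[k + 1]
        if not np.array_equal(X[i], X[j]):
            return True
    return False


def step(
    pop: Population,
    cfg: QGAConfig,
    land,
    best: BestRegister,
    rng: np.random.Generator,
    t_warm: float = 1.0,
) -> tuple[Population, SelectionState, tuple]:
    """One selection + recombination + replacement iteration.

    Returns the updated population (size unchanged at K0), the solved
    selection state, and one trace row.  The evicted variant is the one
    with the smallest weight *before* the recombinant joins; ties go to
    the lowest index.
    """
    state = solve_selection_scale(
        pop, cfg.target_entropy_bits, cfg.entropy_match_tol, t_init=t_warm
    )
    if cfg.recombination.center_policy == "best_observed":
        center = best.x
    else:
        center = state.p @ pop.X
    if cfg.recombination.mode == "population":
        x_new = recombine_population(pop, state, cfg.recombination, center, rng)
    else:
        x_new = recombine_pair(pop, state, center, rng)
    f_new = land.fitness(x_new)
    best.offer(x_new, f_new)

    worst = int(np.argmin(state.p))
    X = pop.X.copy()
    f = pop.f.copy()
    X[worst] = x_new
    f[worst] = f_new
    new_pop = Population.uniform(X, f)

    F_mean = float(state.p @ pop.f)
    row = (
        land.evaluations,
        state.t,
        -best.fitness,
        state.entropy_bits,
        state.K_eff,
        F_mean,
    )
    return new_pop, state, row


def run(cfg: QGAConfig, land: FitnessLandscape) -> RunRecord:
    """Run the full optimization loop and return its trace.

    All termination modes are recorded, never raised: ``converged``
    (objective gap to a known optimum within ``fitness_tolerance``),
    ``budget_exhausted``, ``duplicate_fitness`` (bit-identical fitness
    on distinct phenotypes in the working population) and
    ``degenerate_population`` (entropy target unreachable).
    """
    counter = land if isinstance(land, EvalCounter) else EvalCounter(land)
    rng = np.random.default_rng(cfg.rng_seed)
    pop = initialize(cfg, counter, rng)
    i_best = int(np.argmax(pop.f))
    best = BestRegister(x=pop.X[i_best].copy(), fitness=float(pop.f[i_best]))

    obj_min = counter.objective_minimum
    check_convergence = cfg.fitness_tolerance is not None and obj_min is not None

    rows: list[tuple] = []
    reason = "budget_exhausted"
    t_warm = 1.0
    while True:
        if check_convergence and (-best.fitness) - obj_min <= cfg.fitness_tolerance:
            reason = "converged"
            break
        if _has_fitness_collision(pop.X, pop.f):
            reason = "duplicate_fitness"
            break
        if counter.evaluations >= cfg.max_evaluations:
            reason = "budget_exhausted"
            break
        try:
            pop, state, row = step(pop, cfg, counter, best, rng, t_warm)
        except DegeneratePopulationError:
            reason = "degenerate_population"
            break
        t_warm = state.t if state.t > 0.0 else 1.0
        rows.append(row)

    arr = np.array(rows, dtype=float) if rows else np.empty((0, 6))
    return RunRecord(
        evaluations=arr[:, 0].astype(int),
        t=arr[:, 1],
        best_objective=arr[:, 2],
        entropy_bits=arr[:, 3],
        K_eff=arr[:, 4],
        mean_fitness=arr[:, 5],
        termination_reason=reason,
        best_x=best.x.copy(),
        final_best_objective=-best.fitness,
        n_evaluations=int(counter.evaluations),
        seed=int(cfg.rng_seed),
        config=_config_dict(cfg),
    )
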