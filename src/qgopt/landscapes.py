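"""Fitness-landscape abstractions and built-in test functions.

The optimizer internally *maximizes* fitness, while benchmark objectives
are conventionally *minimized*.  The sign flip ``fitness = -objective``
happens in exactly one place — :func:`from_objective` — and every
built-in landscape is constructed through it (or directly on the fitness
scale for analytic quadratics).  All run logs report the objective scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "FitnessLandscape",
    "EvalCounter",
    "from_objective",
    "make_quadratic",
    "test_ellipsoid",
    "rosenbrock2d",
    "random_quadratic_instance",
    "get_landscape",
    "finite_difference_gradient",
]


@dataclass
class FitnessLandscape:
    """A continuous phenotype-to-fitness map.

    Parameters
    ----------
    dimension
        Number of phenotype coordinates D.
    fitness
        Callable mapping a D-vector to a scalar fitness (maximized).
    gradient
        Optional callable returning the fitness gradient (D-vector).
    curvature
        Optional callable returning the fitness curvature C, the
        *negative* of the matrix of second derivatives of fitness.
        For a landscape whose objective is convex quadratic, C equals
        the objective Hessian and is positive semi-definite.
    optimum
        Optional ``(x_star, f_star)`` — a maximizer and the maximal
        fitness.  For degenerate (rank-deficient) quadratics this is one
        representative of the optimal set.
    name
        Registry name used in logs and the CLI.
    """

    dimension: int
    fitness: Callable[[np.ndarray], float]
    gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None
    curvature: Optional[Callable[[np.ndarray], np.ndarray]] = None
    optimum: Optional[tuple] = None
    name: str = "landscape"

    def objective(self, x: np.ndarray) -> float:
        """The minimization-scale value, ``-fitness(x)``."""
        return -self.fitness(np.asarray(x, dtype=float))

    @property
    def objective_minimum(self) -> Optional[float]:
        if self.optimum is None:
            return None
        return -float(self.optimum[1])


class EvalCounter:
    """Wrap a landscape so fitness evaluations are counted.

    Budgets in the optimizer are enforced against ``evaluations``.
    Gradient/curvature calls are not counted: the optimizer itself is
    derivative-free and never calls them.
    """

    def __init__(self, land: FitnessLandscape):
        self.land = land
        self.evaluations = 0

    @property
    def dimension(self) -> int:
        return self.land.dimension

    @property
    def optimum(self):
        return self.land.optimum

    @property
    def objective_minimum(self):
        return self.land.objective_minimum

    def fitness(self, x: np.ndarray) -> float:
        self.evaluations += 1
        return self.land.fitness(x)

    def objective(self, x: np.ndarray) -> float:
        return -self.fitness(x)


def from_objective(
    func: Callable[[np.ndarray], float],
    dimension: int,
    *,
    gradient: Optional[Callable] = None,
    hessian: Optional[Callable] = None,
    minimum: Optional[tuple] = None,
    name: str = "custom",
) -> FitnessLandscape:
    """Adapt a minimization objective into a fitness landscape.

    This is the single point where the sign convention is applied:
    ``fitness = -objective``, the fitness gradient is the negated
    objective gradient, and the fitness curvature C equals the objective
    Hessian.  ``minimum`` is ``(x_min, obj_min)`` on the objective scale.
    Use this to wrap any external benchmark callable.
    """
    fit = lambda x: -float(func(np.asarray(x, dtype=float)))
    grad = None if gradient is None else (lambda x: -np.asarray(gradient(x), float))
    curv = None if hessian is None else (lambda x: np.asarray(hessian(x), float))
    opt = None
    if minimum is not None:
        x_min, obj_min = minimum
        opt = (np.asarray(x_min, dtype=float), -float(obj_min))
    return FitnessLandscape(
        dimension=dimension,
        fitness=fit,
        gradient=grad,
        curvature=curv,
        optimum=opt,
        name=name,
    )


def make_quadratic(
    x_star: np.ndarray, C: np.ndarray, f_star: float = 0.0, name: str = "quadratic"
) -> FitnessLandscape:
    """Quadratic landscape ``f(x) = f* - (x-x*)' C (x-x*) / 2``.

    C is the fitness curvature (negative fitness Hessian) and must be
    symmetric positive semi-definite; the maximum is at ``x_star`` with
    value ``f_star``.
    """
    x_star = np.asarray(x_star, dtype=float)
    C = np.asarray(C, dtype=float)
    D = x_star.size
    if C.shape != (D, D):
        raise ValueError(f"curvature must be {D}x{D}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10 * max(1.0, np.abs(C).max())):
        raise ValueError("curvature matrix must be symmetric")
    if np.linalg.eigvalsh(C).min() < -1e-10 * max(1.0, np.abs(C).max()):
        raise ValueError("curvature matrix must be positive semi-definite")

    def fitness(x):
        d = np.asarray(x, dtype=float) - x_star
        return float(f_star) - 0.5 * float(d @ C @ d)

    def gradient(x):
        return -C @ (np.asarray(x, dtype=float) - x_star)

    def curvature(x):
        return C

    return FitnessLandscape(
        dimension=D,
        fitness=fitness,
        gradient=gradient,
        curvature=curvature,
        optimum=(x_star, float(f_star)),
        name=name,
    )


def test_ellipsoid() -> FitnessLandscape:
    """The 5-D test ellipsoid, objective ``(x1 + 2 x2 + ... + 5 x5)^2``.

    As printed this is a rank-1 quadratic: the objective vanishes on the
    whole hyperplane ``sum_i i*x_i = 0``, so the optimum set is
    degenerate.  The stored representative optimum is the origin.  Use
    :func:`random_quadratic_instance` for a full-rank test surface.
    """
    a = np.arange(1.0, 6.0)
    # objective a.x squared == 0.5 x' (2 a a') x; curvature C = 2 a a'
    C = 2.0 * np.outer(a, a)

    def fitness(x):
        return -float(np.dot(a, np.asarray(x, dtype=float)) ** 2)

    def gradient(x):
        return -2.0 * float(np.dot(a, np.asarray(x, dtype=float))) * a

    return FitnessLandscape(
        dimension=5,
        fitness=fitness,
        gradient=gradient,
        curvature=lambda x: C,
        optimum=(np.zeros(5), 0.0),
        name="ellipsoid5",
    )


test_ellipsoid.__test__ = False  # API name; not a pytest case


def rosenbrock2d() -> FitnessLandscape:
    """The 2-D Rosenbrock valley, objective ``(1-x1)^2 + 100 (x2-x1^2)^2``.

    Non-convex, with the global minimum 0 at (1, 1) at the end of a
    curved, nearly flat valley.
    """

    def objective(x):
        x1, x2 = x
        return (1.0 - x1) ** 2 + 100.0 * (x2 - x1 * x1) ** 2

    def obj_grad(x):
        x1, x2 = x
        g1 = -2.0 * (1.0 - x1) - 400.0 * x1 * (x2 - x1 * x1)
        g2 = 200.0 * (x2 - x1 * x1)
        return np.array([g1, g2])

    def obj_hess(x):
        x1, x2 = x
        h11 = 2.0 - 400.0 * (x2 - 3.0 * x1 * x1)
        h12 = -400.0 * x1
        return np.array([[h11, h12], [h12, 200.0]])

    return from_objective(
        objective,
        dimension=2,
        gradient=obj_grad,
        hessian=obj_hess,
        minimum=(np.array([1.0, 1.0]), 0.0),
        name="rosenbrock2",
    )


#: Box half-width for randomized optimum locations (matches the
#: 3-standard-deviation initialization scale of the benchmarks).
OPTIMUM_BOX = 3.0


def random_quadratic_instance(
    D: int, condition_spread: float = 10.0, seed: int = 0
) -> FitnessLandscape:
    """A full-rank random quadratic instance with a randomized optimum.

    Curvature eigenvalues are log-spaced from 1 to ``condition_spread``
    in a uniformly random orthogonal frame; the optimum location is
    uniform in the box ``[-OPTIMUM_BOX, OPTIMUM_BOX]^D``.  Reproducible
    from ``seed``.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    eigs = np.logspace(0.0, np.log10(condition_spread), D) if D > 1 else np.ones(1)
    A = rng.standard_normal((D, D))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))  # unique, Haar-distributed orthogonal factor
    C = (Q * eigs) @ Q.T
    C = 0.5 * (C + C.T)
    x_star = rng.uniform(-OPTIMUM_BOX, OPTIMUM_BOX, size=D)
    return make_quadratic(x_star, C, 0.0, name=f"quad:D={D},seed={seed}")


def finite_difference_gradient(
    land: FitnessLandscape, x: np.ndarray, h: float = 1e-6
) -> np.ndarray:
    """Central finite-difference gradient of the fitness at x."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h
        g[j] = (land.fitness(x + e) - land.fitness(x - e)) / (2.0 * h)
    return g


def get_landscape(name: str) -> FitnessLandscape:
    """Resolve a landscape by registry name.

    Accepted names: ``ellipsoid5``, ``rosenbrock2`` and parametric
    ``quad:D=<int>,seed=<int>[,spread=<float>]``.
    """
    if name == "ellipsoid5":
        return test_ellipsoid()
    if name == "rosenbrock2":
        return rosenbrock2d()
    if name.startswith("quad:"):
        params = {}
        for item in name[len("quad:"):].split(","):
            key, _, value = item.partition("=")
            params[key.strip()] = value.strip()
        try:
            D = int(params["D"])
            seed = int(params.get("seed", 0))
            spread = float(params.get("spread", 10.0))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed quadratic spec {name!r}") from exc
        return random_quadratic_instance(D, spread, seed)
    raise KeyError(f"unknown landscape {name!r}")
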