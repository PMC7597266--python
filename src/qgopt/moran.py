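"""Moran birth-death simulation of mutant extinction.

Stochastic fitness-proportionate selection loses most beneficial
variants to drift: in a population of N individuals, a single mutant
with relative fitness r has fixation probability
``(1 - 1/r) / (1 - r^-N)``, so a 1% advantage is lost about 99% of the
time.  This module measures that extinction fraction by simulation.

The simulation follows the embedded jump chain of the Moran process:
steps that do not change the mutant count are skipped, and conditional
on a change the mutant count rises with probability ``r / (1 + r)``
independently of its current value (birth rates are proportional to
r·i·(N−i) upward and i·(N−i) downward).  Each replicate is therefore a
biased gambler's-ruin walk from 1 absorbed at 0 (extinction) or N
(fixation) — the same absorption probabilities as the full process, at
a fraction of the steps.  Replicates exit as soon as they absorb.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fixation_probability", "moran_extinction_fraction"]


def fixation_probability(N: int, r: float) -> float:
    """Closed-form fixation probability of one mutant of relative
    fitness r in a Moran population of size N."""
    if r == 1.0:
        return 1.0 / N
    return (1.0 - 1.0 / r) / (1.0 - r ** (-N))


def moran_extinction_fraction(
    N: int,
    r: float,
    replicates: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> float:
    """Fraction of replicates in which a single mutant goes extinct.

    Vectorized over replicates; each live replicate advances ``chunk``
    jump-chain steps at a time and is retired at its first boundary hit
    (the first crossing inside a chunk is located exactly, so overshoot
    past a boundary never counts).
    """
    if N < 2 or replicates < 1:
        raise ValueError("need N >= 2 and at least one replicate")
    p_up = r / (1.0 + r)
    count = np.ones(replicates, dtype=np.int64)
    extinct = 0
    fixed = 0
    while count.size:
        n_live = count.size
        steps = np.where(
            rng.random((n_live, chunk)) < p_up, 1, -1
        ).astype(np.int64)
        paths = count[:, None] + np.cumsum(steps, axis=1)
        hit = (paths <= 0) | (paths >= N)
        any_hit = hit.any(axis=1)
        if any_hit.any():
            first = np.argmax(hit[any_hit], axis=1)
            landing = paths[any_hit, first]
            extinct += int(np.count_nonzero(landing <= 0))
            fixed += int(np.count_nonzero(landing >= N))
        count = paths[~any_hit, -1]
    assert extinct + fixed == replicates
    return extinct / replicates
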