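# Methods

## Model

`qgopt` treats black-box optimization of a continuous objective
`g(x)`, `x ∈ R^D`, as natural selection on a fitness landscape
`f(x) = −g(x)`. A population is a finite set of K *variants* (unique
phenotypes `x_i`) with frequencies `p_i`. Deterministic selection —
replicator dynamics without mutation or drift —

    dp_i/dt = p_i (f_i − F̄),     F̄ = Σ_i p_i f_i,

integrates in closed form to Boltzmann weights

    p_i(t) = p_i(0) e^{t f_i} / Z_t .

Two facts make this more than a softmax: (i) on the manifold of
categorical distributions the replicator flow is the *natural gradient*
of mean fitness under the Fisher information metric, so selection is
steepest ascent in the geometry of the distribution, not of parameter
space; (ii) for normally distributed phenotypes on a quadratic fitness
landscape with curvature `C = −∇²f`, the weighted mean moves as

    μ_t − μ0 = (Σ0⁻¹/t + C)⁻¹ ∇f ,

a regularized Newton step that tends to the exact Newton step `C⁻¹∇f`
as `t → ∞`. The selection scale `t` (units: inverse fitness) therefore
interpolates between a small quantitative-genetics response `t Σ0 ∇f`
and Newton's method. These identities are implemented in
`gaussian_theory` and validated by the test suite; the optimizer itself
never computes them.

Selection buys fitness with diversity. Population entropy
`S_t = −Σ p_i log2 p_i` (bits) defines an effective variant count
`K_t = 2^{S_t}`; the genetic load `F* − F̄` tends to `D/(2t)` for
Gaussian populations, so the unit-less scaled load `t(F† − F̄)` peaks at
intermediate selection and vanishes in both limits.

## The optimizer

The quantitative genetic algorithm (`qga.run`) holds diversity fixed
and lets selection strength emerge:

1. draw `K0 = 2^(S+1)` phenotypes from a diagonal normal
   `N(init_mean, init_std²)`, uniform base frequencies;
2. each iteration, solve for the `t ≥ 0` at which the Boltzmann entropy
   equals the target `S` (bits). With uniform base weights the entropy
   is non-increasing in `t`, so the solver brackets geometrically
   (warm-started at the previous `t`) and bisects to `entropy_match_tol`
   (default 1e-6 bits). `t` is re-solved from scratch each iteration
   and is free to *decrease* when a newly found high-fitness variant
   concentrates the weights;
3. generate exactly one recombinant

       x' = center + Σ_i η_i c_i (x_i − μ_t),   η_i ~ N(0,1),

   with deviations always taken about the weighted mean μ_t. The
   coefficients are `c_i = √(p_i/(1−Σ_j p_j²))` by default: `√p_i`
   makes the conditional covariance of `x'` equal the weighted
   population covariance Σ_t *exactly* (an algebraic identity tested at
   machine precision), and the `1−Σp²` radicand divisor undoes the
   downward bias of the weighted covariance when few variants carry
   weight. The default `center` is the best phenotype ever evaluated
   (the mean at infinite selection), which benchmarks markedly better
   than centering on μ_t; both policies are exposed;
4. evaluate the recombinant (one objective call), update the best-ever
   register, and replace the variant with the smallest weight (ties:
   lowest index). Population size stays K0; no covariance matrix is
   stored and no factorization is performed — per-iteration cost is
   O(K0·D).

Termination: `converged` (best objective within `fitness_tolerance` of
a known optimum — benchmark landscapes only), `budget_exhausted`,
`duplicate_fitness` (two distinct phenotypes with bit-identical
fitness, the numerical signature of premature convergence at diverging
`t`; checked over the working population each iteration), or
`degenerate_population` (entropy target unreachable, e.g. tied maxima
force an entropy floor above `S`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `target_entropy_bits` S | — | diversity held during the run; K0 = 2^(S+1). Small S converges fast but risks premature convergence on a slope; large S costs evaluations. S=4–5 is a good starting range in D≈5 |
| `init_mean`, `init_std` | — | diagonal normal for the initial draw; should cover the basin of interest |
| `max_evaluations` | 5×10⁴ | objective-call budget, counting initialization |
| `fitness_tolerance` | 1e-8 | success gap to a known optimum; `None` disables the check |
| `entropy_match_tol` | 1e-6 bits | entropy-solver tolerance; far below any behavioral effect |
| `RecombinationConfig.unbiased` | True | covariance-bias correction `1/(1−Σp²)` |
| `RecombinationConfig.center_policy` | `best_observed` | recombinant center; `weighted_mean` is the unmodified operator |
| `coefficient_form` | `sqrt` | `literal` (`c_i = p_i`) kept only for comparison experiments |

## Synthetic test surfaces

Built-in landscapes are the package's data generator. `ellipsoid5` is
the rank-1 quadratic `(x1+2x2+3x3+4x4+5x5)²` kept verbatim (its optimum
set is a hyperplane, so it exercises degenerate geometry);
`rosenbrock2` is `(1−x1)² + 100(x2−x1²)²` with its curved, nearly flat
valley; `quad:D=n,seed=k` draws a full-rank quadratic with curvature
eigenvalues log-spaced from 1 to `condition_spread` (default 10) in a
Haar-random frame and an optimum uniform in `[−3,3]^D`, mirroring
standard benchmark practice of randomized instances. Benchmark runs on
random quadratics initialize at mean 0, std 3 per coordinate, so the
optimum is not centered in the initial cloud; Rosenbrock runs
initialize at mean (0,1), std 0.25, away from the optimum (1,1).

These surfaces are smooth, noise-free and cheap. Passing tests show the
selection/recombination mechanics and the convergence behavior they are
designed to probe; they say nothing about noisy, discontinuous or
heavily multimodal objectives, where the duplicate-fitness guard (on
plateaued functions) deliberately aborts rather than spin.

The Moran module simulates the *embedded jump chain* of the
birth-death process: steps that change the mutant count occur with
up-probability `r/(1+r)` independent of the count, so each replicate is
a gambler's-ruin walk from 1 absorbed at 0 or N. Absorption
probabilities are identical to the full process; replicates exit at
their first boundary hit.

## Numerical choices

- Boltzmann weights are always computed log-sum-exp shifted by
  `max(t·f)`; `t` reaches ~10⁶–10⁸ on convergent runs and the shift is
  what keeps `Z_t` representable.
- Entropy is reported in bits everywhere; the single natural-log/bits
  conversion lives in `replicator.entropy_and_diversity`. `0·log 0 ≡ 0`.
- Input weight vectors are accepted within 1e-9 of normalization and
  renormalized exactly; fitness NaNs are rejected.
- The theory layer (`gaussian_theory`) solves linear systems via
  Cholesky/LU factorization and never stores explicit inverses;
  indefinite `Σ0⁻¹ + tC` raises rather than returning a non-covariance.
- Flat fitness vectors and targets at/above the uniform entropy return
  `t = 0` by convention; the eviction tie-break is the lowest index.
- `t` is capped at 1e300 during bracketing; exceeding it raises the
  degenerate-population signal.

## Problem sizes

The shipped checks use 10⁵ Moran replicates, 10⁵-sample Monte-Carlo
verifications of the Gaussian mean-shift formula, 50–100 random
populations per identity, and 20-seed benchmark sweeps at the 5×10⁴
evaluation budget — small enough to run in well under a minute each,
large enough that the Monte-Carlo bands (4 standard errors) are tight.

## Known limitations

- Convergence detection requires a known optimum; on real problems
  termination is by budget or the duplicate-fitness guard only.
- The duplicate-fitness guard makes the algorithm fail by design on
  step/plateau functions (any two variants on one plateau collide).
- The entropy-matching strategy has one hyper-parameter, S, and
  performance is genuinely sensitive to it; there is no internal
  adaptation of S.
- The Gaussian closed forms are exact only on pure quadratics; on other
  landscapes `propagate` is a local approximation with ∇f and C frozen
  at μ0.
- Pairwise recombination samples parents without replacement, giving an
  O(Σp²) downward covariance bias; the exact moment identity holds for
  the with-replacement ensemble and for the whole-population operator.
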