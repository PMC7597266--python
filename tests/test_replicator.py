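import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qgopt.replicator import (
    Population,
    boltzmann_weights,
    entropy_and_diversity,
    load_diagnostics,
    natural_gradient_check,
    population_table,
    replicator_flow,
    weighted_moments,
)


def pop_1d(x, f):
    return Population.uniform(np.asarray(x, float)[:, None], np.asarray(f, float))


class TestBoltzmannWeights:
    def test_zero_time_returns_base_frequencies(self):
        pop = pop_1d([0, 1, 2, 3], [5.0, -1.0, 2.0, 0.0])
        state = boltzmann_weights(pop, 0.0)
        assert np.allclose(state.p, 0.25)
        assert state.entropy_bits == pytest.approx(2.0)

    def test_two_variant_weights(self):
        pop = pop_1d([0, 1], [0.0, np.log(2.0)])
        state = boltzmann_weights(pop, 1.0)
        assert np.allclose(state.p, [1.0 / 3.0, 2.0 / 3.0])

    def test_strong_selection_concentrates_on_argmax(self):
        pop = pop_1d([0, 1, 2], [0.0, 1.0, 0.5])
        state = boltzmann_weights(pop, 1e4)
        assert state.p[1] > 1.0 - 1e-9

    def test_overflow_safe_at_huge_scale(self):
        pop = pop_1d([0, 1], [1e4, -1e4])
        state = boltzmann_weights(pop, 1e100)
        assert np.all(np.isfinite(state.p))
        assert state.p[0] == pytest.approx(1.0)

    def test_rejects_nan_and_negative_time(self):
        with pytest.raises(ValueError):
            pop_1d([0, 1], [np.nan, 1.0])
        pop = pop_1d([0, 1], [0.0, 1.0])
        with pytest.raises(ValueError):
            boltzmann_weights(pop, -0.5)

    @given(
        t=st.floats(0.0, 50.0),
        shift=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_invariance(self, t, shift, seed):
        """Adding a constant to all fitness values leaves weights unchanged."""
        r = np.random.default_rng(seed)
        f = r.standard_normal(6)
        pop_a = pop_1d(np.arange(6), f)
        pop_b = pop_1d(np.arange(6), f + shift)
        pa = boltzmann_weights(pop_a, t).p
        pb = boltzmann_weights(pop_b, t).p
        assert np.allclose(pa, pb, atol=1e-12)

    @given(
        t1=st.floats(0.0, 10.0), t2=st.floats(0.0, 10.0), seed=st.integers(0, 2**16)
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_composition_group_property(self, t1, t2, seed):
        """Selecting for t1 then t2 equals selecting for t1 + t2."""
        r = np.random.default_rng(seed)
        X = np.arange(5, dtype=float)[:, None]
        f = r.standard_normal(5)
        pop = Population.uniform(X, f)
        direct = boltzmann_weights(pop, t1 + t2).p
        stage1 = boltzmann_weights(pop, t1).p
        staged = boltzmann_weights(Population(X=X, f=f, p0=stage1), t2).p
        assert np.allclose(direct, staged, atol=1e-12)

    def test_entropy_nonincreasing_in_t(self, population_factory):
        pop = population_factory(seed=5, K=20, D=2)
        ts = np.logspace(-3, 3, 40)
        entropies = [boltzmann_weights(pop, t).entropy_bits for t in ts]
        assert np.all(np.diff(entropies) <= 1e-12)


class TestEntropyAndDiversity:
    @pytest.mark.parametrize(
        "p,S,K_eff",
        [
            (np.full(16, 1 / 16), 4.0, 16.0),
            (np.array([1.0, 0.0, 0.0]), 0.0, 1.0),
            (np.array([1 / 3, 2 / 3]), 0.9182958340544896, 1.8898815748423097),
        ],
    )
    def test_examples(self, p, S, K_eff):
        s, k = entropy_and_diversity(p)
        assert s == pytest.approx(S, abs=1e-12)
        assert k == pytest.approx(K_eff, abs=1e-12)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            entropy_and_diversity(np.array([0.5, 0.6]))


class TestWeightedMoments:
    def test_symmetric_pair(self):
        pop = pop_1d([-1.0, 1.0], [0.0, 0.0])
        mu, Sigma, F, varF = weighted_moments(pop, np.array([0.5, 0.5]))
        assert mu == pytest.approx(0.0)
        assert Sigma == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        pop = pop_1d([0.0, 3.0], [0.0, 3.0])
        mu, Sigma, F, varF = weighted_moments(pop, np.array([1 / 3, 2 / 3]))
        assert mu == pytest.approx(2.0)
        assert Sigma == pytest.approx(2.0)
        assert F == pytest.approx(2.0)
        assert varF == pytest.approx(2.0)

    def test_point_mass_zero_covariance(self):
        pop = pop_1d([0.0, 3.0], [0.0, 3.0])
        _, Sigma, _, varF = weighted_moments(pop, np.array([0.0, 1.0]))
        assert np.allclose(Sigma, 0.0)
        assert varF == pytest.approx(0.0)


class TestLoadDiagnostics:
    def test_zero_selection_gives_zero(self, population_factory):
        pop = population_factory(seed=2)
        state = boltzmann_weights(pop, 0.0)
        load, varF = load_diagnostics(pop, state)
        assert load == 0.0 and varF == 0.0

    def test_vanishes_at_strong_selection(self, population_factory):
        pop = population_factory(seed=2)
        state = boltzmann_weights(pop, 1e6)
        load, _ = load_diagnostics(pop, state)
        assert load == pytest.approx(0.0, abs=1e-6)

    def test_interior_peak_over_selection_sweep(self, rng):
        """Scaled load on a sampled quadratic population peaks at
        intermediate selection."""
        X = rng.standard_normal((100, 2))
        f = -0.5 * np.sum(X**2, axis=1)
        pop = Population.uniform(X, f)
        ts = np.logspace(-2, 3, 60)
        loads = []
        for t in ts:
            state = boltzmann_weights(pop, t)
            loads.append(load_diagnostics(pop, state)[0])
        loads = np.array(loads)
        k = int(np.argmax(loads))
        assert 0 < k < len(ts) - 1
        assert loads[k] > loads[0] and loads[k] > loads[-1]


class TestReplicatorFlow:
    def test_flat_fitness_is_stationary(self):
        dp = replicator_flow(np.array([0.2, 0.3, 0.5]), np.array([1.0, 1.0, 1.0]))
        assert np.allclose(dp, 0.0)

    def test_two_variant_hand_example(self):
        dp = replicator_flow(np.array([0.5, 0.5]), np.array([0.0, 1.0]))
        assert np.allclose(dp, [-0.25, 0.25])
        assert dp.sum() == pytest.approx(0.0, abs=1e-15)

    def test_matches_finite_difference_of_boltzmann(self, population_factory):
        """dp/dt from the flow equals the t-derivative of the Boltzmann
        weights along the selection trajectory."""
        pop = population_factory(seed=11, K=8, D=2)
        t0, h = 0.35, 1e-4
        p_mid = boltzmann_weights(pop, t0).p
        p_hi = boltzmann_weights(pop, t0 + h).p
        p_lo = boltzmann_weights(pop, t0 - h).p
        fd = (p_hi - p_lo) / (2.0 * h)
        assert np.allclose(fd, replicator_flow(p_mid, pop.f), atol=1e-6)

    def test_fisher_theorem(self, population_factory):
        """dF/dt equals the fitness variance along the trajectory."""
        for seed in range(10):
            pop = population_factory(seed=seed, K=15, D=2)
            t0, h = 0.4, 1e-5
            _, _, F_hi, _ = weighted_moments(pop, boltzmann_weights(pop, t0 + h).p)
            _, _, F_lo, _ = weighted_moments(pop, boltzmann_weights(pop, t0 - h).p)
            dFdt = (F_hi - F_lo) / (2.0 * h)
            _, _, _, varF = weighted_moments(pop, boltzmann_weights(pop, t0).p)
            assert dFdt == pytest.approx(varF, rel=1e-4)


class TestNaturalGradient:
    def test_explicit_three_variant_example(self):
        dev = natural_gradient_check(
            np.array([0.2, 0.3, 0.5]), np.array([1.0, 2.0, 3.0])
        )
        assert dev < 1e-10

    def test_flat_fitness_both_zero(self):
        dev = natural_gradient_check(np.array([0.4, 0.6]), np.array([2.0, 2.0]))
        assert dev < 1e-15

    def test_two_variant_closed_form(self):
        """dp1/dt = p1 (1-p1) (f1 - f2) for two variants."""
        p1, f1, f2 = 0.3, 1.5, -0.5
        flow = replicator_flow(np.array([p1, 1 - p1]), np.array([f1, f2]))
        assert flow[0] == pytest.approx(p1 * (1 - p1) * (f1 - f2))
        dev = natural_gradient_check(np.array([p1, 1 - p1]), np.array([f1, f2]))
        assert dev < 1e-12

    def test_singular_metric_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            natural_gradient_check(np.array([1.0, 0.0]), np.array([1.0, 2.0]))


def test_population_table_roundtrip(population_factory):
    pop = population_factory(seed=3, K=6, D=2)
    state = boltzmann_weights(pop, 1.0)
    table = population_table(pop, state.p)
    assert list(table.columns) == ["x1", "x2", "fitness", "weight"]
    assert len(table) == 6
    assert table["weight"].sum() == pytest.approx(1.0)
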