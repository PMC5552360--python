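"""Unit and property tests for the coupled-repressilator model core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from repmc import _kernel, model

STANDARD = model.THETA_STANDARD
X0 = model.X0_MEAN


class TestDrift:
    def test_tetr_mrna_fixed_point(self):
        # a = alpha / (1 + C^m) is a fixed point of the a-equation
        state = X0.copy()
        state[5] = 0.0  # C1 = 0 -> Hill term = alpha
        state[0] = STANDARD[2]  # a1 = alpha
        d = model.drift(state, STANDARD)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_tetr_mrna_hand_value(self):
        # C1 = 1, m arbitrary -> C^m = 1; a1 = 0 -> drift = alpha / 2
        state = X0.copy()
        state[5] = 1.0
        state[0] = 0.0
        d = model.drift(state, STANDARD)
        assert d[0] == pytest.approx(216.0 / 2.0)

    def test_ai_equation_vanishes_without_sources(self):
        state = X0.copy()
        state[[4, 6, 13]] = 0.0  # B1 = S1 = S2 = 0
        d = model.drift(state, STANDARD)
        assert d[6] == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_rejected(self):
        state = X0.copy()
        state[3] = np.nan
        with pytest.raises(model.InvalidStateError):
            model.drift(state, STANDARD)

    def test_batched_rows_match_scalar(self):
        rng = np.random.default_rng(0)
        states = rng.uniform(0.0, 10.0, size=(6, 14))
        batch = model.drift(states, STANDARD)
        for i in range(6):
            assert np.allclose(batch[i], model.drift(states[i], STANDARD))


class TestExtracellularAI:
    @pytest.mark.parametrize(
        "s1, s2, q, expected",
        [(0.0, 0.0, 0.3, 0.0), (2.0, 4.0, 1.0, 3.0), (1.0, 1.0, 0.85, 0.85)],
    )
    def test_values(self, s1, s2, q, expected):
        assert model.extracellular_ai(s1, s2, q) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(model.InvalidStateError):
            model.extracellular_ai(-0.1, 1.0, 0.5)

    @given(
        s1=st.floats(0, 1e3),
        s2=st.floats(0, 1e3),
        q=st.floats(0, 1),
        c=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_and_homogeneous(self, s1, s2, q, c):
        base = model.extracellular_ai(s1, s2, q)
        assert model.extracellular_ai(c * s1, c * s2, q) == pytest.approx(
            c * base, rel=1e-12, abs=1e-12
        )
        assert model.extracellular_ai(s1, s2, c / 5.0 * q) == pytest.approx(
            c / 5.0 * base, rel=1e-12, abs=1e-12
        )


class TestEulerMaruyamaStep:
    def test_zero_step_is_identity(self):
        out = model.em_step(X0, STANDARD, h=0.0)
        assert np.array_equal(out, X0)

    def test_noise_free_step_is_euler(self):
        h = 1e-3
        out = model.em_step(X0, STANDARD, h=h)
        expected = np.maximum(X0 + h * model.drift(X0, STANDARD), 0.0)
        assert np.array_equal(out, expected)

    def test_multiplicative_noise_variance(self):
        # per-step noise increment on a has variance (sigma_a * a)^2 * h
        n = 10**5
        h = 1e-3
        sigma = 0.05
        states = np.tile(X0, (n, 1))
        noise = model.NoiseScales(sigma_a=sigma)
        out = model.em_step(
            states, STANDARD, noise=noise, h=h, rng=np.random.default_rng(11)
        )
        drift_part = X0[0] + h * model.drift(X0, STANDARD)[0]
        incr = out[:, 0] - drift_part
        expected_var = (sigma * X0[0]) ** 2 * h
        assert np.var(incr) == pytest.approx(expected_var, rel=0.05)
        # other components were noise-free
        assert np.ptp(out[:, 1]) == 0.0

    def test_noise_amplitude_conventions(self):
        noise = model.NoiseScales.uniform(0.05)
        h = 1e-3
        std_amp = model.noise_amplitudes(noise, h, "em_standard")
        assert np.allclose(std_amp, 0.05 * np.sqrt(h))
        lit_amp = model.noise_amplitudes(noise, h, "literal")
        assert np.allclose(lit_amp, 0.05**2)

    def test_positivity_floor(self):
        state = np.full(14, 1e-3)
        state[0] = 5.0
        noise = model.NoiseScales.uniform(5.0)  # violent noise to force negatives
        rng = np.random.default_rng(3)
        out = model.em_step(state, STANDARD, noise=noise, h=1e-3, rng=rng)
        assert np.all(out >= 0.0)

    def test_blowup_raises_named_component(self):
        state = X0.copy()
        state[1] = 1e300  # drift ~ -b, so h * drift overflows the double range
        with pytest.raises(model.BlowupError, match="component"):
            model.em_step(state, STANDARD, h=1e10)


class TestPropagate:
    def test_single_substep_matches_em_step(self):
        noise = model.NoiseScales.uniform(0.05)
        seed = np.random.SeedSequence(5)
        a = model.em_step(
            X0, STANDARD, noise=noise, h=1e-3, rng=np.random.default_rng(seed)
        )
        b = model.propagate(
            X0, STANDARD, m0=1, noise=noise, h=1e-3, rng=np.random.default_rng(seed)
        )
        assert np.allclose(a, b, rtol=0, atol=1e-12)

    def test_deterministic_composition(self):
        state = X0.copy()
        for _ in range(20):
            state = model.em_step(state, STANDARD, h=1e-3)
        composed = model.propagate(X0, STANDARD, m0=20, h=1e-3)
        assert np.allclose(state, composed, rtol=1e-10, atol=1e-12)

    def test_reproducible_given_seed(self):
        noise = model.NoiseScales.uniform(0.05)
        outs = [
            model.propagate(
                X0, STANDARD, m0=20, noise=noise, h=1e-3, rng=np.random.default_rng(7)
            )
            for _ in range(2)
        ]
        assert np.array_equal(outs[0], outs[1])

    def test_kernel_backends_agree(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.0, 10.0, size=(8, 14))
        th = model.sample_prior(rng, 8)
        fv = model.FixedParameters().as_array()
        amp = model.noise_amplitudes(model.NoiseScales.uniform(0.05), 1e-3, "em_standard")
        z = rng.standard_normal((5, 8, 14))
        a = x.copy()
        b = x.copy()
        _kernel.em_chunk(a, th, fv, amp, 1e-3, z, use_numba=True)
        _kernel.em_chunk(b, th, fv, amp, 1e-3, z, use_numba=False)
        assert np.allclose(a, b, rtol=1e-10, atol=1e-12)
        a = x.copy()
        b = x.copy()
        _kernel.em_chunk_det(a, th, fv, 1e-3, 5, use_numba=True)
        _kernel.em_chunk_det(b, th, fv, 1e-3, 5, use_numba=False)
        assert np.allclose(a, b, rtol=1e-10, atol=1e-12)


class TestSimulateAndObserve:
    def test_step_and_observation_counts(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=1.0)
        traj = model.simulate(STANDARD, X0, grid)
        assert traj.states.shape == (1001, 14)
        y = model.observe(traj, sigma_y=1.0, seed=0)
        assert len(y) == 50

    def test_noise_free_runs_are_seed_independent(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=2.0)
        t1 = model.simulate(STANDARD, X0, grid, seed=1)
        t2 = model.simulate(STANDARD, X0, grid, seed=2)
        assert np.array_equal(t1.states, t2.states)

    def test_stochastic_runs_are_seed_reproducible(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=1.0)
        noise = model.NoiseScales.uniform(0.05)
        t1 = model.simulate(STANDARD, X0, grid, noise=noise, seed=9)
        t2 = model.simulate(STANDARD, X0, grid, noise=noise, seed=9)
        assert np.array_equal(t1.states, t2.states)

    def test_trajectories_stay_bounded(self, deterministic_long_run):
        assert np.all(deterministic_long_run.states < 10.0 * STANDARD[2])

    def test_sustained_aperiodic_oscillation(self, deterministic_long_run):
        # drop the initial transient, then look at tetR mRNA peaks; one
        # oscillation takes roughly forty time units, so the window must
        # span several hundred to hold a dozen cycles
        a1 = deterministic_long_run.states[20000:, 0]
        peaks, _ = find_peaks(a1, prominence=0.5)
        assert peaks.size >= 10
        intervals = np.diff(peaks)
        assert np.std(intervals) > 0  # not a strict limit cycle on the grid

    def test_first_order_convergence_in_h(self):
        def state_at_one(h):
            grid = model.SimulationGrid(h=h, m0=1, t_total=1.0)
            return model.simulate(STANDARD, X0, grid).states[-1]

        ref = state_at_one(1e-5)
        err_coarse = np.max(np.abs(state_at_one(2e-3) - ref))
        err_fine = np.max(np.abs(state_at_one(1e-3) - ref))
        assert 1.5 < err_coarse / err_fine < 2.5

    def test_observation_indexing_and_noise_limit(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=1.0)
        traj = model.simulate(STANDARD, X0, grid)
        y = model.observe(traj, sigma_y=1e-12, seed=4)
        latent = traj.states[20::20, [0, 7]]
        assert np.allclose(y.y, latent, atol=1e-9)

    def test_observation_noise_variance(self, deterministic_full_run):
        traj = deterministic_full_run
        y = model.observe(traj, sigma_y=1.0, seed=8)
        resid = y.y - traj.states[20::20, [0, 7]]
        assert resid.shape[0] == 4000
        assert np.var(resid) == pytest.approx(1.0, rel=0.05)

    def test_observe_rejects_excessive_thinning(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=1.0)
        traj = model.simulate(STANDARD, X0, grid)
        with pytest.raises(ValueError):
            model.observe(traj, m0=5000, sigma_y=1.0, seed=0)


@pytest.fixture(scope="module")
def deterministic_long_run():
    grid = model.SimulationGrid(h=1e-3, m0=20, t_total=600.0)
    return model.simulate(STANDARD, X0, grid)


@pytest.fixture(scope="module")
def deterministic_full_run():
    grid = model.SimulationGrid(h=1e-3, m0=20, t_total=80.0)
    return model.simulate(STANDARD, X0, grid)


class TestPriorAndInitialState:
    def test_prior_support_and_moments(self):
        draws = model.sample_prior(np.random.default_rng(0), 10**5)
        assert np.all(model.in_support(draws))
        assert np.allclose(
            draws.mean(axis=0), [0.5, 3.0, 175.0, 0.5], rtol=0.01
        )

    def test_prior_reproducible(self):
        a = model.sample_prior(np.random.default_rng(42))
        b = model.sample_prior(np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_log_prior_values(self):
        assert model.log_prior(STANDARD) == pytest.approx(-np.log(1000.0))
        assert model.log_prior(np.array([1.5, 3.0, 175.0, 0.5])) == -np.inf

    def test_initial_state_point_mass(self):
        init = model.InitialStateModel(sigma_0=0.0)
        assert np.array_equal(
            model.sample_initial_state(init, np.random.default_rng(0)), X0
        )

    def test_initial_state_spread(self):
        init = model.InitialStateModel(sigma_0=0.05)
        draws = model.sample_initial_state(init, np.random.default_rng(1), size=10**5)
        # S2 has mean 0.08, so the floor clips a tiny fraction of draws there;
        # check the unclipped components
        stds = draws[:, :6].std(axis=0)
        assert np.allclose(stds, 0.05, rtol=0.03)
        assert np.all(draws >= 0.0)


class TestGridValidation:
    def test_incompatible_grid_rejected(self):
        with pytest.raises(ValueError):
            model.SimulationGrid(h=1e-3, m0=7, t_total=0.01)

    def test_counts(self):
        grid = model.SimulationGrid(h=1e-3, m0=20, t_total=80.0)
        assert grid.n_steps == 80_000
        assert grid.n_observations == 4_000
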