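import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.integrate import solve_ivp

from glvsim import (
    DivergenceError,
    DomainError,
    InteractionMap,
    InterventionSpec,
    NodeSpec,
    SimulationConfig,
    glv_step,
    sample_reads,
    simulate_timecourse,
    to_relative,
)


def logistic_closed_form(t, g=1.0, a=0.5, z0=0.1):
    """Exact logistic solution with carrying capacity K = g/a."""
    K = g / a
    return K * z0 * np.exp(g * t) / (K + z0 * (np.exp(g * t) - 1.0))


class TestGlvStep:
    def test_zero_abundance_is_absorbing(self):
        z = np.zeros(4)
        out = glv_step(z, np.ones(4), np.eye(4), np.ones(4), np.ones(4), 0.1)
        assert np.array_equal(out, np.zeros(4))

    def test_zero_derivative_returns_input_exactly(self):
        z = np.array([0.3, 1.7])
        out = glv_step(z, np.zeros(2), np.zeros((2, 2)), np.zeros(2), np.zeros(2), 0.05)
        assert np.array_equal(out, z)

    def test_logistic_iteration_converges_to_fixed_point(self):
        z = np.array([0.1])
        for _ in range(5000):
            z = glv_step(z, np.array([1.0]), np.array([[-0.5]]), np.zeros(1), np.zeros(1), 0.01)
        assert abs(z[0] - 2.0) < 1e-3

    def test_negative_excursion_clamped_to_zero(self):
        # strong decay: z + dt*z*rate < 0 -> clamped
        out = glv_step(np.array([1.0]), np.array([-200.0]), np.zeros((1, 1)),
                       np.zeros(1), np.zeros(1), 0.01)
        assert out[0] == 0.0

    def test_divergence_raises_with_step_index(self):
        huge = np.array([1e308])
        with pytest.raises(DivergenceError) as err:
            glv_step(huge, np.array([1e308]), np.zeros((1, 1)),
                     np.zeros(1), np.zeros(1), 1.0, step=17)
        assert err.value.step == 17
        assert err.value.coordinates == [0]


class TestSimulateTimecourse:
    def test_stationary_system_keeps_initial_abundances(self):
        nodes = [
            NodeSpec("a", 2, np.zeros(2), np.array([1.0, 2.0])),
            NodeSpec("b", 1, np.zeros(1), np.array([3.0])),
        ]
        cfg = SimulationConfig(n_timepoints=10, noise_var=0.0, n_reads=100, seed=0)
        tc = simulate_timecourse(nodes, InteractionMap(), [], cfg)
        assert np.array_equal(tc.Z, np.tile([1.0, 2.0, 3.0], (10, 1)))

    def test_logistic_terminal_value(self, logistic_system):
        node, imap = logistic_system
        cfg = SimulationConfig(n_timepoints=5000, dt=0.01, noise_var=0.0, n_reads=100, seed=1)
        tc = simulate_timecourse([node], imap, [], cfg)
        assert abs(tc.Z[-1, 0] - 2.0) < 1e-3

    def test_logistic_matches_independent_integrator(self, logistic_system):
        """Euler trajectory tracks a high-resolution ODE solve and the closed form."""
        node, imap = logistic_system
        cfg = SimulationConfig(n_timepoints=2000, dt=0.01, noise_var=0.0, n_reads=100, seed=1)
        tc = simulate_timecourse([node], imap, [], cfg)
        sol = solve_ivp(
            lambda t, z: z * (1.0 - 0.5 * z), (0, tc.times[-1]), [0.1],
            t_eval=tc.times, rtol=1e-10, atol=1e-12,
        )
        rel = np.abs(tc.Z[:, 0] - sol.y[0]) / sol.y[0]
        assert abs(tc.Z[-1, 0] - sol.y[0][-1]) < 1e-3 * sol.y[0][-1]
        assert rel.max() < 1e-2  # O(dt) transient envelope of forward Euler
        # closed form agrees with the ODE oracle (oracle self-check)
        assert np.allclose(sol.y[0], logistic_closed_form(tc.times), rtol=1e-8)

    def test_monotone_convergence_after_transient(self, logistic_system):
        node, imap = logistic_system
        cfg = SimulationConfig(n_timepoints=3000, dt=0.01, noise_var=0.0, n_reads=100, seed=1)
        tc = simulate_timecourse([node], imap, [], cfg)
        z = tc.Z[:, 0]
        assert np.all(np.diff(z) >= -1e-12)  # monotone rise from below K

    def test_seed_determinism(self, small_community, quiet_sim_config):
        nodes, imap, _ = small_community
        cfg = SimulationConfig(n_timepoints=20, noise_var=0.05, n_reads=200, seed=42)
        a = simulate_timecourse(nodes, imap, [], cfg)
        b = simulate_timecourse(nodes, imap, [], cfg)
        assert np.array_equal(a.Z, b.Z)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.Y, b.Y)

    def test_absorbing_zeros_under_noise_and_intervention(self):
        """A dimension starting at 0 stays exactly 0 whatever the forcing."""
        nodes = [NodeSpec("a", 3, np.array([0.5, 0.8, -0.2]), np.array([1.0, 0.0, 2.0]))]
        imap = InteractionMap({("a", "a"): np.full((3, 3), 0.2) - np.eye(3)})
        iv = InterventionSpec("a", np.ones(15), np.array([5.0, 5.0, 5.0]))
        for seed in range(20):
            cfg = SimulationConfig(n_timepoints=15, noise_var=0.5, n_reads=100, seed=seed)
            tc = simulate_timecourse(nodes, imap, [iv], cfg)
            assert np.all(tc.Z[:, 1] == 0.0)
            assert np.all(tc.Y[:, 1] == 0)

    def test_intervention_applies_only_to_target_node(self):
        nodes = [
            NodeSpec("a", 1, np.zeros(1), np.array([1.0])),
            NodeSpec("b", 1, np.zeros(1), np.array([1.0])),
        ]
        iv = InterventionSpec("b", np.ones(10), np.array([0.5]))
        cfg = SimulationConfig(n_timepoints=10, noise_var=0.0, n_reads=100, seed=0)
        tc = simulate_timecourse(nodes, InteractionMap(), [iv], cfg)
        assert np.all(tc.Z[:, 0] == 1.0)  # untargeted node is untouched
        assert tc.Z[-1, 1] > 1.0  # targeted node is driven up

    def test_burn_in_and_downsample_grid(self, logistic_system):
        """burn_in shifts the first sample; downsample strides the grid."""
        node, imap = logistic_system
        full = simulate_timecourse([node], imap, [], SimulationConfig(
            n_timepoints=21, noise_var=0.0, n_reads=100, seed=0))
        strided = simulate_timecourse([node], imap, [], SimulationConfig(
            n_timepoints=5, noise_var=0.0, n_reads=100, seed=0, burn_in=4, downsample=4))
        assert np.allclose(strided.times, full.times[4::4])
        assert np.allclose(strided.Z[:, 0], full.Z[4::4, 0])

    def test_shape_mismatch_raises(self, logistic_system):
        node, imap = logistic_system
        iv = InterventionSpec("n", np.ones(3), np.array([1.0]))  # wrong |T|
        cfg = SimulationConfig(n_timepoints=10, n_reads=10, seed=0)
        with pytest.raises(Exception, match="magnitudes"):
            simulate_timecourse([node], imap, [iv], cfg)


class TestToRelative:
    def test_direct_normalization(self):
        assert np.allclose(to_relative(np.array([[2.0, 2.0, 4.0]])), [[0.25, 0.25, 0.5]])

    def test_zero_row_maps_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = to_relative(np.array([[0.0, 0.0], [1.0, 3.0]]))
        assert np.array_equal(out[0], [0.0, 0.0])
        assert np.allclose(out[1], [0.25, 0.75])
        assert any("all-zero" in r.message for r in caplog.records)

    def test_negative_entries_rejected(self):
        with pytest.raises(DomainError):
            to_relative(np.array([[1.0, -1.0]]))

    @given(hnp.arrays(np.float64, (3, 5), elements=st.floats(0.0, 1e6)))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one_or_zero(self, Z):
        X = to_relative(Z)
        sums = X.sum(axis=1)
        zero = Z.sum(axis=1) == 0
        assert np.all(np.abs(sums[~zero] - 1.0) < 1e-12)
        assert np.all(sums[zero] == 0.0)


class TestSampleReads:
    def test_degenerate_row(self):
        Y = sample_reads(np.array([[1.0, 0.0, 0.0]]), 100, seed=0)
        assert np.array_equal(Y, [[100, 0, 0]])

    def test_zero_row_yields_zero_counts(self):
        Y = sample_reads(np.array([[0.0, 0.0]]), 50, seed=0)
        assert np.array_equal(Y, [[0, 0]])

    def test_row_sum_out_of_tolerance_rejected(self):
        with pytest.raises(DomainError):
            sample_reads(np.array([[0.6, 0.6]]), 10, seed=0)

    def test_row_sums_equal_read_depth(self):
        rng = np.random.default_rng(3)
        X = to_relative(rng.random((20, 6)))
        Y = sample_reads(X, 777, seed=1)
        assert np.all(Y.sum(axis=1) == 777)

    def test_monte_carlo_mean_matches_binomial_moments(self):
        """1000 draws of (0.5, 0.5) at R=10^4: mean first count ~ 5000 +/- 3 SE."""
        X = np.tile([0.5, 0.5], (1000, 1))
        Y = sample_reads(X, 10_000, seed=5)
        # sd per draw = sqrt(R * 0.25) = 50; 3 SE of the mean over 1000 draws
        assert abs(Y[:, 0].mean() - 5000) < 15

    def test_law_of_large_numbers_in_read_depth(self):
        """Max |Y/R - X| shrinks as R grows (averaged over seeded draws)."""
        rng = np.random.default_rng(9)
        x = rng.dirichlet(np.ones(8))
        devs = []
        for R in (100, 1000, 10_000, 100_000):
            X = np.tile(x, (200, 1))
            Y = sample_reads(X, R, seed=13)
            devs.append(np.abs(Y / R - x).max(axis=1).mean())
        assert all(a > b for a, b in zip(devs, devs[1:]))
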