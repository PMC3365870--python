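"""Network SDE integration, escape detection and escape statistics."""

import math
import warnings

import numpy as np
import pytest

from escapenet import (
    DirectedGraph,
    NodeParameters,
    SimulationConfig,
    Trajectory,
    dynkin_mean_exit,
    escape_ensemble,
    exponential_fit,
    integrate_sde,
    network_escape_time,
    node_transition_times,
    transitions_per_hour,
)
from escapenet.simulate import EscapeSample, _escape_times_batch


def make_sample(times: np.ndarray, t_max: float = 1e9) -> EscapeSample:
    mean = float(np.mean(times))
    return EscapeSample(
        escape_times=np.asarray(times, float),
        n_censored=0,
        t_max=t_max,
        mean=mean,
        gamma_rate=1 / mean,
        gamma_ci=(float("nan"), float("nan")),
    )


class TestIntegrator:
    def test_origin_is_invariant_without_noise(self, complete3):
        p = NodeParameters(0.9, 20.0, alpha=0.0)
        cfg = SimulationConfig(dt=0.01, t_max=1.0, coupling_beta=1.0)
        traj = integrate_sde(complete3, p, cfg, np.zeros(3, complex))
        assert np.all(traj.states == 0)

    def test_stable_cycle_modulus_constant_phase_advances_at_omega(self):
        p = NodeParameters(lambda_=0.9, omega=20.0, alpha=0.0)
        r_s = math.sqrt(1 + math.sqrt(0.9))
        cfg = SimulationConfig(dt=0.001, t_max=2.0, coupling_beta=0.0)
        traj = integrate_sde(DirectedGraph.empty(1), p, cfg, np.array([r_s + 0j]))
        radii = np.abs(traj.states[:, 0])
        assert np.allclose(radii, r_s, rtol=1e-6)
        phase = np.unwrap(np.angle(traj.states[:, 0]))
        slope = np.polyfit(traj.times, phase, 1)[0]
        assert slope == pytest.approx(20.0, rel=1e-3)

    def test_synchronised_network_follows_isolated_node(self, complete3):
        """Diffusive coupling vanishes on the synchrony manifold: equal
        initial states evolve exactly as the isolated node."""
        p = NodeParameters(0.7, 20.0, alpha=0.0)
        z0 = 0.3 + 0.1j
        cfg = SimulationConfig(dt=0.002, t_max=1.0, coupling_beta=5.0)
        net = integrate_sde(complete3, p, cfg, np.full(3, z0))
        single = integrate_sde(DirectedGraph.empty(1), p, cfg, np.array([z0]))
        assert np.allclose(net.states, single.states[:, [0] * 3], rtol=1e-10)

    def test_blowup_aborts_with_diagnostics(self, complete3):
        p = NodeParameters(0.9, 20.0, alpha=0.01)
        # dt far beyond the coupling stability limit; threshold above the
        # safety bound so divergence cannot masquerade as an escape
        cfg = SimulationConfig(
            dt=0.05, t_max=50.0, coupling_beta=100.0, seed=1,
            escape_threshold_sq=1e8,
        )
        with pytest.raises(RuntimeError, match="reduce dt"):
            escape_ensemble(complete3, p, cfg, 4)


class TestEscapeDetection:
    def test_pinned_trajectory_never_crosses(self):
        traj = Trajectory(times=np.arange(5.0), states=np.zeros((5, 2), complex))
        assert np.all(np.isnan(node_transition_times(traj, 0.1)))

    def test_initial_condition_beyond_boundary_crosses_at_zero(self):
        states = np.full((4, 1), 2.0 + 0j)
        traj = Trajectory(times=np.arange(4.0), states=states)
        assert node_transition_times(traj, 0.1)[0] == 0.0

    def test_crossing_time_interpolated(self):
        # |z|^2 goes 0 -> 0.04 -> 0.16; threshold 0.1 crossed 0.5 of the
        # way through the second step
        states = np.array([[0.0], [0.2], [0.4]], dtype=complex)
        traj = Trajectory(times=np.array([0.0, 1.0, 2.0]), states=states)
        t = node_transition_times(traj, 0.1)[0]
        assert t == pytest.approx(1.5)

    def test_network_escape_is_kth_order_statistic(self):
        # three nodes crossing at t = 5, 9, 14 -> network escape at 9
        times = np.arange(0.0, 20.0, 1.0)
        states = np.zeros((len(times), 3), complex)
        for node, tc in enumerate((5, 9, 14)):
            states[times >= tc, node] = 1.0
        traj = Trajectory(times=times, states=states)
        cfg = SimulationConfig(network_escape_fraction=0.5)
        assert network_escape_time(traj, cfg, threshold_sq=0.5) == pytest.approx(9.0, abs=0.5)

    def test_all_censored_marker(self):
        traj = Trajectory(times=np.arange(5.0), states=np.zeros((5, 3), complex))
        cfg = SimulationConfig()
        assert network_escape_time(traj, cfg, threshold_sq=0.1) is None

    def test_single_node_fraction(self):
        states = np.array([[0.0], [1.0]], dtype=complex)
        traj = Trajectory(times=np.array([0.0, 1.0]), states=states)
        cfg = SimulationConfig(network_escape_fraction=0.5)
        t = network_escape_time(traj, cfg, threshold_sq=0.25)
        assert t == node_transition_times(traj, 0.25)[0]


class TestEnsemble:
    def test_bit_identical_repeat_runs(self, complete3, reference_params):
        cfg = SimulationConfig(dt=0.005, t_max=200.0, seed=5, coupling_beta=1.0)
        s1 = escape_ensemble(complete3, reference_params, cfg, 40)
        s2 = escape_ensemble(complete3, reference_params, cfg, 40)
        assert np.array_equal(s1.escape_times, s2.escape_times)
        assert s1.gamma_ci == s2.gamma_ci

    def test_numpy_fallback_matches_compiled_kernel(self, complete3, reference_params, monkeypatch):
        """The pure-numpy stepping path and the compiled kernel implement
        the same scheme on the same noise streams."""
        import escapenet._kernels as kernels

        cfg = SimulationConfig(dt=0.005, t_max=300.0, seed=4, coupling_beta=1.0)
        fast = _escape_times_batch(complete3, reference_params, cfg, 20)
        monkeypatch.setattr(kernels, "HAVE_NUMBA", False)
        slow = _escape_times_batch(complete3, reference_params, cfg, 20)
        assert np.allclose(fast, slow, rtol=1e-10, equal_nan=True)

    def test_trial_reproducible_in_isolation(self, complete3, reference_params):
        """Per-trial seed streams: trial k alone equals trial k in a batch."""
        cfg = SimulationConfig(dt=0.005, t_max=300.0, seed=9, coupling_beta=1.0)
        batch = _escape_times_batch(complete3, reference_params, cfg, 6)
        solo = _escape_times_batch(complete3, reference_params, cfg, 1, first_trial=3)
        assert batch[3] == solo[0]

    def test_single_node_mean_matches_dynkin_oracle(self, reference_params):
        """MC absorbed at the separatrix agrees with the exact BVP within
        3 standard errors (lambda = 0.9, alpha = 0.05)."""
        lam = reference_params.lambda_
        cfg = SimulationConfig(
            dt=0.005, t_max=400.0, seed=21,
            escape_threshold_sq=1 - math.sqrt(lam),
        )
        s = escape_ensemble(DirectedGraph.empty(1), reference_params, cfg, 2000)
        bvp = dynkin_mean_exit(lam, reference_params.alpha)
        assert abs(s.mean - bvp) < 3 * s.standard_error

    def test_disconnected_network_escape_independent_of_beta(self, reference_params):
        """With no edges the vector field never sees beta: identical
        noise streams give identical escapes."""
        g = DirectedGraph.empty(2)
        results = []
        for beta in (0.01, 1.0, 100.0):
            cfg = SimulationConfig(dt=0.005, t_max=300.0, seed=3, coupling_beta=beta)
            results.append(escape_ensemble(g, reference_params, cfg, 50).escape_times)
        assert np.array_equal(results[0], results[1])
        assert np.array_equal(results[0], results[2])

    def test_censoring_enters_mean_as_exposure(self):
        p = NodeParameters(0.9, 20.0, 0.05)
        cfg = SimulationConfig(dt=0.005, t_max=15.0, seed=2)
        s = escape_ensemble(DirectedGraph.empty(1), p, cfg, 150)
        assert s.n_censored > 0
        expected = (s.escape_times.sum() + s.n_censored * cfg.t_max) / len(s.escape_times)
        assert s.mean == pytest.approx(expected)

    def test_all_censored_is_an_error(self):
        p = NodeParameters(0.5, 20.0, 0.02)
        cfg = SimulationConfig(dt=0.005, t_max=5.0, seed=0)
        with pytest.raises(RuntimeError, match="censored"):
            escape_ensemble(DirectedGraph.empty(1), p, cfg, 5)

    def test_step_size_robustness(self, reference_params):
        """Halving dt moves the ensemble mean by less than the combined
        Monte-Carlo standard error."""
        lam = reference_params.lambda_
        thr = 1 - math.sqrt(lam)
        means, ses = [], []
        for dt in (0.005, 0.0025):
            cfg = SimulationConfig(dt=dt, t_max=400.0, seed=31, escape_threshold_sq=thr)
            s = escape_ensemble(DirectedGraph.empty(1), reference_params, cfg, 2000)
            means.append(s.mean)
            ses.append(s.standard_error)
        assert abs(means[0] - means[1]) < ses[0] + ses[1]


class TestExponentialFit:
    def test_parametric_recovery(self, rng):
        times = rng.exponential(scale=100.0, size=1000)
        fit = exponential_fit(make_sample(times))
        se = 0.01 / math.sqrt(1000)
        assert abs(fit.gamma - 0.01) < 2.5 * se
        assert fit.ks_pvalue > 0.01

    def test_single_observation(self):
        fit = exponential_fit(make_sample(np.array([40.0])))
        assert fit.gamma == pytest.approx(1 / 40.0)
        assert math.isnan(fit.ks_statistic)

    def test_small_sample_has_no_ks_screen(self, rng):
        fit = exponential_fit(make_sample(rng.exponential(10.0, size=20)))
        assert math.isnan(fit.ks_pvalue)

    def test_detects_non_exponential_tail(self, rng):
        times = rng.uniform(10.0, 20.0, size=500)
        fit = exponential_fit(make_sample(times))
        assert fit.ks_pvalue < 1e-6


class TestTransitionsPerHour:
    def test_renewal_rate_matches_reciprocal_mean(self, reference_params):
        g = DirectedGraph.empty(1)
        cfg = SimulationConfig(dt=0.005, t_max=400.0, seed=8)
        s = escape_ensemble(g, reference_params, cfg, 400)
        rate = transitions_per_hour(g, reference_params, cfg, total_hours=0.25)
        expected = 3600.0 / s.mean
        assert rate == pytest.approx(expected, rel=0.35)  # Poisson counting error

    def test_rate_monotone_in_noise(self):
        g = DirectedGraph.complete(2)
        rates = []
        for alpha in (0.05, 0.1, 0.2):
            p = NodeParameters(0.9, 20.0, alpha)
            cfg = SimulationConfig(dt=0.005, t_max=500.0, seed=12, coupling_beta=0.1)
            rates.append(transitions_per_hour(g, p, cfg, total_hours=0.1))
        assert rates[0] <= rates[1] <= rates[2]

    def test_deep_well_rate_zero_with_warning(self):
        p = NodeParameters(0.5, 20.0, 0.02)
        cfg = SimulationConfig(dt=0.005, t_max=20.0, seed=0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            rate = transitions_per_hour(DirectedGraph.empty(1), p, cfg, total_hours=0.01)
        assert rate == 0.0
        assert any("no transitions" in str(w.message) for w in caught)


class TestConfigValidation:
    def test_rejects_bad_settings(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(dt=1.0, t_max=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(adjacency_mode="spectral")
        with pytest.raises(ValueError):
            SimulationConfig(network_escape_fraction=0.0)

    def test_default_threshold_is_printed_exit_boundary(self):
        cfg = SimulationConfig()
        assert cfg.threshold_sq(NodeParameters(0.9, 20.0, 0.05)) == pytest.approx(0.1)
        cfg2 = SimulationConfig(escape_threshold_sq=0.25)
        assert cfg2.threshold_sq(NodeParameters(0.9, 20.0, 0.05)) == 0.25
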