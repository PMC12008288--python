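import numpy as np
import pytest
import scipy.linalg

from ctrlenergy.control import (
    ControlConfig,
    ControlSchedule,
    EnergyProfile,
    controllability_gramian,
    energy_timeseries,
    min_energy_closed_form,
    min_energy_transition,
    windowed_mean,
)
from ctrlenergy.states import StateSeries

from conftest import stable_system


def brute_force_energy(a, b, x0, xf, T=1.0, n_steps=2000):
    """Discretized least-squares oracle for the minimum control energy.

    Exact zero-order-hold discretization of the dynamics; the piecewise
    constant input sequence reaching xf with minimum sum(u'u) dt is the
    minimum-norm solution of the resulting linear map.
    """
    n = a.shape[0]
    dt = T / n_steps
    bmat = np.diag(np.broadcast_to(b, (n,)).astype(float))
    ad = scipy.linalg.expm(a * dt)
    bd = np.linalg.solve(a, (ad - np.eye(n))) @ bmat
    # xf - Ad^K x0 = sum_j Ad^(K-1-j) Bd u_j
    cols = np.empty((n, n * n_steps))
    acc = np.eye(n)
    for j in range(n_steps - 1, -1, -1):
        cols[:, j * n:(j + 1) * n] = acc @ bd
        acc = ad @ acc
    d = np.asarray(xf, float) - acc @ np.asarray(x0, float)  # acc = Ad^K
    u, *_ = np.linalg.lstsq(cols, d, rcond=None)
    return float(u @ u) * dt


class TestGramian:
    def test_scalar_closed_form(self):
        w = controllability_gramian(-np.eye(2), 1.0, T=1.0)
        np.testing.assert_allclose(w, (1 - np.exp(-2)) / 2 * np.eye(2), rtol=1e-12)

    def test_quadratic_scaling_in_b(self):
        rng = np.random.default_rng(0)
        a = stable_system(5, rng)
        b = rng.uniform(0.5, 2.0, 5)
        w1 = controllability_gramian(a, b)
        w3 = controllability_gramian(a, 3.0 * b)
        np.testing.assert_allclose(w3, 9.0 * w1, rtol=1e-10)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        a = stable_system(6, rng)
        b = rng.uniform(0.5, 2.0, 6)
        w = controllability_gramian(a, b, T=1.0)
        ts = np.linspace(0, 1, 4001)
        q = np.diag(b * b)
        vals = np.array(
            [scipy.linalg.expm(a * t) @ q @ scipy.linalg.expm(a.T * t) for t in ts]
        )
        w_quad = np.trapezoid(vals, ts, axis=0)
        np.testing.assert_allclose(w, w_quad, rtol=1e-6)

    def test_positive_definite(self):
        rng = np.random.default_rng(2)
        a = stable_system(8, rng)
        w = controllability_gramian(a, 1.0)
        assert np.all(np.linalg.eigvalsh(w) > 0)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            controllability_gramian(-np.eye(2), np.array([1.0, 0.0]))


class TestMinEnergyTransition:
    def test_zero_transition_zero_energy(self):
        rng = np.random.default_rng(3)
        a = stable_system(4, rng)
        regional, glob = min_energy_transition(a, 1.0, np.zeros(4), np.zeros(4))
        assert glob == 0.0
        np.testing.assert_array_equal(regional, np.zeros(4))

    def test_single_region_closed_form(self):
        # A = -1, b = 1, T = 1, x0 = 0 -> xf = 1: E = d' W^-1 d = 2/(1 - e^-2)
        _, glob = min_energy_transition(-np.eye(1), 1.0, [0.0], [1.0])
        assert glob == pytest.approx(2.0 / (1.0 - np.exp(-2.0)), rel=1e-9)

    def test_b_scaling_law(self):
        rng = np.random.default_rng(4)
        a = stable_system(5, rng)
        x0, xf = rng.standard_normal(5), rng.standard_normal(5)
        b = rng.uniform(0.5, 2.0, 5)
        _, e1 = min_energy_transition(a, b, x0, xf)
        _, e2 = min_energy_transition(a, 2.0 * b, x0, xf)
        assert e2 == pytest.approx(e1 / 4.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_trajectory_integral_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a = stable_system(6, rng)
        b = rng.uniform(0.5, 2.0, 6)
        x0, xf = rng.standard_normal(6), rng.standard_normal(6)
        _, glob = min_energy_transition(a, b, x0, xf)
        closed = min_energy_closed_form(a, b, x0, xf)
        assert glob == pytest.approx(closed, rel=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = stable_system(4, rng)
        x0, xf = rng.standard_normal(4), rng.standard_normal(4)
        _, glob = min_energy_transition(a, 1.0, x0, xf)
        assert glob == pytest.approx(brute_force_energy(a, 1.0, x0, xf), rel=5e-3)

    def test_reachability_of_target_state(self):
        """Integrating the dynamics under u*(t) lands on xf."""
        rng = np.random.default_rng(5)
        n = 8
        a = stable_system(n, rng)
        b = rng.uniform(0.5, 1.5, n)
        x0, xf = rng.standard_normal(n), rng.standard_normal(n)
        T = 1.0
        w = controllability_gramian(a, b, T)
        d = xf - scipy.linalg.expm(a * T) @ x0
        lam = scipy.linalg.solve(w, d, assume_a="pos")
        bmat = np.diag(b)

        m = 4001
        ts = np.linspace(0, T, m)
        x = x0.astype(float).copy()
        step = scipy.linalg.expm(a * (T / (m - 1)))
        half = T / (m - 1) / 2.0
        u = lambda t: bmat @ scipy.linalg.expm(a.T * (T - t)) @ lam
        for k in range(m - 1):
            # trapezoidal update of the input convolution
            x = step @ x + half * (step @ (bmat @ u(ts[k])) + bmat @ u(ts[k + 1]))
        np.testing.assert_allclose(x, xf, rtol=2e-4, atol=2e-4)


class TestEnergyTimeseries:
    def test_constant_zero_series_gives_zero(self):
        a = -np.eye(3)
        series = StateSeries(np.zeros((3, 5)), injection_volume=1)
        prof = energy_timeseries(series, a)
        np.testing.assert_array_equal(prof.global_, np.zeros(4))

    def test_quadratic_scaling_in_states(self):
        rng = np.random.default_rng(6)
        a = stable_system(4, rng)
        x = rng.standard_normal((4, 6))
        p1 = energy_timeseries(StateSeries(x), a)
        p3 = energy_timeseries(StateSeries(3.0 * x), a)
        np.testing.assert_allclose(p3.regional, 9.0 * p1.regional, rtol=1e-9)

    def test_matches_per_transition_calls(self, synth_cfg, connectome, bold):
        from ctrlenergy.connectome import stabilize

        drug, _ = bold
        series = drug[0]
        sys = stabilize(connectome)
        cfg = ControlConfig(integration_steps=101)
        prof = energy_timeseries(series, sys, cfg=cfg)
        x = series.states
        for k in [0, 7, series.n_transitions - 1]:
            regional, glob = min_energy_transition(
                sys, 1.0, x[:, k], x[:, k + 1], cfg
            )
            np.testing.assert_allclose(prof.regional[:, k], regional, rtol=1e-9)
            assert prof.global_[k] == pytest.approx(glob, rel=1e-9)

    def test_network_rows_sum_to_global(self, synth_cfg, connectome, bold):
        from ctrlenergy.connectome import stabilize

        _, placebo = bold
        prof = energy_timeseries(
            placebo[0], stabilize(connectome),
            cfg=ControlConfig(integration_steps=101), connectome=connectome,
        )
        assert prof.network is not None
        np.testing.assert_allclose(
            prof.network.sum(axis=0), prof.global_, rtol=1e-9
        )

    def test_schedule_shape_mismatch_rejected(self):
        a = -np.eye(3)
        series = StateSeries(np.random.default_rng(0).standard_normal((3, 5)))
        bad = ControlSchedule(np.ones((3, 2)))
        with pytest.raises(ValueError, match="schedule"):
            energy_timeseries(series, a, schedule=bad)


class TestControlSchedule:
    def test_uniform_flag_consistency(self):
        s = ControlSchedule.make_uniform(3, 4)
        assert s.uniform
        s2 = ControlSchedule(np.full((3, 4), 2.0))
        assert not s2.uniform

    def test_nonpositive_entries_rejected(self):
        with pytest.raises(ValueError):
            ControlSchedule(np.zeros((2, 2)))


class TestWindowedMean:
    def test_count_arithmetic_drops_partial_window(self):
        # 838 transitions at TR = 2 s -> 27 complete 60 s windows of 30
        out = windowed_mean(np.arange(838, dtype=float), 60.0, 2.0)
        assert out.size == 27
        np.testing.assert_allclose(out[0], np.arange(30).mean())

    def test_constant_series(self):
        out = windowed_mean(np.full(90, 3.25), 60.0, 2.0)
        np.testing.assert_array_equal(out, np.full(3, 3.25))

    def test_window_equal_to_series_is_grand_mean(self):
        x = np.random.default_rng(1).standard_normal(30)
        out = windowed_mean(x, 60.0, 2.0)
        assert out.size == 1
        assert out[0] == pytest.approx(x.mean())

    def test_subtr_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_mean(np.zeros(10), 1.0, 2.0)


class TestEnergyProfile:
    def test_global_is_column_sum(self):
        r = np.abs(np.random.default_rng(2).standard_normal((5, 7)))
        prof = EnergyProfile(regional=r)
        np.testing.assert_allclose(prof.global_, r.sum(axis=0), rtol=1e-12)

    def test_negative_regional_rejected(self):
        with pytest.raises(ValueError):
            EnergyProfile(regional=np.array([[-1.0, 0.0]]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ControlConfig(integration_steps=100)   # even
        with pytest.raises(ValueError):
            ControlConfig(time_horizon=0.0)
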