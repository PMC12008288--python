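import numpy as np
import pytest

from ctrlenergy.connectome import stabilize
from ctrlenergy.control import ControlConfig, ControlSchedule, energy_timeseries
from ctrlenergy.pksim import (
    ConcentrationSeries,
    PkParams,
    ScheduleSpec,
    build_schedule,
    compare_models,
    fit_alpha_grid,
    simulate_concentration,
    simulate_drug_energy,
)
from ctrlenergy.regional import ReceptorMap
from ctrlenergy.states import StateSeries


@pytest.fixture(scope="module")
def concentration():
    return simulate_concentration(PkParams(), np.arange(-60.0, 1500.0, 2.0))


class TestSimulateConcentration:
    def test_mass_balance_auc_identity(self):
        """For a mammillary system, plasma AUC times clearance equals the dose."""
        p = PkParams()
        grid = np.arange(0.0, 8 * 3600.0, 2.0)
        cs = simulate_concentration(p, grid)
        auc_ng_min_per_ml = np.trapezoid(cs.plasma, grid / 60.0)
        cleared_ng = auc_ng_min_per_ml * p.clearance_l_per_min * 1000.0
        assert cleared_ng == pytest.approx(p.dose_mg * 1e6, rel=5e-3)

    def test_bolus_without_elimination_plateaus_at_dose_over_volume(self):
        p = PkParams(n_compartments=1, volumes=(10.0,),
                     rate_constants={"k10": 0.0}, infusion_seconds=0.5)
        cs = simulate_concentration(p, np.arange(0.0, 120.0, 0.5))
        # 20 mg into 10 L = 2 ug/mL = 2000 ng/mL for all t past the infusion
        np.testing.assert_allclose(cs.plasma[cs.times > 1.0], 2000.0, rtol=1e-9)

    def test_instant_equilibration_limit(self):
        p = PkParams(ke0=1e6)
        cs = simulate_concentration(p, np.arange(0.0, 300.0, 1.0))
        late = cs.times > 1.0
        np.testing.assert_allclose(cs.effect[late], cs.plasma[late], rtol=1e-3)

    def test_effect_peak_lags_plasma_peak(self, concentration):
        cs = concentration
        assert cs.times[np.argmax(cs.effect)] >= cs.times[np.argmax(cs.plasma)]

    @pytest.mark.parametrize("seed", range(5))
    def test_effect_lag_on_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        p = PkParams(
            volumes=(rng.uniform(10, 50), rng.uniform(20, 100)),
            rate_constants={"k10": rng.uniform(0.2, 1.5),
                            "k12": rng.uniform(0.1, 1.0),
                            "k21": rng.uniform(0.1, 1.0)},
            ke0=rng.uniform(0.1, 2.0),
        )
        cs = simulate_concentration(p, np.arange(0.0, 1800.0, 2.0))
        assert cs.times[np.argmax(cs.effect)] >= cs.times[np.argmax(cs.plasma)]

    def test_zero_before_infusion(self, concentration):
        pre = concentration.times < 0
        np.testing.assert_array_equal(concentration.plasma[pre], 0.0)
        np.testing.assert_array_equal(concentration.effect[pre], 0.0)

    def test_flush_adds_drug(self):
        base = PkParams()
        flushed = PkParams(flush=(5.0, 15.0))
        grid = np.arange(0.0, 600.0, 1.0)
        c0 = simulate_concentration(base, grid)
        c1 = simulate_concentration(flushed, grid)
        assert c1.plasma.max() > c0.plasma.max()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PkParams(volumes=(0.0, 1.0))
        with pytest.raises(ValueError):
            PkParams(rate_constants={"k10": 0.5})    # missing k12/k21
        with pytest.raises(ValueError):
            PkParams(ke0=0.0)


def _rmap(n=6):
    rng = np.random.default_rng(0)
    return ReceptorMap(np.exp(rng.standard_normal(n)))


class TestBuildSchedule:
    def test_alpha_zero_gives_uniform(self, concentration):
        sched = build_schedule(concentration, _rmap(), ScheduleSpec(alpha=0.0,
                               injection_volume=5), n_transitions=20)
        assert sched.uniform

    def test_zero_concentration_multiplicative_uniform(self):
        conc = ConcentrationSeries(np.arange(0.0, 100.0, 2.0),
                                   np.zeros(50), np.zeros(50))
        sched = build_schedule(conc, _rmap(), ScheduleSpec(alpha=30.0,
                               mode="multiplicative", injection_volume=5),
                               n_transitions=20)
        assert sched.uniform

    def test_uniform_density_additive_identical_across_regions(self, concentration):
        rho = ReceptorMap(np.full(6, 3.0))
        sched = build_schedule(concentration, rho, ScheduleSpec(alpha=10.0,
                               injection_volume=5), n_transitions=20)
        np.testing.assert_allclose(sched.v, np.tile(sched.v[0], (6, 1)))

    def test_preinjection_columns_are_ones(self, concentration):
        sched = build_schedule(concentration, _rmap(), ScheduleSpec(alpha=30.0,
                               injection_volume=10), n_transitions=30)
        np.testing.assert_array_equal(sched.v[:, :9], 1.0)
        assert np.all(sched.v >= 1.0)       # control is only ever added

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            ScheduleSpec(alpha=-1.0)


@pytest.fixture(scope="module")
def small_system():
    rng = np.random.default_rng(42)
    n, v, subjects = 6, 40, 3
    w = np.abs(rng.standard_normal((n, n)))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    system = stabilize(w)
    placebo = []
    for s in range(subjects):
        x = rng.standard_normal((n, v))
        placebo.append(StateSeries(x, injection_volume=12,
                                   subject_id=f"sub-{s}", condition="placebo"))
    rmap = ReceptorMap(np.exp(rng.standard_normal(n)))
    cfg = ControlConfig(integration_steps=101)
    return system, placebo, rmap, cfg


class TestSimulateDrugEnergy:
    def test_uniform_schedule_reproduces_placebo_energy(self, small_system):
        system, placebo, _, cfg = small_system
        k = placebo[0].n_transitions
        sched = ControlSchedule.make_uniform(6, k)
        sim = simulate_drug_energy(placebo, system, sched, cfg)
        direct = np.mean(
            [energy_timeseries(s, system, cfg=cfg).global_ for s in placebo], axis=0
        )
        np.testing.assert_allclose(sim.group_global, direct, rtol=1e-9)

    def test_added_control_strictly_lowers_post_energy(self, small_system,
                                                       concentration):
        system, placebo, rmap, cfg = small_system
        k = placebo[0].n_transitions
        uniform = simulate_drug_energy(
            placebo, system, ControlSchedule.make_uniform(6, k), cfg)
        sched = build_schedule(concentration, rmap,
                               ScheduleSpec(alpha=10.0, injection_volume=12), k)
        boosted = simulate_drug_energy(placebo, system, sched, cfg)
        post = slice(12, k)
        assert np.all(boosted.group_global[post] < uniform.group_global[post])
        np.testing.assert_allclose(boosted.group_global[:11],
                                   uniform.group_global[:11], rtol=1e-9)

    def test_energy_monotone_decreasing_in_alpha(self, small_system, concentration):
        system, placebo, rmap, cfg = small_system
        k = placebo[0].n_transitions
        means = []
        for alpha in (0.0, 5.0, 20.0, 60.0):
            sched = build_schedule(concentration, rmap,
                                   ScheduleSpec(alpha=alpha, injection_volume=12), k)
            sim = simulate_drug_energy(placebo, system, sched, cfg)
            means.append(sim.group_global[12:].mean())
        assert all(a > b for a, b in zip(means, means[1:]))


class TestFitAlphaGrid:
    def test_self_consistency_recovers_planted_alpha(self, small_system,
                                                     concentration):
        system, placebo, rmap, cfg = small_system
        k = placebo[0].n_transitions
        spec = ScheduleSpec(injection_volume=12)
        planted = build_schedule(concentration, rmap,
                                 ScheduleSpec(alpha=20.0, injection_volume=12), k)
        truth = simulate_drug_energy(placebo, system, planted, cfg).group_global
        best, distances, sims = fit_alpha_grid(
            placebo, truth, system, concentration, rmap, spec=spec,
            grid=(1.0, 10.0, 20.0, 30.0, 40.0), cfg=cfg)
        assert best == 20.0
        assert distances[20.0] == pytest.approx(0.0, abs=1e-9)
        assert all(d >= 0 for d in distances.values())

    def test_argmin_stable_under_grid_reordering(self, small_system, concentration):
        system, placebo, rmap, cfg = small_system
        k = placebo[0].n_transitions
        spec = ScheduleSpec(injection_volume=12)
        planted = build_schedule(concentration, rmap,
                                 ScheduleSpec(alpha=10.0, injection_volume=12), k)
        truth = simulate_drug_energy(placebo, system, planted, cfg).group_global
        b1, *_ = fit_alpha_grid(placebo, truth, system, concentration, rmap,
                                spec=spec, grid=(1.0, 10.0, 30.0), cfg=cfg)
        b2, *_ = fit_alpha_grid(placebo, truth, system, concentration, rmap,
                                spec=spec, grid=(30.0, 1.0, 10.0), cfg=cfg)
        assert b1 == b2 == 10.0

    def test_empty_grid_rejected(self, small_system, concentration):
        system, placebo, rmap, cfg = small_system
        with pytest.raises(ValueError, match="empty"):
            fit_alpha_grid(placebo, np.zeros(placebo[0].n_transitions), system,
                           concentration, rmap, grid=(), cfg=cfg)


class TestCompareModels:
    def test_matched_variant_wins_on_effect_receptor_data(self, small_system,
                                                          concentration):
        system, placebo, rmap, cfg = small_system
        k = placebo[0].n_transitions
        spec = ScheduleSpec(injection_volume=12)
        planted = build_schedule(concentration, rmap,
                                 ScheduleSpec(alpha=20.0, injection_volume=12), k)
        truth = simulate_drug_energy(placebo, system, planted, cfg).group_global
        out = compare_models(placebo, truth, concentration, rmap, system,
                             spec=spec, grid=(1.0, 10.0, 20.0, 40.0), cfg=cfg)
        assert set(out) == {"effect+receptor", "plasma+receptor", "effect+uniform"}
        best_variant = min(out, key=lambda v: out[v][1])
        assert best_variant == "effect+receptor"
        assert all(d >= 0 for _, d in out.values())

    def test_uniform_data_matched_by_uniform_variant(self, small_system,
                                                     concentration):
        system, placebo, _, cfg = small_system
        k = placebo[0].n_transitions
        spec = ScheduleSpec(injection_volume=12)
        uniform_rho = ReceptorMap(np.full(6, 2.0))
        planted = build_schedule(concentration, uniform_rho,
                                 ScheduleSpec(alpha=20.0, injection_volume=12), k)
        truth = simulate_drug_energy(placebo, system, planted, cfg).group_global
        out = compare_models(placebo, truth, concentration, uniform_rho, system,
                             spec=spec, grid=(1.0, 10.0, 20.0, 40.0), cfg=cfg)
        assert out["effect+uniform"][1] == pytest.approx(0.0, abs=1e-8)

    def test_unknown_variant_rejected(self, small_system, concentration):
        system, placebo, rmap, cfg = small_system
        with pytest.raises(ValueError, match="unknown variant"):
            compare_models(placebo, np.zeros(placebo[0].n_transitions),
                           concentration, rmap, system,
                           variants=("plasma+uniform",), cfg=cfg)
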