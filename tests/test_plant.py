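"""Plant dynamics: pump fluxes, enzyme kinetics, integration, generators."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from chromostat.errors import ActuationError, ParameterError
from chromostat.plant import (
    GDH_MIX_MM,
    ElectrodeModel,
    GDHParams,
    PlantState,
    VesiclePreparation,
    build_default_plant,
    gdh_rate,
    measure_voltage,
    plant_derivatives,
    pump_flux,
    sample_vesicle_population,
    simulate,
    simulate_digestion_assay,
    step_plant,
    wash_to_pH,
    with_substrates,
)

BLUE = {"blue": 1.0, "red": 0.0}
RED = {"blue": 0.0, "red": 1.0}
DARK = {"blue": 0.0, "red": 0.0}


def _pump(model, name):
    return next(p for p in model.pumps if p.name == name)


class TestPumpFlux:
    def test_dark_flux_is_zero(self, default_plant):
        state = wash_to_pH(7.0)
        for pump in default_plant.pumps:
            assert pump_flux(pump, state, DARK) == 0.0

    def test_stall_at_maximal_gradient(self, default_plant):
        """A pump cannot move protons against a fully established gradient."""
        bpr = _pump(default_plant, "BPR")
        dmax = bpr.kinetics.dph_max
        # BPR acidifies outside -> its opposing gradient is ph_in - ph_out
        state = PlantState(ph_out=6.0, ph_in=6.0 + dmax)
        assert pump_flux(bpr, state, BLUE) == 0.0

    def test_backpressure_linear_halfway(self, default_plant):
        bpr = _pump(default_plant, "BPR")
        dmax = bpr.kinetics.dph_max
        fresh = PlantState(ph_out=7.0, ph_in=7.0)
        # hold ph_out fixed so the activity window is identical in both states
        half = PlantState(ph_out=7.0, ph_in=7.0 + dmax / 2)
        assert pump_flux(bpr, half, BLUE) == pytest.approx(
            0.5 * pump_flux(bpr, fresh, BLUE)
        )

    def test_full_blue_acidifies_fresh_prep(self, default_plant):
        """Net proton flux under blue is into the bulk: pH outside falls."""
        d = plant_derivatives(default_plant, wash_to_pH(7.0), BLUE)
        assert d.ph_out < 0.0

    def test_power_out_of_range_rejected(self, default_plant):
        bpr = _pump(default_plant, "BPR")
        with pytest.raises(ActuationError):
            pump_flux(bpr, wash_to_pH(7.0), {"blue": 1.2, "red": 0.0})
        with pytest.raises(ActuationError):
            pump_flux(bpr, wash_to_pH(7.0), {"blue": -0.1, "red": 0.0})


class TestGDHRate:
    def test_zero_without_substrate(self):
        p = GDHParams()
        assert gdh_rate(p, PlantState(ph_out=8.0, akg=1.0, nh4=5.0, nadh=0.0)) == 0.0

    def test_slow_at_low_ph(self):
        """The reaction idles at pH 6 relative to near-neutral pH."""
        p = GDHParams()
        pools = dict(akg=1.25, nh4=5.0, nadh=2.0)
        v6 = gdh_rate(p, PlantState(ph_out=6.0, **pools))
        v74 = gdh_rate(p, PlantState(ph_out=7.4, **pools))
        assert v6 / v74 <= 0.3

    def test_saturating_substrates_approach_vmax(self):
        p = GDHParams()
        state = PlantState(ph_out=p.ph_opt, akg=100.0, nh4=200.0, nadh=50.0)
        assert gdh_rate(p, state) == pytest.approx(p.vmax, rel=0.05)


class TestPlantDerivatives:
    def test_equilibrium_all_zero(self, default_plant):
        d = plant_derivatives(default_plant, wash_to_pH(7.0), DARK)
        assert all(
            getattr(d, f) == 0.0
            for f in ("ph_out", "ph_in", "akg", "nh4", "nadh", "glu", "nad")
        )

    def test_gdh_stoichiometry(self, gdh_plant):
        state = with_substrates(wash_to_pH(7.5))
        v = gdh_rate(gdh_plant.gdh, state)
        d = plant_derivatives(gdh_plant, state, DARK)
        assert v > 0
        assert d.nadh == pytest.approx(-v)
        assert d.glu == pytest.approx(v)
        assert d.akg == pytest.approx(-v)
        assert d.nad == pytest.approx(v)

    def test_red_light_raises_outside_lowers_lumen(self, default_plant):
        d = plant_derivatives(default_plant, wash_to_pH(7.0), RED)
        assert d.ph_out > 0.0
        assert d.ph_in < 0.0

    def test_buffer_weighted_proton_conservation(self, default_plant):
        """Acid equivalents leaving the lumen appear outside, exactly."""
        p = default_plant.params
        d = plant_derivatives(default_plant, wash_to_pH(6.5), BLUE)
        total = (
            p.beta_out * p.volume_out_ul * d.ph_out
            + p.beta_in * p.volume_in_ul * d.ph_in
        )
        assert abs(total) < 1e-12


class TestStepPlant:
    def test_fixed_point_unchanged(self, default_plant):
        s0 = wash_to_pH(7.0)
        s1 = step_plant(default_plant, s0, DARK, dt=0.5)
        assert s1.ph_out == s0.ph_out and s1.ph_in == s0.ph_in

    def test_rk4_matches_fine_euler(self, default_plant):
        """RK4 at dt=0.1 s tracks a 1000x finer Euler oracle over 60 s."""
        s_rk = simulate(default_plant, wash_to_pH(7.0), BLUE, 60.0, dt=0.1, method="rk4")
        s_eu = simulate(
            default_plant, wash_to_pH(7.0), BLUE, 60.0, dt=0.001, method="euler"
        )
        assert abs(s_rk.ph_out - s_eu.ph_out) < 1e-4

    def test_concentrations_clamped_and_conserved(self, default_cfg):
        """Overshooting the remaining NADH never drives pools negative."""
        model = default_cfg.build_plant(with_gdh=True)
        fast = replace(model, gdh=replace(model.gdh, vmax=5.0))
        state = with_substrates(wash_to_pH(8.0), nadh=0.01)
        total0 = state.nadh + state.nad
        for _ in range(20):
            state = step_plant(fast, state, DARK, dt=0.5)
        assert state.nadh >= 0.0
        assert state.nadh + state.nad == pytest.approx(total0, abs=1e-9)

    def test_invalid_dt(self, default_plant):
        with pytest.raises(ParameterError):
            step_plant(default_plant, wash_to_pH(7.0), DARK, dt=0.0)


class TestWash:
    def test_wash_resets_both_compartments(self):
        s = wash_to_pH(6.0)
        assert s.ph_out == 6.0 and s.ph_in == 6.0 and s.t == 0.0
        assert s.nadh == 0.0 and s.akg == 0.0

    def test_idempotent(self):
        assert wash_to_pH(6.0) == wash_to_pH(6.0)

    def test_static_without_stimulus(self, default_plant):
        s = simulate(default_plant, wash_to_pH(7.0), DARK, 120.0)
        assert s.ph_out == pytest.approx(7.0, abs=1e-12)

    def test_out_of_range_target(self):
        with pytest.raises(ParameterError):
            wash_to_pH(2.0)
        with pytest.raises(ParameterError):
            wash_to_pH(12.5)


class TestTrajectoryInvariants:
    def test_conservation_over_closed_trajectory(self, default_plant):
        """Buffer-weighted total acid is invariant with pumps and leak only."""
        p = default_plant.params
        s0 = wash_to_pH(6.5)
        s = simulate(default_plant, s0, BLUE, 300.0)
        drift = p.beta_out * p.volume_out_ul * (s.ph_out - s0.ph_out) + (
            p.beta_in * p.volume_in_ul * (s.ph_in - s0.ph_in)
        )
        scale = p.beta_out * p.volume_out_ul
        assert abs(drift) / scale < 1e-6

    def test_substrate_totals_invariant(self, gdh_plant):
        s0 = with_substrates(wash_to_pH(7.0))
        s = simulate(gdh_plant, s0, RED, 600.0)
        assert s.nadh + s.nad == pytest.approx(s0.nadh + s0.nad, abs=1e-9)
        assert s.akg + s.glu == pytest.approx(s0.akg + s0.glu, abs=1e-9)

    def test_blue_initially_faster_than_red(self, default_plant):
        """BPR's pool and spectral match make acidification the faster move."""
        s = wash_to_pH(7.0)
        db = plant_derivatives(default_plant, s, BLUE).ph_out
        dr = plant_derivatives(default_plant, s, RED).ph_out
        assert abs(db) > abs(dr)

    def test_excursion_bounded_by_gradient_limit(self, default_plant):
        dmax = max(p.kinetics.dph_max for p in default_plant.pumps)
        s = simulate(default_plant, wash_to_pH(7.0), BLUE, 1800.0)
        assert abs(s.ph_out - 7.0) <= dmax


class TestElectrode:
    def test_noise_free_affine_map(self):
        e = ElectrodeModel(noise_sd=0.0)
        assert measure_voltage(e, 7.0) == pytest.approx(-0.057 * 7.0 + 2.5)

    def test_sample_mean_clt_bound(self):
        e = ElectrodeModel(noise_sd=0.002, seed=7)
        draws = np.array([e.measure(7.0) for _ in range(10_000)])
        true = -0.057 * 7.0 + 2.5
        assert abs(draws.mean() - true) < 3 * 0.002 / 100.0

    def test_equal_seeds_equal_sequences(self):
        e1 = ElectrodeModel(seed=42)
        e2 = ElectrodeModel(seed=42)
        assert [e1.measure(7.0) for _ in range(5)] == [
            e2.measure(7.0) for _ in range(5)
        ]

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            ElectrodeModel(slope=0.0)


class TestVesiclePopulation:
    def test_degenerate_lognormal(self):
        prep = VesiclePreparation(diameter_logsigma=0.0, diameter_logmu=math.log(130))
        d, _ = sample_vesicle_population(prep, 100, seed=0)
        np.testing.assert_allclose(d, 130.0)

    def test_mean_diameter_near_130nm(self):
        d, summary = sample_vesicle_population(VesiclePreparation(), 100_000, seed=0)
        assert summary["mean_diameter_nm"] == pytest.approx(130.0, rel=0.02)
        assert summary["particle_conc_nm"] == 20.0

    def test_sample_mean_matches_analytic_moment(self):
        prep = VesiclePreparation()
        d, summary = sample_vesicle_population(prep, 100_000, seed=1)
        analytic = summary["analytic_mean_nm"]
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean() - analytic) < 4 * se

    def test_invalid_n(self):
        with pytest.raises(ParameterError):
            sample_vesicle_population(VesiclePreparation(), 0)


class TestDigestionAssay:
    def test_br_fraction_consistent_with_two_thirds(self):
        res = simulate_digestion_assay(VesiclePreparation(), 10_000, seed=0)["BR"]
        assert res.ci_low <= 2.0 / 3.0 <= res.ci_high
        assert res.fraction == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_bpr_never_digested(self):
        res = simulate_digestion_assay(VesiclePreparation(), 10_000, seed=0)["BPR"]
        assert res.fraction == 0.0 and res.ci_low == 0.0

    def test_certain_digestion(self):
        prep = VesiclePreparation(br_out_fraction=1.0)
        res = simulate_digestion_assay(prep, 500, seed=0)["BR"]
        assert res.fraction == 1.0 and res.ci_high == 1.0

    def test_ci_against_exact_binomial_oracle(self):
        """Clopper-Pearson bounds agree with the exact binomial test CI."""
        res = simulate_digestion_assay(VesiclePreparation(), 50, seed=3)["BR"]
        oracle = stats.binomtest(res.n_digested, 50).proportion_ci(
            confidence_level=0.95, method="exact"
        )
        assert res.ci_low == pytest.approx(oracle.low, abs=1e-12)
        assert res.ci_high == pytest.approx(oracle.high, abs=1e-12)

    def test_reproducible_under_seed(self):
        a = simulate_digestion_assay(VesiclePreparation(), 1000, seed=9)
        b = simulate_digestion_assay(VesiclePreparation(), 1000, seed=9)
        assert a == b
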