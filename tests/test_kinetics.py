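"""Two-compartment kinetics: baseline resolution, ODE behavior, antagonist
steady states."""

import math

import numpy as np
import pytest

from etkinetics import (
    AntagonistSpec,
    Segment,
    InfusionProtocol,
    ModelParameters,
    SimulateOptions,
    builtin_protocol,
    derived_production_rates,
    ode_rhs,
    quasi_steady_state,
    resolve_baseline,
    simulate,
    steady_state_init,
    steady_state_with_antagonist,
)
from etkinetics.binding import bound_complex, split_receptor_pool


class TestBaseline:
    def test_tissue_free_et1_near_calibrated_value(self, baseline):
        # volume-weighted plasma steady-state constraint gives 88.90; the
        # published rounded value is 88.3 (within 2%)
        assert baseline.et1_t_free == pytest.approx(88.90093353, rel=1e-8)
        assert baseline.et1_t_free == pytest.approx(88.3, rel=0.02)
        assert baseline.et1_p_free == 3.2

    def test_production_rates_with_given_ece(self):
        p = ModelParameters().replace(ece_nmol=98.0)
        prod_big, prod_et1 = derived_production_rates(p)
        assert prod_big == pytest.approx(2.64e-4 * 0.93 * 98e3, rel=1e-12)  # 24.06
        assert prod_et1 == pytest.approx(prod_big * p.v_t, rel=1e-12)

    def test_production_linear_in_ece(self):
        p1, _ = derived_production_rates(ModelParameters().replace(ece_nmol=50.0))
        p2, _ = derived_production_rates(ModelParameters().replace(ece_nmol=100.0))
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_default_baseline_derives_ece(self, baseline):
        # with R_tot,t fixed at 7738 the tissue balance implies ~58.8 nmol/L
        assert baseline.ece_nmol == pytest.approx(58.81, rel=1e-3)
        assert baseline.r_tot_t == 7738.0

    def test_given_ece_derives_receptor_pool(self):
        b = resolve_baseline(ModelParameters().replace(ece_nmol=98.0))
        assert b.r_tot_t == pytest.approx(13308.0, rel=1e-3)

    def test_overdetermined_parameters_rejected(self):
        import dataclasses
        p = dataclasses.replace(ModelParameters(), ece_nmol=98.0)  # r_tot_t kept
        with pytest.raises(ValueError, match="over-determined"):
            resolve_baseline(p)

    def test_too_small_ece_violates_constraint(self):
        with pytest.raises(ValueError, match="negative"):
            resolve_baseline(ModelParameters().replace(ece_nmol=0.1))


class TestOdeRhs:
    def test_zero_at_steady_state(self, calibrated_params):
        state = steady_state_init(calibrated_params)
        y = [state.big_et, state.et1_tot_t, state.et1_tot_p, 0.0, 0.0]
        dy = ode_rhs(0.0, y, calibrated_params, None)
        assert np.max(np.abs(dy[:3])) < 1e-8

    def test_infusion_additivity(self, calibrated_params):
        state = steady_state_init(calibrated_params)
        y = [state.big_et, state.et1_tot_t, state.et1_tot_p, 0.0, 0.0]
        proto = InfusionProtocol(
            name="const",
            segments=(Segment(0.0, 10.0, "ET1", 42.0, "pmol/min"),),
            sampling_times=(0.0, 10.0),
        )
        dy0 = ode_rhs(5.0, y, calibrated_params, None)
        dy1 = ode_rhs(5.0, y, calibrated_params, proto)
        assert dy1[2] - dy0[2] == pytest.approx(42.0 / calibrated_params.v_p, rel=1e-12)

    def test_etb_blockade_removes_etb_share_of_clearance(self, calibrated_params, baseline):
        # with a saturating perfectly selective ET_B antagonist the plasma
        # clearance term falls to the ET_A share at the same free ET-1
        p = calibrated_params
        x_p = baseline.et1_p_free
        ra_p, rb_p = split_receptor_pool(p.r_tot_p, p.f_b_c)
        full = p.k_int * p.v_p * bound_complex(p.r_tot_p, x_p, p.k_d)
        eta_only = p.k_int * p.v_p * bound_complex(ra_p, x_p, p.k_d)
        assert eta_only / full == pytest.approx(1.0 - p.f_b_c, rel=1e-12)


class TestSimulate:
    def test_null_protocol_is_flat(self, calibrated_params, baseline):
        proto = InfusionProtocol(name="null", sampling_times=(0.0, 500.0, 1000.0))
        res = simulate(proto, calibrated_params)
        assert np.allclose(res.et1_tot_p, baseline.et1_tot_p, rtol=1e-6)
        assert np.allclose(res.et1_tot_t, baseline.et1_tot_t, rtol=1e-6)
        assert np.allclose(res.big_et, baseline.big_et, rtol=1e-6)

    def test_stepped_et1_increases_across_plateaus(self, calibrated_params):
        res = simulate(builtin_protocol("stepped_et1"), calibrated_params)
        obs = res.at_times([0.0, 75.0, 125.0, 175.0])
        assert np.all(np.diff(obs) > 0)

    def test_stepped_biget_raises_plasma_et1(self, calibrated_params):
        res = simulate(builtin_protocol("stepped_biget"), calibrated_params)
        obs = res.at_times([0.0, 90.0])
        assert obs[1] > obs[0] * 2

    def test_tracer_output_normalized(self, calibrated_params):
        res = simulate(builtin_protocol("bolus_tracer"), calibrated_params)
        rel = res.plasma_et1
        assert rel.max() == pytest.approx(1.0)
        assert rel[0] == pytest.approx(0.0, abs=1e-9)
        # tracer washes out towards baseline
        assert rel[-1] < 0.1

    def test_pd_delay_slows_early_rise(self, calibrated_params):
        proto = builtin_protocol("validation_bq788")
        fast = simulate(proto, calibrated_params)
        slow = simulate(proto, calibrated_params, SimulateOptions(pd_delay_ke0=0.05))
        t_early = [10.0, 15.0]
        assert np.all(slow.at_times(t_early) < fast.at_times(t_early))

    @pytest.mark.parametrize("name", ["stepped_et1", "validation_bq788"])
    def test_mass_balance_bookkeeping(self, calibrated_params, name):
        # change in total ET-1 amount == (produced + infused) - cleared
        p = calibrated_params
        res = simulate(builtin_protocol(name), p)
        amount = res.et1_tot_t * p.v_t + res.et1_tot_p * p.v_p
        lhs = amount - amount[0]
        rhs = res.cumulative_input - res.cumulative_cleared
        # cumulative production over the horizon is O(10^3-10^4) pmol
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-4)

    def test_binding_consistency_at_every_output_step(self, calibrated_params):
        res = simulate(builtin_protocol("validation_bq123"), calibrated_params)
        recon_p = res.et1_free_p + res.complex_a_p + res.complex_b_p
        recon_t = res.et1_free_t + res.complex_a_t + res.complex_b_t
        assert np.allclose(recon_p, res.et1_tot_p, rtol=1e-9)
        assert np.allclose(recon_t, res.et1_tot_t, rtol=1e-9)

    def test_tidy_frame_schema(self, calibrated_params):
        res = simulate(builtin_protocol("stepped_biget"), calibrated_params)
        df = res.to_frame()
        assert set(df.columns) == {"time_min", "compartment", "variable", "value_pmol_per_L"}
        assert {"plasma", "tissue"} <= set(df.compartment.unique())


class TestSteadyStateWithAntagonist:
    def test_zero_concentration_matches_baseline(self, calibrated_params, baseline):
        antag = AntagonistSpec(1.0, math.inf)
        state, sol_p, sol_t = steady_state_with_antagonist(calibrated_params, antag, 0.0)
        assert state.et1_tot_p == pytest.approx(baseline.et1_tot_p, rel=1e-10)
        assert state.et1_tot_t == pytest.approx(baseline.et1_tot_t, rel=1e-10)
        assert sol_p.ET1_free == pytest.approx(3.2, rel=1e-10)

    def test_saturating_eta_antagonist_suppresses_eta_complex(self, calibrated_params):
        antag = AntagonistSpec(1.0, math.inf)
        _, sol_p0, _ = steady_state_with_antagonist(calibrated_params, antag, 0.0)
        _, sol_p, _ = steady_state_with_antagonist(calibrated_params, antag, 1000.0)
        assert sol_p.ET1_RA < 0.01 * sol_p0.ET1_RA  # > 99% suppression

    @pytest.mark.parametrize("conc", [0.5, 50.0, 5000.0])
    def test_algebraic_fixed_point_survives_long_integration(self, calibrated_params, conc):
        antag = AntagonistSpec(1.0, math.inf)
        # raises if 1,000 min of integration drifts any state by > 0.1%
        steady_state_with_antagonist(calibrated_params, antag, conc, verify=True)

    def test_quasi_steady_state_converges_to_algebraic(self, calibrated_params):
        antag = AntagonistSpec(1.0, math.inf)
        alg, sp_a, _ = steady_state_with_antagonist(calibrated_params, antag, 10.0)
        dyn, sp_d, _ = quasi_steady_state(calibrated_params, antag, 10.0, horizon_min=5000.0)
        assert dyn.et1_tot_p == pytest.approx(alg.et1_tot_p, rel=1e-3)
        assert sp_d.ET1_RB == pytest.approx(sp_a.ET1_RB, rel=1e-3)

    def test_negative_concentration_rejected(self, calibrated_params):
        with pytest.raises(ValueError):
            steady_state_with_antagonist(calibrated_params, AntagonistSpec(1.0, 1.0), -1.0)
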