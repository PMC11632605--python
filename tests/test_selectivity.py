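"""Antagonist selectivity sweeps: baseline anchoring, monotone suppression,
the rise-then-fall of the spared complex, and receptor-fraction scenarios."""

import math

import numpy as np
import pytest
from scipy import stats

from etkinetics.selectivity import (
    DRUG_SELECTIVITY,
    SweepSpec,
    concentration_grid,
    fb_scenario,
    run_sweep,
    summarize_sweep,
)

# coarse grids keep each sweep to a few dozen steady-state solves
COARSE = dict(points_per_decade=4)


@pytest.fixture(scope="module")
def eta_sweep():
    return run_sweep(SweepSpec(mode="eta_perfect", **COARSE))


@pytest.fixture(scope="module")
def etb_sweep():
    return run_sweep(SweepSpec(mode="etb_perfect", **COARSE))


class TestGrids:
    def test_concentration_grid_shape(self):
        g = concentration_grid(1e-3, 1e3, 25)
        assert len(g) == 151
        assert g[0] == pytest.approx(1e-3) and g[-1] == pytest.approx(1e3)
        assert np.all(np.diff(np.log(g)) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(mode="bogus")
        with pytest.raises(ValueError):
            SweepSpec(f_b=1.5)
        with pytest.raises(ValueError):
            run_sweep(SweepSpec(mode="grid"))  # needs selectivities


class TestPerfectlySelective:
    def test_tiny_concentration_leaves_baseline(self, eta_sweep):
        first = eta_sweep.frame[eta_sweep.frame.multiple == eta_sweep.frame.multiple.min()]
        assert np.all(np.abs(first["pct_change"]) < 0.5)

    def test_antagonized_complex_monotone_suppressed(self, eta_sweep):
        pc = eta_sweep.pct("perfect_ETA", "plasma", "et1_eta_complex")["pct_change"].to_numpy()
        assert np.all(np.diff(pc) < 0)
        assert pc[-1] < -99.0

    def test_spared_complex_rises_in_both_compartments(self, eta_sweep, etb_sweep):
        assert eta_sweep.max_pct_change("plasma", "et1_etb_complex") > 30.0
        assert eta_sweep.max_pct_change("tissue", "et1_etb_complex") > 20.0
        assert etb_sweep.max_pct_change("plasma", "et1_eta_complex") > 100.0
        assert etb_sweep.max_pct_change("tissue", "et1_eta_complex") > 100.0

    def test_etb_blockade_raises_et1_more_than_eta_blockade(self, eta_sweep, etb_sweep):
        # ET_B carries most clearance, so its blockade accumulates more ET-1
        assert (etb_sweep.max_pct_change("plasma", "et1_free")
                > 2 * eta_sweep.max_pct_change("plasma", "et1_free"))

    def test_i50_shifted_above_affinity(self, eta_sweep, etb_sweep):
        # the compensatory ET-1 rise pushes 50% suppression beyond I = K_i,
        # much further for the ET_B antagonist
        s_eta = summarize_sweep(eta_sweep)
        s_etb = summarize_sweep(etb_sweep)
        i50_eta = s_eta[s_eta.compartment == "plasma"].i50_multiple.iloc[0]
        i50_etb = s_etb[s_etb.compartment == "plasma"].i50_multiple.iloc[0]
        assert i50_eta > 1.0
        assert i50_etb > i50_eta

    def test_spared_zero_crossing_not_reached(self, eta_sweep):
        s = summarize_sweep(eta_sweep)
        assert s.spared_zero_cross_multiple.isna().all()


class TestFiniteSelectivity:
    def test_spared_complex_rises_then_falls_once(self):
        res = run_sweep(SweepSpec(mode="grid", selectivities=(100.0,), **COARSE))
        pc = res.pct("selectivity_100", "plasma", "et1_etb_complex")["pct_change"].to_numpy()
        assert pc.max() > 20.0 and pc[-1] < 0.0
        signs = np.sign(pc[np.abs(pc) > 1e-6])
        assert np.count_nonzero(np.diff(signs)) == 1  # exactly one sign change

    def test_equal_affinities_suppress_both_complexes_equally(self):
        res = run_sweep(SweepSpec(mode="grid", selectivities=(1.0,), **COARSE))
        ca = res.pct("selectivity_1", "plasma", "et1_eta_complex")["pct_change"].to_numpy()
        cb = res.pct("selectivity_1", "plasma", "et1_etb_complex")["pct_change"].to_numpy()
        assert ca == pytest.approx(cb, rel=1e-6, abs=1e-9)
        assert ca[-1] < -90.0  # deep suppression at the top of the grid

    def test_zero_crossing_concentration_increases_with_selectivity(self):
        res = run_sweep(SweepSpec(mode="grid", selectivities=(30.0, 1000.0), **COARSE))
        s = summarize_sweep(res)
        plasma = s[s.compartment == "plasma"].set_index("selectivity")
        lo = plasma.loc[30.0, "spared_zero_cross_multiple"]
        hi = plasma.loc[1000.0, "spared_zero_cross_multiple"]
        assert np.isnan(hi) or hi > lo

    def test_drug_presets_run(self):
        res = run_sweep(SweepSpec(mode="drugs", drugs=("bosentan",), points_per_decade=2))
        assert set(res.frame.label) == {"bosentan"}
        assert DRUG_SELECTIVITY["bosentan"] == res.frame.selectivity.iloc[0]


class TestReceptorFractionScenarios:
    def test_equal_fractions_make_antagonists_symmetric(self):
        cmp = fb_scenario(0.5, points_per_decade=3)
        rise_eta, rise_etb = cmp.spared_rise("plasma")
        assert rise_eta == pytest.approx(rise_etb, rel=0.01)
        rise_eta_t, rise_etb_t = cmp.spared_rise("tissue")
        assert rise_eta_t == pytest.approx(rise_etb_t, rel=0.01)

    def test_extreme_etb_dominance(self):
        cmp = fb_scenario(0.999, points_per_decade=3)
        # almost no ET_A receptors: ET_A antagonism barely changes ET1-ETB
        assert abs(cmp.eta_sweep.max_pct_change("plasma", "et1_etb_complex")) < 1.0
        # ET_B antagonism frees nearly all clearance: large ET1-ETA rise
        caf = cmp.etb_sweep.frame
        sub = caf[(caf.compartment == "plasma") & (caf.variable == "et1_eta_complex")]
        fold = (sub["value"] / sub["baseline"]).max()
        assert fold > 100.0

    def test_curve_shapes_invariant_across_fb(self):
        # the concentration dependence is set by K_i; receptor fractions
        # only rescale the magnitude
        mults = tuple(concentration_grid(1e-3, 1e3, 3))
        default = fb_scenario(None, multiples=mults)
        half = fb_scenario(0.5, multiples=mults)
        a = default.eta_sweep.pct("perfect_ETA", "plasma", "et1_etb_complex")["pct_change"]
        b = half.eta_sweep.pct("perfect_ETA", "plasma", "et1_etb_complex")["pct_change"]
        rho = stats.spearmanr(a, b).statistic
        assert rho > 0.99
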