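"""Quasi-equilibrium binding algebra: closed forms, the competitive cubic,
conservation and limiting behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etkinetics.binding import (
    AntagonistSpec,
    ReceptorPool,
    bound_complex,
    free_ligand_no_inhibitor,
    free_ligand_with_inhibitor,
    inhibited_binding_solution,
    split_receptor_pool,
)
from .conftest import random_binding_draws


class TestReceptorSplit:
    @pytest.mark.parametrize(
        "r_tot, f_b, ra, rb",
        [
            (460.0, 0.8, 92.0, 368.0),       # plasma pool
            (0.0, 0.5, 0.0, 0.0),            # empty pool
            (7738.0, 0.65, 2708.3, 5029.7),  # tissue pool
        ],
    )
    def test_split_values(self, r_tot, f_b, ra, rb):
        got_ra, got_rb = split_receptor_pool(r_tot, f_b)
        assert got_ra == pytest.approx(ra, abs=1e-9)
        assert got_rb == pytest.approx(rb, abs=1e-9)
        assert got_ra + got_rb == r_tot  # exact in floats

    @pytest.mark.parametrize("r_tot, f_b", [(-1.0, 0.5), (100.0, -0.1), (100.0, 1.5)])
    def test_invalid_inputs_rejected(self, r_tot, f_b):
        with pytest.raises(ValueError):
            split_receptor_pool(r_tot, f_b)

    def test_pool_properties_sum_exactly(self):
        pool = ReceptorPool(R_tot=7738.0, f_B=0.65)
        assert pool.RA_tot + pool.RB_tot == pool.R_tot


class TestFreeLigandNoInhibitor:
    def test_no_ligand(self):
        assert free_ligand_no_inhibitor(0.0, 460.0, 400.0) == 0.0

    def test_no_receptors_all_free(self):
        assert free_ligand_no_inhibitor(10.0, 0.0, 400.0) == pytest.approx(10.0)

    def test_inversion_recovers_tissue_free(self):
        # forward: free 88.3 with R_tot 7738, Kd 400 gives total 1487.6;
        # the inverse solve must recover it (oracle value 88.3019)
        free = free_ligand_no_inhibitor(1487.6, 7738.0, 400.0)
        assert free == pytest.approx(88.3, abs=0.1)
        total = free + bound_complex(7738.0, free, 400.0)
        assert total == pytest.approx(1487.6, rel=1e-9)

    def test_rejects_nonpositive_kd(self):
        with pytest.raises(ValueError):
            free_ligand_no_inhibitor(1.0, 1.0, 0.0)

    @given(
        tot=st.floats(1e-6, 1e7),
        r=st.floats(0.0, 1e6),
        kd=st.floats(1e-3, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_and_bounds(self, tot, r, kd):
        x = free_ligand_no_inhibitor(tot, r, kd)
        assert 0.0 <= x <= tot
        assert x + bound_complex(r, x, kd) == pytest.approx(tot, rel=1e-9, abs=1e-12)


class TestBoundComplex:
    @pytest.mark.parametrize(
        "r_tot, free, kd, expected",
        [
            (460.0, 400.0, 400.0, 230.0),        # half-saturation at x = Kd
            (460.0, 0.0, 400.0, 0.0),
            (460.0, 3.2, 400.0, 3.650793650793651),  # plasma baseline
        ],
    )
    def test_values(self, r_tot, free, kd, expected):
        assert bound_complex(r_tot, free, kd) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        xs = np.geomspace(1e-3, 1e6, 50)
        ys = [bound_complex(460.0, x, 400.0) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))
        assert ys[-1] < 460.0


class TestCompetitiveCubic:
    def test_zero_inhibitor_reduces_to_quadratic(self):
        with_i = free_ligand_with_inhibitor(10.0, 92.0, 368.0, 400.0, 0.0, 1.0, 1.0)
        without = free_ligand_no_inhibitor(10.0, 460.0, 400.0)
        assert with_i == pytest.approx(without, rel=1e-12)

    def test_symmetric_inhibition_collapses_to_effective_kd(self):
        ki, i = 5.0, 37.0
        with_i = free_ligand_with_inhibitor(10.0, 92.0, 368.0, 400.0, i, ki, ki)
        eff = free_ligand_no_inhibitor(10.0, 460.0, 400.0 * (1 + i / ki))
        assert with_i == pytest.approx(eff, rel=1e-12)

    def test_selective_example_against_frozen_oracle_value(self):
        # bisection oracle on the expanded cubic gives 5.1837256230817115
        x = free_ligand_with_inhibitor(10.0, 92.0, 368.0, 400.0, 10.0, 1.0, 1e20)
        assert x == pytest.approx(5.18372562308, rel=1e-9)

    def test_infinite_affinity_flag_matches_1e20_convention(self):
        x20 = free_ligand_with_inhibitor(50.0, 92.0, 368.0, 400.0, 7.0, 1.0, 1e20)
        xinf = free_ligand_with_inhibitor(50.0, 92.0, 368.0, 400.0, 7.0, 1.0, math.inf)
        assert x20 == pytest.approx(xinf, rel=1e-9)

    def test_oracle_equivalence_over_random_draws(self, cubic_oracle):
        draws = random_binding_draws(1000, seed=42)
        for tot, ra, rb, kd, i, kia, kib in draws:
            got = free_ligand_with_inhibitor(tot, ra, rb, kd, i, kia, kib)
            want = cubic_oracle(tot, ra, rb, kd, i, kia, kib)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-10)


class TestInhibitedBindingSolution:
    def test_conservation_over_random_draws(self):
        draws = random_binding_draws(400, seed=7)
        for tot, ra, rb, kd, i, kia, kib in draws:
            sol = inhibited_binding_solution(tot, ra, rb, kd, i, kia, kib)
            assert sol.ET1_tot == pytest.approx(tot, rel=1e-9, abs=1e-12)
            assert min(sol.ET1_free, sol.ET1_RA, sol.ET1_RB,
                       sol.RA_free, sol.RB_free) >= 0.0
            assert sol.RA_free + sol.ET1_RA <= ra * (1 + 1e-12)
            assert sol.RB_free + sol.ET1_RB <= rb * (1 + 1e-12)

    def test_receptor_sum_equality_without_antagonist_binding(self):
        sol = inhibited_binding_solution(10.0, 92.0, 368.0, 400.0, 0.0, 1.0, 1.0)
        assert sol.RA_free + sol.ET1_RA == pytest.approx(92.0, rel=1e-12)
        assert sol.RB_free + sol.ET1_RB == pytest.approx(368.0, rel=1e-12)

    def test_zero_inhibitor_matches_simple_complexes(self):
        sol = inhibited_binding_solution(10.0, 92.0, 368.0, 400.0, 0.0, 1.0, 1.0)
        assert sol.ET1_RA == pytest.approx(bound_complex(92.0, sol.ET1_free, 400.0), rel=1e-12)
        assert sol.ET1_RB == pytest.approx(bound_complex(368.0, sol.ET1_free, 400.0), rel=1e-12)

    def test_saturating_inhibitor_frees_all_ligand(self):
        sol = inhibited_binding_solution(10.0, 92.0, 368.0, 400.0, 1e15, 1.0, 1.0)
        assert sol.ET1_free == pytest.approx(10.0, rel=1e-6)
        assert sol.ET1_RA < 1e-6 and sol.ET1_RB < 1e-6

    def test_own_complex_strictly_decreasing_in_inhibitor(self):
        cas = []
        for i in np.geomspace(1e-3, 1e4, 25):
            sol = inhibited_binding_solution(10.0, 92.0, 368.0, 400.0, i, 1.0, 1e20)
            cas.append(sol.ET1_RA)
        assert all(b < a for a, b in zip(cas, cas[1:]))

    def test_linear_binding_regime_limits(self):
        # R_tot -> 0: all ligand free
        sol = inhibited_binding_solution(10.0, 1e-9, 1e-9, 400.0, 0.0, 1.0, 1.0)
        assert sol.ET1_free == pytest.approx(10.0, rel=1e-8)
        # Kd -> large: complexes approach R_tot * x / Kd
        kd = 1e9
        sol = inhibited_binding_solution(10.0, 92.0, 368.0, kd, 0.0, 1.0, 1.0)
        assert sol.ET1_RA == pytest.approx(92.0 * sol.ET1_free / kd, rel=1e-6)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            AntagonistSpec(K_ia=0.0, K_ib=1.0)
        assert AntagonistSpec(K_ia=2.0, K_ib=50.0).selectivity == 25.0
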