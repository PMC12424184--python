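"""Equilibrium solver: closed forms vs the independent mass-action oracle."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from ternacoop import (
    TernarySystem,
    hook_severity,
    optimal_fraction,
    optimal_free_ligand,
    optimal_total_ligand,
    response_surface,
    solve_equilibrium,
    solve_free_ligand,
    ternary_fraction,
    titration,
)
from ternacoop.equilibrium import _alb_given_free_ligand, _ltot_given_free_ligand
from ternacoop.errors import (
    InsufficientRangeError,
    InvalidParameterError,
    UndefinedFractionError,
)

from conftest import draw_random_system, mass_action_oracle, rel_err


def log_uniform_system(a, b, l, kal, kbl, alpha) -> TernarySystem:
    return TernarySystem(A_tot=10**a, B_tot=10**b, L_tot=10**l,
                         K_AL=10**kal, K_BL=10**kbl, alpha=10**alpha)


system_strategy = st.builds(
    log_uniform_system,
    a=st.floats(-8, -4), b=st.floats(-8, -4), l=st.floats(-8, -4),
    kal=st.floats(-9, -3), kbl=st.floats(-9, -3), alpha=st.floats(-2, 3),
)


class TestValidation:
    @pytest.mark.parametrize("field,value", [
        ("A_tot", -1e-9), ("L_tot", float("nan")), ("K_AL", 0.0),
        ("K_BL", -1e-6), ("alpha", 0.0), ("alpha", float("inf")),
    ])
    def test_invalid_inputs_rejected(self, symmetric_micromolar, field, value):
        with pytest.raises(InvalidParameterError):
            replace(symmetric_micromolar, **{field: value})

    def test_rel_tol_out_of_range(self, symmetric_micromolar):
        with pytest.raises(InvalidParameterError):
            solve_free_ligand(symmetric_micromolar, rel_tol=1e-2)


class TestFreeLigand:
    def test_no_ligand(self, symmetric_micromolar):
        assert solve_free_ligand(replace(symmetric_micromolar, L_tot=0.0)) == 0.0

    def test_nothing_to_bind(self):
        s = TernarySystem(0.0, 0.0, 1e-6, 1e-6, 1e-6, 10.0)
        assert solve_free_ligand(s) == 1e-6

    def test_matches_simultaneous_solve(self, symmetric_micromolar):
        L = solve_free_ligand(symmetric_micromolar)
        oracle = mass_action_oracle(symmetric_micromolar)
        assert rel_err(L, oracle["L"]) <= 1e-8

    def test_free_ligand_bounded_by_total(self, rng):
        for _ in range(20):
            s = draw_random_system(rng)
            assert 0 <= solve_free_ligand(s) <= s.L_tot


class TestEquilibrium:
    def test_no_ligand_leaves_free_proteins(self, symmetric_micromolar):
        st_ = solve_equilibrium(replace(symmetric_micromolar, L_tot=0.0))
        assert st_.ALB == st_.AL == st_.BL == 0.0
        assert st_.A == symmetric_micromolar.A_tot
        assert st_.B == symmetric_micromolar.B_tot

    def test_one_protein_absent_reduces_to_binary_isotherm(self):
        s = TernarySystem(0.0, 1e-6, 2e-6, 1e-6, 5e-7, 10.0)
        st_ = solve_equilibrium(s)
        assert st_.ALB == 0.0 and st_.AL == 0.0
        # the binary isotherm is exact
        assert rel_err(st_.BL * s.K_BL, st_.B * st_.L) <= 1e-12
        assert rel_err(st_.B + st_.BL, s.B_tot) <= 1e-12
        assert rel_err(st_.L + st_.BL, s.L_tot) <= 1e-12

    def test_matches_oracle_on_random_systems(self, rng):
        for _ in range(100):
            s = draw_random_system(rng)
            st_ = solve_equilibrium(s)
            oracle = mass_action_oracle(s)
            for name, v in oracle.items():
                assert rel_err(getattr(st_, name), v) <= 1e-6, (s, name)

    def test_residuals_within_contract(self, rng):
        for _ in range(50):
            st_ = solve_equilibrium(draw_random_system(rng))
            assert st_.residual_mass <= 1e-8
            assert st_.residual_K <= 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(system=system_strategy)
    def test_mass_and_equilibrium_residuals_property(self, system):
        st_ = solve_equilibrium(system)
        assert st_.residual_mass <= 1e-8
        assert st_.residual_K <= 1e-8
        assert all(v >= 0 for v in st_.species().values())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(system=system_strategy)
    def test_swapping_proteins_leaves_ternary_invariant(self, system):
        alb = solve_equilibrium(system).ALB
        alb_swapped = solve_equilibrium(system.swapped()).ALB
        assert rel_err(alb, alb_swapped) <= 1e-9 or alb < 1e-30

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(system=system_strategy, factor=st.floats(1.5, 50.0))
    def test_ternary_strictly_increasing_in_alpha(self, system, factor):
        lo = solve_equilibrium(system).ALB
        hi = solve_equilibrium(replace(system, alpha=system.alpha * factor)).ALB
        saturation = min(system.A_tot, system.B_tot, system.L_tot)
        if lo > 1e-30 and lo < 0.999 * saturation:
            assert hi > lo
        else:
            assert hi >= lo * (1 - 1e-9)


class TestTernaryFraction:
    def test_bounds_and_trivia(self, symmetric_micromolar):
        st_ = solve_equilibrium(symmetric_micromolar)
        f3 = ternary_fraction(st_, symmetric_micromolar)
        assert 0 <= f3 <= 1
        zero = solve_equilibrium(replace(symmetric_micromolar, alpha=1e-10))
        assert ternary_fraction(zero, symmetric_micromolar) == pytest.approx(0.0, abs=1e-6)

    def test_zero_limiting_species_is_an_error(self):
        s = TernarySystem(0.0, 1e-6, 1e-6, 1e-6, 1e-6, 1.0)
        with pytest.raises(UndefinedFractionError):
            ternary_fraction(solve_equilibrium(s), s)

    def test_matches_oracle_value(self, symmetric_micromolar):
        oracle = mass_action_oracle(symmetric_micromolar)
        st_ = solve_equilibrium(symmetric_micromolar)
        f3 = ternary_fraction(st_, symmetric_micromolar)
        assert rel_err(f3, oracle["ALB"] / 1e-6) <= 1e-8


class TestTitration:
    def test_single_point_equals_direct_solve(self, symmetric_micromolar):
        curve = titration(symmetric_micromolar, [2e-6])
        direct = solve_equilibrium(symmetric_micromolar)
        assert curve.states[0].ALB == pytest.approx(direct.ALB, rel=1e-12)

    def test_grid_validation(self, symmetric_micromolar):
        with pytest.raises(InvalidParameterError):
            titration(symmetric_micromolar, [1e-6, 1e-6])
        with pytest.raises(InvalidParameterError):
            titration(symmetric_micromolar, [])

    def test_ternary_peak_near_closed_form_dose(self):
        s = TernarySystem(1e-6, 1e-6, 0.0, 2e-7, 2e-7, 1.0)
        grid = np.geomspace(1e-9, 1e-3, 400)
        curve = titration(s, grid)
        alb = np.array([x.ALB for x in curve.states])
        peak = grid[np.argmax(alb)]
        assert rel_err(peak, optimal_total_ligand(s)) <= 0.05  # grid resolution

    def test_higher_cooperativity_keeps_more_ternary_past_optimum(self):
        grid = np.geomspace(1e-9, 1e-3, 200)
        f3 = {}
        for a in (1.0, 100.0):
            s = TernarySystem(1e-6, 1e-6, 0.0, 2e-7, 2e-7, a)
            curve = titration(s, grid)
            probe = 100.0 * optimal_total_ligand(s)
            f3[a] = float(np.interp(np.log(probe), np.log(grid), curve.f3))
        assert f3[100.0] > f3[1.0]

    def test_dataframe_round_trip_columns(self, symmetric_micromolar):
        df = titration(symmetric_micromolar, np.geomspace(1e-8, 1e-5, 5)).to_dataframe()
        assert list(df.columns) == ["L_tot", "L", "A", "B", "AL", "BL", "ALB", "f3"]
        assert len(df) == 5


class TestOptima:
    def test_symmetric_free_ligand_optimum(self):
        assert optimal_free_ligand(1e-6, 1e-6) == 1e-6
        assert optimal_free_ligand(4e-6, 1e-6) == pytest.approx(2e-6, rel=1e-15)

    def test_invalid_kd(self):
        with pytest.raises(InvalidParameterError):
            optimal_free_ligand(0.0, 1e-6)

    def test_symmetric_total_optimum(self, symmetric_micromolar):
        assert optimal_total_ligand(symmetric_micromolar) == pytest.approx(2e-6, rel=1e-12)

    def test_total_optimum_independent_of_alpha(self, symmetric_micromolar):
        values = {optimal_total_ligand(replace(symmetric_micromolar, alpha=a))
                  for a in (1.0, 10.0, 100.0)}
        assert len(values) == 1

    def test_free_ligand_optimum_is_ternary_argmax(self, rng):
        """sqrt(K_AL*K_BL) maximises [ALB] over the free-ligand axis.

        The numeric argmax is conditioning-limited when the protein totals
        dominate the binding polynomial (the peak flattens), hence the 1e-4
        tolerance.
        """
        for _ in range(20):
            s = draw_random_system(rng)
            res = minimize_scalar(
                lambda u: -_alb_given_free_ligand(s, math.exp(u)),
                bounds=(math.log(1e-12), math.log(1.0)), method="bounded",
                options={"xatol": 1e-12})
            assert rel_err(math.exp(res.x),
                           optimal_free_ligand(s.K_AL, s.K_BL)) <= 1e-4

    def test_total_optimum_is_dose_argmax(self, rng):
        """Eq-7-style closed form matches the numeric [ALB] argmax over dose."""
        for _ in range(10):
            s = draw_random_system(rng)

            def neg_alb(u: float) -> float:
                return -solve_equilibrium(s.with_L_tot(math.exp(u))).ALB

            lt_opt = optimal_total_ligand(s)
            res = minimize_scalar(
                neg_alb,
                bounds=(math.log(lt_opt) - 7.0, math.log(lt_opt) + 7.0),
                method="bounded", options={"xatol": 1e-10})
            assert rel_err(math.exp(res.x), lt_opt) <= 1e-4

    def test_optimal_fraction_saturates_at_huge_alpha(self):
        s = TernarySystem(1e-6, 1e-6, 0.0, 1e-6, 1e-6, 1e12)
        assert optimal_fraction(s) == pytest.approx(1.0, abs=1e-3)

    def test_optimal_fraction_monotone_in_alpha(self):
        f = [optimal_fraction(TernarySystem(1e-6, 1e-6, 0.0, 1e-6, 1e-6, a))
             for a in (1.0, 10.0, 100.0)]
        assert f[0] < f[1] < f[2]

    def test_optimal_fraction_equals_fraction_at_optimal_dose(self, rng):
        for _ in range(10):
            s = draw_random_system(rng)
            lt_opt = optimal_total_ligand(s)
            s_opt = s.with_L_tot(lt_opt)
            f3_at_opt = ternary_fraction(solve_equilibrium(s_opt), s_opt)
            assert rel_err(optimal_fraction(s), f3_at_opt) <= 1e-6


class TestHookSeverity:
    @staticmethod
    def curve(alpha: float, n: int = 150):
        s = TernarySystem(1e-6, 1e-6, 0.0, 2e-7, 2e-7, alpha)
        return titration(s, np.geomspace(1e-9, 1e-3, n))

    def test_flat_post_peak_curve_is_zero(self):
        from ternacoop import EquilibriumState, TitrationCurve

        grid = np.geomspace(1e-9, 1e-3, 30)
        states = tuple(
            EquilibriumState(A=0.0, B=0.0, L=g, AL=0.0, BL=0.0, ALB=5e-7,
                             residual_mass=0.0, residual_K=0.0)
            for g in grid
        )
        flat = TitrationCurve(
            L_tot_grid=grid, states=states, f3=np.full(30, 0.5),
            system_base=TernarySystem(1e-6, 1e-6, 0.0, 1e-6, 1e-6, 1.0))
        assert hook_severity(flat) == 0.0

    def test_severity_ordering_matches_cooperativity(self):
        sev = [hook_severity(self.curve(a)) for a in (1.0, 100.0)]
        assert sev[0] > sev[1]

    def test_severity_non_increasing_along_alpha_sweep(self):
        sev = [hook_severity(self.curve(a)) for a in (1.0, 3.0, 10.0, 30.0, 100.0)]
        assert all(a >= b for a, b in zip(sev, sev[1:]))

    def test_insufficient_range_rejected(self):
        s = TernarySystem(1e-6, 1e-6, 0.0, 2e-7, 2e-7, 1.0)
        with pytest.raises(InsufficientRangeError):
            hook_severity(titration(s, np.geomspace(1e-9, 2e-6, 40)))


class TestResponseSurface:
    def test_single_cell_equals_optimal_fraction(self):
        out = response_surface(1e-6, 1e-6, [1e-6], [1e-6], {"alpha": 10.0})
        expected = optimal_fraction(TernarySystem(1e-6, 1e-6, 0.0, 1e-6, 1e-6, 10.0))
        assert out.shape == (1, 1) and out[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_kd_mode_symmetric_under_axis_swap(self):
        ks = np.geomspace(1e-8, 1e-5, 4)
        out = response_surface(1e-6, 1e-6, ks, ks, {"alpha": 10.0})
        assert np.allclose(out, out.T, rtol=1e-10)

    def test_alpha_raises_every_cell(self):
        ks = np.geomspace(1e-7, 1e-5, 3)
        lo = response_surface(1e-6, 1e-6, ks, ks, {"alpha": 1.0})
        hi = response_surface(1e-6, 1e-6, ks, ks, {"alpha": 10.0})
        assert np.all(hi > lo)

    def test_alpha_axis_mode(self):
        out = response_surface(1e-6, 1e-6, [1e-6, 1e-5], [1.0, 10.0, 100.0],
                               {"K_AL": 1e-6})
        assert out.shape == (2, 3)
        assert np.all(np.diff(out, axis=1) > 0)  # monotone in alpha

    def test_unsupported_axis_pair(self):
        with pytest.raises(InvalidParameterError):
            response_surface(1e-6, 1e-6, [1e-6], [1e-6], {"K_BL": 1e-6})


class TestInternalClosedForm:
    def test_implied_total_is_monotone_in_free_ligand(self, rng):
        for _ in range(5):
            s = draw_random_system(rng)
            ls = np.geomspace(1e-12, 1e-2, 200)
            tots = [_ltot_given_free_ligand(s, l) for l in ls]
            assert all(a < b for a, b in zip(tots, tots[1:]))
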