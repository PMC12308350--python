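"""Cubic equilibrium solver: root selection, residuals, ODE cross-checks."""

import numpy as np
import pytest

from avibind import (
    AssayGeometry,
    ModelParameters,
    RateParameters,
    a2_from_a1,
    build_cubic,
    derive_rates,
    integrate_to_steady_state,
    solve_bivalent_equilibrium,
    solve_monovalent_equilibrium,
    steady_state_residuals,
)

from conftest import random_model_parameters


class TestCrosslinkBalance:
    def test_endpoints_give_no_bivalent_binding(self):
        assert a2_from_a1(0.0, 5.0) == 0.0
        assert a2_from_a1(5.0, 5.0) == 0.0

    def test_exceeding_antigen_total_rejected(self):
        with pytest.raises(ValueError):
            a2_from_a1(6.0, 5.0)

    def test_satisfies_crosslink_steady_state(self):
        # substituting the returned a2 back into the rate balance zeroes it
        rng = np.random.default_rng(1)
        for _ in range(50):
            params = random_model_parameters(rng)
            big_k2 = params.k2 / params.koff
            a1 = rng.uniform(0, params.rtot / 2)
            a2 = a2_from_a1(big_k2 * a1, big_k2 * params.rtot) / big_k2
            r = params.rtot - a1 - 2 * a2
            residual = params.k2 * r * a1 - 2 * params.koff * a2
            # r is a difference of near-equal numbers at high occupancy, so the
            # residual carries roundoff of order eps * k2 * a1 * rtot
            assert abs(residual) <= 1e-10 * params.k2 * a1 * params.rtot


class TestCubic:
    def test_zero_dose_root_is_origin(self):
        cubic = build_cubic(rtot_hat=10.0, ainit_hat=0.0, k21=1e5)
        assert cubic.c0 == 0.0
        roots = np.roots(cubic.as_array())
        positive = [x.real for x in roots if abs(x.imag) < 1e-12 and x.real > 0]
        assert positive == []

    def test_reference_parameters_satisfy_descartes_condition(self):
        geometry, rates = AssayGeometry(), RateParameters()
        derived = derive_rates(geometry, rates)
        assert derived.k21 > 1e4  # k2*sigma/kon >> 1 for the literature values
        params = ModelParameters.from_assay(geometry, rates, 1e4, 1e-10)
        big_k2 = params.k2 / params.koff
        cubic = build_cubic(big_k2 * params.rtot, big_k2 * params.atot, derived.k21)
        assert cubic.sign_changes() == 1

    def test_unique_positive_root_across_literature_ranges(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            params = random_model_parameters(rng)
            big_k2 = params.k2 / params.koff
            k21 = params.k2 / params.k1
            cubic = build_cubic(big_k2 * params.rtot, big_k2 * params.atot, k21)
            roots = np.roots(cubic.as_array())
            positive = [x for x in roots if abs(x.imag) <= 1e-9 * (abs(x.real) + 1) and x.real > 0]
            assert len(positive) == 1


class TestBivalentEquilibrium:
    def test_zero_dose_trivial(self):
        params = ModelParameters(k1=2e-10, k2=1e-5, koff=1e-4, rtot=1e4, atot=0.0)
        eq = solve_bivalent_equilibrium(params)
        assert (eq.a1, eq.a2) == (0.0, 0.0)

    def test_agrees_with_ode_integration(self, baseline_system):
        rng = np.random.default_rng(9)
        for _ in range(10):
            params = random_model_parameters(rng)
            eq = solve_bivalent_equilibrium(params)
            state = integrate_to_steady_state(params)
            assert state.a1 == pytest.approx(eq.a1, rel=1e-6)
            assert state.a2 == pytest.approx(eq.a2, rel=1e-6)

    def test_reference_low_dose_occupancy_near_saturation(self, baseline_system):
        # at 1e-10 M the cell's antigens are almost fully engaged
        params = baseline_system.at_dose(1e-10)
        eq = solve_bivalent_equilibrium(params)
        occupancy = (eq.a1 + 2 * eq.a2) / params.rtot
        assert 0.9 < occupancy < 1.0
        higher = solve_bivalent_equilibrium(baseline_system.at_dose(1e-9))
        assert (higher.a1 + 2 * higher.a2) / params.rtot > occupancy

    def test_residuals_below_contract(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            params = random_model_parameters(rng)
            eq = solve_bivalent_equilibrium(params)
            res1, res2 = steady_state_residuals(eq.a1, eq.a2, params, r=eq.r, a0=eq.a0)
            assert max(res1, res2) < 1e-8

    def test_conservation_of_returned_state(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            params = random_model_parameters(rng)
            eq = solve_bivalent_equilibrium(params)
            assert eq.r + eq.a1 + 2 * eq.a2 == pytest.approx(params.rtot, rel=1e-9)
            assert eq.a0 + eq.a1 + eq.a2 == pytest.approx(params.atot, rel=1e-9)

    def test_hat_scaling_round_trip(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            params = random_model_parameters(rng)
            big_k2 = params.k2 / params.koff
            values = rng.uniform(0, params.rtot, 5)
            np.testing.assert_allclose((values * big_k2) / big_k2, values, rtol=1e-12)


class TestMonovalentEquilibrium:
    def test_zero_dose(self):
        params = ModelParameters(k1=2e-10, k2=0.0, koff=1e-4, rtot=1e4, atot=0.0)
        assert solve_monovalent_equilibrium(params) == 0.0

    def test_antibody_excess_limit(self, geometry):
        # with antibody in vast excess: occupancy x/(1+x), x = 2 kon Ainit / koff
        rates = RateParameters(kon=1e5, koff=1e-4)
        ainit = 5e-10  # = koff/(2 kon): half-occupancy point
        params = ModelParameters.from_assay(geometry, rates, 100.0, ainit).monovalent()
        a1 = solve_monovalent_equilibrium(params)
        assert a1 / params.rtot == pytest.approx(0.5, rel=1e-3)

    def test_agrees_with_ode_at_zero_crosslinking(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            params = random_model_parameters(rng).monovalent()
            a1 = solve_monovalent_equilibrium(params)
            state = integrate_to_steady_state(params)
            assert state.a1 == pytest.approx(a1, rel=1e-8)
            assert state.a2 == 0.0

    def test_bivalent_solver_recovers_monovalent_limit(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            base = random_model_parameters(rng)
            mono_a1 = solve_monovalent_equilibrium(base.monovalent())
            shrunk = ModelParameters(
                k1=base.k1, k2=base.k2 * 1e-14, koff=base.koff, rtot=base.rtot, atot=base.atot
            )
            eq = solve_bivalent_equilibrium(shrunk)
            assert eq.a1 == pytest.approx(mono_a1, rel=1e-6)
            assert eq.a2 <= 1e-6 * max(eq.a1, 1.0)
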