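"""Rate laws, generator structure, steady states, dV1/2 and phi."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.stats import binom

from mwcgate import (FARADAY, GAS_CONSTANT, GateParams, LigandSpec, Mechanism,
                     binding_rates, build_generator, delta_v_half,
                     detailed_balance_cycles, liganded_rates, open_mass,
                     open_probability_closed_form, phi_value, state_index,
                     steady_state, voltage_rates)
from mwcgate.gating import N_STATES, STATE_LABELS

RT = GAS_CONSTANT * 296.15


# -- strategies for random valid parameter sets -----------------------------

gate_st = st.builds(
    GateParams,
    alpha0=st.floats(0.5, 500.0),
    beta0=st.floats(10.0, 5000.0),
    z=st.floats(0.2, 2.5),
)

ligand_st = st.builds(
    LigandSpec,
    name=st.just("lig"),
    mechanism=st.sampled_from([Mechanism.TYPE_I, Mechanism.TYPE_II]),
    Kd=st.floats(1e-7, 1e-2),
    ddG=st.floats(-8000.0, -500.0),
    kon=st.floats(1e3, 1e8),
)


class TestVoltageRates:
    def test_identity_at_zero_mV(self, gate):
        assert voltage_rates(gate, 0.0) == (10.4, 1110.0)

    def test_at_plus_120_mV(self, gate):
        # direct evaluation of the exponential rate law
        x = 0.5 * 0.82 * FARADAY * 0.120 / RT
        a, b = voltage_rates(gate, 0.120)
        assert a == pytest.approx(10.4 * math.exp(x), rel=1e-12)
        assert a == pytest.approx(71.5065, rel=1e-4)
        assert b == pytest.approx(161.4398, rel=1e-4)

    def test_vanishing_charge_removes_voltage_dependence(self):
        g = GateParams(alpha0=10.0, beta0=100.0, z=1e-9)
        a1, b1 = voltage_rates(g, -0.14)
        a2, b2 = voltage_rates(g, 0.22)
        assert a1 == pytest.approx(a2, rel=1e-8)
        assert b1 == pytest.approx(b2, rel=1e-8)

    @given(gate_st, st.floats(-0.25, 0.25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_product_is_voltage_invariant(self, g, V):
        a, b = voltage_rates(g, V)
        assert a > 0 and b > 0
        assert a * b == pytest.approx(g.alpha0 * g.beta0, rel=1e-9)

    def test_rejects_non_finite_voltage(self, gate):
        with pytest.raises(ValueError):
            voltage_rates(gate, float("nan"))


class TestLigandedRates:
    def test_unliganded_matches_voltage_rates(self, gate, menthol):
        assert liganded_rates(gate, menthol, 0, 0.05) == voltage_rates(gate, 0.05)

    def test_type_i_fully_bound_slows_closing_only(self, gate, menthol):
        a4, b4 = liganded_rates(gate, menthol, 4, 0.0)
        assert a4 == 10.4
        assert b4 == pytest.approx(1110.0 * math.exp(4 * -4500.0 / RT), rel=1e-12)
        assert b4 == pytest.approx(0.7420, rel=1e-3)

    def test_type_ii_speeds_opening_only(self, gate, aitc):
        a2, b2 = liganded_rates(gate, aitc, 2, 0.0)
        assert b2 == 1110.0
        assert a2 == pytest.approx(10.4 * math.exp(2 * 2700.0 / RT), rel=1e-12)
        assert a2 == pytest.approx(93.22, rel=1e-3)

    def test_monotone_in_occupancy(self, gate, menthol, aitc):
        betas = [liganded_rates(gate, menthol, i, 0.0)[1] for i in range(5)]
        assert all(b2 < b1 for b1, b2 in zip(betas, betas[1:]))
        alphas = [liganded_rates(gate, aitc, i, 0.0)[0] for i in range(5)]
        assert all(a2 > a1 for a1, a2 in zip(alphas, alphas[1:]))

    @given(ligand_st, st.integers(0, 4))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equilibrium_constant_mechanism_independent(self, lig, i):
        g = GateParams(alpha0=10.4, beta0=1110.0)
        a, b = liganded_rates(g, lig, i, 0.0)
        expected = (10.4 / 1110.0) * math.exp(-i * lig.ddG / RT)
        assert a / b == pytest.approx(expected, rel=1e-9)

    def test_rejects_out_of_range_occupancy(self, gate, menthol):
        with pytest.raises(ValueError):
            liganded_rates(gate, menthol, 5, 0.0)


class TestBindingRates:
    def test_saturated_sites_block_binding(self, menthol):
        fwd, _ = binding_rates(menthol, "O", 4, 1.0)
        assert fwd == 0.0

    def test_open_forward_rate_at_kd(self, menthol):
        fwd, bwd = binding_rates(menthol, "O", 0, 21e-6)
        assert fwd == pytest.approx(4 * 551e3 * 21e-6, rel=1e-12)  # 46.284
        assert bwd == 0.0

    def test_closed_unbinding_set_by_detailed_balance(self, menthol):
        _, bwd = binding_rates(menthol, "C", 1, 0.0)
        koff_o = 551e3 * 21e-6
        assert bwd == pytest.approx(koff_o * math.exp(4500.0 / RT), rel=1e-12)
        assert bwd == pytest.approx(71.96, rel=1e-3)

    def test_rejects_negative_concentration(self, menthol):
        with pytest.raises(ValueError):
            binding_rates(menthol, "O", 0, -1e-6)


class TestGenerator:
    def test_has_ten_states(self, gate, menthol):
        Q = build_generator(gate, menthol, 1e-5, 0.0)
        assert Q.shape == (10, 10)
        assert len(STATE_LABELS) == N_STATES == 10

    def test_nearest_neighbour_sparsity(self, gate, menthol):
        Q = build_generator(gate, menthol, 1e-5, 0.05)
        for i in range(10):
            for j in range(10):
                if i == j or abs(Q[i, j]) == 0:
                    continue
                ci, cj = i % 5, j % 5
                same_tier = (i < 5) == (j < 5)
                assert (same_tier and abs(ci - cj) == 1) or (not same_tier and ci == cj)

    def test_zero_ligand_reduces_to_two_state(self, gate, menthol):
        Q = build_generator(gate, menthol, 0.0, 0.0)
        c0, o0 = state_index("C", 0), state_index("O", 0)
        occupied = [k for k in range(10) if k not in (c0, o0)]
        assert np.all(Q[c0, occupied] == 0)
        assert np.all(Q[o0, occupied] == 0)

    @given(gate_st, ligand_st, st.floats(0.0, 1e-2), st.floats(-0.15, 0.22))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rows_sum_to_zero_offdiag_nonnegative(self, g, lig, L, V):
        Q = build_generator(g, lig, L, V)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * max(1.0, np.abs(Q).max())
        off = Q - np.diag(np.diag(Q))
        assert off.min() >= 0

    @given(gate_st, ligand_st, st.floats(1e-7, 1e-2), st.floats(-0.15, 0.22))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_detailed_balance_cycle_closure(self, g, lig, L, V):
        for check in detailed_balance_cycles(g, lig, L, V):
            assert check.ratio == pytest.approx(1.0, rel=1e-10)


class TestSteadyState:
    def test_two_state_closed_form_at_plus_120(self, gate, menthol):
        Q = build_generator(gate, menthol, 0.0, 0.120)
        a, b = voltage_rates(gate, 0.120)
        assert open_mass(steady_state(Q)) == pytest.approx(a / (a + b), abs=1e-10)
        assert a / (a + b) == pytest.approx(0.307, abs=5e-4)

    def test_strong_depolarization_opens_fully(self, gate, menthol):
        Q = build_generator(gate, menthol, 0.0, 0.8)
        assert open_mass(steady_state(Q)) > 0.999

    @pytest.mark.parametrize("V", [-0.12, -0.06, 0.0, 0.06, 0.12])
    @pytest.mark.parametrize("Lrel", [0.0, 0.1, 1.0, 3.0, 10.0])
    def test_matches_partition_function_everywhere(self, gate, menthol, V, Lrel):
        L = Lrel * menthol.Kd
        p = steady_state(build_generator(gate, menthol, L, V))
        po = open_probability_closed_form(gate, menthol, L, V)
        assert open_mass(p) == pytest.approx(po, abs=1e-8)

    def test_occupancy_is_binomial_within_each_tier(self, gate, menthol):
        L = 3e-5
        p = steady_state(build_generator(gate, menthol, L, 0.0))
        for tier, kd in (("C", menthol.Kd_closed), ("O", menthol.Kd)):
            mass = np.array([p[state_index(tier, i)] for i in range(5)])
            cond = mass / mass.sum()
            expect = binom.pmf(np.arange(5), 4, L / (L + kd))
            np.testing.assert_allclose(cond, expect, atol=1e-10)

    def test_mechanism_independence_of_equilibrium(self, gate):
        lig1 = LigandSpec("a", Mechanism.TYPE_I, Kd=5e-5, ddG=-3000.0, kon=1e5)
        lig2 = LigandSpec("b", Mechanism.TYPE_II, Kd=5e-5, ddG=-3000.0, kon=1e5)
        for V in (-0.08, 0.0, 0.12):
            p1 = steady_state(build_generator(gate, lig1, 1e-4, V))
            p2 = steady_state(build_generator(gate, lig2, 1e-4, V))
            np.testing.assert_allclose(p1, p2, atol=1e-10)


class TestDeltaVHalf:
    def test_zero_at_zero_concentration(self, menthol):
        assert delta_v_half(menthol, 0.0, 0.82) == 0.0

    def test_zero_for_neutral_ligand(self):
        lig = LigandSpec("x", Mechanism.TYPE_I, Kd=1e-5, ddG=0.0, kon=1e5)
        assert delta_v_half(lig, 1e-3, 0.82) == pytest.approx(0.0, abs=1e-15)

    def test_menthol_at_kd(self, menthol):
        # direct evaluation of the shift equation
        x = 1.0
        num = (1 + x) ** 4
        den = (1 + x * math.exp(-4500.0 / RT)) ** 4
        expect = -(RT / (0.82 * FARADAY)) * math.log(num / den)
        got = delta_v_half(menthol, 21e-6, 0.82)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got * 1e3 == pytest.approx(-67.7, abs=0.05)

    def test_monotone_and_saturating(self, menthol):
        concs = np.geomspace(1e-7, 1e-1, 30)
        dv = [delta_v_half(menthol, L, 0.82) for L in concs]
        assert all(b < a for a, b in zip(dv, dv[1:]))
        limit = 4 * -4500.0 / (0.82 * FARADAY)
        assert dv[-1] == pytest.approx(limit, rel=1e-3)

    def test_consistent_with_open_probability_midpoint(self, gate, menthol):
        """dV1/2 from the closed form equals the numerical midpoint shift."""
        def v_half(L):
            return optimize.brentq(
                lambda V: open_probability_closed_form(gate, menthol, L, V) - 0.5,
                -0.5, 0.8, xtol=1e-12)
        for L in (1e-5, 3e-5, 2.1e-4):
            shift = v_half(L) - v_half(0.0)
            assert shift == pytest.approx(delta_v_half(menthol, L, 0.82),
                                          abs=1e-5)  # < 0.01 mV


class TestPhi:
    def test_type_i_is_exactly_zero(self, gate, menthol):
        assert phi_value(gate, menthol) == pytest.approx(0.0, abs=1e-12)

    def test_type_ii_is_exactly_one(self, gate, aitc):
        assert phi_value(gate, aitc) == pytest.approx(1.0, abs=1e-12)

    def test_voltage_independent(self, gate, menthol, aitc):
        for V in (-0.08, 0.12):
            assert phi_value(gate, menthol, V) == pytest.approx(0.0, abs=1e-12)
            assert phi_value(gate, aitc, V) == pytest.approx(1.0, abs=1e-12)

    def test_undefined_for_zero_ddG(self, gate):
        lig = LigandSpec("x", Mechanism.TYPE_I, Kd=1e-5, ddG=0.0, kon=1e5)
        with pytest.raises(ValueError):
            phi_value(gate, lig)
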