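"""Gating kinetics, calcium pool and cable-solver correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulbnet.biophysics import (
    CHANNELS,
    CableGroup,
    CableModel,
    CalciumPool,
    Compartment,
    evaluate_gate,
    get_channel,
    integrate,
    kca_activation,
    step_calcium,
    trap,
)

TFAC = 2.0 ** ((35.0 - 24.0) / 10.0)


class TestTrap:
    def test_limit_at_singularity(self):
        # at V == th the analytic limit a*q*2^((35-24)/10) applies
        assert trap(-30.0, -30.0, 4.0e5, 7.2) == pytest.approx(
            4.0e5 * 1e-3 * 7.2 * TFAC)

    def test_zero_rate_for_zero_amplitude(self):
        for v in (-80.0, -30.0, 10.0):
            assert trap(v, -30.0, 0.0, 7.2) == 0.0

    def test_continuity_across_guard(self):
        a, q, th = 4.0e5, 7.2, -30.0
        lim = trap(th, th, a, q)
        near = trap(th + 1e-6, th, a, q)
        assert abs(near - lim) < 1e-6 * a * 1e-3 * q

    @given(st.floats(-100.0, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_positive_everywhere(self, v):
        assert trap(v, -30.0, 4.0e5, 7.2) >= 0.0


class TestGateKinetics:
    def test_ka_ms_activation_midpoint(self):
        m = get_channel("KA_ms").gates[0]
        inf, tau = evaluate_gate(m, 17.5)
        assert inf == pytest.approx(0.5)
        assert tau > 0

    def test_tca_inactivation_midpoint(self):
        h = get_channel("TCa_d").gates[1]
        inf, _ = evaluate_gate(h, -78.0)
        assert inf == pytest.approx(0.5)

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            get_channel("Na_nonexistent")

    @pytest.mark.parametrize("name", sorted(CHANNELS))
    def test_gate_invariants_over_voltage_range(self, name):
        """Steady states bounded in [0,1], taus positive, monotone direction
        consistent over the physiological range."""
        v = np.linspace(-120.0, 60.0, 361)
        for g in CHANNELS[name].gates:
            inf, tau = evaluate_gate(g, v)
            assert np.all(inf >= -1e-12) and np.all(inf <= 1 + 1e-12)
            assert np.all(tau > 0)
            d = np.diff(inf)
            # each printed gate is monotone (activation up or inactivation
            # down); allow tiny numerical wiggle
            assert np.all(d >= -1e-9) or np.all(d <= 1e-9)

    def test_na_tau_floors(self):
        na = get_channel("Na_mit_initialsegment_MS")
        v = np.linspace(-120, 60, 200)
        _, tau_m = evaluate_gate(na.gates[0], v)
        _, tau_h = evaluate_gate(na.gates[1], v)
        assert np.all(tau_m >= 0.02 - 1e-12)
        assert np.all(tau_h >= 0.5 - 1e-12)


class TestKcaActivation:
    def test_half_points(self):
        assert kca_activation(0.0055, "pg") == pytest.approx(0.5)
        assert kca_activation(0.015, "mitral") == pytest.approx(0.5)

    def test_monotone(self):
        ca = np.linspace(0, 0.1, 200)
        out = kca_activation(ca, "mitral")
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            kca_activation(-0.01)


class TestCalciumPool:
    def test_fixed_point_without_current(self):
        pool = CalciumPool(concentration=5e-5, baseline=5e-5)
        out = step_calcium(pool, 0.0, 1.0)
        assert out.concentration == pytest.approx(5e-5)

    def test_steady_state_closed_form(self):
        pool = CalciumPool(concentration=5e-5, baseline=5e-5,
                           influx_scale=0.02, decay_time=10.0)
        for _ in range(5000):
            pool = step_calcium(pool, 0.5, 0.5)
        expect = 5e-5 + 0.02 * 0.5 * 10.0
        assert pool.concentration == pytest.approx(expect, rel=1e-4)

    def test_richardson_halving(self):
        p_full = step_calcium(CalciumPool(concentration=1e-3), 0.2, 1.0)
        p_half = step_calcium(step_calcium(CalciumPool(concentration=1e-3),
                                           0.2, 0.5), 0.2, 0.5)
        # exact exponential update: both agree to machine precision
        assert p_full.concentration == pytest.approx(p_half.concentration,
                                                     rel=1e-12)


def _passive_comp():
    return Compartment("soma", 20.0, 20.0, -1)


class TestCableSolver:
    def test_rc_step_matches_closed_form(self):
        c = _passive_comp()
        m = CableModel([c])
        area = c.area * 1e-12
        R = c.membrane_resistivity / area / 1e6  # MOhm
        tau = c.membrane_resistivity * c.specific_capacitance * 1000.0
        I = 0.05
        t, tr, _ = integrate(m, dt=0.025, duration=200.0,
                             i_inj=lambda tt: np.array([I]))
        expect = -65.0 + I * R * (1.0 - np.exp(-t / tau))
        assert np.max(np.abs(tr[:, 0] - expect)) < 0.01 * I * R

    def test_rest_without_input(self):
        m = CableModel([_passive_comp()])
        _, tr, spikes = integrate(m, dt=0.05, duration=100.0)
        assert np.allclose(tr[:, 0], -65.0, atol=1e-9)
        assert len(spikes) == 0

    def test_two_compartment_divider(self):
        c1 = Compartment("a", 50.0, 2.0, -1)
        c2 = Compartment("b", 50.0, 2.0, 0)
        m = CableModel([c1, c2])
        inj = np.array([0.05, 0.0])
        t, tr, _ = integrate(m, dt=0.05, duration=800.0,
                             i_inj=lambda tt: inj, record=[0, 1])
        g = CableGroup(m)
        ga = g.off[1]
        A = np.array([[g.gleak[0] + ga, -ga], [-ga, g.gleak[1] + ga]])
        b = np.array([g.gleak[0] * -65.0 + 0.05, g.gleak[1] * -65.0])
        expect = np.linalg.solve(A, b)
        assert tr[-1] == pytest.approx(expect, rel=1e-3)

    def test_charge_conservation_of_implicit_solve(self):
        """The solved voltages satisfy the discrete theta-scheme balance:
        capacitive current equals the theta-weighted membrane + axial
        currents plus injection (residual at machine precision)."""
        c1 = Compartment("a", 40.0, 3.0, -1)
        c2 = Compartment("b", 60.0, 2.0, 0)
        c3 = Compartment("c", 30.0, 1.0, 1)
        m = CableModel([c1, c2, c3])
        grp = CableGroup(m)
        th = grp.theta
        dt = 0.05
        grp.build_tables(dt)
        v_old = grp.v.copy()
        inj = np.zeros((1, 3))
        inj[0, 0] = 0.08
        v_new = grp.step(dt, i_inj=inj).copy()

        def balance(v):
            out = np.zeros(3)
            for k in range(3):
                out[k] = grp.gleak[k] * (v[0, k]
                                         - m.compartments[k].leak_reversal)
                for j in range(1, 3):
                    p = grp.parent[j]
                    flow = grp.off[j] * (v[0, p] - v[0, j])
                    if j == k:
                        out[k] -= flow
                    if p == k:
                        out[k] += flow
            return out

        lhs = grp.cm / dt * (v_new[0] - v_old[0])
        rhs = inj[0] - th * balance(v_new) - (1 - th) * balance(v_old)
        for k in range(3):
            assert abs(lhs[k] - rhs[k]) < 1e-9 * max(abs(lhs[k]), 1.0)

    def test_gate_bounds_along_trajectory(self):
        """Gate state variables stay in [0, 1] through a spiking run."""
        from bulbnet.cells import build_granule
        g = build_granule()
        grp = CableGroup(g)
        grp.build_tables(0.05)
        inj = np.zeros((1, g.n_comp))
        inj[0, 0] = 0.2
        for _ in range(4000):
            grp.step(0.05, i_inj=inj)
            assert np.all(grp._states >= -1e-9)
            assert np.all(grp._states <= 1 + 1e-9)
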