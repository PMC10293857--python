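"""Regulation rules: errors, rates, gate sigmoid, feedback signal, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeoburst import (ControlScheme, GateParams, alpha_target,
                        conductance_rate, error_rates, feedback_signal,
                        sensor_error)
from homeoburst.params import DEFAULT_L


class TestControlScheme:
    def test_default_matrix(self):
        s = ControlScheme()
        # columns: Na CaT CaS A KCa Kd H
        expect = {
            "Na": (1, 0, 0), "CaT": (0, 1, 0), "CaS": (0, 1, 0),
            "A": (0, -1, -1), "KCa": (0, -1, -1), "Kd": (1, -1, 0),
            "H": (0, 1, 1)}
        cols = ["Na", "CaT", "CaS", "A", "KCa", "Kd", "H"]
        for j, name in enumerate(cols):
            assert tuple(s.L[:, j]) == expect[name], name
        assert s.targets == pytest.approx([0.1, 0.07, 0.07])

    def test_sensor_error(self):
        s = ControlScheme()
        assert sensor_error(0.1, 0.07, 0.07, s) == pytest.approx([0, 0, 0])
        assert sensor_error(0.0, 0.0, 0.0, s) == pytest.approx([0.1, 0.07, 0.07])
        assert sensor_error(0.2, 0.07, 0.07, s)[0] == pytest.approx(-0.1)


class TestConductanceRate:
    def test_gate_zero_freezes(self):
        s = ControlScheme()
        g = np.full(7, 2.0)
        r = conductance_rate(g, [0.1, 0.0, 0.0], s, alpha=0.0, mode="gated")
        assert r == pytest.approx(np.zeros(7))

    def test_kd_column_combination(self):
        s = ControlScheme()
        dF, dS, dD = 0.03, -0.02, 0.05
        g = np.ones(7)
        r = conductance_rate(g, [dF, dS, dD], s, mode="original")
        # Kd (index 5) has coefficients (1, -1, 0)
        assert r[5] == pytest.approx((dF - dS) / s.tau_g)
        # Na (index 0) only listens to the fast error
        assert r[0] == pytest.approx(dF / s.tau_g)

    def test_original_mode_drops_cubic(self):
        s = ControlScheme(gamma=1e-5)
        g = np.full(7, 100.0)
        r_orig = conductance_rate(g, [0.1, 0.1, 0.1], s, mode="original")
        r_bnd = conductance_rate(g, [0.1, 0.1, 0.1], s, mode="bounded")
        assert np.all(r_bnd <= r_orig)
        assert not np.allclose(r_bnd, r_orig)

    def test_bounded_equilibrium_sqrt(self):
        """Constant drive c per unit g: bounded equilibrium at sqrt(c/gamma)."""
        s = ControlScheme(gamma=1e-5)
        c = 0.07      # CaT drive when delta_S = 0.07
        g_star = np.sqrt(c / s.gamma)
        r = conductance_rate(np.full(7, g_star), [0.0, c, 0.0], s,
                             mode="bounded")
        assert r[1] == pytest.approx(0.0, abs=1e-12)   # CaT at equilibrium
        below = conductance_rate(np.full(7, 0.9 * g_star), [0.0, c, 0.0], s,
                                 mode="bounded")
        above = conductance_rate(np.full(7, 1.1 * g_star), [0.0, c, 0.0], s,
                                 mode="bounded")
        assert below[1] > 0 > above[1]

    def test_zero_is_invariant(self):
        s = ControlScheme()
        r = conductance_rate(np.zeros(7), [0.1, 0.07, 0.07], s, mode="bounded")
        assert r == pytest.approx(np.zeros(7))

    def test_boundedness_under_worst_case_drive(self):
        """Constant worst-case drive confines g below sqrt(drive/gamma)."""
        s = ControlScheme(gamma=1e-5)
        delta = np.array([0.2, 0.2, 0.2])
        c = s.L.T @ delta                 # per-channel constant drive
        cap = np.sqrt(c.max() / s.gamma)
        g = np.full(7, 5.0)
        dt = 2.0
        for _ in range(40_000):           # 80 s >> growth time
            g = g + dt * conductance_rate(g, delta, s, mode="bounded")
        assert np.all(g <= cap * 1.01)
        assert g.max() >= cap * 0.9       # the cap is actually approached
        assert np.all(g >= 0.0)

    def test_off_mode(self):
        s = ControlScheme()
        assert conductance_rate(np.ones(7), [1, 1, 1], s, mode="off") \
            == pytest.approx(np.zeros(7))


class TestGate:
    def test_half_activation(self):
        g = GateParams()
        assert alpha_target(g.rho, g) == pytest.approx(0.5)

    def test_near_one_at_zero_feedback(self):
        g = GateParams()
        assert alpha_target(0.0, g) == pytest.approx(1 / (1 + np.exp(-7.5)),
                                                     rel=1e-9)

    def test_feedback_above_tenth_shuts_gate(self):
        g = GateParams()
        assert alpha_target(0.1, g) == pytest.approx(0.076, abs=0.003)
        assert alpha_target(0.3, g) < 1e-9

    @given(st.floats(0.0, 1.0), st.floats(1e-6, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing(self, s_f, step):
        g = GateParams()
        hi = min(1.0, s_f + step)
        if hi > s_f:
            assert alpha_target(hi, g) < alpha_target(s_f, g)


class TestErrorsAndFeedback:
    def test_error_equilibrium(self):
        g = GateParams(tau_s=2000.0)
        assert error_rates([0.1, 0.0, -0.1], [0.1, 0.0, -0.1], g) \
            == pytest.approx(np.zeros(3))
        assert error_rates([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], g) \
            == pytest.approx(np.zeros(3))

    def test_exponential_relaxation(self):
        """Constant delta: E(t) -> delta with timescale tau_S (closed form)."""
        g = GateParams(tau_s=2000.0)
        delta = np.array([0.05, -0.02, 0.01])
        e = np.zeros(3)
        dt = 1.0
        n = 4000                     # 4 s = 2 tau
        for _ in range(n):
            e = e + dt * error_rates(delta, e, g)
        expect = delta * (1 - np.exp(-n * dt / 2000.0))
        assert e == pytest.approx(expect, rel=2e-3)

    def test_feedback_values(self):
        g = GateParams()
        assert feedback_signal([0.0, 0.0, 0.0], g) == 1.0
        assert feedback_signal([np.sqrt(g.spread), 0.0, 0.0], g) \
            == pytest.approx(np.exp(-1.0))
        # AND gate: one error of 0.1 kills the signal regardless of others
        assert feedback_signal([0.1, 0.0, 0.0], g) \
            == pytest.approx(np.exp(-10.0), rel=1e-9)
        assert feedback_signal([0.1, 0.0, 0.0], g) < 1e-4

    @given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_range_and_identity(self, e):
        g = GateParams()
        e = np.array(e)
        s = feedback_signal(e, g)
        assert 0.0 <= s <= 1.0
        if (e ** 2).sum() / g.spread < 700:   # above that, exp underflows
            assert s > 0.0
        if s == 1.0:
            assert np.allclose(e, 0.0)
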