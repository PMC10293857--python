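"""Exponential-Euler stepping: exactness, ordering, kernel equivalence."""

import numpy as np
import pytest

from homeoburst import Model, SimulationConfig
from homeoburst.biophysics import IntrinsicState, ionic_currents, nernst_eca
from homeoburst.channels import gate_targets
from homeoburst.integrator import (SLOW_COLS, STATE_SIZE, YIDX, advance_kernel,
                                   exp_euler_update)
from homeoburst.params import pack_params
from homeoburst.regulation import (alpha_target, conductance_rate,
                                   feedback_signal, sensor_error)
from homeoburst.sensors import SensorState, sensor_gate_targets, sensor_outputs
from homeoburst.simulator import draw_initial_conductances, initial_state, run


class TestExpEuler:
    def test_fixed_point(self):
        assert exp_euler_update(0.7, 0.7, 5.0, 0.1) == pytest.approx(0.7)

    def test_small_dt_identity(self):
        assert exp_euler_update(0.2, 1.0, 5.0, 1e-12) == pytest.approx(0.2)

    def test_one_tau_step(self):
        # x = 0 -> target 1 with tau = dt: 1 - e^-1
        assert exp_euler_update(0.0, 1.0, 1.0, 1.0) \
            == pytest.approx(1.0 - np.exp(-1.0))

    def test_semigroup(self):
        """One step of 2*dt equals two steps of dt for constant targets."""
        x = 0.123
        one = exp_euler_update(x, 1.0, 3.0, 0.2)
        two = exp_euler_update(exp_euler_update(x, 1.0, 3.0, 0.1), 1.0, 3.0, 0.1)
        assert one == pytest.approx(two, rel=1e-14)

    def test_never_overshoots(self):
        x = exp_euler_update(0.0, 1.0, 0.01, 100.0)
        assert x <= 1.0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            exp_euler_update(0.0, 1.0, -1.0, 0.1)


def python_advance(y, g, model, dt, mode_code, i_ext=0.0):
    """Independent single-step re-derivation from the module-level operations.

    Mirrors the documented update order: channel gates, currents, sensor
    gates, errors/feedback/alpha, V, Ca, then conductances.
    """
    n, sp, sc, gp = model.neuron, model.sensors, model.scheme, model.gate
    v, ca = y[0], y[1]
    m = y[YIDX.M:YIDX.M + 7].copy()
    h = y[YIDX.H:YIDX.H + 4].copy()
    m_inf, tau_m, h_inf, tau_h = gate_targets(v, ca)
    m = exp_euler_update(m, m_inf, tau_m, dt)
    h = exp_euler_update(h, h_inf, tau_h, dt)

    from dataclasses import replace
    neuron = replace(n, gbar=g.copy())
    st = IntrinsicState(v=v, m=m, h=np.clip(h, 0, 1), ca_in=ca)
    cur = ionic_currents(st, neuron)
    i_ca = cur[1] + cur[2]

    sm = y[YIDX.SM:YIDX.SM + 3].copy()
    sh = y[YIDX.SH:YIDX.SH + 2].copy()
    m_bar, h_bar = sensor_gate_targets(float(i_ca), sp)
    sm = exp_euler_update(sm, m_bar, sp.tau_m, dt)
    sh = exp_euler_update(sh, h_bar, sp.tau_h, dt)
    F, S, D = sensor_outputs(SensorState(m=sm, h=sh), sp)
    delta = sensor_error(F, S, D, sc)

    e = y[YIDX.E:YIDX.E + 3].copy()
    tau_s = gp.tau_s_effective(sc.tau_g)
    e = exp_euler_update(e, delta, tau_s, dt)
    s_f = feedback_signal(e, gp)
    alpha = exp_euler_update(y[YIDX.ALPHA], alpha_target(s_f, gp),
                             gp.tau_alpha, dt)

    e_ca = float(nernst_eca(ca, n.ca_out_mM, n.nernst_mV))
    rev = n.reversals(e_ca)
    from homeoburst.channels import P_EXP, Q_EXP, CHANNELS, INACTIVATING
    m_full = np.append(m, 1.0)
    h_full = np.ones(8)
    for j, name in enumerate(INACTIVATING):
        h_full[CHANNELS.index(name)] = h[j]
    ge = g * m_full ** P_EXP * h_full ** Q_EXP
    gtot = ge.sum()
    vinf = (i_ext + (ge * rev).sum()) / gtot
    v_new = vinf + (v - vinf) * np.exp(-dt * gtot / n.c_nF)

    ca_inf = n.ca_0 - n.ca_f * i_ca
    ca_new = max(ca_inf + (ca - ca_inf) * np.exp(-dt / n.tau_ca), 1e-9)

    mode = ("off", "original", "bounded", "gated")[mode_code]
    g_new = g.copy()
    g_new[:7] = g[:7] + dt * conductance_rate(g[:7], delta, sc,
                                              alpha=alpha, mode=mode)
    y_new = np.empty(STATE_SIZE)
    y_new[0], y_new[1] = v_new, ca_new
    y_new[YIDX.M:YIDX.M + 7] = m
    y_new[YIDX.H:YIDX.H + 4] = h
    y_new[YIDX.SM:YIDX.SM + 3] = sm
    y_new[YIDX.SH:YIDX.SH + 2] = sh
    y_new[YIDX.E:YIDX.E + 3] = e
    y_new[YIDX.ALPHA] = alpha
    return y_new, g_new


class TestKernelEquivalence:
    def test_kernel_matches_python_composition(self):
        """200 compiled steps agree with the op-by-op python re-derivation."""
        model = Model()
        g0 = np.array([40.0, 1.5, 2.0, 3.0, 5.0, 40.0, 0.2, 0.03])
        state = initial_state(model, g0)
        y_py, g_py = state.y.copy(), state.gbar.copy()
        y_k, g_k = state.y.copy(), state.gbar.copy()
        dt = 0.1
        P = pack_params(model, mode="gated")
        v_rec = np.empty(0)
        s_rec = np.empty((0, len(SLOW_COLS)))
        c_rec = np.empty((1, 8))
        advance_kernel(200, dt, y_k, g_k, np.ones(7), P,
                       v_rec, 10**9, s_rec, 0, c_rec, 0, 10**9)
        for _ in range(200):
            y_py, g_py = python_advance(y_py, g_py, model, dt, 3)
        assert y_k == pytest.approx(y_py, rel=1e-9, abs=1e-12)
        assert g_k == pytest.approx(g_py, rel=1e-9)

    def test_regulation_off_keeps_conductances(self):
        model = Model()
        g0 = np.array([40.0, 1.5, 2.0, 3.0, 5.0, 40.0, 0.2, 0.03])
        traj = run(model, 5000.0, mode="off", gbar0=g0)
        assert np.allclose(traj.gbar, g0, atol=0)
        assert traj.final_state.gbar == pytest.approx(g0)


class TestRunMechanics:
    def test_zero_duration(self):
        traj = run(Model(), 0.0, gbar0=np.full(7, 0.01))
        assert len(traj.v) == 0
        assert traj.duration == 0.0
        assert not traj.diverged

    def test_draw_determinism(self):
        a = draw_initial_conductances(123)
        b = draw_initial_conductances(123)
        c = draw_initial_conductances(124)
        assert a == pytest.approx(b)
        assert np.all(a > 0)
        assert not np.allclose(a, c)

    def test_recording_stride_does_not_alter_dynamics(self):
        model = Model()
        g0 = draw_initial_conductances(5)
        cfg1 = SimulationConfig(stride_v=10, stride_slow=500)
        cfg2 = SimulationConfig(stride_v=20, stride_slow=1000)
        t1 = run(model, 20_000.0, config=cfg1, gbar0=g0)
        t2 = run(model, 20_000.0, config=cfg2, gbar0=g0)
        assert t1.final_state.y == pytest.approx(t2.final_state.y, rel=0,
                                                 abs=0)
        assert t1.v[1::2] == pytest.approx(t2.v, rel=0, abs=0)
        assert t1.slow[1::2] == pytest.approx(t2.slow, rel=0, abs=0)

    def test_state_invariants_along_trajectory(self, burster, model):
        """Gates stay in [0,1] and calcium positive over a long stretch."""
        cfg = SimulationConfig(stride_slow=100)
        traj = run(model, 60_000.0, mode="gated", state=burster.state,
                   config=cfg)
        y = traj.final_state.y
        gates = np.concatenate([y[YIDX.M:YIDX.M + 7], y[YIDX.H:YIDX.H + 4],
                                y[YIDX.SM:YIDX.SM + 3], y[YIDX.SH:YIDX.SH + 2]])
        assert np.all(gates >= 0) and np.all(gates <= 1)
        assert np.all(traj.ca > 0)
        assert np.all(traj.gbar >= 0)
        assert 0.0 < traj.final_state.alpha < 1.0


class TestSelfAssemblyDeterminism:
    def test_identical_seed_identical_burster(self, model, burster):
        """Re-running self-assembly from the same seed stream reproduces the
        converged conductances bit for bit."""
        from homeoburst.experiments import make_bursters
        again = make_bursters(model, 1, seed=77)[0]
        assert again.final_gbar == pytest.approx(burster.final_gbar,
                                                 rel=0, abs=0)
        assert again.gate_off_ms == burster.gate_off_ms
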