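"""Exponential-Euler integration kernel for the full regulated neuron.

The coupled system (membrane + channel gates + calcium + sensors + error
integrators + gate alpha + conductances) is advanced with a fixed step
``dt`` (default 0.1 ms).  Conductances are in uS so g*(V-E) is nA.  Every equation of relaxation form

    tau(x) dx/dt = x_target - x

is stepped exactly for frozen target/timescale via
``x <- x_target + (x - x_target) exp(-dt/tau)``; the conductance rule is
not of relaxation form and uses forward Euler (dt/tau_G ~ 5e-5, so
stability is not a concern).  Within one step the update order is:

1. channel gating variables (targets evaluated at the current V, Ca),
2. per-channel effective conductances and the calcium currents,
3. sensor gates, sensor outputs, errors, averaged errors E, S_f, alpha,
4. membrane potential (exponential Euler against the conductance-weighted
   reversal),
5. intracellular calcium,
6. maximal conductances (forward Euler on the regulation rate).

The inner loop is a single :func:`numba.njit` kernel over flat float64
arrays -- no Python callbacks -- so multi-hour simulated runs stay cheap.
A guard check every ``guard_every`` steps flags divergence (any regulated
conductance above ``P[GUARD_G]``, |V| above ``P[GUARD_V]``, or non-finite
V) and halts instead of overflowing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PIDX  # noqa: F401  (index layout documented there)

__all__ = ["exp_euler_update", "advance_kernel", "rk4_fixed_conductances",
           "STATE_SIZE", "SLOW_COLS", "YIDX"]

#: number of state variables carried by the kernel state vector
STATE_SIZE = 22


class YIDX:
    """Index constants of the kernel state vector."""
    V = 0
    CA = 1
    M = 2      # 2..8   m (Na, CaT, CaS, A, KCa, Kd, H)
    H = 9      # 9..12  h (Na, CaT, CaS, A)
    SM = 13    # 13..15 sensor activation (F, S, D)
    SH = 16    # 16..17 sensor inactivation (F, S)
    E = 18     # 18..20 averaged errors (F, S, D)
    ALPHA = 21


#: column names of the slow record array produced by the kernel
SLOW_COLS = ("V", "Ca", "g_Na", "g_CaT", "g_CaS", "g_A", "g_KCa", "g_Kd",
             "g_H", "g_leak", "F", "S", "D", "E_F", "E_S", "E_D", "S_f",
             "alpha")


def exp_euler_update(x, x_target, tau, dt):
    """One exponential-Euler step: x_target + (x - x_target) exp(-dt/tau).

    Exact for relaxation toward a constant target, hence it obeys the
    semigroup property (one step of 2*dt equals two steps of dt) and can
    never overshoot the target.
    """
    if np.any(np.asarray(tau) <= 0) or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return x_target + (x - x_target) * np.exp(-dt / np.asarray(tau, dtype=float))


@njit(cache=True, fastmath=True)
def advance_kernel(n_steps, dt, y, g, reg_mask, P,
                   v_rec, stride_v, s_rec, stride_s, c_rec, stride_c,
                   guard_every):  # pragma: no cover - exercised via wrappers
    """Advance the full system ``n_steps`` of size ``dt``, recording on the fly.

    ``y`` (STATE_SIZE,) and ``g`` (8,) are updated in place.  ``reg_mask``
    (7,) zeroes the regulation rate of pinned (deleted) channels.  Records
    are written every ``stride_v`` steps (V only), every ``stride_s`` steps
    (slow variables, SLOW_COLS order) and every ``stride_c`` steps
    (per-channel currents, nA); a stride <= 0 disables that record.

    Returns (status, steps_done, n_v, n_s, n_c); status 1 means the
    divergence guard tripped at step ``steps_done``.
    """
    C = P[0]
    e_na = P[1]; e_k = P[2]; e_h = P[3]; e_leak = P[4]
    ca_out = P[5] * 1000.0       # uM
    pref = P[6]; ca_f = P[7]; ca_0 = P[8]
    zmf = P[10]; zms = P[11]; zmd = P[12]; zhf = P[13]; zhs = P[14]
    gf = P[20]; gs = P[21]; gd = P[22]
    fbar = P[23]; sbar = P[24]; dbar = P[25]
    tau_g = P[47]; gamma = P[48]
    rho = P[50]; dalpha = P[51]; spread = P[53]
    mode = int(P[54]); i_ext = P[55]
    guard_g = P[56]; guard_v = P[57]

    gam = 0.0 if mode == 1 else gamma

    # decay factors of the constant-timescale relaxations
    dMF = np.exp(-dt / P[15]); dMS = np.exp(-dt / P[16]); dMD = np.exp(-dt / P[17])
    dHF = np.exp(-dt / P[18]); dHS = np.exp(-dt / P[19])
    dE = np.exp(-dt / P[49]); dAl = np.exp(-dt / P[52]); dCad = np.exp(-dt / P[9])

    v = y[0]; ca = y[1]
    mna = y[2]; mcat = y[3]; mcas = y[4]; ma = y[5]; mkca = y[6]; mkd = y[7]; mh = y[8]
    hna = y[9]; hcat = y[10]; hcas = y[11]; ha = y[12]
    MF = y[13]; MS = y[14]; MD = y[15]; HF = y[16]; HS = y[17]
    EF = y[18]; ES = y[19]; ED = y[20]; al = y[21]

    iv = 0; isl = 0; icr = 0
    status = 0
    k_done = n_steps

    for k in range(1, n_steps + 1):
        # --- 1. channel gates (Liu et al. 1998 kinetics) ------------------
        x = 1.0 / (1.0 + np.exp((v + 25.5) / -5.29))
        t = 1.32 - 1.26 / (1.0 + np.exp((v + 120.0) / -25.0))
        mna = x + (mna - x) * np.exp(-dt / t)
        x = 1.0 / (1.0 + np.exp((v + 48.9) / 5.18))
        t = (0.67 / (1.0 + np.exp((v + 62.9) / -10.0))) \
            * (1.5 + 1.0 / (1.0 + np.exp((v + 34.9) / 3.6)))
        hna = x + (hna - x) * np.exp(-dt / t)

        x = 1.0 / (1.0 + np.exp((v + 27.1) / -7.2))
        t = 21.7 - 21.3 / (1.0 + np.exp((v + 68.1) / -20.5))
        mcat = x + (mcat - x) * np.exp(-dt / t)
        x = 1.0 / (1.0 + np.exp((v + 32.1) / 5.5))
        t = 105.0 - 89.8 / (1.0 + np.exp((v + 55.0) / -16.9))
        hcat = x + (hcat - x) * np.exp(-dt / t)

        x = 1.0 / (1.0 + np.exp((v + 33.0) / -8.1))
        t = 1.4 + 7.0 / (np.exp((v + 27.0) / 10.0) + np.exp((v + 70.0) / -13.0))
        mcas = x + (mcas - x) * np.exp(-dt / t)
        x = 1.0 / (1.0 + np.exp((v + 60.0) / 6.2))
        t = 60.0 + 150.0 / (np.exp((v + 55.0) / 9.0) + np.exp((v + 65.0) / -16.0))
        hcas = x + (hcas - x) * np.exp(-dt / t)

        x = 1.0 / (1.0 + np.exp((v + 27.2) / -8.7))
        t = 11.6 - 10.4 / (1.0 + np.exp((v + 32.9) / -15.2))
        ma = x + (ma - x) * np.exp(-dt / t)
        x = 1.0 / (1.0 + np.exp((v + 56.9) / 4.9))
        t = 38.6 - 29.2 / (1.0 + np.exp((v + 38.9) / -26.5))
        ha = x + (ha - x) * np.exp(-dt / t)

        x = (ca / (ca + 3.0)) / (1.0 + np.exp((v + 28.3) / -12.6))
        t = 90.3 - 75.1 / (1.0 + np.exp((v + 46.0) / -22.7))
        mkca = x + (mkca - x) * np.exp(-dt / t)

        x = 1.0 / (1.0 + np.exp((v + 12.3) / -11.8))
        t = 7.2 - 6.4 / (1.0 + np.exp((v + 28.3) / -19.2))
        mkd = x + (mkd - x) * np.exp(-dt / t)

        x = 1.0 / (1.0 + np.exp((v + 70.0) / 6.0))
        t = 272.0 + 1499.0 / (1.0 + np.exp((v + 42.2) / -8.73))
        mh = x + (mh - x) * np.exp(-dt / t)

        # --- 2. effective conductances and calcium currents ---------------
        eca = pref * np.log(ca_out / ca)
        ge_na = g[0] * mna * mna * mna * hna
        ge_cat = g[1] * mcat * mcat * mcat * hcat
        ge_cas = g[2] * mcas * mcas * mcas * hcas
        ge_a = g[3] * ma * ma * ma * ha
        m2 = mkca * mkca
        ge_kca = g[4] * m2 * m2
        m2 = mkd * mkd
        ge_kd = g[5] * m2 * m2
        ge_h = g[6] * mh

        icat = ge_cat * (v - eca)
        icas = ge_cas * (v - eca)
        ica = icat + icas

        # --- 3. sensors, averaged errors, feedback, gate ------------------
        x = zmf + ica
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        b = 1.0 / (1.0 + np.exp(x))
        MF = b + (MF - b) * dMF
        x = zms + ica
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        b = 1.0 / (1.0 + np.exp(x))
        MS = b + (MS - b) * dMS
        x = zmd + ica
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        b = 1.0 / (1.0 + np.exp(x))
        MD = b + (MD - b) * dMD
        x = -zhf - ica
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        b = 1.0 / (1.0 + np.exp(x))
        HF = b + (HF - b) * dHF
        x = -zhs - ica
        if x > 60.0:
            x = 60.0
        elif x < -60.0:
            x = -60.0
        b = 1.0 / (1.0 + np.exp(x))
        HS = b + (HS - b) * dHS

        F = gf * MF * MF * HF
        S = gs * MS * MS * HS
        D = gd * MD * MD
        dF = fbar - F; dS = sbar - S; dD = dbar - D

        EF = dF + (EF - dF) * dE
        ES = dS + (ES - dS) * dE
        ED = dD + (ED - dD) * dE
        sf = np.exp(-(EF * EF + ES * ES + ED * ED) / spread)
        b = 1.0 / (1.0 + np.exp((sf - rho) / dalpha))
        al = b + (al - b) * dAl

        # --- 4. membrane potential ----------------------------------------
        gtot = ge_na + ge_cat + ge_cas + ge_a + ge_kca + ge_kd + ge_h + g[7]
        if gtot > 1e-12:
            se = (ge_na * e_na + (ge_cat + ge_cas) * eca
                  + (ge_a + ge_kca + ge_kd) * e_k + ge_h * e_h + g[7] * e_leak)
            vinf = (i_ext + se) / gtot
            v = vinf + (v - vinf) * np.exp(-dt * gtot / C)
        else:
            v = v + dt * i_ext / C

        # --- 5. intracellular calcium --------------------------------------
        b = ca_0 - ca_f * ica
        ca = b + (ca - b) * dCad
        if ca < 1e-9:
            ca = 1e-9

        # --- 6. conductance regulation -------------------------------------
        if mode >= 1:
            a_eff = al if mode == 3 else 1.0
            fac = a_eff * dt / tau_g
            for i in range(7):
                gi = g[i]
                drive = P[26 + i] * dF + P[33 + i] * dS + P[40 + i] * dD
                g[i] = gi + reg_mask[i] * fac * (drive * gi - gam * gi * gi * gi)

        # --- recording ------------------------------------------------------
        if k % stride_v == 0 and iv < v_rec.shape[0]:
            v_rec[iv] = v
            iv += 1
        if stride_s > 0 and k % stride_s == 0 and isl < s_rec.shape[0]:
            s_rec[isl, 0] = v; s_rec[isl, 1] = ca
            for i in range(8):
                s_rec[isl, 2 + i] = g[i]
            s_rec[isl, 10] = F; s_rec[isl, 11] = S; s_rec[isl, 12] = D
            s_rec[isl, 13] = EF; s_rec[isl, 14] = ES; s_rec[isl, 15] = ED
            s_rec[isl, 16] = sf; s_rec[isl, 17] = al
            isl += 1
        if stride_c > 0 and k % stride_c == 0 and icr < c_rec.shape[0]:
            c_rec[icr, 0] = ge_na * (v - e_na)
            c_rec[icr, 1] = ge_cat * (v - eca)
            c_rec[icr, 2] = ge_cas * (v - eca)
            c_rec[icr, 3] = ge_a * (v - e_k)
            c_rec[icr, 4] = ge_kca * (v - e_k)
            c_rec[icr, 5] = ge_kd * (v - e_k)
            c_rec[icr, 6] = ge_h * (v - e_h)
            c_rec[icr, 7] = g[7] * (v - e_leak)
            icr += 1

        # --- divergence guard ----------------------------------------------
        if k % guard_every == 0:
            gm = g[0]
            for i in range(1, 8):
                if g[i] > gm:
                    gm = g[i]
            if (not np.isfinite(v)) or (v > guard_v) or (v < -guard_v) \
                    or gm > guard_g:
                status = 1
                k_done = k
                break

    y[0] = v; y[1] = ca
    y[2] = mna; y[3] = mcat; y[4] = mcas; y[5] = ma; y[6] = mkca; y[7] = mkd; y[8] = mh
    y[9] = hna; y[10] = hcat; y[11] = hcas; y[12] = ha
    y[13] = MF; y[14] = MS; y[15] = MD; y[16] = HF; y[17] = HS
    y[18] = EF; y[19] = ES; y[20] = ED; y[21] = al
    return status, k_done, iv, isl, icr


# ---------------------------------------------------------------------------
# high-accuracy reference integrator (fixed conductances)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deriv13(y, g, P, out):  # pragma: no cover - exercised via wrapper
    """Time derivative of the 13-dim fast subsystem (V, Ca, m[7], h[4])."""
    C = P[0]
    e_na = P[1]; e_k = P[2]; e_h = P[3]; e_leak = P[4]
    ca_out = P[5] * 1000.0
    pref = P[6]; ca_f = P[7]; ca_0 = P[8]; tau_ca = P[9]
    i_ext = P[55]

    v = y[0]; ca = y[1]
    mna = y[2]; mcat = y[3]; mcas = y[4]; ma = y[5]; mkca = y[6]; mkd = y[7]; mh = y[8]
    hna = y[9]; hcat = y[10]; hcas = y[11]; ha = y[12]

    out[2] = (1.0 / (1.0 + np.exp((v + 25.5) / -5.29)) - mna) \
        / (1.32 - 1.26 / (1.0 + np.exp((v + 120.0) / -25.0)))
    out[9] = (1.0 / (1.0 + np.exp((v + 48.9) / 5.18)) - hna) \
        / ((0.67 / (1.0 + np.exp((v + 62.9) / -10.0)))
           * (1.5 + 1.0 / (1.0 + np.exp((v + 34.9) / 3.6))))
    out[3] = (1.0 / (1.0 + np.exp((v + 27.1) / -7.2)) - mcat) \
        / (21.7 - 21.3 / (1.0 + np.exp((v + 68.1) / -20.5)))
    out[10] = (1.0 / (1.0 + np.exp((v + 32.1) / 5.5)) - hcat) \
        / (105.0 - 89.8 / (1.0 + np.exp((v + 55.0) / -16.9)))
    out[4] = (1.0 / (1.0 + np.exp((v + 33.0) / -8.1)) - mcas) \
        / (1.4 + 7.0 / (np.exp((v + 27.0) / 10.0) + np.exp((v + 70.0) / -13.0)))
    out[11] = (1.0 / (1.0 + np.exp((v + 60.0) / 6.2)) - hcas) \
        / (60.0 + 150.0 / (np.exp((v + 55.0) / 9.0) + np.exp((v + 65.0) / -16.0)))
    out[5] = (1.0 / (1.0 + np.exp((v + 27.2) / -8.7)) - ma) \
        / (11.6 - 10.4 / (1.0 + np.exp((v + 32.9) / -15.2)))
    out[12] = (1.0 / (1.0 + np.exp((v + 56.9) / 4.9)) - ha) \
        / (38.6 - 29.2 / (1.0 + np.exp((v + 38.9) / -26.5)))
    out[6] = ((ca / (ca + 3.0)) / (1.0 + np.exp((v + 28.3) / -12.6)) - mkca) \
        / (90.3 - 75.1 / (1.0 + np.exp((v + 46.0) / -22.7)))
    out[7] = (1.0 / (1.0 + np.exp((v + 12.3) / -11.8)) - mkd) \
        / (7.2 - 6.4 / (1.0 + np.exp((v + 28.3) / -19.2)))
    out[8] = (1.0 / (1.0 + np.exp((v + 70.0) / 6.0)) - mh) \
        / (272.0 + 1499.0 / (1.0 + np.exp((v + 42.2) / -8.73)))

    eca = pref * np.log(ca_out / ca)
    ge_na = g[0] * mna * mna * mna * hna
    ge_cat = g[1] * mcat * mcat * mcat * hcat
    ge_cas = g[2] * mcas * mcas * mcas * hcas
    ge_a = g[3] * ma * ma * ma * ha
    m2 = mkca * mkca
    ge_kca = g[4] * m2 * m2
    m2 = mkd * mkd
    ge_kd = g[5] * m2 * m2
    ge_h = g[6] * mh

    itot = (ge_na * (v - e_na) + (ge_cat + ge_cas) * (v - eca)
            + (ge_a + ge_kca + ge_kd) * (v - e_k) + ge_h * (v - e_h)
            + g[7] * (v - e_leak))
    out[0] = (i_ext - itot) / C
    ica = (ge_cat + ge_cas) * (v - eca)
    out[1] = (-ca_f * ica - ca + ca_0) / tau_ca


@njit(cache=True)
def rk4_fixed_conductances(n_steps, dt, y, g, P, v_rec, stride_v):
    """Classic 4th-order Runge--Kutta on the fixed-conductance subsystem.

    Independent of the exponential-Euler path: integrates the 13 coupled
    ODEs simultaneously with no operator splitting.  Used as the accuracy
    oracle for the production kernel.
    """
    k1 = np.empty(13); k2 = np.empty(13); k3 = np.empty(13); k4 = np.empty(13)
    tmp = np.empty(13)
    iv = 0
    for k in range(1, n_steps + 1):
        _deriv13(y, g, P, k1)
        for i in range(13):
            tmp[i] = y[i] + 0.5 * dt * k1[i]
        _deriv13(tmp, g, P, k2)
        for i in range(13):
            tmp[i] = y[i] + 0.5 * dt * k2[i]
        _deriv13(tmp, g, P, k3)
        for i in range(13):
            tmp[i] = y[i] + dt * k3[i]
        _deriv13(tmp, g, P, k4)
        for i in range(13):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if k % stride_v == 0 and iv < v_rec.shape[0]:
            v_rec[iv] = y[0]
            iv += 1
    return iv
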