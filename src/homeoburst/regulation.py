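"""Conductance-evolution rules and the regulation gate.

Three variants of the homeostatic rule are supported:

``original``
    tau_G dg_i/dt = (sum_k L_ki delta_k) g_i  -- the classic three-sensor
    rule; unbounded, and known to diverge when the sensors cannot all be
    satisfied.
``bounded``
    adds a cubic degradation term -gamma g_i^3, which caps each conductance
    near sqrt(drive/gamma).
``gated``
    multiplies the whole bounded rate by a gate alpha in (0, 1).  The gate
    relaxes toward a steep sigmoid of a feedback signal S_f built from
    time-averaged sensor errors; S_f ~ 1 only when all three sensors sit at
    their targets simultaneously, which drives alpha -> 0 and freezes the
    conductances (effective timescale tau_G / alpha -> infinity).
"""

from __future__ import annotations

import numpy as np

from .params import ControlScheme, GateParams

__all__ = [
    "sensor_error",
    "conductance_rate",
    "alpha_target",
    "error_rates",
    "feedback_signal",
]


def sensor_error(f, s, d, scheme: ControlScheme) -> np.ndarray:
    """Error vector delta = targets - (F, S, D)."""
    return scheme.targets - np.array([f, s, d], dtype=float)


def conductance_rate(gbar, delta, scheme: ControlScheme, alpha: float = 1.0,
                     mode: str = "gated") -> np.ndarray:
    """dgbar/dt (nS/ms) for the 7 regulated conductances.

    Parameters
    ----------
    gbar : (7,) array
        Regulated maximal conductances, nS (leak is not regulated).
    delta : (3,) array
        Sensor errors ordered (F, S, D).
    alpha : float
        Gate value; forced to 1 for modes "original" and "bounded".
    mode : {"off", "original", "bounded", "gated"}
        "original" drops the cubic term; "off" returns zeros.

    Every term carries a factor of ``gbar_i`` (linear or cubic), so
    ``gbar = 0`` is invariant and conductances can never change sign.
    """
    gbar = np.asarray(gbar, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if mode == "off":
        return np.zeros_like(gbar)
    if mode not in ("original", "bounded", "gated"):
        raise ValueError(f"unknown mode {mode!r}")
    gamma = 0.0 if mode == "original" else scheme.gamma
    a = 1.0 if mode in ("original", "bounded") else float(alpha)
    drive = scheme.L.T @ delta
    return a * (drive * gbar - gamma * gbar ** 3) / scheme.tau_g


def alpha_target(s_f, gate: GateParams):
    """Gate steady state alpha_inf(S_f) = 1 / (1 + exp((S_f - rho)/Delta_alpha)).

    Strictly decreasing in ``s_f``: a feedback signal above the threshold
    rho switches the gate (and with it the regulation) off.
    """
    s_f = np.asarray(s_f, dtype=float)
    return 1.0 / (1.0 + np.exp((s_f - gate.rho) / gate.delta_alpha))


def error_rates(delta, e, gate: GateParams, tau_g: float = 2000.0) -> np.ndarray:
    """dE/dt (1/ms): first-order relaxation of the averaged errors toward delta."""
    tau_s = gate.tau_s_effective(tau_g)
    return (np.asarray(delta, dtype=float) - np.asarray(e, dtype=float)) / tau_s


def feedback_signal(e, gate: GateParams):
    """S_f = prod_X exp(-E_X^2 / Delta): an AND gate over the three sensors.

    Equals 1 iff all averaged errors vanish; any single |E_X| of a few
    times sqrt(Delta) drives S_f to ~0 regardless of the others.
    """
    e = np.asarray(e, dtype=float)
    return np.exp(-(e ** 2).sum(axis=-1) / gate.spread)
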