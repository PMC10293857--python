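"""Calcium-current sensors reading out activity on three timescales.

Each sensor X in {F, S, D} low-pass filters a sigmoidal function of the
total calcium current I_Ca = I_CaT + I_CaS through activation M_X and (for
F and S) inactivation H_X gates, and reports

    F = G_F M_F^2 H_F,   S = G_S M_S^2 H_S,   D = G_D M_D^2.

Larger inward (more negative) calcium current increases activation and
decreases inactivation, so the fast sensor fires during spikes, the slow
sensor follows the burst envelope and the DC sensor tracks the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SensorParams

__all__ = [
    "SensorState",
    "sensor_drive",
    "sensor_gate_targets",
    "sensor_outputs",
    "steady_outputs",
]

SENSORS = ("F", "S", "D")


@dataclass
class SensorState:
    """Activation (F, S, D) and inactivation (F, S) gates, each in [0, 1]."""

    m: np.ndarray = field(default_factory=lambda: np.zeros(3))
    h: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float).copy()
        self.h = np.asarray(self.h, dtype=float).copy()
        if self.m.shape != (3,) or self.h.shape != (2,):
            raise ValueError("sensor state needs 3 activations and 2 inactivations")
        if np.any((self.m < 0) | (self.m > 1)) or np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("sensor gates must lie in [0, 1]")


def sensor_drive(i_cat, i_cas):
    """Sensor input: total calcium current (nA), numerically nA/nF at C = 1 nF.

    Inward calcium currents are negative, so strong calcium influx gives a
    large negative drive.
    """
    return i_cat + i_cas


def sensor_gate_targets(i_ca, params: SensorParams):
    """Steady-state activation and inactivation targets at drive ``i_ca``.

    Returns ``(m_bar, h_bar)`` with ``m_bar`` ordered (F, S, D) and
    ``h_bar`` ordered (F, S):

        m_bar_X = 1 / (1 + exp(Z_M_X + i_ca))
        h_bar_X = 1 / (1 + exp(-Z_H_X - i_ca))

    ``m_bar`` is decreasing and ``h_bar`` increasing in ``i_ca``.
    """
    i_ca = np.asarray(i_ca, dtype=float)
    m_bar = 1.0 / (1.0 + np.exp(np.clip(params.z_m + i_ca[..., None], -500, 500)))
    h_bar = 1.0 / (1.0 + np.exp(np.clip(-params.z_h - i_ca[..., None], -500, 500)))
    if i_ca.ndim == 0:
        return m_bar.reshape(3), h_bar.reshape(2)
    return m_bar, h_bar


def sensor_outputs(state: SensorState, params: SensorParams) -> np.ndarray:
    """Sensor activities (F, S, D) = G * M^2 * H (H absent for D)."""
    h_full = np.array([state.h[0], state.h[1], 1.0])
    return params.gain * state.m ** 2 * h_full


def steady_outputs(i_ca, params: SensorParams) -> np.ndarray:
    """Closed-form sensor outputs under a constant drive: G * m_bar^2 * h_bar."""
    m_bar, h_bar = sensor_gate_targets(float(i_ca), params)
    return sensor_outputs(SensorState(m=m_bar, h=h_bar), params)
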