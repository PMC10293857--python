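"""Fast subsystem: membrane currents and intracellular-calcium dynamics.

Implements the single-compartment Hodgkin--Huxley equations

    C dV/dt  = I_ext - sum_i I_i,          I_i = gbar_i m^p h^q (V - E_i)
    tau_Ca d[Ca]/dt = -Ca_F (I_CaT + I_CaS) - [Ca] + Ca_0

with the calcium reversal potential obtained from the Nernst equation at
each instant.  Gating kinetics live in :mod:`homeoburst.channels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS, CA_CHANNELS, P_EXP, Q_EXP, INACTIVATING, gate_targets
from .params import NeuronParams, G_TO_NA

__all__ = [
    "IntrinsicState",
    "nernst_eca",
    "ionic_currents",
    "membrane_and_calcium_derivatives",
    "steady_gates",
]


@dataclass
class IntrinsicState:
    """Membrane potential, gating variables and intracellular calcium.

    ``m`` is ordered (Na, CaT, CaS, A, KCa, Kd, H); ``h`` is ordered
    (Na, CaT, CaS, A).  Gates live in [0, 1] and ``ca_in`` (uM) is positive.
    """

    v: float = -50.0
    m: np.ndarray = field(default_factory=lambda: np.zeros(7))
    h: np.ndarray = field(default_factory=lambda: np.ones(4))
    ca_in: float = 0.05

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float).copy()
        self.h = np.asarray(self.h, dtype=float).copy()
        if self.m.shape != (7,) or self.h.shape != (4,):
            raise ValueError("m must have 7 entries and h 4")
        if np.any((self.m < 0) | (self.m > 1)) or np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("gates must lie in [0, 1]")
        if self.ca_in <= 0:
            raise ValueError("intracellular calcium must be positive")


def nernst_eca(ca_in, ca_out_mM, prefactor_mV=12.2):
    """Calcium reversal potential (mV) from the Nernst equation.

    Parameters
    ----------
    ca_in : float or ndarray
        Intracellular calcium, uM.  Must be positive.
    ca_out_mM : float
        Extracellular calcium, mM.  Must be positive.
    prefactor_mV : float
        RT/zF for a divalent ion, mV.

    Strictly decreasing in ``ca_in``; zero when the two concentrations are
    equal (1 mM = 1000 uM).
    """
    ca_in = np.asarray(ca_in, dtype=float)
    if np.any(ca_in <= 0) or ca_out_mM <= 0:
        raise ValueError("calcium concentrations must be positive")
    return prefactor_mV * np.log(ca_out_mM * 1000.0 / ca_in)


def steady_gates(v, ca_in):
    """Gating variables at their voltage (and calcium) steady states."""
    m_inf, _, h_inf, _ = gate_targets(v, ca_in)
    return m_inf, h_inf


def ionic_currents(state: IntrinsicState, params: NeuronParams) -> np.ndarray:
    """Per-channel membrane currents (nA), in CHANNELS order.

    Positive values are outward.  CaT/CaS use the instantaneous Nernst
    reversal; leak has no gates.
    """
    e_ca = float(nernst_eca(state.ca_in, params.ca_out_mM, params.nernst_mV))
    rev = params.reversals(e_ca)
    gates = np.ones(8)
    m_full = np.append(state.m, 1.0)          # leak "activation"
    h_full = np.ones(8)
    for j, name in enumerate(INACTIVATING):
        h_full[CHANNELS.index(name)] = state.h[j]
    gates = m_full ** P_EXP * h_full ** Q_EXP
    return params.gbar * gates * (state.v - rev) * G_TO_NA


def membrane_and_calcium_derivatives(state: IntrinsicState, params: NeuronParams,
                                     i_ext: float = 0.0):
    """(dV/dt, dCa/dt) in (mV/ms, uM/ms) at the given state.

    ``i_ext`` is an externally applied current in nA (positive
    depolarising).
    """
    currents = ionic_currents(state, params)
    dv = (i_ext - currents.sum()) / params.c_nF
    i_ca = currents[list(CA_CHANNELS)].sum()
    dca = (-params.ca_f * i_ca - state.ca_in + params.ca_0) / params.tau_ca
    return dv, dca
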