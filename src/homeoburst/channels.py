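"""Channel inventory and gating kinetics for the lobster STG model neuron.

The single compartment carries eight currents: fast sodium (Na), transient
and slow calcium (CaT, CaS), the transient potassium A-current (A), a
calcium-dependent potassium current (KCa), the delayed rectifier (Kd), the
hyperpolarization-activated inward current (H), and an ohmic leak.  Each
voltage-gated current has the Hodgkin--Huxley form

    I_i = gbar_i * m_i^p * h_i^q * (V - E_i)

with V in mV, gbar in uS and I in nA.  The steady-state activation /
inactivation curves and their voltage-dependent time constants are the
standard crustacean stomatogastric-ganglion kinetics of Liu, Golowasch,
Abbott & Marder (J. Neurosci. 18:2309-2320, 1998), also tabulated by Prinz,
Billimoria & Marder (J. Neurophysiol. 90:3998-4015, 2003).  KCa activation
additionally requires intracellular calcium (in uM) through the factor
Ca / (Ca + 3).

All functions are vectorised over V.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CHANNELS",
    "REGULATED",
    "GATED",
    "INACTIVATING",
    "P_EXP",
    "Q_EXP",
    "ChannelSpec",
    "channel_specs",
    "gate_targets",
]

#: Channel order used for every per-channel array in the package.
CHANNELS = ("Na", "CaT", "CaS", "A", "KCa", "Kd", "H", "leak")

#: Channels whose maximal conductance is a regulated state variable.
REGULATED = CHANNELS[:7]

#: Channels with voltage-gated activation (everything but leak).
GATED = CHANNELS[:7]

#: Channels carrying an inactivation gate (q = 1).
INACTIVATING = ("Na", "CaT", "CaS", "A")

#: Activation-gate exponents p, in CHANNELS order.
P_EXP = np.array([3, 3, 3, 3, 4, 4, 1, 0], dtype=np.int64)

#: Inactivation-gate exponents q, in CHANNELS order.
Q_EXP = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int64)

#: Index of CaT and CaS in CHANNELS order (the calcium-carrying currents).
CA_CHANNELS = (1, 2)


def _sig(v, half, slope):
    """Logistic 1 / (1 + exp((v + half) / slope)); slope sign sets direction."""
    return 1.0 / (1.0 + np.exp((v + half) / slope))


# ---------------------------------------------------------------------------
# steady-state curves
# ---------------------------------------------------------------------------

def _m_inf(v, ca):
    """Activation targets for (Na, CaT, CaS, A, KCa, Kd, H) at voltage v.

    ``ca`` (uM) enters only through KCa.
    """
    return np.stack([
        _sig(v, 25.5, -5.29),                       # Na
        _sig(v, 27.1, -7.2),                        # CaT
        _sig(v, 33.0, -8.1),                        # CaS
        _sig(v, 27.2, -8.7),                        # A
        (ca / (ca + 3.0)) * _sig(v, 28.3, -12.6),   # KCa
        _sig(v, 12.3, -11.8),                       # Kd
        _sig(v, 70.0, 6.0),                         # H
    ])


def _h_inf(v):
    """Inactivation targets for (Na, CaT, CaS, A)."""
    return np.stack([
        _sig(v, 48.9, 5.18),    # Na
        _sig(v, 32.1, 5.5),     # CaT
        _sig(v, 60.0, 6.2),     # CaS
        _sig(v, 56.9, 4.9),     # A
    ])


def _tau_m(v):
    """Activation time constants (ms) for (Na, CaT, CaS, A, KCa, Kd, H)."""
    v = np.asarray(v, dtype=float)
    return np.stack([
        1.32 - 1.26 * _sig(v, 120.0, -25.0),
        21.7 - 21.3 * _sig(v, 68.1, -20.5),
        1.4 + 7.0 / (np.exp((v + 27.0) / 10.0) + np.exp((v + 70.0) / -13.0)),
        11.6 - 10.4 * _sig(v, 32.9, -15.2),
        90.3 - 75.1 * _sig(v, 46.0, -22.7),
        7.2 - 6.4 * _sig(v, 28.3, -19.2),
        272.0 + 1499.0 * _sig(v, 42.2, -8.73),
    ])


def _tau_h(v):
    """Inactivation time constants (ms) for (Na, CaT, CaS, A)."""
    v = np.asarray(v, dtype=float)
    return np.stack([
        (0.67 / (1.0 + np.exp((v + 62.9) / -10.0)))
        * (1.5 + 1.0 / (1.0 + np.exp((v + 34.9) / 3.6))),
        105.0 - 89.8 * _sig(v, 55.0, -16.9),
        60.0 + 150.0 / (np.exp((v + 55.0) / 9.0) + np.exp((v + 65.0) / -16.0)),
        38.6 - 29.2 * _sig(v, 38.9, -26.5),
    ])


def gate_targets(v, ca_in):
    """Gating steady states and time constants at voltage ``v`` (mV).

    Parameters
    ----------
    v : float or ndarray
        Membrane potential in mV.
    ca_in : float or ndarray
        Intracellular calcium in uM (used by KCa activation only).

    Returns
    -------
    m_inf, tau_m : ndarray, leading axis 7 (Na, CaT, CaS, A, KCa, Kd, H)
    h_inf, tau_h : ndarray, leading axis 4 (Na, CaT, CaS, A)

    Steady states lie in (0, 1) (KCa's is additionally scaled by the calcium
    factor, so it vanishes as ca_in -> 0) and every time constant is
    strictly positive for finite v.
    """
    v = np.asarray(v, dtype=float)
    ca_in = np.asarray(ca_in, dtype=float)
    return _m_inf(v, ca_in), _tau_m(v), _h_inf(v), _tau_h(v)


class ChannelSpec:
    """Static description of one channel type (name, exponents, reversal mode)."""

    def __init__(self, name: str):
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        self.name = name
        i = CHANNELS.index(name)
        self.index = i
        self.p = int(P_EXP[i])
        self.q = int(Q_EXP[i])
        self.reversal_mode = "dynamic-calcium" if i in CA_CHANNELS else "fixed"

    def __repr__(self):  # pragma: no cover
        return (f"ChannelSpec({self.name}, p={self.p}, q={self.q}, "
                f"reversal={self.reversal_mode})")


def channel_specs():
    """Return the eight :class:`ChannelSpec` objects in canonical order."""
    return [ChannelSpec(name) for name in CHANNELS]
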