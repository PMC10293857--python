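"""Parameter containers and their serialisation.

Unit conventions used throughout the package: voltage mV, time ms, current
nA, capacitance nF, conductance uS, calcium concentration uM.  With these
units a current is ``gbar * gates * (V - E)`` in nA and ``dV/dt = I / C``
is in mV/ms.  All containers are plain dataclasses; :func:`pack_params`
flattens a full parameter set into the float64 vector consumed by the
compiled integration kernel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .channels import CHANNELS, REGULATED

__all__ = [
    "NeuronParams",
    "SensorParams",
    "ControlScheme",
    "GateParams",
    "SimulationConfig",
    "Model",
    "MODES",
    "pack_params",
    "save_model",
    "load_model",
    "PIDX",
    "NP",
]

#: Conversion uS * mV -> nA (identity in this unit system).
G_TO_NA = 1.0

#: Regulation modes understood by the kernel, in kernel encoding order.
MODES = ("off", "original", "bounded", "gated")

#: Default control matrix L (rows F, S, D; columns in CHANNELS[:7] order
#: Na, CaT, CaS, A, KCa, Kd, H).  Entries are the A_i/B_i/C_i control
#: coefficients of the original three-sensor regulation scheme.
DEFAULT_L = np.array([
    [1,  0,  0,  0,  0,  1, 0],   # fast-sensor error
    [0,  1,  1, -1, -1, -1, 1],   # slow-sensor error
    [0,  0,  0, -1, -1,  0, 1],   # DC-sensor error
], dtype=float)


def _arr(x, n):
    a = np.asarray(x, dtype=float).copy()
    if a.shape != (n,):
        raise ValueError(f"expected shape ({n},), got {a.shape}")
    return a


@dataclass
class NeuronParams:
    """Biophysical parameters of the single-compartment neuron.

    ``gbar`` is the maximal-conductance vector in CHANNELS order
    (Na, CaT, CaS, A, KCa, Kd, H, leak), in uS.  Under regulation the first
    seven entries are state variables and only serve as initial values.
    """

    gbar: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.03]))
    c_nF: float = 1.0
    e_na: float = 30.0
    e_k: float = -80.0
    e_h: float = -20.0
    e_leak: float = -50.0
    ca_out_mM: float = 3.0
    #: RT/2F in mV; near-room-temperature crustacean convention.
    nernst_mV: float = 12.2
    #: current-to-concentration factor, uM/nA
    ca_f: float = 0.94
    #: steady-state calcium at zero calcium current, uM
    ca_0: float = 0.05
    #: calcium buffering/extrusion time constant, ms
    tau_ca: float = 200.0

    def __post_init__(self):
        self.gbar = _arr(self.gbar, 8)
        if np.any(self.gbar < 0):
            raise ValueError("maximal conductances must be non-negative")
        if self.c_nF <= 0 or self.tau_ca <= 0:
            raise ValueError("C and tau_ca must be positive")

    def reversals(self, e_ca: float = 0.0) -> np.ndarray:
        """Per-channel reversal potentials (mV); ``e_ca`` fills CaT/CaS."""
        return np.array([self.e_na, e_ca, e_ca, self.e_k, self.e_k,
                         self.e_k, self.e_h, self.e_leak])


@dataclass
class SensorParams:
    """Constants of the fast (F), slow (S) and DC (D) calcium-current sensors.

    Arrays are ordered (F, S, D); inactivation arrays are (F, S) because the
    DC sensor has no inactivation gate.  Half-(in)activations Z are in the
    units of the sensor drive (nA with C = 1 nF), time constants in ms.
    """

    gain: np.ndarray = field(default_factory=lambda: np.array([10.0, 3.0, 1.0]))
    z_m: np.ndarray = field(default_factory=lambda: np.array([14.8, 7.2, 3.0]))
    z_h: np.ndarray = field(default_factory=lambda: np.array([9.8, 2.8]))
    tau_m: np.ndarray = field(default_factory=lambda: np.array([0.5, 50.0, 500.0]))
    tau_h: np.ndarray = field(default_factory=lambda: np.array([1.5, 60.0]))

    def __post_init__(self):
        self.gain = _arr(self.gain, 3)
        self.z_m = _arr(self.z_m, 3)
        self.z_h = _arr(self.z_h, 2)
        self.tau_m = _arr(self.tau_m, 3)
        self.tau_h = _arr(self.tau_h, 2)
        if np.any(self.tau_m <= 0) or np.any(self.tau_h <= 0):
            raise ValueError("sensor time constants must be positive")


@dataclass
class ControlScheme:
    """Sensor targets, control matrix and conductance-evolution constants."""

    #: 3 x 7 sign matrix; rows = (F, S, D) errors, columns = regulated channels.
    L: np.ndarray = field(default_factory=lambda: DEFAULT_L.copy())
    #: sensor targets (Fbar, Sbar, Dbar)
    targets: np.ndarray = field(default_factory=lambda: np.array([0.1, 0.07, 0.07]))
    #: conductance-evolution timescale, ms
    tau_g: float = 2000.0
    #: cubic-degradation coefficient (bounded/gated modes)
    gamma: float = 1e-5

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float).copy()
        if self.L.shape != (3, 7):
            raise ValueError("control matrix must be 3 x 7")
        self.targets = _arr(self.targets, 3)
        if self.tau_g <= 0:
            raise ValueError("tau_g must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class GateParams:
    """Constants of the regulation gate alpha and its feedback signal S_f."""

    #: half-activation of alpha_inf(S_f)
    rho: float = 0.075
    #: steepness of alpha_inf(S_f)
    delta_alpha: float = 0.01
    #: gate time constant, ms
    tau_alpha: float = 1000.0
    #: Gaussian spread of the per-sensor error terms in S_f
    spread: float = 0.001
    #: error-integration timescale, ms; None means "use tau_g"
    tau_s: float | None = None

    def __post_init__(self):
        for name in ("rho", "delta_alpha", "tau_alpha", "spread"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be positive")

    def tau_s_effective(self, tau_g: float) -> float:
        return float(self.tau_s) if self.tau_s is not None else float(tau_g)


@dataclass
class SimulationConfig:
    """Integration and recording settings."""

    dt: float = 0.1                      # ms
    mode: str = "gated"
    stride_v: int = 10                   # record V every stride_v steps (1 ms)
    stride_slow: int = 1000              # record slow variables every 100 ms
    stride_currents: int = 0             # 0 disables per-channel current records
    guard_gbar: float = 1e6              # uS; divergence guard
    guard_v: float = 500.0               # mV; non-physical voltage guard
    guard_every: int = 100               # steps between guard checks
    halt_on_divergence: bool = True
    sensor_avg_window: float = 2000.0    # ms, display averaging only

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.stride_v < 1 or self.stride_slow < 1:
            raise ValueError("strides must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class Model:
    """Bundle of all model parameters (the regulated neuron)."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    sensors: SensorParams = field(default_factory=SensorParams)
    scheme: ControlScheme = field(default_factory=ControlScheme)
    gate: GateParams = field(default_factory=GateParams)

    def copy(self) -> "Model":
        return load_model_dict(model_dict(self))


# ---------------------------------------------------------------------------
# flat parameter vector for the compiled kernel
# ---------------------------------------------------------------------------

class PIDX:
    """Index constants of the flat kernel parameter vector."""
    C = 0
    E_NA = 1
    E_K = 2
    E_H = 3
    E_LEAK = 4
    CA_OUT = 5
    NERNST = 6
    CA_F = 7
    CA_0 = 8
    TAU_CA = 9
    ZM = 10          # 10..12 (F,S,D)
    ZH = 13          # 13..14 (F,S)
    TAU_M = 15       # 15..17
    TAU_H = 18       # 18..19
    GAIN = 20        # 20..22
    TARGETS = 23     # 23..25
    L = 26           # 26..46 row-major 3x7
    TAU_G = 47
    GAMMA = 48
    TAU_S = 49
    RHO = 50
    DELTA_ALPHA = 51
    TAU_ALPHA = 52
    SPREAD = 53
    MODE = 54
    I_EXT = 55
    GUARD_G = 56
    GUARD_V = 57


NP = 58  # length of the kernel parameter vector


def pack_params(model: Model, mode: str = "gated", i_ext: float = 0.0,
                config: SimulationConfig | None = None) -> np.ndarray:
    """Flatten a :class:`Model` into the kernel parameter vector."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    cfg = config or SimulationConfig(mode=mode)
    n, s, c, g = model.neuron, model.sensors, model.scheme, model.gate
    P = np.zeros(NP)
    P[PIDX.C] = n.c_nF
    P[PIDX.E_NA] = n.e_na
    P[PIDX.E_K] = n.e_k
    P[PIDX.E_H] = n.e_h
    P[PIDX.E_LEAK] = n.e_leak
    P[PIDX.CA_OUT] = n.ca_out_mM
    P[PIDX.NERNST] = n.nernst_mV
    P[PIDX.CA_F] = n.ca_f
    P[PIDX.CA_0] = n.ca_0
    P[PIDX.TAU_CA] = n.tau_ca
    P[PIDX.ZM:PIDX.ZM + 3] = s.z_m
    P[PIDX.ZH:PIDX.ZH + 2] = s.z_h
    P[PIDX.TAU_M:PIDX.TAU_M + 3] = s.tau_m
    P[PIDX.TAU_H:PIDX.TAU_H + 2] = s.tau_h
    P[PIDX.GAIN:PIDX.GAIN + 3] = s.gain
    P[PIDX.TARGETS:PIDX.TARGETS + 3] = c.targets
    P[PIDX.L:PIDX.L + 21] = c.L.ravel()
    P[PIDX.TAU_G] = c.tau_g
    P[PIDX.GAMMA] = c.gamma
    P[PIDX.TAU_S] = g.tau_s_effective(c.tau_g)
    P[PIDX.RHO] = g.rho
    P[PIDX.DELTA_ALPHA] = g.delta_alpha
    P[PIDX.TAU_ALPHA] = g.tau_alpha
    P[PIDX.SPREAD] = g.spread
    P[PIDX.MODE] = float(MODES.index(mode))
    P[PIDX.I_EXT] = i_ext
    P[PIDX.GUARD_G] = cfg.guard_gbar
    P[PIDX.GUARD_V] = cfg.guard_v
    return P


# ---------------------------------------------------------------------------
# structured-text (YAML) round trip
# ---------------------------------------------------------------------------

def _asdict_np(obj):
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def model_dict(model: Model) -> dict:
    """Model as a nested plain-python dict (for YAML/JSON)."""
    return {
        "neuron": _asdict_np(model.neuron) | {
            "gbar_nS": dict(zip(CHANNELS, model.neuron.gbar.tolist()))},
        "sensors": _asdict_np(model.sensors),
        "scheme": _asdict_np(model.scheme) | {
            "channels": list(REGULATED)},
        "gate": _asdict_np(model.gate),
    }


def load_model_dict(d: dict) -> Model:
    nd = dict(d.get("neuron", {}))
    gd = nd.pop("gbar_nS", None)
    if gd is not None:
        nd["gbar"] = [gd[name] for name in CHANNELS]
    sd = dict(d.get("sensors", {}))
    cd = dict(d.get("scheme", {}))
    cd.pop("channels", None)
    return Model(
        neuron=NeuronParams(**nd),
        sensors=SensorParams(**sd),
        scheme=ControlScheme(**cd),
        gate=GateParams(**d.get("gate", {})),
    )


def save_model(model: Model, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_dict(model), fh, sort_keys=False)


def load_model(path) -> Model:
    with open(path) as fh:
        return load_model_dict(yaml.safe_load(fh))
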