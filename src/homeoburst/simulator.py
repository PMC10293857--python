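"""Coupled simulation driver: full-system runs, protocols and self-assembly.

A run integrates the complete regulated neuron (biophysics + sensors +
regulation) with the compiled exponential-Euler kernel, applying any
perturbation protocol at its event times, and returns a downsampled
:class:`Trajectory`.  :func:`self_assemble` wraps a run started from small
random initial conductances and stops once the regulation gate has been
off (alpha below threshold) for a sustained hold window, the signature of
successful convergence onto the target bursting pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophysics import IntrinsicState, ionic_currents, nernst_eca
from .channels import CHANNELS, gate_targets
from .integrator import advance_kernel, SLOW_COLS, STATE_SIZE, YIDX
from .params import (Model, SimulationConfig, pack_params, MODES)
from .regulation import alpha_target
from .sensors import sensor_gate_targets

__all__ = [
    "FullState",
    "Trajectory",
    "initial_state",
    "draw_initial_conductances",
    "run",
    "self_assemble",
    "SelfAssemblyResult",
    "INIT_REF_GBAR",
]

#: Per-channel reference magnitudes (uS) for random initial conductances, in
#: regulated-channel order (Na, CaT, CaS, A, KCa, Kd, H).  These are the
#: rounded median conductances of converged self-assembled bursters; initial
#: draws are log-uniform over [1e-3, 1e-1] of them, i.e. "small" relative to
#: converged values without biasing channel ratios.
INIT_REF_GBAR = np.array([60.0, 1.5, 2.0, 4.0, 6.0, 60.0, 0.5])


@dataclass
class FullState:
    """Complete dynamical state: intrinsic + sensor + regulator variables."""

    y: np.ndarray = field(default_factory=lambda: np.zeros(STATE_SIZE))
    gbar: np.ndarray = field(default_factory=lambda: np.zeros(8))
    #: 1.0 for channels under regulation; 0.0 pins a (deleted) channel.
    reg_mask: np.ndarray = field(default_factory=lambda: np.ones(7))

    def copy(self) -> "FullState":
        return FullState(self.y.copy(), self.gbar.copy(), self.reg_mask.copy())

    @property
    def v(self) -> float:
        return float(self.y[YIDX.V])

    @property
    def ca_in(self) -> float:
        return float(self.y[YIDX.CA])

    @property
    def alpha(self) -> float:
        return float(self.y[YIDX.ALPHA])

    def intrinsic(self) -> IntrinsicState:
        return IntrinsicState(v=self.v, m=self.y[YIDX.M:YIDX.M + 7],
                              h=self.y[YIDX.H:YIDX.H + 4], ca_in=self.ca_in)


def initial_state(model: Model, gbar, v0: float = -50.0) -> FullState:
    """Standard initial condition: gates at steady state for ``v0``.

    Channel gates sit at their voltage steady states, calcium at its
    baseline Ca_0, sensor gates at steady state for the instantaneous
    calcium current, averaged errors at zero and the gate at
    alpha_inf(S_f = 0), i.e. regulation on.
    """
    gbar = np.asarray(gbar, dtype=float)
    if gbar.shape == (7,):
        gbar = np.append(gbar, model.neuron.gbar[7])
    if gbar.shape != (8,):
        raise ValueError("gbar must have 7 (regulated) or 8 entries")
    y = np.zeros(STATE_SIZE)
    y[YIDX.V] = v0
    y[YIDX.CA] = model.neuron.ca_0
    m_inf, _, h_inf, _ = gate_targets(v0, model.neuron.ca_0)
    y[YIDX.M:YIDX.M + 7] = m_inf
    y[YIDX.H:YIDX.H + 4] = h_inf
    neuron = replace(model.neuron, gbar=gbar)
    cur = ionic_currents(IntrinsicState(v=v0, m=m_inf, h=h_inf,
                                        ca_in=model.neuron.ca_0), neuron)
    i_ca = cur[1] + cur[2]
    m_bar, h_bar = sensor_gate_targets(float(i_ca), model.sensors)
    y[YIDX.SM:YIDX.SM + 3] = m_bar
    y[YIDX.SH:YIDX.SH + 2] = h_bar
    y[YIDX.E:YIDX.E + 3] = 0.0
    y[YIDX.ALPHA] = float(alpha_target(0.0, model.gate))
    return FullState(y=y, gbar=gbar.copy())


def draw_initial_conductances(seed, scale: float = 1.0, low: float = 1e-3,
                              high: float = 1e-1, ref=None) -> np.ndarray:
    """Seeded draw of small random initial conductances (7 regulated, uS).

    Each channel's conductance is log-uniform over
    ``[low, high] * scale * ref_channel`` so that draws span two decades of
    "small" without biasing channel ratios.  ``seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    if scale <= 0 or low <= 0 or high < low:
        raise ValueError("need scale > 0 and 0 < low <= high")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ref = INIT_REF_GBAR if ref is None else np.asarray(ref, dtype=float)
    u = rng.uniform(np.log(low), np.log(high), size=7)
    return scale * ref * np.exp(u)


@dataclass
class Trajectory:
    """Downsampled record of one run.

    ``v`` is the fine-grid membrane potential (every ``stride_v`` steps);
    ``slow`` holds the slow variables (columns :data:`SLOW_COLS`) every
    ``stride_slow`` steps; ``currents`` optionally holds per-channel
    currents (nA, CHANNELS order).  ``events`` is the applied-event log and
    ``diverged``/``t_diverged`` flag runaway conductance growth.
    """

    dt: float
    stride_v: int
    stride_slow: int
    v: np.ndarray
    slow: np.ndarray
    currents: np.ndarray | None = None
    stride_currents: int = 0
    t0: float = 0.0
    mode: str = "gated"
    events: list = field(default_factory=list)
    diverged: bool = False
    t_diverged: float | None = None
    final_state: FullState | None = None
    meta: dict = field(default_factory=dict)

    # -- time grids ---------------------------------------------------------
    @property
    def dt_v(self) -> float:
        return self.dt * self.stride_v

    @property
    def t_v(self) -> np.ndarray:
        return self.t0 + self.dt_v * np.arange(1, len(self.v) + 1)

    @property
    def t_slow(self) -> np.ndarray:
        return self.t0 + self.dt * self.stride_slow * np.arange(1, len(self.slow) + 1)

    @property
    def duration(self) -> float:
        return float(self.t_v[-1] - self.t0) if len(self.v) else 0.0

    # -- column accessors ---------------------------------------------------
    def _col(self, name: str) -> np.ndarray:
        return self.slow[:, SLOW_COLS.index(name)]

    @property
    def gbar(self) -> np.ndarray:
        """(n, 8) conductance series in CHANNELS order."""
        return self.slow[:, 2:10]

    @property
    def alpha(self) -> np.ndarray:
        return self._col("alpha")

    @property
    def s_f(self) -> np.ndarray:
        return self._col("S_f")

    @property
    def sensor_outputs(self) -> np.ndarray:
        """(n, 3) raw sensor activities (F, S, D)."""
        return self.slow[:, 10:13]

    @property
    def errors(self) -> np.ndarray:
        return self.slow[:, 13:16]

    @property
    def ca(self) -> np.ndarray:
        return self._col("Ca")

    # -- export -------------------------------------------------------------
    def slow_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.slow, columns=list(SLOW_COLS))
        df.insert(0, "t_ms", self.t_slow)
        return df

    def v_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t_v, "V_mV": self.v})

    def currents_frame(self) -> pd.DataFrame | None:
        if self.currents is None:
            return None
        t = self.t0 + self.dt * self.stride_currents * \
            np.arange(1, len(self.currents) + 1)
        df = pd.DataFrame(self.currents, columns=[f"I_{c}" for c in CHANNELS])
        df.insert(0, "t_ms", t)
        return df

    def save(self, basepath) -> None:
        """Write <base>_v.csv, <base>_slow.csv (+currents) and a JSON sidecar."""
        base = str(basepath)
        self.v_frame().to_csv(base + "_v.csv", index=False)
        self.slow_frame().to_csv(base + "_slow.csv", index=False)
        cf = self.currents_frame()
        if cf is not None:
            cf.to_csv(base + "_currents.csv", index=False)
        side = {
            "dt_ms": self.dt, "stride_v": self.stride_v,
            "stride_slow": self.stride_slow, "t0_ms": self.t0,
            "mode": self.mode, "events": self.events,
            "diverged": self.diverged, "t_diverged_ms": self.t_diverged,
            "meta": self.meta,
        }
        with open(base + "_meta.json", "w") as fh:
            json.dump(side, fh, indent=2, default=float)

    def save_npz(self, path) -> None:
        """Compact binary dump of all recorded series (numpy .npz)."""
        arrays = {"v": self.v, "slow": self.slow,
                  "dt": np.array([self.dt]),
                  "strides": np.array([self.stride_v, self.stride_slow,
                                       self.stride_currents])}
        if self.currents is not None:
            arrays["currents"] = self.currents
        np.savez_compressed(path, **arrays)

    @staticmethod
    def concat(pieces: list["Trajectory"]) -> "Trajectory":
        """Join consecutive trajectory pieces sharing dt and strides."""
        if not pieces:
            raise ValueError("nothing to concatenate")
        first = pieces[0]
        for p in pieces[1:]:
            if (p.dt, p.stride_v, p.stride_slow) != \
                    (first.dt, first.stride_v, first.stride_slow):
                raise ValueError("pieces must share dt and strides")
        cur = None
        if all(p.currents is not None for p in pieces):
            cur = np.concatenate([p.currents for p in pieces])
        out = Trajectory(
            dt=first.dt, stride_v=first.stride_v, stride_slow=first.stride_slow,
            v=np.concatenate([p.v for p in pieces]),
            slow=np.concatenate([p.slow for p in pieces]),
            currents=cur, stride_currents=first.stride_currents,
            t0=first.t0, mode=first.mode,
            events=[e for p in pieces for e in p.events],
            diverged=any(p.diverged for p in pieces),
            t_diverged=next((p.t_diverged for p in pieces
                             if p.t_diverged is not None), None),
            final_state=pieces[-1].final_state, meta=dict(first.meta))
        return out


def _segment_run(model: Model, state: FullState, t0: float, n_steps: int,
                 mode: str, i_ext: float, cfg: SimulationConfig):
    """Integrate one protocol-free segment; returns a Trajectory piece."""
    P = pack_params(model, mode=mode, i_ext=i_ext, config=cfg)
    nv = n_steps // cfg.stride_v
    ns = n_steps // cfg.stride_slow
    v_rec = np.empty(nv)
    s_rec = np.empty((ns, len(SLOW_COLS)))
    if cfg.stride_currents > 0:
        c_rec = np.empty((n_steps // cfg.stride_currents, 8))
        stride_c = cfg.stride_currents
    else:
        c_rec = np.empty((1, 8))
        stride_c = 0
    status, k_done, iv, isl, icr = advance_kernel(
        n_steps, cfg.dt, state.y, state.gbar, state.reg_mask, P,
        v_rec, cfg.stride_v, s_rec, cfg.stride_slow, c_rec, stride_c,
        cfg.guard_every)
    piece = Trajectory(
        dt=cfg.dt, stride_v=cfg.stride_v, stride_slow=cfg.stride_slow,
        v=v_rec[:iv], slow=s_rec[:isl],
        currents=c_rec[:icr] if stride_c > 0 else None,
        stride_currents=stride_c, t0=t0, mode=mode)
    if status == 1:
        piece.diverged = True
        piece.t_diverged = t0 + k_done * cfg.dt
    return piece, status


def run(model: Model, duration_ms: float, *, mode: str = "gated",
        config: SimulationConfig | None = None, protocol=None,
        state: FullState | None = None, gbar0=None, i_ext: float = 0.0,
        record_currents: bool = False) -> Trajectory:
    """Integrate the full system for ``duration_ms``, applying a protocol.

    Parameters
    ----------
    model : Model
        Parameter bundle.  Never mutated; perturbations act on a copy.
    duration_ms : float
        Total simulated time.  A zero-duration run returns an empty but
        valid trajectory.
    mode : {"off", "original", "bounded", "gated"}
        Regulation mode.
    protocol : Protocol or sequence of PerturbationEvent, optional
        Events are applied at their times (rounded to dt).
    state : FullState, optional
        Resume from this state; otherwise built from ``gbar0`` (7 or 8
        conductances) via :func:`initial_state`.
    i_ext : float
        Baseline applied current (nA); protocol current injections add to it.

    Returns
    -------
    Trajectory
        With ``final_state`` attached; ``diverged`` set if the overflow
        guard tripped (the run then ends at ``t_diverged``).
    """
    from .perturbations import Protocol, apply_event  # local import, no cycle

    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    cfg = config or SimulationConfig(mode=mode)
    if record_currents and cfg.stride_currents == 0:
        cfg = replace(cfg, stride_currents=cfg.stride_v)
    if state is None:
        if gbar0 is None:
            raise ValueError("provide either state or gbar0")
        state = initial_state(model, gbar0)
    else:
        state = state.copy()

    events = list(protocol.events) if isinstance(protocol, Protocol) \
        else list(protocol or [])
    events.sort(key=lambda e: e.time_ms)
    for e in events:
        if e.time_ms < 0 or e.time_ms > duration_ms:
            raise ValueError(f"event at {e.time_ms} ms outside run span")

    model = model.copy()
    ctx = {"i_ext": i_ext, "applied": {}}
    pieces = []
    log = []
    t = 0.0
    n_total = int(round(duration_ms / cfg.dt))
    step_now = 0
    # event boundaries in steps
    bounds = [(int(round(e.time_ms / cfg.dt)), e) for e in events]
    idx = 0
    diverged = False
    while step_now < n_total and not diverged:
        while idx < len(bounds) and bounds[idx][0] <= step_now:
            ev = bounds[idx][1]
            apply_event(model, state, ctx, ev)
            log.append({"t_ms": step_now * cfg.dt, "kind": ev.kind,
                        "target": ev.target, "value": ev.value,
                        "label": ev.label})
            idx += 1
        step_next = bounds[idx][0] if idx < len(bounds) else n_total
        step_next = max(step_next, step_now + 1)
        piece, status = _segment_run(model, state, t, step_next - step_now,
                                     mode, ctx["i_ext"], cfg)
        pieces.append(piece)
        if status == 1:
            diverged = True
            if not cfg.halt_on_divergence:
                raise RuntimeError(
                    f"divergence guard tripped at t = {piece.t_diverged} ms")
        step_done = step_next if status == 0 else \
            step_now + int(round((piece.t_diverged - t) / cfg.dt))
        t = step_done * cfg.dt
        step_now = step_done

    if pieces:
        traj = Trajectory.concat(pieces)
    else:  # zero-duration run
        traj = Trajectory(dt=cfg.dt, stride_v=cfg.stride_v,
                          stride_slow=cfg.stride_slow, v=np.empty(0),
                          slow=np.empty((0, len(SLOW_COLS))), mode=mode)
    traj.events = log
    traj.mode = mode
    traj.final_state = state
    traj.meta = {"duration_ms": duration_ms, "i_ext": i_ext}
    return traj


@dataclass
class SelfAssemblyResult:
    """Outcome of a self-assembly run."""

    converged: bool
    gate_off_ms: float | None
    trajectory: Trajectory
    final_gbar: np.ndarray
    state: FullState
    seed: object = None

    @property
    def model_gbar(self) -> np.ndarray:
        """Converged conductance vector (8,), usable as a burster fixture."""
        return self.final_gbar.copy()


def self_assemble(model: Model, seed, *, mode: str = "gated",
                  config: SimulationConfig | None = None,
                  max_duration_ms: float = 1.8e6,
                  chunk_ms: float = 60_000.0,
                  gate_threshold: float = 0.01,
                  hold_ms: float = 60_000.0,
                  settle_ms: float = 60_000.0,
                  init_scale: float = 1.0,
                  v0: float = -50.0) -> SelfAssemblyResult:
    """Run from small random initial conductances until the gate switches off.

    Integrates in chunks and stops as soon as alpha has stayed below
    ``gate_threshold`` for ``hold_ms`` plus an extra ``settle_ms`` margin,
    or at ``max_duration_ms`` (returned as unconverged if the gate never
    switched off -- for the original, ungated rule the run always spans the
    full duration).  Identical seeds give identical trajectories.
    """
    from .analysis import gate_off_time

    cfg = config or SimulationConfig(mode=mode)
    gbar0 = draw_initial_conductances(seed, scale=init_scale)
    state = initial_state(model, gbar0, v0=v0)
    pieces = []
    t = 0.0
    gate_off = None
    while t < max_duration_ms:
        n = int(round(min(chunk_ms, max_duration_ms - t) / cfg.dt))
        piece, status = _segment_run(model, state, t, n, mode, 0.0, cfg)
        pieces.append(piece)
        t = piece.t_v[-1] if len(piece.v) else t
        if status == 1:
            break
        if mode in ("gated",):
            alpha = np.concatenate([p.slow[:, SLOW_COLS.index("alpha")]
                                    for p in pieces])
            dts = cfg.dt * cfg.stride_slow
            gate_off = gate_off_time(alpha, dts, threshold=gate_threshold,
                                     hold_ms=hold_ms)
            if gate_off is not None and t >= gate_off + hold_ms + settle_ms:
                break
    traj = Trajectory.concat(pieces)
    traj.final_state = state
    traj.meta = {"seed": str(seed), "init_gbar": gbar0.tolist()}
    converged = gate_off is not None and not traj.diverged
    return SelfAssemblyResult(converged=converged, gate_off_ms=gate_off,
                              trajectory=traj, final_gbar=state.gbar.copy(),
                              state=state, seed=seed)
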