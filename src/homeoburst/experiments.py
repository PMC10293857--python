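"""Reproducible multi-run experiments built on the simulator.

Every experiment here is seed-deterministic end to end: the master seed
spawns per-run seeds through :class:`numpy.random.SeedSequence`, so the
same seed reproduces the same ensemble, scans and perturbation responses
bit for bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (alpha_episodes, classify_activity, ensemble_summary,
                       gate_off_time, recovery_outcome)
from .channels import CHANNELS
from .params import Model, SimulationConfig
from .perturbations import PerturbationEvent, Protocol
from .simulator import SelfAssemblyResult, run, self_assemble

__all__ = [
    "EnsembleResult", "run_ensemble", "make_bursters",
    "perturbation_run", "deletion_battery", "reversal_scan", "leak_scan",
    "compare_depolarizations", "repeated_injections",
]

#: default post-perturbation observation window (20 simulated minutes)
OBSERVATION_MS = 1_200_000.0


def _child_seeds(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


@dataclass
class EnsembleResult:
    """Per-run outcomes of a self-assembly ensemble plus summary statistics."""

    outcomes: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.outcomes)


def run_ensemble(model: Model, n_runs: int, seed, *,
                 max_duration_ms: float = 1_800_000.0,
                 config: SimulationConfig | None = None,
                 keep_results: bool = False) -> EnsembleResult:
    """Self-assemble ``n_runs`` gated models from random initial conductances.

    Each run gets an independent child seed; runs stop early once the gate
    has been off for the sustained hold window (or at ``max_duration_ms``,
    default 30 simulated minutes).  Outcomes record convergence, gate-off
    time, final activity label and the number of supra-threshold gate
    episodes (1 = canonical single-transient self-assembly).
    """
    outcomes = []
    results = []
    for i, ss in enumerate(_child_seeds(seed, n_runs)):
        rng = np.random.default_rng(ss)
        res = self_assemble(model, rng, config=config,
                            max_duration_ms=max_duration_ms)
        traj = res.trajectory
        dts = traj.dt * traj.stride_slow
        n_seg = int(round(60_000.0 / traj.dt_v))
        cls = classify_activity(traj.v[-n_seg:], traj.dt_v)
        eps = alpha_episodes(traj.alpha, dts)
        outcomes.append({
            "run": i,
            "converged": bool(res.converged),
            "gate_off_ms": res.gate_off_ms,
            "label": cls.label,
            "n_episodes": len(eps),
            "duration_ms": traj.t_slow[-1] if len(traj.slow) else 0.0,
            "diverged": traj.diverged,
            **{f"g_{c}": res.final_gbar[j] for j, c in enumerate(CHANNELS)},
        })
        if keep_results:
            results.append(res)
    out = EnsembleResult(outcomes=outcomes, summary=ensemble_summary(outcomes))
    if keep_results:
        out.results = results
    return out


def make_bursters(model: Model, n: int, seed, *,
                  max_duration_ms: float = 1_800_000.0,
                  config: SimulationConfig | None = None,
                  max_tries: int | None = None) -> list[SelfAssemblyResult]:
    """Self-assemble until ``n`` converged bursters are collected.

    Seeds are drawn deterministically from ``seed``; non-converged draws
    are skipped.  Raises if ``max_tries`` (default 6n) draws do not yield
    ``n`` bursters.
    """
    max_tries = max_tries or 6 * n
    out = []
    for ss in _child_seeds(seed, max_tries):
        res = self_assemble(model, np.random.default_rng(ss), config=config,
                            max_duration_ms=max_duration_ms)
        if res.converged:
            out.append(res)
            if len(out) == n:
                return out
    raise RuntimeError(f"only {len(out)}/{n} self-assembly runs converged")


def perturbation_run(model: Model, burster: SelfAssemblyResult,
                     protocol: Protocol, *,
                     observation_ms: float = OBSERVATION_MS,
                     mode: str = "gated",
                     config: SimulationConfig | None = None,
                     early_stop: bool = True,
                     record_currents: bool = False):
    """Apply a protocol to a converged burster and observe for 20 minutes.

    Returns ``(trajectory, outcome)`` where outcome is the
    :func:`recovery_outcome` of the final stretch.  With ``early_stop``
    the run is cut short once the gate has been off for a sustained hold
    (recovery can then already be judged); protocols with late events are
    never cut before their last event.
    """
    cfg = config or SimulationConfig(mode=mode)
    last_event = max((e.time_ms for e in protocol.events), default=0.0)
    total = last_event + observation_ms
    state = burster.state.copy()
    if not early_stop:
        traj = run(model, total, mode=mode, config=cfg, protocol=protocol,
                   state=state, record_currents=record_currents)
        return traj, recovery_outcome(traj)

    # chunked run with gate-off early stopping after the last event
    from .integrator import SLOW_COLS
    from .simulator import Trajectory
    pieces = []
    t = 0.0
    # the first chunk spans every protocol event so that paired events
    # (e.g. a labelled perturbation and its restore) share one context
    chunk = max(120_000.0, last_event + cfg.dt)
    remaining_protocol = list(protocol.events)
    state_now = state
    while t < total:
        t_next = min(total, t + chunk)
        evs = [PerturbationEvent(e.time_ms - t, e.kind, e.target, e.value, e.label)
               for e in remaining_protocol if t <= e.time_ms < t_next]
        # events already shifted; protocol events at exact chunk borders
        remaining_protocol = [e for e in remaining_protocol if e.time_ms >= t_next]
        piece = run(model, t_next - t, mode=mode, config=cfg,
                    protocol=evs, state=state_now,
                    record_currents=record_currents)
        piece.t0 = t
        state_now = piece.final_state
        pieces.append(piece)
        if piece.diverged:
            break
        t = t_next
        if t > last_event + 180_000.0 and not remaining_protocol:
            alpha = np.concatenate([p.slow[:, SLOW_COLS.index("alpha")]
                                    for p in pieces])
            dts = cfg.dt * cfg.stride_slow
            off = gate_off_time(alpha, dts)
            if off is not None and t >= off + 180_000.0:
                break
    traj = Trajectory.concat(pieces)
    traj.final_state = state_now
    # carry restored model context is internal to each chunk; events spanning
    # chunks are applied at their own times above.
    return traj, recovery_outcome(traj)


def deletion_battery(model: Model, bursters, *,
                     observation_ms: float = OBSERVATION_MS) -> pd.DataFrame:
    """Delete each regulated current on each burster; report recovery.

    Returns one row per (burster, channel) with the recovery outcome of a
    20-minute observation window.
    """
    rows = []
    for bi, b in enumerate(bursters):
        for ch in CHANNELS[:7]:
            proto = Protocol([PerturbationEvent(0.0, "delete_conductance",
                                                target=ch)],
                             label=f"delete_{ch}")
            traj, out = perturbation_run(model, b, proto,
                                         observation_ms=observation_ms)
            rows.append({"burster": bi, "channel": ch,
                         "recovered": out.recovered, "label": out.label,
                         "reason": out.reason})
    return pd.DataFrame(rows)


def reversal_scan(model: Model, bursters, levels_mV, *,
                  target: str = "E_K",
                  observation_ms: float = OBSERVATION_MS) -> pd.DataFrame:
    """Step a reversal potential to each level on each burster; report recovery."""
    rows = []
    for bi, b in enumerate(bursters):
        for lvl in levels_mV:
            proto = Protocol([PerturbationEvent(0.0, "set_reversal",
                                                target=target, value=float(lvl))])
            traj, out = perturbation_run(model, b, proto,
                                         observation_ms=observation_ms)
            rows.append({"burster": bi, "level_mV": float(lvl),
                         "recovered": out.recovered, "label": out.label})
    return pd.DataFrame(rows)


def leak_scan(model: Model, bursters, levels, *,
              observation_ms: float = OBSERVATION_MS) -> pd.DataFrame:
    """Step the (unregulated) leak conductance to each level; report recovery."""
    rows = []
    for bi, b in enumerate(bursters):
        for lvl in levels:
            proto = Protocol([PerturbationEvent(0.0, "set_leak",
                                                value=float(lvl))])
            traj, out = perturbation_run(model, b, proto,
                                         observation_ms=observation_ms)
            rows.append({"burster": bi, "g_leak": float(lvl),
                         "recovered": out.recovered, "label": out.label})
    return pd.DataFrame(rows)


def recovery_boundary(scan: pd.DataFrame, column: str) -> float | None:
    """Largest perturbation level recovered by the majority of bursters."""
    maj = scan.groupby(column)["recovered"].mean() >= 0.5
    ok = maj[maj].index
    return float(ok.max()) if len(ok) else None


def compare_depolarizations(model: Model, burster, *, ek_mV: float = -60.0,
                            iapp_nA: float = 0.4,
                            observation_ms: float = OBSERVATION_MS) -> dict:
    """Same burster, two depolarising perturbations; compare the strategies.

    Runs a potassium-reversal step (``E_K -> ek_mV``) and a current
    injection (``iapp_nA``) from the identical initial state and returns
    the per-channel conductance changes after adaptation, the initial
    activity labels during the perturbation, and the recovery outcomes.
    """
    out = {}
    g0 = burster.final_gbar[:7]
    for name, proto in [
            ("ek", Protocol([PerturbationEvent(0.0, "set_reversal",
                                               target="E_K", value=ek_mV)])),
            ("iapp", Protocol([PerturbationEvent(0.0, "inject_current",
                                                 value=iapp_nA)]))]:
        traj, rec = perturbation_run(model, burster, proto,
                                     observation_ms=observation_ms)
        # instantaneous response: first 30 s after perturbation onset
        n0 = int(round(30_000.0 / traj.dt_v))
        instant = classify_activity(traj.v[:n0], traj.dt_v,
                                    min_duration_ms=20_000.0)
        gf = traj.final_state.gbar[:7]
        out[name] = {
            "recovered": rec.recovered,
            "instant_label": instant.label,
            "delta_g": gf - g0,
            "final_g": gf,
        }
    return out


def repeated_injections(model: Model, burster, *, amp_nA: float = 0.4,
                        on_ms: float = 600_000.0, off_ms: float = 600_000.0,
                        n_applications: int = 3,
                        config: SimulationConfig | None = None) -> dict:
    """Apply the same depolarising current repeatedly with washouts between.

    After each perturb--release cycle the conductance vector is compared
    with the pre-perturbation control; the instantaneous activity label at
    each application onset probes the (possibly cryptic) accrued changes.
    """
    cfg = config or SimulationConfig()
    g_control = burster.final_gbar[:7].copy()
    state = burster.state.copy()
    labels, dists, g_after = [], [], []
    for rep in range(n_applications):
        on = Protocol([PerturbationEvent(0.0, "inject_current", value=amp_nA,
                                         label=f"app{rep}"),
                       PerturbationEvent(on_ms, "restore", target=f"app{rep}")])
        traj = run(model, on_ms + off_ms, mode="gated", config=cfg,
                   protocol=on, state=state)
        state = traj.final_state
        n0 = int(round(30_000.0 / traj.dt_v))
        labels.append(classify_activity(traj.v[:n0], traj.dt_v,
                                        min_duration_ms=20_000.0).label)
        g_now = state.gbar[:7].copy()
        g_after.append(g_now)
        dists.append(float(np.linalg.norm(g_now - g_control)))
    return {"instant_labels": labels,
            "distance_from_control": dists,
            "g_after_release": np.array(g_after),
            "g_control": g_control}
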