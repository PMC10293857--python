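"""End-to-end experiment presets.

Each preset reproduces one of the package's canonical experiments from a
single seed with no external input: self-assembly under the original and
gated rules, divergence under an unrecoverable potassium-reversal step,
recovery from a calcium-channel deletion, the dissociation between two
depolarising perturbations, repeated-perturbation accrual, the
self-assembly ensemble, and the recovery-boundary scans.  A preset
returns a result bundle with the trajectory/report and a boolean check of
its expected qualitative outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (classify_activity, currentscape_shares, gate_off_time,
                       recovery_outcome)
from .channels import CHANNELS
from .experiments import (compare_depolarizations, deletion_battery,
                          leak_scan, make_bursters, perturbation_run,
                          recovery_boundary, repeated_injections,
                          reversal_scan, run_ensemble)
from .params import Model, SimulationConfig
from .perturbations import PerturbationEvent, Protocol
from .simulator import draw_initial_conductances, run, self_assemble

__all__ = ["PRESETS", "run_preset", "PresetResult"]


@dataclass
class PresetResult:
    """Outcome bundle of one preset run."""

    name: str
    passed: bool
    report: dict = field(default_factory=dict)
    trajectory: object = None
    extra: dict = field(default_factory=dict)


def _cfg(overrides: dict | None, mode: str = "gated") -> SimulationConfig:
    kw = dict(overrides or {})
    kw.setdefault("mode", mode)
    return SimulationConfig(**kw)


def _model(tau_g: float | None) -> Model:
    m = Model()
    if tau_g is not None:
        m.scheme.tau_g = float(tau_g)
        return m
    return m


def _final_label(traj, window_ms: float = 60_000.0):
    n = int(round(window_ms / traj.dt_v))
    return classify_activity(traj.v[-n:], traj.dt_v)


def fig1_selfassembly_original(seed, tau_g=None, **kw):
    """Original rule from small random inits: self-assembles to bursting."""
    m = _model(tau_g)
    g0 = draw_initial_conductances(np.random.default_rng(seed))
    traj = run(m, 3_600_000.0, mode="original", gbar0=g0)
    cls = _final_label(traj)
    return PresetResult("fig1_selfassembly_original",
                        passed=cls.label == "periodic_bursting"
                        and not traj.diverged,
                        report={"label": cls.label, "diverged": traj.diverged},
                        trajectory=traj)


def fig2_divergence(seed, tau_g=None, **kw):
    """Original rule, long run: conductances eventually diverge."""
    m = _model(tau_g)
    g0 = draw_initial_conductances(np.random.default_rng(seed))
    traj = run(m, 7_200_000.0, mode="original", gbar0=g0)
    return PresetResult("fig2_divergence", passed=traj.diverged,
                        report={"diverged": traj.diverged,
                                "t_diverged_ms": traj.t_diverged},
                        trajectory=traj)


def fig3_ek_block(seed, tau_g=None, **kw):
    """Original rule + E_K = -35 mV: depolarisation block, then divergence."""
    m = _model(tau_g)
    b = make_bursters(m, 1, seed)[0]
    proto = Protocol([PerturbationEvent(0.0, "set_reversal", target="E_K",
                                        value=-35.0)])
    state = b.state.copy()
    traj = run(m, 1_200_000.0, mode="original", protocol=proto, state=state)
    return PresetResult("fig3_ek_block", passed=traj.diverged,
                        report={"diverged": traj.diverged,
                                "t_diverged_ms": traj.t_diverged},
                        trajectory=traj)


def fig4_selfassembly_gated(seed, tau_g=None, **kw):
    """Gated rule: self-assembly, gate-off, conductances flat thereafter."""
    m = _model(tau_g)
    res = self_assemble(m, np.random.default_rng(seed))
    traj = res.trajectory
    cls = _final_label(traj)
    flat = True
    if res.converged and res.gate_off_ms is not None:
        dts = traj.dt * traj.stride_slow
        i0 = int(res.gate_off_ms / dts)
        g = traj.gbar[i0:, :7]
        ref = np.maximum(g[-1], 1e-12)
        flat = bool(np.all(np.abs(g - ref) / ref < 0.01))
    return PresetResult("fig4_selfassembly_gated",
                        passed=res.converged
                        and cls.label == "periodic_bursting" and flat,
                        report={"converged": res.converged,
                                "gate_off_min": (res.gate_off_ms or 0) / 60_000,
                                "label": cls.label,
                                "conductances_flat": flat},
                        trajectory=traj)


def fig5_cas_deletion(seed, tau_g=None, **kw):
    """CaS deletion on a burster: recovery with CaT taking over inward share."""
    m = _model(tau_g)
    b = make_bursters(m, 1, seed)[0]
    control = run(m, 30_000.0, mode="gated", state=b.state,
                  record_currents=True)
    proto = Protocol([PerturbationEvent(0.0, "delete_conductance",
                                        target="CaS")])
    traj, out = perturbation_run(m, b, proto, record_currents=True)
    n = int(round(30_000.0 / (traj.dt * traj.stride_currents)))
    pin_c, _ = currentscape_shares(control.currents)
    pin_a, _ = currentscape_shares(traj.currents[-n:])
    cat = CHANNELS.index("CaT")
    share_control = float(pin_c[:, cat].mean())
    share_adapted = float(pin_a[:, cat].mean())
    return PresetResult("fig5_cas_deletion",
                        passed=out.recovered and share_adapted > share_control,
                        report={"recovered": out.recovered,
                                "label": out.label,
                                "cat_inward_share_control_pct": share_control,
                                "cat_inward_share_adapted_pct": share_adapted},
                        trajectory=traj)


def fig6_ek_vs_iapp(seed, tau_g=None, strong: bool = False, **kw):
    """E_K step vs current injection: similar depolarisation, different fix."""
    m = _model(tau_g)
    b = make_bursters(m, 1, seed)[0]
    ek, iapp = (-55.0, 0.9) if strong else (-60.0, 0.4)
    cmp = compare_depolarizations(m, b, ek_mV=ek, iapp_nA=iapp)
    dg_ek = cmp["ek"]["delta_g"]
    dg_ia = cmp["iapp"]["delta_g"]
    na, kd, kca = (CHANNELS.index(c) for c in ("Na", "Kd", "KCa"))
    dissociated = (dg_ek[na] + dg_ek[kd] > dg_ia[na] + dg_ia[kd]) \
        and (dg_ia[kca] > dg_ek[kca])
    return PresetResult("fig6_ek_vs_iapp",
                        passed=bool(dissociated and cmp["ek"]["recovered"]
                                    and cmp["iapp"]["recovered"]),
                        report={k: {"recovered": v["recovered"],
                                    "instant_label": v["instant_label"],
                                    "delta_g": v["delta_g"].tolist()}
                                for k, v in cmp.items()},
                        extra={"levels": {"ek_mV": ek, "iapp_nA": iapp}})


def fig7_triple_application(seed, tau_g=None, **kw):
    """Three identical current injections: history-dependent responses."""
    m = _model(tau_g)
    b = make_bursters(m, 1, seed)[0]
    rep = repeated_injections(m, b)
    d = rep["distance_from_control"]
    growing = all(x > 0 for x in d) and d[-1] >= d[0]
    distinct = len(set(rep["instant_labels"])) > 1
    return PresetResult("fig7_triple_application",
                        passed=bool(growing and distinct),
                        report={"instant_labels": rep["instant_labels"],
                                "distance_from_control": d})


def ensemble_s1(seed, tau_g=None, n_runs: int = 20, **kw):
    """Self-assembly ensemble: fraction converged, gate-off statistics."""
    m = _model(tau_g)
    ens = run_ensemble(m, n_runs, seed)
    s = ens.summary
    return PresetResult("ensemble_s1",
                        passed=s["fraction_converged"] >= 0.9,
                        report=s, extra={"frame": ens.frame()})


def ek_scan(seed, tau_g=None, levels=tuple(range(-62, -49)),
            n_bursters: int = 3, **kw):
    """E_K recovery boundary scan."""
    m = _model(tau_g)
    bs = make_bursters(m, n_bursters, seed)
    scan = reversal_scan(m, bs, [float(v) for v in levels])
    bnd = recovery_boundary(scan, "level_mV")
    return PresetResult("ek_scan", passed=bnd is not None,
                        report={"boundary_mV": bnd},
                        extra={"frame": scan})


def gleak_scan(seed, tau_g=None,
               levels=(0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3),
               n_bursters: int = 3, **kw):
    """Leak-conductance recovery boundary scan."""
    m = _model(tau_g)
    bs = make_bursters(m, n_bursters, seed)
    scan = leak_scan(m, bs, levels)
    bnd = recovery_boundary(scan, "g_leak")
    return PresetResult("gleak_scan", passed=bnd is not None,
                        report={"boundary": bnd},
                        extra={"frame": scan})


def deletion_battery_preset(seed, tau_g=None, n_bursters: int = 3, **kw):
    """Single-channel deletion battery over several bursters."""
    m = _model(tau_g)
    bs = make_bursters(m, n_bursters, seed)
    df = deletion_battery(m, bs)
    maj = df.groupby("channel")["recovered"].mean() >= 0.5
    recoverable = sorted(maj[maj].index)
    expected = sorted(["A", "H", "CaS", "CaT"])
    return PresetResult("deletion_battery",
                        passed=recoverable == expected,
                        report={"recoverable": recoverable,
                                "table": df.groupby("channel")["recovered"]
                                .mean().to_dict()},
                        extra={"frame": df})


PRESETS = {
    "fig1_selfassembly_original": fig1_selfassembly_original,
    "fig2_divergence": fig2_divergence,
    "fig3_ek_block": fig3_ek_block,
    "fig4_selfassembly_gated": fig4_selfassembly_gated,
    "fig5_cas_deletion": fig5_cas_deletion,
    "fig6_ek_vs_iapp": fig6_ek_vs_iapp,
    "fig7_triple_application": fig7_triple_application,
    "ensemble_s1": ensemble_s1,
    "ek_scan": ek_scan,
    "gleak_scan": gleak_scan,
    "deletion_battery": deletion_battery_preset,
}


def run_preset(name: str, seed, **overrides) -> PresetResult:
    """Execute a named preset from a seed; unknown names raise KeyError."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; know {sorted(PRESETS)}")
    return PRESETS[name](seed, **overrides)
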