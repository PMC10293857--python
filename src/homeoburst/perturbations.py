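"""Declarative perturbation events and the standard experiment protocols.

Perturbations change a parameter that would otherwise be fixed: deleting a
current (its conductance is set to zero and pinned there -- the
multiplicative regulation rate could never regrow it, and pinning guards
against numerical drift), stepping the potassium reversal potential,
changing the unregulated leak conductance, or injecting external current.
``restore`` reverts a previously applied, labelled event (regulated
conductances then resume evolving from wherever regulation left them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS
from .params import Model

__all__ = ["PerturbationEvent", "Protocol", "apply_event",
           "standard_protocols", "protocol_from_file", "KINDS"]

KINDS = ("delete_conductance", "set_reversal", "set_leak", "inject_current",
         "restore")

_REVERSALS = {"E_K": "e_k", "E_Na": "e_na", "E_H": "e_h", "E_leak": "e_leak"}


@dataclass
class PerturbationEvent:
    """One scheduled parameter change.

    ``target`` names a channel (delete_conductance), a reversal potential
    ("E_K", ...; set_reversal), or a prior event's label (restore).
    ``value`` is in the target's units (mV, nS or nA).
    """

    time_ms: float
    kind: str
    target: str | None = None
    value: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.time_ms < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class Protocol:
    """Time-ordered list of events with a label."""

    events: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time_ms)
        labels = {e.label for e in self.events if e.label}
        for e in self.events:
            if e.kind == "restore" and e.target not in labels:
                raise ValueError(f"restore references unknown event {e.target!r}")


def apply_event(model: Model, state, ctx: dict, event: PerturbationEvent) -> None:
    """Apply ``event`` in place to the model copy, state and run context.

    ``ctx`` carries the running applied-current value (``ctx['i_ext']``)
    and the pre-event values needed by ``restore``
    (``ctx['applied'][label]``).
    """
    applied = ctx.setdefault("applied", {})
    kind = event.kind
    if kind == "delete_conductance":
        if event.target not in CHANNELS:
            raise ValueError(f"unknown channel {event.target!r}")
        i = CHANNELS.index(event.target)
        if event.label:
            applied[event.label] = ("delete", i, float(state.gbar[i]))
        state.gbar[i] = 0.0
        if i < 7:
            state.reg_mask[i] = 0.0
    elif kind == "set_reversal":
        if event.target not in _REVERSALS:
            raise ValueError(f"unknown reversal {event.target!r}")
        attr = _REVERSALS[event.target]
        if event.label:
            applied[event.label] = ("reversal", attr, getattr(model.neuron, attr))
        setattr(model.neuron, attr, float(event.value))
    elif kind == "set_leak":
        if event.label:
            applied[event.label] = ("leak", None, float(state.gbar[7]))
        state.gbar[7] = float(event.value)
    elif kind == "inject_current":
        if event.label:
            applied[event.label] = ("current", None, float(event.value))
        ctx["i_ext"] = ctx.get("i_ext", 0.0) + float(event.value)
    elif kind == "restore":
        if event.target not in applied:
            raise ValueError(f"restore without matching event {event.target!r}")
        what, key, prev = applied.pop(event.target)
        if what == "delete":
            state.gbar[key] = prev
            if key < 7:
                state.reg_mask[key] = 1.0
        elif what == "reversal":
            setattr(model.neuron, key, prev)
        elif what == "leak":
            state.gbar[7] = prev
        elif what == "current":
            ctx["i_ext"] = ctx.get("i_ext", 0.0) - prev


def protocol_from_file(path) -> Protocol:
    """Load a protocol from a YAML file: a list of event mappings.

    Each entry needs ``time_ms`` and ``kind`` plus the kind's ``target`` /
    ``value`` / ``label`` fields, e.g.::

        label: ek_step_and_release
        events:
          - {time_ms: 0, kind: set_reversal, target: E_K, value: -60, label: step}
          - {time_ms: 600000, kind: restore, target: step}
    """
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    events = [PerturbationEvent(**e) for e in doc.get("events", [])]
    return Protocol(events, label=doc.get("label", str(path)))


#: default post-perturbation observation window (20 simulated minutes)
OBSERVATION_MS = 20 * 60_000.0


def standard_protocols(*, ek_levels=(-60.0, -55.0, -35.0),
                       leak_levels=(0.01, 0.1),
                       current_steps=(0.4, 0.9),
                       washout_amp: float = 0.4,
                       washout_on_ms: float = 600_000.0,
                       washout_off_ms: float = 600_000.0) -> dict:
    """Named library of the standard perturbation protocols.

    Returns a dict mapping names to :class:`Protocol`:

    - ``delete_<ch>`` for each of the 7 regulated channels (perturbation at
      t = 0, to be observed for 20 min);
    - ``ek_<level>`` potassium-reversal steps;
    - ``leak_<value>`` leak-conductance steps;
    - ``iapp_<amp>`` depolarising current steps;
    - ``triple_iapp`` three identical current applications, each followed
      by a washout release of equal default length.
    """
    protos: dict[str, Protocol] = {}
    for ch in CHANNELS[:7]:
        protos[f"delete_{ch}"] = Protocol(
            [PerturbationEvent(0.0, "delete_conductance", target=ch)],
            label=f"delete_{ch}")
    for lvl in ek_levels:
        protos[f"ek_{lvl:g}"] = Protocol(
            [PerturbationEvent(0.0, "set_reversal", target="E_K", value=lvl)],
            label=f"ek_{lvl:g}")
    for lvl in leak_levels:
        protos[f"leak_{lvl:g}"] = Protocol(
            [PerturbationEvent(0.0, "set_leak", value=lvl)],
            label=f"leak_{lvl:g}")
    for amp in current_steps:
        protos[f"iapp_{amp:g}"] = Protocol(
            [PerturbationEvent(0.0, "inject_current", value=amp)],
            label=f"iapp_{amp:g}")
    ev = []
    t = 0.0
    for rep in range(3):
        on = PerturbationEvent(t, "inject_current", value=washout_amp,
                               label=f"iapp_rep{rep}")
        off = PerturbationEvent(t + washout_on_ms, "restore",
                                target=f"iapp_rep{rep}")
        ev += [on, off]
        t += washout_on_ms + washout_off_ms
    protos["triple_iapp"] = Protocol(ev, label="triple_iapp")
    return protos
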