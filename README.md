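# homeoburst

Gated homeostatic regulation of intrinsic excitability in a
conductance-based model neuron.

## The problem

Ion channels in a neuron's membrane turn over on timescales of hours to
weeks, yet long-lived neurons keep their characteristic firing patterns
for years.  Activity-dependent homeostatic models explain this by making
the maximal conductances ḡᵢ state variables: intracellular-calcium
sensors read out the neuron's activity, and deviations from target
activity drive coordinated changes in channel densities.  The classic
three-sensor scheme self-assembles a bursting neuron from small random
conductances and recovers from many perturbations — but it can also blow
up, because nothing bounds conductance growth and nothing stops
regulation once the target is reached.

`homeoburst` implements a gated variant of that scheme for a lobster
stomatogastric-ganglion (STG) model neuron with eight currents
(Na, CaT, CaS, A, KCa, Kd, H, leak):

    τ_G dḡᵢ/dt = { (Σₖ L_kᵢ δₖ) ḡᵢ − γ ḡᵢ³ } · α
    τ_α dα/dt  = α∞(S_f) − α,      S_f = Π_X exp(−E_X²/Δ)

where δ = (F̄−F, S̄−S, D̄−D) are the errors of fast/slow/DC calcium-current
sensors, L is a fixed sign matrix, the cubic term bounds growth, and the
gate α switches regulation off (α → 0) when the time-averaged errors E_X
of all three sensors are simultaneously small — an AND gate over sensors.
The model self-assembles into periodic bursting, freezes its conductances
once on target, recovers from channel deletions and reversal-potential or
current perturbations, and accrues cryptic, history-dependent conductance
changes that are invisible at baseline but shape responses to later
perturbations.

It is a tool for computational neuroscientists studying homeostatic
control, degeneracy of conductance space, and perturbation memory.

## Worked example

```python
import numpy as np
from homeoburst import Model
from homeoburst.simulator import self_assemble
from homeoburst.analysis import classify_activity

model = Model()                       # all defaults: tau_G = 2 s, gated
res = self_assemble(model, np.random.default_rng(11))
traj = res.trajectory
n = int(60_000 / traj.dt_v)           # final minute of membrane potential
cls = classify_activity(traj.v[-n:], traj.dt_v)
print(res.converged, round(res.gate_off_ms / 60_000, 2), cls.label,
      round(cls.stats.period_ms), np.round(res.final_gbar, 2))
```

prints

```
True 3.22 periodic_bursting 485 [63.97  1.09  2.32  2.89  7.47 58.04  0.    0.03]
```

i.e. this seed self-assembles from small random conductances into
periodic bursting (cycle period ≈ 0.49 s), the regulation gate switches
off after ≈ 3 minutes of simulated time, and the conductance vector
(µS; Na, CaT, CaS, A, KCa, Kd, H, leak) is frozen thereafter.  Different
seeds converge to similar bursting with different conductances — the
degeneracy that underlies cryptic storage of perturbation history.

The same machinery drives perturbation experiments:

```python
from homeoburst.experiments import make_bursters, perturbation_run
from homeoburst.perturbations import standard_protocols

b = make_bursters(model, 1, seed=7)[0]
traj, outcome = perturbation_run(model, b, standard_protocols()["delete_CaS"])
print(outcome.recovered, outcome.label)
```

A CLI mirrors these workflows (`homeoburst assemble / run / perturb /
ensemble / scan / preset / classify`); outputs are CSV series with JSON
sidecars.

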