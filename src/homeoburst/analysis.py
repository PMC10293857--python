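"""Trace classification and experiment metrics.

Operational definitions (all thresholds overridable):

- spikes: upward crossings of -20 mV with a 2 ms refractory lockout;
- bursts: spike groups separated by inter-spike gaps longer than
  max(50 ms, 3x the median intra-burst interval);
- periodic bursting: >= 5 complete burst cycles with >= 2 spikes per burst
  on average and cycle-period CV < 5%;
- single-spike bursting: regular one-spike cycles slower than 300 ms;
- tonic: regular spiking with unimodal inter-spike intervals;
- gate off: alpha below 0.01 sustained for 60 s;
- recovery: periodic bursting in the final stretch of the observation
  window with the gate off at its end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BurstStats", "Classification", "detect_spikes", "classify_activity",
    "gate_off_time", "alpha_episodes", "check_divergence",
    "recovery_outcome", "currentscape_shares", "ensemble_summary",
    "window_average", "ACTIVITY_LABELS",
]

ACTIVITY_LABELS = ("quiescent", "tonic", "periodic_bursting",
                   "single_spike_bursting", "irregular", "indeterminate")


@dataclass
class BurstStats:
    """Cycle metrics of a bursting (or spiking) trace."""

    period_ms: float = np.nan
    spikes_per_burst: float = np.nan
    burst_duration_ms: float = np.nan
    duty_cycle: float = np.nan
    period_cv: float = np.nan
    n_cycles: int = 0


@dataclass
class Classification:
    label: str = "indeterminate"
    stats: BurstStats = field(default_factory=BurstStats)
    spike_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_spikes(v, dt_ms, threshold: float = -20.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings with a lockout.

    Deterministic: a spike is the first sample at or above ``threshold``
    following a sample below it, and further crossings within
    ``refractory_ms`` are ignored.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        return np.empty(0)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    if up.size == 0:
        return np.empty(0)
    times = up * dt_ms
    keep = [times[0]]
    for tt in times[1:]:
        if tt - keep[-1] >= refractory_ms:
            keep.append(tt)
    return np.asarray(keep)


def _burst_groups(spikes: np.ndarray, gap_factor: float = 3.0,
                  gap_floor_ms: float = 50.0) -> list[np.ndarray]:
    """Group spikes into bursts by large inter-spike gaps."""
    if spikes.size == 0:
        return []
    isi = np.diff(spikes)
    if isi.size == 0:
        return [spikes]
    # median of the shorter intervals estimates the intra-burst ISI
    short = np.median(isi[isi <= np.median(isi)])
    thr = max(gap_floor_ms, gap_factor * short)
    cut = np.flatnonzero(isi > thr)
    return np.split(spikes, cut + 1)


def classify_activity(v, dt_ms, *, threshold: float = -20.0,
                      refractory_ms: float = 2.0,
                      min_duration_ms: float = 4000.0,
                      tonic_cv: float = 0.15,
                      period_cv_tol: float = 0.05,
                      min_cycles: int = 5,
                      slow_cycle_ms: float = 300.0,
                      gap_factor: float = 3.0,
                      gap_floor_ms: float = 50.0) -> Classification:
    """Label a voltage trace and report its burst statistics.

    Returns label ``indeterminate`` for traces shorter than
    ``min_duration_ms``; ``quiescent`` when no spikes occur; ``tonic``
    for regular ungrouped spiking faster than ``slow_cycle_ms``;
    ``single_spike_bursting`` for regular one-spike slow cycles;
    ``periodic_bursting`` for regular multi-spike cycles; ``irregular``
    otherwise.
    """
    v = np.asarray(v, dtype=float)
    duration = v.size * dt_ms
    if duration < min_duration_ms:
        return Classification("indeterminate")
    spikes = detect_spikes(v, dt_ms, threshold, refractory_ms)
    if spikes.size == 0:
        return Classification("quiescent")
    if spikes.size < max(3, min_cycles):
        # a handful of spikes over the whole window: not a sustained pattern
        return Classification("irregular", spike_times_ms=spikes)

    isi = np.diff(spikes)
    cv_isi = isi.std() / isi.mean()
    bursts = _burst_groups(spikes, gap_factor, gap_floor_ms)
    sizes = np.array([b.size for b in bursts])

    if cv_isi < tonic_cv and len(bursts) <= 1:
        # regular undivided train: rate decides tonic vs slow one-spike cycles
        label = "single_spike_bursting" if isi.mean() > slow_cycle_ms else "tonic"
        st = BurstStats(period_ms=float(isi.mean()), spikes_per_burst=1.0,
                        burst_duration_ms=0.0, duty_cycle=np.nan,
                        period_cv=float(cv_isi), n_cycles=int(isi.size))
        return Classification(label, st, spikes)

    if len(bursts) >= min_cycles + 1:
        starts = np.array([b[0] for b in bursts])
        periods = np.diff(starts)
        # use the trailing cycles; transients at the front are common
        tail = periods[-max(min_cycles, periods.size // 2):]
        cv = tail.std() / tail.mean()
        mean_size = sizes[1:-1].mean() if len(bursts) > 2 else sizes.mean()
        durs = np.array([b[-1] - b[0] for b in bursts[1:-1] or bursts])
        st = BurstStats(period_ms=float(tail.mean()),
                        spikes_per_burst=float(mean_size),
                        burst_duration_ms=float(durs.mean()),
                        duty_cycle=float(durs.mean() / tail.mean()),
                        period_cv=float(cv), n_cycles=int(periods.size))
        if cv < period_cv_tol and mean_size >= 2.0:
            return Classification("periodic_bursting", st, spikes)
        if cv < period_cv_tol and mean_size < 2.0 \
                and st.period_ms > slow_cycle_ms:
            return Classification("single_spike_bursting", st, spikes)
        return Classification("irregular", st, spikes)

    return Classification("irregular", spike_times_ms=spikes)


def gate_off_time(alpha, dt_ms, threshold: float = 0.01,
                  hold_ms: float = 60_000.0) -> float | None:
    """Earliest time after which alpha stays below ``threshold`` for ``hold_ms``.

    Returns None if no such sustained sub-threshold stretch exists.  A
    transient dip shorter than the hold window does not count.
    """
    alpha = np.asarray(alpha, dtype=float)
    below = alpha < threshold
    n_hold = max(1, int(round(hold_ms / dt_ms)))
    if below.size < n_hold:
        return None
    csum = np.cumsum(np.concatenate(([0], below.astype(int))))
    runs = csum[n_hold:] - csum[:-n_hold]        # count of below in each window
    hits = np.flatnonzero(runs == n_hold)
    if hits.size == 0:
        return None
    return float((hits[0] + 1) * dt_ms)          # records start at t = dt


def alpha_episodes(alpha, dt_ms, threshold: float = 0.01,
                   min_duration_ms: float = 1000.0,
                   merge_gap_ms: float = 2000.0) -> list[tuple[float, float]]:
    """Supra-threshold episodes of the gate variable as (start, end) times.

    Contiguous stretches with alpha >= threshold are merged when separated
    by gaps shorter than ``merge_gap_ms`` and kept when at least
    ``min_duration_ms`` long.  A canonical self-assembly run has exactly
    one episode (the initial transient); blips or gate oscillations after
    convergence add more.
    """
    a = np.asarray(alpha, dtype=float) >= threshold
    if a.size == 0:
        return []
    edges = np.diff(a.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if a[0]:
        starts.insert(0, 0)
    if a[-1]:
        ends.append(a.size)
    eps = [[s, e] for s, e in zip(starts, ends)]
    merged = []
    for s, e in eps:
        if merged and (s - merged[-1][1]) * dt_ms < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = [((s + 1) * dt_ms, e * dt_ms) for s, e in merged
           if (e - s) * dt_ms >= min_duration_ms]
    return out


def check_divergence(gbar_series, bound: float = 1e6):
    """(flag, onset_ms_index) -- first time any conductance exceeds ``bound``.

    ``gbar_series`` is (n,) or (n, k); non-finite values also count.
    Returns (False, None) when everything stays below the bound.
    """
    g = np.atleast_2d(np.asarray(gbar_series, dtype=float))
    if g.shape[0] == 1 and np.ndim(gbar_series) == 1:
        g = g.T
    bad = (~np.isfinite(g)) | (g > bound)
    rows = np.flatnonzero(bad.any(axis=1))
    if rows.size == 0:
        return False, None
    return True, int(rows[0])


@dataclass
class RecoveryOutcome:
    recovered: bool
    reason: str
    label: str
    adapted_gbar: np.ndarray | None = None
    classification: Classification | None = None


def recovery_outcome(traj, *, segment_ms: float = 60_000.0,
                     gate_threshold: float = 0.01) -> RecoveryOutcome:
    """Did the model recover its target bursting after the perturbation?

    Recovered iff the final ``segment_ms`` of the trajectory classifies as
    periodic bursting AND the regulation gate is off (alpha sustained below
    ``gate_threshold`` over that same stretch).  A divergence flag always
    means not recovered.
    """
    if traj.diverged:
        return RecoveryOutcome(False, "divergence", "divergent")
    n_seg = int(round(segment_ms / traj.dt_v))
    if n_seg < 2 or len(traj.v) < n_seg:
        return RecoveryOutcome(False, "trace too short", "indeterminate")
    cls = classify_activity(traj.v[-n_seg:], traj.dt_v)
    dts = traj.dt * traj.stride_slow
    n_slow = int(round(segment_ms / dts))
    gate_off = bool(np.all(traj.alpha[-n_slow:] < gate_threshold))
    ok = cls.label == "periodic_bursting" and gate_off
    reason = "recovered" if ok else \
        (f"activity {cls.label}" if cls.label != "periodic_bursting"
         else "gate still on")
    return RecoveryOutcome(ok, reason, cls.label,
                           adapted_gbar=traj.gbar[-1].copy(),
                           classification=cls)


def currentscape_shares(currents):
    """Percent contribution of each channel to inward and outward current.

    ``currents`` is (n, k) in nA (negative = inward).  Returns masked
    arrays ``(inward_pct, outward_pct)`` of the same shape; at samples
    where a side's total magnitude vanishes its shares are masked rather
    than NaN.  Unmasked rows each sum to 100.
    """
    c = np.asarray(currents, dtype=float)
    inward = np.where(c < 0, -c, 0.0)
    outward = np.where(c > 0, c, 0.0)
    tot_in = inward.sum(axis=-1, keepdims=True)
    tot_out = outward.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pin = np.ma.masked_invalid(100.0 * inward / np.where(tot_in > 0, tot_in, np.nan))
        pout = np.ma.masked_invalid(100.0 * outward / np.where(tot_out > 0, tot_out, np.nan))
    return pin, pout


def window_average(x, dt_ms, window_ms: float = 2000.0) -> np.ndarray:
    """Causal moving average used for sensor-activity display (2 s window)."""
    x = np.asarray(x, dtype=float)
    n = max(1, int(round(window_ms / dt_ms)))
    kern = np.ones(n) / n
    pad = np.concatenate([np.full(n - 1, x[0] if x.size else 0.0), x])
    return np.convolve(pad, kern, mode="valid")


def ensemble_summary(outcomes, confidence: float = 0.95) -> dict:
    """Summary of self-assembly ensemble outcomes.

    ``outcomes`` is a sequence of dicts with keys ``converged`` (bool),
    ``gate_off_ms`` (float or None) and optionally ``n_episodes`` (int).
    Returns fractions with Wilson binomial confidence intervals and the
    median gate-off time over converged runs.  "Single episode" counts the
    canonical time course: converged with exactly one supra-threshold gate
    episode (a run whose gate never shuts also has one episode, but it is
    not canonical).
    """
    n = len(outcomes)
    if n == 0:
        raise ValueError("need at least one outcome")
    conv = sum(bool(o["converged"]) for o in outcomes)
    canon = sum(1 for o in outcomes
                if o["converged"] and o.get("n_episodes") == 1)
    offs = [o["gate_off_ms"] for o in outcomes
            if o["converged"] and o["gate_off_ms"] is not None]

    def ci(k):
        res = stats.binomtest(k, n)
        lo, hi = res.proportion_ci(confidence_level=confidence, method="wilson")
        return float(lo), float(hi)

    return {
        "n": n,
        "fraction_converged": conv / n,
        "fraction_converged_ci": ci(conv),
        "fraction_single_episode": canon / n,
        "fraction_single_episode_ci": ci(canon),
        "median_gate_off_ms": float(np.median(offs)) if offs else None,
    }
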