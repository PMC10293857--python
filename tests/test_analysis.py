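"""Trace classification and metrics on synthetic, generator-known traces."""

import numpy as np
import pytest

from homeoburst.analysis import (alpha_episodes, check_divergence,
                                 classify_activity, currentscape_shares,
                                 detect_spikes, ensemble_summary,
                                 gate_off_time, window_average)


def synth_trace(duration_ms, dt, spike_times, base=-55.0, amp=60.0,
                width_ms=2.0):
    """Rectangular 'spikes' on a flat baseline at generator-known times."""
    n = int(duration_ms / dt)
    v = np.full(n, base)
    w = max(1, int(width_ms / dt))
    for t in spike_times:
        i = int(t / dt)
        v[i:i + w] = base + amp
    return v


class TestDetectSpikes:
    def test_constant_trace(self):
        assert detect_spikes(np.full(1000, -50.0), 1.0).size == 0

    def test_single_spike(self):
        v = synth_trace(1000, 1.0, [500])
        t = detect_spikes(v, 1.0)
        assert t.size == 1
        assert t[0] == pytest.approx(500, abs=2)

    def test_known_train(self):
        times = [100, 300, 500, 700, 900]
        v = synth_trace(1000, 1.0, times)
        t = detect_spikes(v, 1.0)
        assert t.size == 5
        assert t == pytest.approx(times, abs=2)

    def test_refractory_lockout(self):
        # two crossings 2 ms apart count once with a 3 ms lockout
        v = np.full(100, -50.0)
        v[10] = 0.0
        v[12] = 0.0
        assert detect_spikes(v, 1.0, refractory_ms=3.0).size == 1
        assert detect_spikes(v, 1.0, refractory_ms=2.0).size == 2


class TestClassify:
    def test_flat_is_quiescent(self):
        v = np.full(10_000, -50.0)
        assert classify_activity(v, 1.0).label == "quiescent"

    def test_too_short_is_indeterminate(self):
        assert classify_activity(np.full(100, -50.0), 1.0).label \
            == "indeterminate"

    def test_tonic(self):
        times = np.arange(100, 20_000, 100)      # regular 10 Hz
        v = synth_trace(20_000, 1.0, times)
        cls = classify_activity(v, 1.0)
        assert cls.label == "tonic"
        assert cls.stats.period_ms == pytest.approx(100, rel=0.02)

    def test_single_spike_bursting(self):
        times = np.arange(200, 20_000, 800)      # slow regular one-spike cycle
        v = synth_trace(20_000, 1.0, times)
        assert classify_activity(v, 1.0).label == "single_spike_bursting"

    def test_periodic_bursting_stats(self):
        """3-spike bursts, 1 s period: label and statistics match."""
        period, intra, nsp = 1000.0, 30.0, 3
        times = []
        for b in range(20):
            start = 100 + b * period
            times += [start + k * intra for k in range(nsp)]
        v = synth_trace(21_000, 1.0, times)
        cls = classify_activity(v, 1.0)
        assert cls.label == "periodic_bursting"
        assert cls.stats.period_ms == pytest.approx(period, rel=0.02)
        assert cls.stats.spikes_per_burst == pytest.approx(3, abs=0.2)
        assert cls.stats.burst_duration_ms == pytest.approx(60, rel=0.1)
        assert cls.stats.duty_cycle == pytest.approx(0.06, rel=0.15)
        assert cls.stats.period_cv < 0.05

    def test_jittered_bursts_are_irregular(self):
        rng = np.random.default_rng(0)
        times = []
        t = 100.0
        for _ in range(25):
            times += [t, t + 30, t + 60]
            t += rng.uniform(400, 1600)
        v = synth_trace(int(t + 500), 1.0, times)
        assert classify_activity(v, 1.0).label == "irregular"


class TestGateOff:
    def test_never_off(self):
        assert gate_off_time(np.ones(1000), 100.0) is None

    def test_step_off(self):
        a = np.concatenate([np.ones(100), np.zeros(2000)])
        t = gate_off_time(a, 100.0, hold_ms=60_000.0)
        assert t == pytest.approx(101 * 100.0, abs=200)

    def test_short_blip_excluded(self):
        # dips below threshold for 30 s, comes back, then stays off
        dt = 1000.0
        a = np.concatenate([np.ones(50), np.zeros(30), np.ones(20),
                            np.zeros(200)])
        t = gate_off_time(a, dt, hold_ms=60_000.0)
        assert t == pytest.approx((100 + 1) * dt, abs=2 * dt)

    def test_episode_counting(self):
        dt = 1000.0
        a = np.concatenate([np.ones(120), np.zeros(300), np.ones(5),
                            np.zeros(300)])
        eps = alpha_episodes(a, dt, min_duration_ms=1000.0)
        assert len(eps) == 2
        a2 = np.concatenate([np.ones(120), np.zeros(500)])
        assert len(alpha_episodes(a2, dt)) == 1


class TestDivergence:
    def test_constant_false(self):
        flag, onset = check_divergence(np.full((100, 7), 10.0), bound=1e6)
        assert not flag and onset is None

    def test_exponential_crossing(self):
        g = 10.0 * np.exp(0.1 * np.arange(200))
        flag, onset = check_divergence(g, bound=1e6)
        assert flag
        assert onset == int(np.ceil(np.log(1e5) / 0.1))

    def test_saturating_below_bound(self):
        g = 1e5 * (1 - np.exp(-0.05 * np.arange(200)))
        flag, _ = check_divergence(g, bound=1e6)
        assert not flag

    def test_nonfinite_counts(self):
        g = np.full(10, 1.0)
        g[7] = np.nan
        flag, onset = check_divergence(g, bound=1e6)
        assert flag and onset == 7


class TestCurrentscape:
    def test_single_outward(self):
        c = np.zeros((5, 3))
        c[:, 1] = 2.0
        pin, pout = currentscape_shares(c)
        assert np.all(pout[:, 1] == 100.0)
        assert np.all(pin.mask)

    def test_two_inward_shares(self):
        c = np.array([[-1.0, -3.0, 0.5]])
        pin, pout = currentscape_shares(c)
        assert pin[0, 0] == pytest.approx(25.0)
        assert pin[0, 1] == pytest.approx(75.0)
        assert pout[0, 2] == pytest.approx(100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(50, 8))
        pin, pout = currentscape_shares(c)
        assert pin.sum(axis=1).filled(100.0) == pytest.approx(
            np.full(50, 100.0))
        assert pout.sum(axis=1).filled(100.0) == pytest.approx(
            np.full(50, 100.0))

    def test_zero_total_masked_not_nan(self):
        c = np.zeros((3, 4))
        pin, pout = currentscape_shares(c)
        assert np.all(pin.mask) and np.all(pout.mask)
        assert not np.isnan(pin.filled(0.0)).any()


class TestEnsembleSummary:
    def test_all_converged(self):
        outs = [{"converged": True, "gate_off_ms": 60000.0 * (i + 1),
                 "n_episodes": 1} for i in range(5)]
        s = ensemble_summary(outs)
        assert s["fraction_converged"] == 1.0
        assert s["median_gate_off_ms"] == 180_000.0

    def test_constructed_fraction(self):
        outs = [{"converged": i < 47, "gate_off_ms": 1000.0 if i < 47 else None,
                 "n_episodes": 1 if i < 45 else 3} for i in range(50)]
        s = ensemble_summary(outs)
        assert s["fraction_converged"] == pytest.approx(0.94)
        assert s["fraction_single_episode"] == pytest.approx(0.90)
        lo, hi = s["fraction_converged_ci"]
        assert lo < 0.94 < hi

    def test_window_average_constant(self):
        x = np.full(100, 3.3)
        assert window_average(x, 100.0, 2000.0) == pytest.approx(x)
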