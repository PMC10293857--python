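"""Quick-look plots for trajectories and currentscapes (matplotlib)."""

from __future__ import annotations

import numpy as np

from .analysis import currentscape_shares, window_average
from .channels import CHANNELS

__all__ = ["plot_trajectory", "plot_currentscape"]


def plot_trajectory(traj, *, fig=None, v_window_ms: float = 5000.0):
    """Overview figure: V (final stretch), conductances, sensors, S_f, alpha."""
    import matplotlib.pyplot as plt

    fig = fig or plt.figure(figsize=(10, 10))
    axes = fig.subplots(5, 1)
    t_min = traj.t_slow / 60_000.0

    n = min(len(traj.v), int(round(v_window_ms / traj.dt_v)))
    axes[0].plot(traj.t_v[-n:] / 1000.0, traj.v[-n:], lw=0.6, color="k")
    axes[0].set_ylabel("V (mV)")
    axes[0].set_xlabel("time (s)")

    g = np.maximum(traj.gbar, 1e-9)
    for i, name in enumerate(CHANNELS):
        axes[1].semilogy(t_min, g[:, i], lw=0.8, label=name)
    axes[1].set_ylabel("gbar (uS)")
    axes[1].legend(ncols=4, fontsize=7)

    dts = traj.dt * traj.stride_slow
    for j, name in enumerate(("F", "S", "D")):
        axes[2].plot(t_min, window_average(traj.sensor_outputs[:, j], dts),
                     lw=0.8, label=name)
    axes[2].set_ylabel("sensors (2 s avg)")
    axes[2].set_ylim(0, 0.3)
    axes[2].legend(fontsize=7)

    axes[3].plot(t_min, traj.s_f, lw=0.6)
    axes[3].axhline(0.1, ls="--", c="grey", lw=0.6)
    axes[3].set_ylabel("S_f")

    axes[4].plot(t_min, traj.alpha, lw=0.6)
    axes[4].set_ylabel("alpha")
    axes[4].set_xlabel("time (min)")
    fig.tight_layout()
    return fig


def plot_currentscape(currents, dt_ms, *, fig=None):
    """Stacked percent-contribution plot of inward and outward currents."""
    import matplotlib.pyplot as plt

    fig = fig or plt.figure(figsize=(10, 5))
    ax_out, ax_in = fig.subplots(2, 1, sharex=True)
    pin, pout = currentscape_shares(currents)
    t = dt_ms * np.arange(1, len(currents) + 1) / 1000.0
    ax_out.stackplot(t, np.nan_to_num(np.ma.filled(pout, 0.0)).T,
                     labels=CHANNELS)
    ax_out.set_ylabel("outward %")
    ax_out.legend(ncols=4, fontsize=7)
    ax_in.stackplot(t, np.nan_to_num(np.ma.filled(pin, 0.0)).T)
    ax_in.set_ylabel("inward %")
    ax_in.set_xlabel("time (s)")
    fig.tight_layout()
    return fig
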