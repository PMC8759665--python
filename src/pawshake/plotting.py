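"""Small plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_cycle_heatmap(grid, value="n_cycles", ax=None, cmap="viridis"):
    """Fig-2-style heat map: transient cycle count over phase x duration;
    cells that switched to the stable fast rhythm are blacked out."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    phases = np.sort(grid["phase"].unique())
    durs = np.sort(grid["duration"].unique())
    piv = grid.pivot_table(index="duration", columns="phase", values=value)
    data = np.ma.masked_invalid(piv.reindex(index=durs, columns=phases)
                                .to_numpy(dtype=float))
    sf = grid.pivot_table(index="duration", columns="phase",
                          values="stable_fast")
    data = np.ma.masked_where(sf.reindex(index=durs, columns=phases)
                              .to_numpy(dtype=float) > 0.5, data)
    im = ax.pcolormesh(phases, durs, data, cmap=cmap, shading="nearest")
    ax.set_facecolor("black")
    ax.set_xlabel("phase of pulse onset (%)")
    ax.set_ylabel("pulse duration (s)")
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax


def plot_trajectory(traj, neurons=(1, 2), ax=None):
    """Membrane potentials of both neurons over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for n, color in zip(neurons, ("tab:blue", "tab:orange")):
        ax.plot(traj.t, traj.V(n), lw=0.5, color=color, label=f"neuron {n}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("V (mV)")
    ax.legend(loc="upper right")
    return ax
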