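"""Static snapshot rendering: agents drawn as polylines, coloured by
suppression state or strain/allele identity."""

from __future__ import annotations

import numpy as np

from .engine import Trajectory

__all__ = ["render_snapshot"]

_STRAIN_COLOURS = {0: "tab:red", 1: "tab:green", 2: "tab:orange"}


def render_snapshot(traj: Trajectory, time_index: int = -1, path=None,
                    color_by: str = "suppression", ax=None):
    """Draw one snapshot; returns the matplotlib Axes.

    ``color_by='suppression'`` paints reversal-suppressed agents blue and
    the rest red; ``color_by='strain'`` colours by strain/allele identity
    (useful for mixture runs).  Chains straddling the periodic boundary
    are unwrapped for display.  With ``path`` given the figure is saved
    (PNG or any matplotlib-supported format) and closed.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    box = traj.cfg.L_sim
    pos = traj.positions()[time_index]
    sup = traj.suppressed()[time_index]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for a in range(traj.n_agents):
        chain = pos[a]
        d = np.diff(chain, axis=0)
        d -= box * np.round(d / box)
        chain = np.vstack([chain[0], chain[0] + np.cumsum(d, axis=0)])
        if color_by == "strain":
            colour = _STRAIN_COLOURS.get(int(traj.strain[a]), "black")
            if int(traj.strain[a]) == 1 and int(traj.allele[a]) != 1:
                colour = "tab:purple"  # distinguish the second OE allele
        else:
            colour = "tab:blue" if sup[a] else "tab:red"
        ax.plot(chain[:, 0], chain[:, 1], lw=1.1, color=colour)
    ax.set_xlim(0, box)
    ax.set_ylim(0, box)
    ax.set_aspect(1.0)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"t = {traj.times[time_index]:.0f} min")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
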