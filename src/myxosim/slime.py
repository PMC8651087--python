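"""Slime-trail field: deposition and following of apolar trail orientations.

Gliding cells extrude slime behind them; later cells crossing a trail
steer their head propulsion parallel to it.  The field is a periodic
square grid (cell size one agent width by default) storing, per cell, the
trail orientation as an angle in [0, π) — trails are apolar, a cell can be
followed in either direction — and the time of the last deposit.  The most
recent passer overwrites the orientation (trail reinforcement).  Trails
persist for the whole run.

Steering is bounded: per step the head propulsion direction rotates toward
the nearer of the two trail branches {ê_s, ê_s+π} by at most ω_s·dt.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig

__all__ = ["SlimeGrid", "steer_toward_trail"]

EMPTY = -1.0  # sentinel orientation for untouched cells


class SlimeGrid:
    """Discretised apolar trail-orientation field on a periodic square."""

    def __init__(self, L_sim: float, cell_size: float = 0.5):
        self.cell_size = float(cell_size)
        self.n = max(1, int(round(L_sim / cell_size)))
        self.L_sim = float(L_sim)
        self.orientation = np.full((self.n, self.n), EMPTY)   # [0, π) or EMPTY
        self.last_deposit_time = np.full((self.n, self.n), -np.inf)

    def cell_index(self, point) -> tuple[int, int]:
        p = np.asarray(point, float)
        i = int(np.floor(p[0] / self.cell_size)) % self.n
        j = int(np.floor(p[1] / self.cell_size)) % self.n
        return i, j

    def deposit(self, tail_point, tail_segment_vector, t: float) -> None:
        """Write the tail segment's orientation (mod π) under the tail node;
        latest writer wins."""
        v = np.asarray(tail_segment_vector, float)
        theta = float(np.arctan2(v[1], v[0])) % np.pi
        i, j = self.cell_index(tail_point)
        self.orientation[i, j] = theta
        self.last_deposit_time[i, j] = t

    def trail_at(self, point, t: float | None = None,
                 decay: float = np.inf) -> float | None:
        """Orientation in [0, π) at ``point``, or None for an empty cell.
        With ``t`` given, cells older than ``decay`` count as empty."""
        i, j = self.cell_index(point)
        theta = self.orientation[i, j]
        if theta == EMPTY:
            return None
        if t is not None and t - self.last_deposit_time[i, j] > decay:
            return None
        return float(theta)

    def follow(self, head_point, heading_angle: float, cfg: SimulationConfig,
               t: float | None = None) -> float:
        """Head propulsion angle after slime steering at ``head_point``.

        No-op when following is disabled, the cell is empty, or the trail
        has decayed; otherwise rotates ``heading_angle`` toward the nearer
        trail branch by at most ω_s·dt (ω_s in deg/min).
        """
        if not cfg.slime_following_enabled:
            return heading_angle
        theta = self.trail_at(head_point, t, cfg.slime_decay_min)
        if theta is None:
            return heading_angle
        max_step = np.deg2rad(cfg.omega_s) * cfg.dt
        return steer_toward_trail(heading_angle, theta, max_step)

    def to_table(self):
        """Dense (i, j, orientation, last_deposit_time) table for debugging."""
        import pandas as pd

        ii, jj = np.meshgrid(np.arange(self.n), np.arange(self.n), indexing="ij")
        return pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "orientation": self.orientation.ravel(),
                "last_deposit_time": self.last_deposit_time.ravel(),
            }
        )


def steer_toward_trail(heading_angle: float, trail_angle: float, max_step: float) -> float:
    """Rotate ``heading_angle`` toward the nearer apolar branch of
    ``trail_angle`` (mod π), by at most ``max_step`` radians.

    The signed misalignment to the nearest branch lies in (−π/2, π/2]; the
    rotation is clipped to ±max_step, so an aligned or exactly antiparallel
    heading is unchanged.
    """
    delta = (trail_angle - heading_angle + np.pi / 2.0) % np.pi - np.pi / 2.0
    return heading_angle + float(np.clip(delta, -max_step, max_step))
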