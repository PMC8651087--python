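"""Trajectory analysis: reversal statistics, circular-aggregate detection,
radial kinematic profiles and suppression summaries.

Works on the engine's :class:`~myxosim.engine.Trajectory` or on any track
table in the same columnar format.  Circular aggregates (CAs) are scored
with a rotational order parameter: density-based clustering (DBSCAN) finds
candidate clusters of agent centroids, and a cluster counts as a CA when
the mean projection of member velocities onto the tangential direction
about the cluster centre exceeds a threshold — i.e. when members circulate
coherently one way around the centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .engine import Trajectory

__all__ = [
    "ReversalEvent",
    "AggregateReport",
    "RadialProfile",
    "NoReversalsObserved",
    "mean_reversal_interval",
    "detect_reversals",
    "detect_aggregates",
    "radial_kinematics",
    "suppression_stats",
    "centroid_velocities",
]


class NoReversalsObserved(ValueError):
    """No reversal events: the mean interval is undefined (effectively
    longer than the observation window)."""


@dataclass(frozen=True)
class ReversalEvent:
    agent_id: int
    time_min: float


@dataclass
class AggregateReport:
    """One detected cluster and its rotation statistics."""

    aggregate_id: int
    center: np.ndarray              # (2,) μm
    radius: float                   # μm, 90th-percentile member distance
    members: np.ndarray             # agent ids
    rotation_sense: str             # "CW" | "CCW" | "none"
    rotational_order: float         # in [0, 1]

    @property
    def is_circular_aggregate(self) -> bool:
        return self.rotation_sense != "none"


@dataclass
class RadialProfile:
    """Binned kinematics as a function of distance from an aggregate centre."""

    bin_centers: np.ndarray         # μm
    mean_speed: np.ndarray          # μm/min
    mean_angular_speed: np.ndarray  # rad/min
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_um": self.bin_centers,
                "mean_speed_um_per_min": self.mean_speed,
                "mean_angular_speed_rad_per_min": self.mean_angular_speed,
                "n_samples": self.counts,
            }
        )


def mean_reversal_interval(n_cells: int, duration_min: float, n_events: int) -> float:
    """Population-mean time between reversals, in hours.

    Pools all tracked cells: total observed cell-time divided by the number
    of reversal events.  E.g. 443 cells watched for 60 min with 12 events
    gives 443·60/12 = 2215 min ≈ 36.9 h — one reversal per cell roughly
    every day and a half.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if n_events < 0:
        raise ValueError("event count cannot be negative")
    if n_events == 0:
        raise NoReversalsObserved(
            f"no reversals observed in {n_cells} cells over {duration_min} min; "
            "the mean interval is unbounded"
        )
    return (n_cells * duration_min / n_events) / 60.0


def _min_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def centroid_velocities(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Centroids (S, M, 2) and centred-difference velocities (S, M, 2).

    End snapshots use one-sided differences.  Displacements are taken
    minimum-image so boundary crossings do not produce spurious speeds.
    """
    cen = traj.centroids()
    cached = getattr(traj, "_velocity_cache", None)
    if cached is not None:
        return cen, cached
    box = traj.cfg.L_sim
    times = np.asarray(traj.times)
    S = len(times)
    vel = np.zeros_like(cen)
    if S < 2:
        return cen, vel
    for s in range(S):
        lo, hi = max(0, s - 1), min(S - 1, s + 1)
        disp = _min_image(cen[hi] - cen[lo], box)
        vel[s] = disp / (times[hi] - times[lo])
    traj._velocity_cache = vel
    return cen, vel


def detect_reversals(
    traj: Trajectory,
    angle_threshold_deg: float = 150.0,
    soft_angle_deg: float = 120.0,
    retrace_distance: float = 1.0,
    persistence: int = 2,
    min_displacement: float = 0.05,
) -> pd.DataFrame:
    """Call reversal events from centroid tracks.

    A reversal is called at snapshot k when the travel direction turns by
    more than ``angle_threshold_deg`` across k, comparing every pair of
    moving intervals up to two before and two after k (the pairwise scan
    is robust to the short arbitrary-direction interval bracketing the
    turnaround itself).  A turn between ``soft_angle_deg`` and the hard
    threshold — the signature of a reversal coinciding with a 90° head
    turn, whose deflection masks part of the 180° flip — is accepted only
    when the track *retraces itself*: some position within three
    snapshots after k returns within ``retrace_distance`` μm of a
    position within three snapshots before k.  Retracing separates true
    reversals from large collision deflections, which redirect without
    backtracking.  The new direction must persist for ``persistence``
    snapshot intervals (within 90°); intervals with displacement below
    ``min_displacement`` μm are treated as pauses and skipped.  Returns a
    table (agent_id, time_min), per agent in time order.
    """
    if traj.n_snapshots < 3:
        warnings.warn("trajectory has fewer than 3 snapshots; no reversals detectable")
        return pd.DataFrame(columns=["agent_id", "time_min"])
    cen = traj.centroids()
    box = traj.cfg.L_sim
    times = np.asarray(traj.times)
    cos_hard = np.cos(np.deg2rad(angle_threshold_deg))
    cos_soft = np.cos(np.deg2rad(soft_angle_deg))
    events: list[tuple[int, float]] = []
    disp = _min_image(cen[1:] - cen[:-1], box)          # (S-1, M, 2)
    norm = np.linalg.norm(disp, axis=2)

    for a in range(traj.n_agents):
        moving = np.nonzero(norm[:, a] >= min_displacement)[0]
        if len(moving) < 2:
            continue
        d = disp[moving, a] / norm[moving, a][:, None]
        track = cen[:, a, :]
        last_event_k = -10
        for idx in range(1, len(d)):
            worst = 1.0
            j_new = idx
            for i in range(max(0, idx - 2), idx):
                for j in range(idx, min(len(d), idx + 2)):
                    dot = d[i] @ d[j]
                    if dot < worst:
                        worst = dot
                        j_new = j
            if worst >= cos_soft:
                continue  # no reversal-scale turn within the window
            k = moving[j_new]
            if worst >= cos_hard:
                # soft tier: require the track to retrace itself
                pre = track[max(0, k - 3):k]
                post = track[k + 1:k + 4]
                if len(pre) == 0 or len(post) == 0:
                    continue
                gap = _min_image(post[:, None, :] - pre[None, :, :], box)
                if np.min(np.linalg.norm(gap, axis=2)) > retrace_distance:
                    continue
            # persistence of the new direction over the next intervals
            ok = True
            for p in range(1, persistence):
                if j_new + p >= len(d):
                    break
                if (d[j_new] @ d[j_new + p]) < 0.0:
                    ok = False
                    break
            if ok and k - last_event_k >= 4:
                events.append((a, float(times[k])))
                last_event_k = k
    return pd.DataFrame(events, columns=["agent_id", "time_min"])


def _unwrap_cluster(points: np.ndarray, box: float) -> np.ndarray:
    """Unwrap a cluster of points across the periodic boundary: minimum
    image relative to a provisional (circular-mean) centroid, iterated once."""
    angles = points / box * 2 * np.pi
    provisional = (
        np.arctan2(np.sin(angles).mean(axis=0), np.cos(angles).mean(axis=0))
        % (2 * np.pi)
    ) / (2 * np.pi) * box
    unwrapped = provisional + _min_image(points - provisional, box)
    centroid = unwrapped.mean(axis=0)
    return centroid + _min_image(unwrapped - centroid, box)


def detect_aggregates(
    traj: Trajectory,
    time_index: int = -1,
    eps: float = 3.0,
    min_size: int = 20,
    order_threshold: float = 0.5,
) -> list[AggregateReport]:
    """Detect aggregates in one snapshot and score their rotation.

    DBSCAN over agent centroids (periodic metric, neighbourhood ``eps``,
    clusters below ``min_size`` agents discarded); per cluster the centre
    is the unwrapped member centroid and the radius the 90th-percentile
    member distance.  The rotational order is the speed-weighted
    tangential fraction |Σ_m (r̂×v)_z| / Σ_m |v| over members: 1 for a
    coherently circulating cluster, ~M^(−1/2) for disordered motion.
    Speed weighting makes the score reflect the visible rotation of the
    moving rim — aggregates carry slow, crowded cores (linear speed rises
    with distance from the centre), and near-stationary members say
    nothing about rotation sense.  Clusters at or above
    ``order_threshold`` are circular aggregates with a definite sense
    (CCW for positive net circulation).
    """
    if traj.n_agents == 0 or traj.n_snapshots == 0:
        return []
    cen, vel = centroid_velocities(traj)
    points = cen[time_index]
    v = vel[time_index]
    box = traj.cfg.L_sim
    if len(points) < min_size:
        return []
    diff = points[:, None, :] - points[None, :, :]
    dist = np.linalg.norm(_min_image(diff, box), axis=2)
    labels = DBSCAN(eps=eps, min_samples=5, metric="precomputed").fit_predict(dist)
    reports: list[AggregateReport] = []
    agg_id = 0
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = np.nonzero(labels == lab)[0]
        if len(members) < min_size:
            continue
        unwrapped = _unwrap_cluster(points[members], box)
        center = unwrapped.mean(axis=0)
        rel = unwrapped - center
        r = np.linalg.norm(rel, axis=1)
        radius = float(np.percentile(r, 90))
        vm = v[members]
        speed = np.linalg.norm(vm, axis=1)
        ok = (r > 1e-9) & (speed > 1e-9)
        if ok.sum() == 0:
            order, cross_mean = 0.0, 0.0
        else:
            r_hat = rel[ok] / r[ok, None]
            cross = r_hat[:, 0] * vm[ok, 1] - r_hat[:, 1] * vm[ok, 0]
            cross_mean = float(cross.sum())
            order = float(abs(cross_mean) / speed[ok].sum())
        if order >= order_threshold:
            sense = "CCW" if cross_mean > 0 else "CW"
        else:
            sense = "none"
        reports.append(
            AggregateReport(agg_id, center % box, radius, members, sense, order)
        )
        agg_id += 1
    return reports


def radial_kinematics(
    traj: Trajectory,
    aggregate: AggregateReport,
    bin_width: float = 2.0,
    window_min: float | None = 30.0,
    end_time: float | None = None,
    max_radius: float | None = None,
) -> RadialProfile:
    """Mean linear and angular speed versus distance from an aggregate centre.

    Pools agent-snapshots over the ``window_min`` minutes ending at
    ``end_time`` (default: the final snapshot; pass the time at which the
    aggregate was detected so the window brackets the structure rather
    than whatever the run ends with; None pools all snapshots).  Per
    sample, speed is the centred-difference centroid speed and angular
    speed the tangential speed divided by the distance to the centre.
    Bins of width ``bin_width`` μm out to ``max_radius`` (default: the
    aggregate radius); empty bins are omitted.
    """
    cen, vel = centroid_velocities(traj)
    times = np.asarray(traj.times)
    box = traj.cfg.L_sim
    if traj.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots for kinematics")
    t_end = times[-1] if end_time is None else float(end_time)
    mask_t = (
        (times >= t_end - window_min) & (times <= t_end)
        if window_min is not None
        else np.ones_like(times, dtype=bool)
    )
    max_radius = aggregate.radius if max_radius is None else max_radius
    rel = _min_image(cen[mask_t] - aggregate.center, box)     # (S', M, 2)
    dist = np.linalg.norm(rel, axis=2)
    v = vel[mask_t]
    speed = np.linalg.norm(v, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_hat = rel / dist[:, :, None]
    tangential = r_hat[:, :, 0] * v[:, :, 1] - r_hat[:, :, 1] * v[:, :, 0]
    angular = np.abs(tangential) / dist
    sel = (dist > 1e-9) & (dist <= max_radius) & np.isfinite(angular)
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    which = np.digitize(dist[sel], edges) - 1
    centers, sp, ang, cnt = [], [], [], []
    for b in range(len(edges) - 1):
        m = which == b
        if m.sum() == 0:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        sp.append(float(speed[sel][m].mean()))
        ang.append(float(angular[sel][m].mean()))
        cnt.append(int(m.sum()))
    return RadialProfile(np.array(centers), np.array(sp), np.array(ang), np.array(cnt))


def suppression_stats(traj: Trajectory, window_min: float = 10.0):
    """(fraction of agents suppressed at the final snapshot, mean lifetime
    of bonds that broke within the final ``window_min`` minutes).

    The lifetime mean is NaN when no bond broke in the window.  Requires
    the engine's bond-break log; trajectories loaded from bare track
    tables do not carry it.
    """
    if traj.bond_breaks is None:
        raise ValueError(
            "trajectory carries no bond-break log; run the simulation with "
            "bond logging (engine runs always log) or use the original Trajectory"
        )
    frac = float(np.mean(traj.suppressed()[-1])) if traj.n_snapshots else 0.0
    t_end = traj.times[-1] if traj.times else 0.0
    recent = traj.bond_breaks[traj.bond_breaks["broke_at"] >= t_end - window_min]
    mean_life = float(recent["lifetime_min"].mean()) if len(recent) else float("nan")
    return frac, mean_life
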