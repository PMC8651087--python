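"""Force model of a single flexible gliding rod and rod-rod mechanics.

An agent is a chain of N circular nodes (diameter w) joined by inextensible
segments of length L/(N−1); the capsule hull (node circles plus the spacer
rectangles between them) is the collision body.  Forces:

* distributed propulsion — N−1 nodes (all but the tail) each carry
  F_T/(N−1) pN directed along the body toward the head; the head node's
  direction is its current heading, optionally redirected by a 90° random
  turn or steered by a slime trail,
* viscous drag −c·v per node,
* angular springs of stiffness k_b resisting bending at interior joints,
* substrate focal-adhesion springs (stiffness k_a) resisting displacement
  transverse to the local body axis, detaching at d_a_max and instantly
  re-anchoring,
* penalty-spring repulsion between overlapping capsules of different agents.

Dynamics are overdamped: the inertial timescale m/c is many orders of
magnitude below dt, so node velocity is net force over drag.  These
functions are the plain-NumPy reference implementation; the engine runs
numerically identical jitted kernels (see ``_kernels``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import SimulationConfig

__all__ = [
    "AgentState",
    "straight_agent",
    "heading",
    "propulsion_forces",
    "drag_forces",
    "bending_forces",
    "substrate_adhesion",
    "contact_repulsion",
    "enforce_length",
    "segment_distance",
    "min_image",
]


class DegenerateGeometryError(RuntimeError):
    """Raised when consecutive nodes coincide (corrupted agent state)."""


@dataclass
class AgentState:
    """State of one agent: node chain, polarity, clocks and identity."""

    agent_id: int
    node_positions: np.ndarray          # (N, 2) μm
    node_velocities: np.ndarray         # (N, 2) μm/min
    head_index: int                     # 0 or N−1
    reversal_clock: float = 0.0         # r_t, min
    turn_sign: int = 0                  # 0 inactive, ±1 active
    turn_remaining: float = 0.0         # min left of the active turn
    turn_timer: float = 0.0             # min since last turn trigger
    strain_label: str = "WT"
    allele_id: int = 1
    suppressed_now: bool = False
    anchors: Optional[np.ndarray] = field(default=None)  # (N, 2) substrate anchor points

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.node_velocities = np.asarray(self.node_velocities, dtype=float)
        n = len(self.node_positions)
        if self.node_positions.shape != (n, 2) or self.node_velocities.shape != (n, 2):
            raise ValueError("node_positions and node_velocities must be (N, 2)")
        if self.head_index not in (0, n - 1):
            raise ValueError("head_index must designate an end node")
        if self.reversal_clock < 0:
            raise ValueError("reversal clock must be non-negative")
        if self.anchors is None:
            self.anchors = self.node_positions.copy()

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def tail_index(self) -> int:
        return self.n_nodes - 1 - self.head_index


def straight_agent(
    agent_id: int,
    origin,
    angle: float,
    cfg: SimulationConfig,
    head_index: int | None = None,
) -> AgentState:
    """Build a straight agent whose tail sits at ``origin`` pointing along
    ``angle`` (radians); node 0 is the head unless ``head_index`` says otherwise."""
    s = cfg.segment_length
    direction = np.array([np.cos(angle), np.sin(angle)])
    # node 0 at the far end so that head_index=0 means "head at origin + L*dir"
    nodes = np.asarray(origin, dtype=float) + s * np.arange(cfg.N - 1, -1, -1)[:, None] * direction
    hi = 0 if head_index is None else head_index
    return AgentState(agent_id, nodes, np.zeros((cfg.N, 2)), hi)


def heading(agent: AgentState) -> np.ndarray:
    """Unit vector from the node behind the head toward the head."""
    h = agent.head_index
    neck = 1 if h == 0 else agent.n_nodes - 2
    v = agent.node_positions[h] - agent.node_positions[neck]
    norm = np.hypot(*v)
    if norm < 1e-12:
        raise DegenerateGeometryError(f"agent {agent.agent_id}: head and neck nodes coincide")
    return v / norm


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([ca * v[0] - sa * v[1], sa * v[0] + ca * v[1]])


def propulsion_forces(
    agent: AgentState,
    cfg: SimulationConfig,
    head_direction: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-node propulsion, total magnitude F_T.

    Every node except the tail carries F_T/(N−1): inner nodes push toward
    their forward neighbour (the next node toward the head); the head node
    pushes along ``head_direction`` if given (turn- or slime-adjusted),
    otherwise along the geometric heading.  During an active 90° turn the
    head force is rotated by the turn sign (counterclockwise for +1).
    """
    n = agent.n_nodes
    f_mag = cfg.F_T / (n - 1)
    forces = np.zeros((n, 2))
    h = agent.head_index
    step = -1 if h == 0 else 1  # index offset from a node to its forward neighbour
    for i in range(n):
        if i == agent.tail_index:
            continue
        if i == h:
            d = heading(agent) if head_direction is None else np.asarray(head_direction, float)
            if agent.turn_sign != 0 and agent.turn_remaining > 0:
                d = _rotate(d, agent.turn_sign * np.pi / 2.0)
        else:
            d = agent.node_positions[i + step] - agent.node_positions[i]
            norm = np.hypot(*d)
            if norm < 1e-12:
                raise DegenerateGeometryError(
                    f"agent {agent.agent_id}: nodes {i} and {i + step} coincide"
                )
            d = d / norm
        forces[i] = f_mag * d
    return forces


def drag_forces(node_velocities: np.ndarray, c: float) -> np.ndarray:
    """Viscous drag F_d = −c·v, per node."""
    return -c * np.asarray(node_velocities, dtype=float)


def bending_forces(node_positions: np.ndarray, k_b: float) -> np.ndarray:
    """Restoring forces of the angular springs at interior joints.

    Each joint i stores energy ½·k_b·φ², φ being the signed deviation of
    the two adjacent segments from collinearity; forces are −∇E, hence
    momentum- and torque-free over the chain.
    """
    x = np.asarray(node_positions, dtype=float)
    n = len(x)
    forces = np.zeros_like(x)
    for i in range(1, n - 1):
        a = x[i] - x[i - 1]
        b = x[i + 1] - x[i]
        la2, lb2 = a @ a, b @ b
        phi = np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b)  # signed turn angle
        ga = np.array([-a[1], a[0]]) / la2   # ∂φ/∂x_{i−1}
        gb = np.array([-b[1], b[0]]) / lb2   # ∂φ/∂x_{i+1}
        forces[i - 1] += -k_b * phi * ga
        forces[i + 1] += -k_b * phi * gb
        forces[i] += k_b * phi * (ga + gb)
    return forces


def substrate_adhesion(
    node: np.ndarray,
    anchor: np.ndarray,
    axis: np.ndarray,
    k_a: float,
    d_a_max: float,
    box: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Focal-adhesion spring force on one node and its (possibly reset) anchor.

    The spring resists only displacement transverse to the local body axis
    (unit vector ``axis``): gliding along the body is unimpeded.  When the
    total displacement reaches ``d_a_max`` the anchor detaches and instantly
    re-forms at the node's position (zero force that step).
    """
    node = np.asarray(node, float)
    disp = min_image(node - np.asarray(anchor, float), box)
    if np.hypot(*disp) >= d_a_max:
        return np.zeros(2), node.copy()
    axis = np.asarray(axis, float)
    axis = axis / np.hypot(*axis)
    transverse = disp - (disp @ axis) * axis
    return -k_a * transverse, np.asarray(anchor, float)


def min_image(delta: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image displacement on a periodic square of edge ``box``."""
    if not np.isfinite(box):
        return np.asarray(delta, float)
    return np.asarray(delta, float) - box * np.round(np.asarray(delta, float) / box)


def segment_distance(p0, p1, q0, q1, box: float = np.inf):
    """Closest approach between segments p0–p1 and q0–q1 (minimum image
    taken on the offset between the segment origins).

    Returns (distance, s, t, direction) with closest points p0+s·(p1−p0)
    and q0+t·(q0 offset)…; ``direction`` is the unit vector from the point
    on segment p toward the point on segment q (zero if coincident).
    """
    p0 = np.asarray(p0, float)
    u = np.asarray(p1, float) - p0
    q0p = p0 + min_image(np.asarray(q0, float) - p0, box)
    v = np.asarray(q1, float) - np.asarray(q0, float)
    v = min_image(v, box)
    w0 = p0 - q0p
    a, b, c_ = u @ u, u @ v, v @ v
    d_, e_ = u @ w0, v @ w0
    denom = a * c_ - b * b
    if denom > 1e-12:
        s = np.clip((b * e_ - c_ * d_) / denom, 0.0, 1.0)
    else:  # parallel
        s = 0.0
    t = (b * s + e_) / c_ if c_ > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # one re-projection of s for clamped t
    if a > 1e-12:
        s = np.clip((b * t - d_) / a, 0.0, 1.0)
    cp = p0 + s * u
    cq = q0p + t * v
    diff = cq - cp
    dist = float(np.hypot(*diff))
    direction = diff / dist if dist > 1e-12 else np.zeros(2)
    return dist, float(s), float(t), direction


def contact_repulsion(agents: list[AgentState], cfg: SimulationConfig) -> list[np.ndarray]:
    """Penalty repulsion between overlapping capsules of different agents.

    For every pair of body segments (capsule radius w/2) of two distinct
    agents whose axes approach closer than w, a linear penalty force
    k_rep·(w − d) acts along the closest-approach direction, split onto the
    segment endpoints by the closest-point barycentric weights.  Per
    contact the two agents receive equal and opposite force totals.
    """
    forces = [np.zeros_like(a.node_positions) for a in agents]
    box = cfg.L_sim
    for ia in range(len(agents)):
        for ib in range(ia + 1, len(agents)):
            A, B = agents[ia], agents[ib]
            for i in range(A.n_nodes - 1):
                for j in range(B.n_nodes - 1):
                    dist, s, t, direction = segment_distance(
                        A.node_positions[i], A.node_positions[i + 1],
                        B.node_positions[j], B.node_positions[j + 1], box,
                    )
                    if dist >= cfg.w or dist < 1e-12:
                        continue
                    f = cfg.k_rep * (cfg.w - dist) * direction  # pushes B away from A
                    forces[ia][i] += -f * (1 - s)
                    forces[ia][i + 1] += -f * s
                    forces[ib][j] += f * (1 - t)
                    forces[ib][j + 1] += f * t
    return forces


def enforce_length(agent: AgentState, cfg: SimulationConfig,
                   tol: float = 1e-3, max_iter: int = 1000) -> AgentState:
    """Project node spacings back to L/(N−1), preserving the centre of mass.

    Position-based projection: each consecutive pair is moved symmetrically
    along its axis toward the target spacing, sweeping the chain until all
    spacings are within ``tol`` (relative) or ``max_iter`` sweeps.
    Symmetric pair moves keep the centroid fixed.
    """
    target = cfg.segment_length
    x = agent.node_positions
    for _ in range(max_iter):
        worst = 0.0
        for i in range(agent.n_nodes - 1):
            d = x[i + 1] - x[i]
            dist = np.hypot(*d)
            if dist < 1e-12:
                raise DegenerateGeometryError(f"agent {agent.agent_id}: coincident nodes")
            worst = max(worst, abs(dist - target) / target)
            corr = 0.5 * (dist - target) / dist * d
            x[i] += corr
            x[i + 1] -= corr
        if worst <= tol:
            break
    return agent
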