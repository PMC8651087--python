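"""Population initialization, the time-stepping loop, and trajectory records.

A :class:`Simulation` owns the full mutable state (node positions, substrate
anchors, polarity, clocks, bond table, slime field) as flat arrays and
advances it in jitted chunks (see ``_kernels``).  Runs are deterministic:
the same (config, seed) yields bit-identical trajectories.

Snapshots of every agent are recorded on a fixed interval (1 min default)
into a :class:`Trajectory`, together with the engine's event logs —
reversal firings and adhesion-bond lifetimes — which ground-truth the
analysis module's detectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import NR, STRAIN_NAMES, SimulationConfig, StrainFraction
from .mechanics import AgentState, segment_distance

__all__ = ["Simulation", "Trajectory", "initialize", "run"]


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested density."""


class NonFiniteStateError(RuntimeError):
    """A node coordinate became non-finite; includes a diagnostic dump."""


def _strain_arrays(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign strain/allele labels by composition fractions (largest-remainder
    rounding), then shuffle so labels are not spatially ordered."""
    M = cfg.n_agents
    comps = cfg.strain_composition
    counts = [int(np.floor(s.fraction * M)) for s in comps]
    rema = [s.fraction * M - c for s, c in zip(comps, counts)]
    for k in np.argsort(rema)[::-1][: M - sum(counts)]:
        counts[int(k)] += 1
    strain = np.concatenate(
        [np.full(c, comp.strain_code, dtype=np.int64) for comp, c in zip(comps, counts)]
    )
    allele = np.concatenate(
        [np.full(c, comp.allele, dtype=np.int64) for comp, c in zip(comps, counts)]
    )
    order = rng.permutation(M)
    return strain[order], allele[order]


def _place_agents(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample M straight, non-overlapping rods; returns (M, 2)
    (tail position, angle packed as x, y, theta) -> actually (M, 3)."""
    M = cfg.n_agents
    box = cfg.L_sim
    budget = 100 * M
    placed = np.empty((M, 3))
    # coarse hash over rod centres for the overlap test
    cell = cfg.L + cfg.w
    nc = max(1, int(box // cell))
    buckets: dict[tuple[int, int], list[int]] = {}
    n_placed = 0
    attempts = 0
    while n_placed < M:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {n_placed}/{M} agents in {budget} attempts; "
                f"achievable density ~{n_placed / box**2:.4f} agents/um^2"
            )
        attempts += 1
        x, y = rng.uniform(0.0, box, size=2)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        p0 = np.array([x, y])
        p1 = p0 + cfg.L * np.array([np.cos(theta), np.sin(theta)])
        centre = (p0 + p1) / 2.0
        ci = int(np.floor(centre[0] / cell)) % nc
        cj = int(np.floor(centre[1] / cell)) % nc
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in buckets.get(((ci + di) % nc, (cj + dj) % nc), ()):
                    q0 = placed[k, :2]
                    q1 = q0 + cfg.L * np.array([np.cos(placed[k, 2]), np.sin(placed[k, 2])])
                    d, *_ = segment_distance(p0, p1, q0, q1, box)
                    if d < cfg.w:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        placed[n_placed] = (x, y, theta)
        buckets.setdefault((ci, cj), []).append(n_placed)
        n_placed += 1
    return placed


class Trajectory:
    """Per-minute records of a run plus the engine's event logs."""

    def __init__(self, cfg: SimulationConfig, strain: np.ndarray, allele: np.ndarray):
        self.cfg = cfg
        self.strain = strain.copy()
        self.allele = allele.copy()
        self.times: list[float] = []
        self._pos: list[np.ndarray] = []
        self._head: list[np.ndarray] = []
        self._clock: list[np.ndarray] = []
        self._suppressed: list[np.ndarray] = []
        self.reversal_events = pd.DataFrame(columns=["agent_id", "time_min"])
        self.bond_breaks = pd.DataFrame(columns=["bond_type", "formed_at", "broke_at"])

    # -- recording ------------------------------------------------------
    def _record(self, t, pos, head, clock, suppressed):
        self.times.append(float(t))
        self._pos.append(pos)
        self._head.append(head)
        self._clock.append(clock)
        self._suppressed.append(suppressed)
        self._centroid_cache = None
        self._velocity_cache = None

    # -- array views ----------------------------------------------------
    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    @property
    def n_agents(self) -> int:
        return len(self.strain)

    def positions(self) -> np.ndarray:
        """(S, M, N, 2) wrapped node positions."""
        return np.stack(self._pos)

    def head_index(self) -> np.ndarray:
        return np.stack(self._head)

    def reversal_clock(self) -> np.ndarray:
        return np.stack(self._clock)

    def suppressed(self) -> np.ndarray:
        return np.stack(self._suppressed)

    def centroids(self) -> np.ndarray:
        """(S, M, 2) agent centroids, wrapped into the box (memoized).

        Nodes are unwrapped relative to node 0 (minimum image) before
        averaging so chains straddling the boundary centroid correctly.
        """
        cached = getattr(self, "_centroid_cache", None)
        if cached is not None:
            return cached
        box = self.cfg.L_sim
        out = np.empty((self.n_snapshots, self.n_agents, 2))
        for s, p in enumerate(self._pos):
            rel = p - p[:, :1, :]
            rel -= box * np.round(rel / box)
            cen = p[:, 0, :] + rel.mean(axis=1)
            out[s] = cen % box
        self._centroid_cache = out
        return out

    # -- tabular interchange -------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """One row per node per snapshot, in the columnar trajectory format."""
        S, M = self.n_snapshots, self.n_agents
        N = self._pos[0].shape[1]
        pos = self.positions()
        head = self.head_index()
        clock = self.reversal_clock()
        sup = self.suppressed()
        t_col = np.repeat(self.times, M * N)
        agent_col = np.tile(np.repeat(np.arange(M), N), S)
        node_col = np.tile(np.arange(N), S * M)
        head_flag = (node_col == head[
            np.repeat(np.arange(S), M * N), agent_col]).astype(np.int8)
        return pd.DataFrame(
            {
                "time_min": t_col,
                "agent_id": agent_col,
                "node_index": node_col,
                "x_um": pos[:, :, :, 0].ravel(),
                "y_um": pos[:, :, :, 1].ravel(),
                "head_flag": head_flag,
                "reversal_clock_min": np.repeat(clock.ravel(), N),
                "suppressed_flag": np.repeat(sup.ravel().astype(np.int8), N),
                "strain_label": np.tile(
                    np.repeat([STRAIN_NAMES[s] for s in self.strain], N), S
                ),
                "allele_id": np.tile(np.repeat(self.allele, N), S),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cfg: SimulationConfig | None = None
                       ) -> "Trajectory":
        """Rebuild a trajectory from the columnar table format."""
        from .config import _STRAIN_CODES

        times = np.sort(df["time_min"].unique())
        agents = np.sort(df["agent_id"].unique())
        M = len(agents)
        first = df[df["time_min"] == times[0]].sort_values(["agent_id", "node_index"])
        N = first["node_index"].nunique()
        if cfg is None:
            span = max(df["x_um"].max(), df["y_um"].max())
            cfg = SimulationConfig(L_sim=float(np.ceil(span + 1)), eta=max(
                1.0 / np.ceil(span + 1) ** 2, M / np.ceil(span + 1) ** 2))
        strain = np.array(
            [_STRAIN_CODES[s] for s in first.groupby("agent_id")["strain_label"].first()],
            dtype=np.int64,
        )
        allele = first.groupby("agent_id")["allele_id"].first().to_numpy(np.int64)
        traj = cls(cfg, strain, allele)
        df = df.sort_values(["time_min", "agent_id", "node_index"])
        pos_all = df[["x_um", "y_um"]].to_numpy().reshape(len(times), M, N, 2)
        head_all = df["head_flag"].to_numpy().reshape(len(times), M, N)
        clock_all = df["reversal_clock_min"].to_numpy().reshape(len(times), M, N)[:, :, 0]
        sup_all = df["suppressed_flag"].to_numpy().reshape(len(times), M, N)[:, :, 0]
        for s, t in enumerate(times):
            head_idx = np.argmax(head_all[s], axis=1).astype(np.int64)
            traj._record(t, pos_all[s], head_idx, clock_all[s], sup_all[s].astype(bool))
        traj.bond_breaks = None  # bare track tables carry no bond log
        return traj

    @classmethod
    def from_csv(cls, path, cfg: SimulationConfig | None = None) -> "Trajectory":
        return cls.from_dataframe(pd.read_csv(path), cfg)


class Simulation:
    """Mutable simulation state and the stepping loop."""

    #: Verlet neighbour-list skin (μm).  Exactness-preserving: lists are
    #: supersets, rebuilt before accumulated motion can hide a pair.
    verlet_skin: float = 0.5

    def __init__(self, cfg: SimulationConfig, seed: int | None = None):
        cfg.validate()
        cutoff = cfg.d_thr_ee + cfg.segment_length + self.verlet_skin
        if cfg.L_sim < 3 * cutoff:
            raise ValueError(f"L_sim must be at least {3 * cutoff:.1f} um")
        self.cfg = cfg
        self.seed = cfg.seed if seed is None else int(seed)
        self._initialized = False

    # -- setup ----------------------------------------------------------
    def initialize(self) -> "Simulation":
        cfg = self.cfg
        rng = np.random.default_rng(self.seed)
        # independent sub-streams so ablations don't shift unrelated draws
        rng_place = np.random.default_rng(rng.integers(2**31))
        rng_heads = np.random.default_rng(rng.integers(2**31))
        rng_clocks = np.random.default_rng(rng.integers(2**31))
        rng_labels = np.random.default_rng(rng.integers(2**31))

        M, N = cfg.n_agents, cfg.N
        placed = _place_agents(cfg, rng_place)
        s = cfg.segment_length
        direction = np.stack([np.cos(placed[:, 2]), np.sin(placed[:, 2])], axis=1)
        # node 0 at the placement origin, chain extending along +direction
        self.pos = (placed[:, None, :2] + s * np.arange(N)[None, :, None]
                    * direction[:, None, :]).reshape(M * N, 2)
        self.anchors = self.pos.copy()
        self.head = (rng_heads.integers(0, 2, size=M) * (N - 1)).astype(np.int64)
        self.strain, self.allele = _strain_arrays(cfg, rng_labels)
        if np.isfinite(cfg.tau_r):
            self.r = rng_clocks.uniform(0.0, cfg.tau_r, size=M)
        else:
            self.r = np.zeros(M)
        self.r[self.strain == NR] = 0.0
        self.turn_sign = np.zeros(M, dtype=np.int64)
        self.turn_remaining = np.zeros(M)
        self.turn_timer = rng_clocks.uniform(0.0, cfg.tau_t, size=M)
        self.turn_count = np.zeros(M, dtype=np.int64)

        # slime field
        self.slime_n = max(1, int(round(cfg.L_sim / cfg.slime_cell_size)))
        self.slime_cell = cfg.L_sim / self.slime_n
        self.slime_orient = np.full((self.slime_n, self.slime_n), -1.0)
        self.slime_time = np.full((self.slime_n, self.slime_n), -np.inf)

        # bond table and workspaces
        Mn = M * N
        self._bond_cap = max(4096, 16 * Mn)
        self.bond_key = np.zeros(self._bond_cap, dtype=np.int64)
        self.bond_formed = np.zeros(self._bond_cap)
        self.bond_type = np.zeros(self._bond_cap, dtype=np.int8)
        self.bond_d = np.zeros(self._bond_cap)
        self.n_bonds = np.zeros(2, dtype=np.int64)

        cutoff = cfg.d_thr_ee + cfg.segment_length + self.verlet_skin
        self._ncells = max(3, int(cfg.L_sim // cutoff))
        nc2 = self._ncells**2
        self._posw = np.zeros((Mn, 2))
        self._cell_of = np.zeros(Mn, dtype=np.int64)
        self._cell_count = np.zeros(nc2, dtype=np.int64)
        self._cell_start = np.zeros(nc2, dtype=np.int64)
        self._cell_order = np.zeros(Mn, dtype=np.int64)
        pair_cap = max(200_000, 48 * Mn)
        self._pair_i = np.zeros(pair_cap, dtype=np.int64)
        self._pair_j = np.zeros(pair_cap, dtype=np.int64)
        self._pair_dx = np.zeros(pair_cap)
        self._pair_dy = np.zeros(pair_cap)
        self._pair_d = np.zeros(pair_cap)
        self._seg_i = np.zeros(max(50_000, 16 * Mn), dtype=np.int64)
        self._seg_j = np.zeros(max(50_000, 16 * Mn), dtype=np.int64)
        self._bnd_i = np.zeros(max(80_000, 24 * Mn), dtype=np.int64)
        self._bnd_j = np.zeros(max(80_000, 24 * Mn), dtype=np.int64)
        self._list_counts = np.zeros(3, dtype=np.int64)
        self._verlet_acc = np.zeros(1)
        self._cand_key = np.zeros(self._bond_cap, dtype=np.int64)
        self._cand_type = np.zeros(self._bond_cap, dtype=np.int8)
        self._cand_d = np.zeros(self._bond_cap)
        self._new_key = np.zeros(self._bond_cap, dtype=np.int64)
        self._new_formed = np.zeros(self._bond_cap)
        self._new_type = np.zeros(self._bond_cap, dtype=np.int8)
        self.forces = np.zeros((Mn, 2))
        self.ee_active = np.zeros(M, dtype=np.int64)
        self.lat_active = np.zeros(M, dtype=np.int64)
        self._pairseen = np.zeros(self._bond_cap, dtype=np.int64)

        # event buffers (drained every chunk)
        self._rev_agent = np.zeros(max(1024, 8 * M), dtype=np.int64)
        self._rev_time = np.zeros(max(1024, 8 * M))
        self._n_rev = np.zeros(2, dtype=np.int64)
        self._break_type = np.zeros(self._bond_cap, dtype=np.int8)
        self._break_formed = np.zeros(self._bond_cap)
        self._break_broke = np.zeros(self._bond_cap)
        self._n_break = np.zeros(2, dtype=np.int64)

        self._rev_log: list[tuple[int, float]] = []
        self._break_log: list[tuple[int, float, float]] = []
        self.step_count = 0
        self._initialized = True
        return self

    @property
    def t(self) -> float:
        return self.step_count * self.cfg.dt

    def invalidate_neighbor_lists(self) -> None:
        """Force a neighbour-list rebuild next step (call after mutating
        positions directly)."""
        self._list_counts[2] = 0

    # -- stepping -------------------------------------------------------
    def step(self, n_steps: int = 1) -> None:
        """Advance ``n_steps`` integration steps."""
        if not self._initialized:
            self.initialize()
        cfg = self.cfg
        status = K.run_chunk(
            self.pos, self.anchors, cfg.n_agents, cfg.N, cfg.L_sim,
            self.head, self.strain, self.allele, self.r,
            self.turn_sign, self.turn_remaining, self.turn_timer, self.turn_count,
            self.slime_orient, self.slime_time, self.slime_n, self.slime_cell,
            cfg.slime_following_enabled,
            self.bond_key, self.bond_formed, self.bond_type, self.bond_d, self.n_bonds,
            cfg.dt, self.t, n_steps, self.seed,
            cfg.F_T, cfg.c_node, cfg.k_b, cfg.k_a, cfg.d_a_max, cfg.k_rep, cfg.w,
            cfg.segment_length,
            cfg.adhesion_enabled, cfg.k_adh_wt, cfg.k_adh_oe,
            cfg.d_thr_ee, cfg.d_thr_lat, cfg.tau_thr,
            cfg.suppression_per_agent_pair, cfg.delta_R_e, cfg.delta_R_l,
            cfg.tau_r, cfg.tau_t, cfg.turn_duration,
            np.deg2rad(cfg.omega_s) * cfg.dt, cfg.slime_decay_min, 6,
            cfg.max_node_step,
            self._ncells, self._posw, self._cell_of, self._cell_count,
            self._cell_start, self._cell_order,
            self._pair_i, self._pair_j, self._pair_dx, self._pair_dy, self._pair_d,
            self._seg_i, self._seg_j, self._bnd_i, self._bnd_j,
            self._list_counts, self._verlet_acc, self.verlet_skin,
            self._cand_key, self._cand_type, self._cand_d,
            self._new_key, self._new_formed, self._new_type,
            self.forces, self.ee_active, self.lat_active, self._pairseen,
            self._rev_agent, self._rev_time, self._n_rev,
            self._break_type, self._break_formed, self._break_broke, self._n_break,
        )
        if status == K.ERR_NONFINITE:
            g = int(self._n_rev[1])
            a, li = divmod(g, cfg.N)
            raise NonFiniteStateError(
                f"non-finite coordinate at t={self.t:.3f} min, agent {a} node {li}; "
                f"agent nodes:\n{self.pos[a * cfg.N:(a + 1) * cfg.N]}"
            )
        if status != K.OK:
            raise RuntimeError(f"engine workspace overflow (status {status})")
        self.step_count += n_steps
        # drain event buffers
        for k in range(int(self._n_rev[0])):
            self._rev_log.append((int(self._rev_agent[k]), float(self._rev_time[k])))
        self._n_rev[0] = 0
        for k in range(int(self._n_break[0])):
            self._break_log.append(
                (int(self._break_type[k]), float(self._break_formed[k]),
                 float(self._break_broke[k]))
            )
        self._n_break[0] = 0

    def run(self, progress: bool = False) -> Trajectory:
        """Run for ``cfg.run_duration`` minutes, recording snapshots."""
        if not self._initialized:
            self.initialize()
        cfg = self.cfg
        traj = Trajectory(cfg, self.strain, self.allele)
        self._snapshot(traj)
        n_snap = int(round(cfg.run_duration / cfg.snapshot_interval))
        iterator = range(1, n_snap + 1)
        if progress:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="simulating", unit="min")
        for k in iterator:
            target = k * cfg.snapshot_interval
            n = int(round((target - self.t) / cfg.dt))
            if n > 0:
                self.step(n)
            self._snapshot(traj)
        traj.reversal_events = pd.DataFrame(
            self._rev_log, columns=["agent_id", "time_min"]
        )
        breaks = pd.DataFrame(
            self._break_log, columns=["bond_type", "formed_at", "broke_at"]
        )
        breaks["lifetime_min"] = breaks["broke_at"] - breaks["formed_at"]
        traj.bond_breaks = breaks
        return traj

    def _snapshot(self, traj: Trajectory) -> None:
        cfg = self.cfg
        pos = (self.pos % cfg.L_sim).reshape(cfg.n_agents, cfg.N, 2).copy()
        suppressed = (self.ee_active + self.lat_active) > 0
        traj._record(self.t, pos, self.head.copy(), self.r.copy(), suppressed.copy())

    # -- inspection -----------------------------------------------------
    def get_agent(self, a: int) -> AgentState:
        """Materialise one agent's state (velocities are the last step's)."""
        cfg = self.cfg
        base = a * cfg.N
        sl = slice(base, base + cfg.N)
        return AgentState(
            agent_id=a,
            node_positions=self.pos[sl].copy(),
            node_velocities=self.forces[sl] / cfg.c_node,
            head_index=int(self.head[a]),
            reversal_clock=float(self.r[a]),
            turn_sign=int(self.turn_sign[a]),
            turn_remaining=float(self.turn_remaining[a]),
            turn_timer=float(self.turn_timer[a]),
            strain_label=STRAIN_NAMES[int(self.strain[a])],
            allele_id=int(self.allele[a]),
            suppressed_now=bool((self.ee_active[a] + self.lat_active[a]) > 0),
            anchors=self.anchors[sl].copy(),
        )


def initialize(cfg: SimulationConfig, seed: int | None = None) -> Simulation:
    """Create and initialise a simulation (module-level convenience)."""
    return Simulation(cfg, seed).initialize()


def run(cfg: SimulationConfig, seed: int | None = None, progress: bool = False
        ) -> Trajectory:
    """Initialise and run a full simulation; returns the trajectory."""
    return Simulation(cfg, seed).initialize().run(progress=progress)
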