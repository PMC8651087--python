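"""Shared fixtures: small configurations and reusable simulation runs.

Expensive population runs used by several acceptance checks are
session-scoped so each condition is simulated once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from myxosim import SimulationConfig, StrainFraction, Simulation

#: domain edge used by the scaled-down emergent-behaviour checks (μm).
#: Density, time step and run length stay at their reference values; only
#: the domain (hence agent count) shrinks to keep the suite's runtime sane.
TEST_L_SIM = 50.0
TEST_SEEDS = (0, 1, 2)


@pytest.fixture
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A tiny box for one- and two-agent mechanics fixtures."""
    return SimulationConfig(L_sim=30.0, eta=1.0 / 900.0, run_duration=10.0)


def _single_agent_sim(seed=1, **overrides) -> Simulation:
    cfg = SimulationConfig(L_sim=30.0, eta=1.0 / 900.0, run_duration=10.0,
                           tau_t=1e9, slime_following_enabled=False, **overrides)
    return Simulation(cfg, seed=seed).initialize()


@pytest.fixture
def single_agent_sim() -> Simulation:
    """One isolated agent, turns and slime disabled."""
    return _single_agent_sim()


def synthetic_trajectory(centroids, box, times=None, strain=None, allele=None):
    """Fabricate a Trajectory whose agent centroids follow ``centroids``
    ((S, M, 2), wrapped into [0, box)): each agent is a short horizontal
    7-node chain centred on its track point.  For analysis-detector tests
    with known answers."""
    import pandas as pd

    from myxosim.engine import Trajectory

    centroids = np.asarray(centroids, dtype=float)
    S, M, _ = centroids.shape
    times = list(range(S)) if times is None else list(times)
    cfg = SimulationConfig(L_sim=box, eta=max(M, 1) / box**2 if M else 1.0 / box**2)
    strain = np.zeros(M, dtype=np.int64) if strain is None else np.asarray(strain)
    allele = np.ones(M, dtype=np.int64) if allele is None else np.asarray(allele)
    traj = Trajectory(cfg, strain, allele)
    offsets = 0.05 * (np.arange(7) - 3.0)  # tiny chain, centroid = track point
    for s in range(S):
        pos = np.zeros((M, 7, 2))
        pos[:, :, 0] = (centroids[s, :, None, 0] + offsets[None, :]) % box
        pos[:, :, 1] = centroids[s, :, None, 1] % box
        traj._record(times[s], pos, np.zeros(M, dtype=np.int64),
                     np.zeros(M), np.zeros(M, dtype=bool))
    traj.bond_breaks = pd.DataFrame(
        columns=["bond_type", "formed_at", "broke_at", "lifetime_min"])
    return traj


def rotating_ring(n_agents=100, radius=10.0, center=(25.0, 25.0), box=50.0,
                  omega=0.05, n_snapshots=7, jitter=0.0, seed=0):
    """Tracks of agents on a ring rotating rigidly at ``omega`` rad/min
    (positive = counterclockwise)."""
    rng = np.random.default_rng(seed)
    phase = np.linspace(0.0, 2 * np.pi, n_agents, endpoint=False)
    radii = np.full(n_agents, radius) + jitter * rng.standard_normal(n_agents)
    out = np.empty((n_snapshots, n_agents, 2))
    for s in range(n_snapshots):
        ang = phase + omega * s
        out[s, :, 0] = center[0] + radii * np.cos(ang)
        out[s, :, 1] = center[1] + radii * np.sin(ang)
    return out % box
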