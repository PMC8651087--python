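"""Force model of the flexible gliding rod: reference implementations and
their agreement with the engine kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myxosim import SimulationConfig, StrainFraction, Simulation
from myxosim.mechanics import (
    AgentState,
    bending_forces,
    contact_repulsion,
    drag_forces,
    enforce_length,
    propulsion_forces,
    segment_distance,
    straight_agent,
    substrate_adhesion,
)


@pytest.fixture
def cfg():
    return SimulationConfig(L_sim=30.0, eta=1.0 / 900.0)


# ---------------------------------------------------------------- propulsion
class TestPropulsion:
    def test_straight_agent_along_x(self, cfg):
        agent = straight_agent(0, (5.0, 5.0), 0.0, cfg)  # head at +x end
        f = propulsion_forces(agent, cfg)
        mag = cfg.F_T / (cfg.N - 1)
        assert mag == pytest.approx(55.0 / 6.0)
        # every node except the tail pushes along +x
        for i in range(cfg.N - 1):
            assert f[i] == pytest.approx([mag, 0.0], abs=1e-12)
        assert f[agent.tail_index] == pytest.approx([0.0, 0.0])
        # total propulsion is F_T
        assert np.linalg.norm(f.sum(axis=0)) == pytest.approx(cfg.F_T)

    def test_active_turn_rotates_head_force_only(self, cfg):
        agent = straight_agent(0, (5.0, 5.0), 0.0, cfg)
        agent.turn_sign, agent.turn_remaining = 1, 0.5
        f = propulsion_forces(agent, cfg)
        mag = cfg.F_T / (cfg.N - 1)
        assert f[agent.head_index] == pytest.approx([0.0, mag], abs=1e-12)  # 90° CCW
        for i in range(1, cfg.N - 1):
            assert f[i] == pytest.approx([mag, 0.0], abs=1e-12)

    def test_degenerate_geometry_raises(self, cfg):
        agent = straight_agent(0, (5.0, 5.0), 0.0, cfg)
        agent.node_positions[1] = agent.node_positions[2]
        from myxosim.mechanics import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            propulsion_forces(agent, cfg)


# ---------------------------------------------------------------- drag
@pytest.mark.parametrize(
    "v, expected",
    [((0.0, 0.0), (0.0, 0.0)), ((1.0, 0.0), (-22.0, 0.0)), ((0.5, -2.0), (-11.0, 44.0))],
)
def test_drag_is_minus_c_v(v, expected):
    f = drag_forces(np.array([v]), 22.0)
    assert f[0] == pytest.approx(expected)
    assert drag_forces(2 * np.array([v]), 22.0)[0] == pytest.approx(
        2 * np.asarray(expected)
    )


# ---------------------------------------------------------------- bending
class TestBending:
    def test_straight_chain_has_no_bending_forces(self):
        x = np.column_stack([np.arange(7.0), np.zeros(7)])
        assert np.allclose(bending_forces(x, 10.0), 0.0)

    def test_single_joint_torque_matches_spring_constant(self):
        # three nodes, middle joint bent by 0.1 rad
        phi = 0.1
        x = np.array([[0.0, 0.0], [1.0, 0.0], [1.0 + np.cos(phi), np.sin(phi)]])
        f = bending_forces(x, 10.0)
        # force on the outer node is torque/arm, perpendicular to its segment
        torque = np.linalg.norm(f[2]) * 1.0
        assert torque == pytest.approx(10.0 * phi, rel=1e-12)

    @given(st.lists(st.floats(-0.8, 0.8), min_size=3, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_momentum_and_torque_neutral(self, turn_angles):
        # random wiggly chain built from successive turn angles
        angles = np.cumsum(turn_angles)
        steps = np.column_stack([np.cos(angles), np.sin(angles)])
        x = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        f = bending_forces(x, 10.0)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)
        torque = np.sum(x[:, 0] * f[:, 1] - x[:, 1] * f[:, 0])
        assert torque == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------- substrate
class TestSubstrateAdhesion:
    def test_node_at_anchor_gives_zero_force(self):
        f, anchor = substrate_adhesion((3.0, 3.0), (3.0, 3.0), (1.0, 0.0), 100.0, 0.5)
        assert np.allclose(f, 0.0)
        assert np.allclose(anchor, (3.0, 3.0))

    def test_transverse_displacement_restored(self):
        # body axis +x, displaced 0.3 μm in +y
        f, anchor = substrate_adhesion((0.0, 0.3), (0.0, 0.0), (1.0, 0.0), 100.0, 0.5)
        assert f == pytest.approx([0.0, -30.0])
        assert np.allclose(anchor, (0.0, 0.0))  # still attached

    def test_longitudinal_displacement_unresisted(self):
        f, _ = substrate_adhesion((0.4, 0.0), (0.0, 0.0), (1.0, 0.0), 100.0, 0.5)
        assert np.allclose(f, 0.0)

    def test_anchor_breaks_and_reattaches_at_threshold(self):
        f, anchor = substrate_adhesion((0.5, 0.0), (0.0, 0.0), (1.0, 0.0), 100.0, 0.5)
        assert np.allclose(f, 0.0)
        assert np.allclose(anchor, (0.5, 0.0))  # re-anchored at the node


# ---------------------------------------------------------------- repulsion
class TestContactRepulsion:
    def test_separated_agents_feel_nothing(self, cfg):
        a = straight_agent(0, (2.0, 2.0), 0.0, cfg)
        b = straight_agent(1, (2.0, 5.0), 0.0, cfg)
        forces = contact_repulsion([a, b], cfg)
        assert np.allclose(forces[0], 0.0) and np.allclose(forces[1], 0.0)

    def test_overlapping_parallel_agents_pushed_apart(self, cfg):
        a = straight_agent(0, (2.0, 2.0), 0.0, cfg)
        b = straight_agent(1, (2.0, 2.4), 0.0, cfg)  # centre-line gap 0.4 < w
        forces = contact_repulsion([a, b], cfg)
        assert forces[0][:, 1].sum() < 0  # a pushed −y
        assert forces[1][:, 1].sum() > 0  # b pushed +y
        # action–reaction over the isolated pair
        total = forces[0].sum(axis=0) + forces[1].sum(axis=0)
        assert np.allclose(total, 0.0, atol=1e-9)

    def test_overlap_relaxes_toward_contact_distance(self, cfg):
        cfg2 = cfg.replace(eta=2.0 / 900.0, tau_t=1e9,
                           slime_following_enabled=False, adhesion_enabled=False)
        sim = Simulation(cfg2, seed=3).initialize()
        # hand-place two parallel agents at 0.4 μm centre-line distance
        x = np.arange(7.0) + 5.0
        sim.pos[:7, 0] = x
        sim.pos[:7, 1] = 10.0
        sim.pos[7:14, 0] = x
        sim.pos[7:14, 1] = 10.4
        sim.anchors[:] = sim.pos
        sim.invalidate_neighbor_lists()
        sim.step(10)
        gap = abs(np.mean(sim.pos[7:14, 1]) - np.mean(sim.pos[:7, 1]))
        assert gap >= 0.45


# ---------------------------------------------------------------- length
class TestEnforceLength:
    def test_exact_chain_unchanged(self, cfg):
        agent = straight_agent(0, (2.0, 2.0), 0.3, cfg)
        before = agent.node_positions.copy()
        enforce_length(agent, cfg)
        assert np.allclose(agent.node_positions, before, atol=1e-12)

    def test_perturbed_spacing_restored(self, cfg):
        agent = straight_agent(0, (2.0, 2.0), 0.0, cfg)
        agent.node_positions[:, 0] *= 1.1  # stretch spacings to 1.1 μm
        com = agent.node_positions.mean(axis=0)
        enforce_length(agent, cfg)
        seg = np.linalg.norm(np.diff(agent.node_positions, axis=0), axis=1)
        assert np.all(np.abs(seg - 1.0) <= 0.01)
        length = seg.sum()
        assert abs(length - 6.0) <= 0.06
        assert np.allclose(agent.node_positions.mean(axis=0), com, atol=1e-9)


# ------------------------------------------------------- closed-form speed
def test_free_gliding_speed_matches_overdamped_closed_form(single_agent_sim):
    sim = single_agent_sim
    cfg = sim.cfg
    p0 = sim.pos.copy()
    n = int(round(1.0 / cfg.dt))
    sim.step(n)
    speed = np.linalg.norm((sim.pos - p0).mean(axis=0)) / sim.t
    assert speed == pytest.approx(cfg.free_speed, rel=0.01)


# ------------------------------------------------------- all-pairs oracle
def test_engine_forces_match_all_pairs_oracle():
    """Spatially-indexed engine repulsion equals a brute-force double loop
    over every segment pair, for a three-agent crossing fixture."""
    cfg = SimulationConfig(L_sim=30.0, eta=3.0 / 900.0, tau_t=1e9,
                           slime_following_enabled=False, adhesion_enabled=False,
                           k_a=1e-9)  # disable anchors: isolate repulsion
    sim = Simulation(cfg, seed=5).initialize()
    # overlapping arrangement: two parallel rods and one crossing diagonally
    placements = [((10.0, 10.0), 0.0), ((10.5, 10.42), 0.0), ((12.0, 8.5), np.pi / 3)]
    agents = []
    from myxosim.mechanics import straight_agent as mk

    for a, (origin, ang) in enumerate(placements):
        ag = mk(a, origin, ang, cfg)
        sim.pos[a * 7:(a + 1) * 7] = ag.node_positions
        agents.append(ag)
    sim.anchors[:] = sim.pos
    sim.head[:] = 0  # match the fixture agents' head designation
    sim.invalidate_neighbor_lists()
    sim.step(1)  # engine assembles forces once
    engine_forces = sim.forces.reshape(3, 7, 2)

    oracle = contact_repulsion(agents, cfg)
    # add the other force terms the engine includes for isolated agents
    for a, ag in enumerate(agents):
        oracle[a] = oracle[a] + propulsion_forces(ag, cfg) + bending_forces(
            ag.node_positions, cfg.k_b
        )
    for a in range(3):
        assert np.allclose(engine_forces[a], oracle[a], rtol=1e-9, atol=1e-9), a


# ------------------------------------------------------- segment distance
@pytest.mark.parametrize(
    "p0,p1,q0,q1,expected",
    [
        ((0, 0), (1, 0), (0, 1), (1, 1), 1.0),          # parallel
        ((0, 0), (2, 0), (1, -1), (1, 1), 0.0),          # crossing
        ((0, 0), (1, 0), (3, 0), (4, 0), 2.0),           # collinear, separated
        ((0, 0), (1, 0), (2, 1), (2, 2), np.sqrt(2.0)),  # endpoint-endpoint
    ],
)
def test_segment_distance_cases(p0, p1, q0, q1, expected):
    d, *_ = segment_distance(p0, p1, q0, q1)
    assert d == pytest.approx(expected, abs=1e-12)
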