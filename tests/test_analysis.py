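"""Trajectory analysis: reversal statistics, circular-aggregate detection,
radial kinematics, suppression summaries — on fixtures with known answers."""

import numpy as np
import pytest
from scipy import stats

from myxosim import SimulationConfig, StrainFraction, Simulation, run
from myxosim.analysis import (
    NoReversalsObserved,
    detect_aggregates,
    detect_reversals,
    mean_reversal_interval,
    radial_kinematics,
    suppression_stats,
)
from .conftest import rotating_ring, synthetic_trajectory


# ------------------------------------------------- mean reversal interval
class TestMeanReversalInterval:
    def test_tracked_population_worked_example(self):
        # 443 cells for 60 min with 12 events: one reversal per ~36.9 h
        assert mean_reversal_interval(443, 60.0, 12) == pytest.approx(36.9, abs=0.05)

    @pytest.mark.parametrize(
        "cells, minutes, events, hours",
        [(1, 60.0, 2, 0.5), (10, 80.0, 1, 13.33), (100, 60.0, 60, 1.6667)],
    )
    def test_hand_computed_cases(self, cells, minutes, events, hours):
        assert mean_reversal_interval(cells, minutes, events) == pytest.approx(
            hours, abs=0.01
        )

    def test_zero_events_flagged_not_numeric(self):
        with pytest.raises(NoReversalsObserved):
            mean_reversal_interval(443, 60.0, 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mean_reversal_interval(0, 60.0, 1)
        with pytest.raises(ValueError):
            mean_reversal_interval(10, -5.0, 1)


# ------------------------------------------------- reversal detection
class TestDetectReversals:
    def test_straight_track_has_no_events(self):
        pts = np.zeros((30, 1, 2))
        pts[:, 0, 0] = 2.0 + 0.4 * np.arange(30)
        traj = synthetic_trajectory(pts, box=50.0)
        assert len(detect_reversals(traj)) == 0

    def test_scripted_reversal_detected_at_turn_time(self):
        # out along +x for 30 min, then straight back
        fwd = 2.0 + 0.4 * np.arange(31)
        back = fwd[-1] - 0.4 * np.arange(1, 30)
        x = np.concatenate([fwd, back])
        pts = np.zeros((len(x), 1, 2))
        pts[:, 0, 0] = x
        traj = synthetic_trajectory(pts, box=50.0)
        events = detect_reversals(traj)
        assert len(events) == 1
        assert abs(events["time_min"].iloc[0] - 30.0) <= 1.0

    def test_right_angle_turn_is_not_a_reversal(self):
        x = np.concatenate([0.4 * np.arange(31), np.full(29, 12.0)])
        y = np.concatenate([np.zeros(31), 0.4 * np.arange(1, 30)])
        pts = np.stack([2.0 + x, 2.0 + y], axis=1)[:, None, :]
        traj = synthetic_trajectory(pts, box=50.0)
        assert len(detect_reversals(traj)) == 0

    def test_short_trajectory_warns_and_returns_empty(self):
        pts = np.zeros((2, 1, 2)) + 5.0
        traj = synthetic_trajectory(pts, box=50.0)
        with pytest.warns(UserWarning):
            events = detect_reversals(traj)
        assert len(events) == 0

    def test_detector_recovers_engine_logged_events(self):
        """Engine-logged reversals are recovered within ±1 snapshot on a
        dilute reversing population, with zero events on nonreversing
        agents.  Recall is bounded near ~92% by reversals that coincide
        with an active 90° head turn: their net direction change falls to
        125–149°, inside the band of large collision deflections, so no
        track-only rule can claim them without producing false positives
        on nonreversing agents."""
        cfg = SimulationConfig(L_sim=50.0, eta=10.0 / 2500.0, run_duration=60.0,
                               slime_following_enabled=False,
                               adhesion_enabled=False)
        traj = run(cfg, seed=21)
        logged = traj.reversal_events
        detected = detect_reversals(traj)
        assert len(logged) >= 50  # ~10 agents × 60/8
        hits = 0
        for _, ev in logged.iterrows():
            mine = detected[detected.agent_id == ev.agent_id]
            if np.any(np.abs(mine.time_min.to_numpy() - ev.time_min) <= 1.0 + 1e-9):
                hits += 1
        assert hits / len(logged) >= 0.90
        # no over-calling: detections do not exceed logged events
        assert len(detected) <= len(logged)

        nr_cfg = cfg.replace(strain_composition=[StrainFraction("NR", 1, 1.0)])
        nr_traj = run(nr_cfg, seed=22)
        assert len(detect_reversals(nr_traj)) == 0  # no false positives


# ------------------------------------------------- aggregate detection
class TestDetectAggregates:
    def test_ccw_ring_is_one_ca(self):
        traj = synthetic_trajectory(rotating_ring(omega=+0.05), box=50.0)
        reports = detect_aggregates(traj)
        assert len(reports) == 1
        (ca,) = reports
        assert ca.rotation_sense == "CCW"
        assert ca.rotational_order == pytest.approx(1.0, abs=0.01)
        assert ca.radius == pytest.approx(10.0, abs=0.3)
        assert np.allclose(ca.center, (25.0, 25.0), atol=0.3)
        assert len(ca.members) == 100

    def test_cw_ring_sense(self):
        traj = synthetic_trajectory(rotating_ring(omega=-0.05), box=50.0)
        (ca,) = detect_aggregates(traj)
        assert ca.rotation_sense == "CW"

    def test_random_motion_is_not_a_ca(self):
        rng = np.random.default_rng(3)
        start = rng.uniform(0, 50, (80, 2))
        vel = rng.normal(0, 0.4, (80, 2))
        pts = np.stack([start + s * vel for s in range(7)]) % 50.0
        traj = synthetic_trajectory(pts, box=50.0)
        for rep in detect_aggregates(traj):
            assert rep.rotational_order < 0.5
            assert rep.rotation_sense == "none"

    def test_empty_snapshot_gives_empty_report(self):
        traj = synthetic_trajectory(np.zeros((3, 0, 2)), box=50.0)
        assert detect_aggregates(traj) == []

    def test_translation_invariance(self):
        base = rotating_ring()
        shifted = (base + 7.3) % 50.0
        r1 = detect_aggregates(synthetic_trajectory(base, box=50.0))
        r2 = detect_aggregates(synthetic_trajectory(shifted, box=50.0))
        assert len(r1) == len(r2) == 1
        assert r1[0].rotational_order == pytest.approx(r2[0].rotational_order,
                                                       abs=1e-6)
        assert np.allclose((r1[0].center + 7.3) % 50.0, r2[0].center, atol=0.5)

    def test_cluster_straddling_periodic_boundary(self):
        traj = synthetic_trajectory(rotating_ring(center=(1.0, 49.0)), box=50.0)
        (ca,) = detect_aggregates(traj)
        assert ca.rotational_order > 0.95
        assert ca.radius == pytest.approx(10.0, abs=0.3)
        assert np.allclose(ca.center, (1.0, 49.0), atol=0.5)


# ------------------------------------------------- radial kinematics
class TestRadialKinematics:
    def _disc_tracks(self, omega=0.1, n_per_ring=40, radii=(3.0, 5.0, 7.0, 9.0)):
        tracks = []
        for rho in radii:
            ring = rotating_ring(n_agents=n_per_ring, radius=rho, omega=omega,
                                 n_snapshots=9)
            tracks.append(ring)
        return np.concatenate(tracks, axis=1)

    def test_rigid_disc_flat_angular_speed_linear_speed_proportional(self):
        omega = 0.1
        traj = synthetic_trajectory(self._disc_tracks(omega), box=50.0)
        (ca,) = detect_aggregates(traj)
        prof = radial_kinematics(traj, ca, bin_width=2.0, window_min=None,
                                 max_radius=11.0)
        assert np.allclose(prof.mean_angular_speed, omega, rtol=0.05)
        # linear speed grows like ω·r
        assert np.allclose(prof.mean_speed, omega * prof.bin_centers, rtol=0.15)

    def test_constant_speed_spiral_angular_speed_falls_as_inverse_radius(self):
        # same tangential speed on every ring: ω(ρ) = v/ρ
        v = 0.4
        tracks = []
        for rho in (3.0, 5.0, 7.0, 9.0):
            tracks.append(rotating_ring(n_agents=40, radius=rho, omega=v / rho,
                                        n_snapshots=9))
        traj = synthetic_trajectory(np.concatenate(tracks, axis=1), box=50.0)
        (ca,) = detect_aggregates(traj)
        prof = radial_kinematics(traj, ca, bin_width=2.0, window_min=None,
                                 max_radius=11.0)
        assert np.allclose(prof.mean_speed, v, rtol=0.05)
        rho_s = stats.spearmanr(prof.bin_centers, prof.mean_angular_speed)
        assert rho_s.statistic < 0
        assert np.allclose(prof.mean_angular_speed, v / prof.bin_centers,
                           rtol=0.15)

    def test_empty_bins_omitted(self):
        from myxosim.analysis import AggregateReport

        traj = synthetic_trajectory(self._disc_tracks(radii=(3.0, 9.0)), box=50.0)
        ca = AggregateReport(0, np.array([25.0, 25.0]), 9.0,
                             np.arange(traj.n_agents), "CCW", 1.0)
        prof = radial_kinematics(traj, ca, bin_width=2.0, window_min=None,
                                 max_radius=11.0)
        assert np.all(prof.counts >= 1)
        assert len(prof.bin_centers) == 2  # only the two populated rings


# ------------------------------------------------- suppression statistics
class TestSuppressionStats:
    def test_no_adhesion_means_no_suppression(self):
        cfg = SimulationConfig(L_sim=30.0, run_duration=10.0,
                               adhesion_enabled=False)
        traj = run(cfg, seed=23)
        frac, life = suppression_stats(traj)
        assert frac == 0.0 and np.isnan(life)

    def test_permanent_end_end_contact_suppresses_both_after_gate(self):
        cfg = SimulationConfig(L_sim=30.0, eta=2.0 / 900.0, run_duration=8.0,
                               tau_t=1e9, tau_r=1e6,
                               slime_following_enabled=False,
                               strain_composition=[StrainFraction("OE", 1, 1.0)])
        sim = Simulation(cfg, seed=24).initialize()
        # collinear head-to-tail pair, gap 1.0 μm, both gliding +x
        x = np.arange(7.0)
        sim.pos[:7, 0] = 5.0 + x
        sim.pos[7:, 0] = 12.0 + x
        sim.pos[:7, 1] = 15.0
        sim.pos[7:, 1] = 15.0
        sim.anchors[:] = sim.pos
        sim.head[:] = 6
        sim.invalidate_neighbor_lists()
        traj = sim.run()
        sup = traj.suppressed()
        assert not sup[4].any()          # bond younger than τ_thr
        assert sup[7].all()              # both partners suppressed after 5 min
        frac, _ = suppression_stats(traj)
        assert frac == 1.0

    def test_track_table_without_bond_log_raises(self):
        pts = np.zeros((5, 1, 2)) + 5.0
        traj = synthetic_trajectory(pts, box=50.0)
        traj.bond_breaks = None
        with pytest.raises(ValueError, match="bond"):
            suppression_stats(traj)
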