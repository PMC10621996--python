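"""Displacement-bounded linking against an exhaustive oracle; motility stats."""

from itertools import permutations

import numpy as np
import pytest

from lysotube import detection, synthetic_scenes as ss, tracking
from lysotube.tracking import Trajectory


def oracle_best_matching(pts_a, pts_b, max_disp):
    """Exhaustive optimum for one frame pair: most links, then least cost.

    Enumerates every injective partial assignment a->b within max_disp and
    returns (n_links, total squared cost) of the optimum.
    """
    n_a, n_b = len(pts_a), len(pts_b)
    best = (0, 0.0)
    idx_b = list(range(n_b)) + [None] * n_a  # None = unmatched
    seen = set()
    for perm in permutations(idx_b, n_a):
        if perm in seen:
            continue
        seen.add(perm)
        links, cost, ok = 0, 0.0, True
        for i, j in enumerate(perm):
            if j is None:
                continue
            d2 = float(((pts_a[i] - pts_b[j]) ** 2).sum())
            if d2 > max_disp**2:
                ok = False
                break
            links += 1
            cost += d2
        if not ok:
            continue
        if links > best[0] or (links == best[0] and cost < best[1]):
            best = (links, cost)
    return best


def _links_per_pair(tracks, n_frames):
    """(n_links, cost) per consecutive frame pair from linked trajectories."""
    out = {t: [0, 0.0] for t in range(n_frames - 1)}
    for tr in tracks:
        for k in range(len(tr) - 1):
            if tr.frames[k + 1] == tr.frames[k] + 1:
                t = int(tr.frames[k])
                d2 = float(((tr.positions[k + 1] - tr.positions[k]) ** 2).sum())
                out[t][0] += 1
                out[t][1] += d2
    return out


class TestMaxDisplacement:
    def test_tubular_lysosome_size_at_spinning_disk_pixels(self):
        assert tracking.max_displacement_px(2.4, 120.0) == 20

    @pytest.mark.parametrize(
        "size,px,expected", [(1.2, 120.0, 10), (2.4, 100.0, 24)]
    )
    def test_linearity(self, size, px, expected):
        assert tracking.max_displacement_px(size, px) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tracking.max_displacement_px(0.0, 120.0)


class TestLinkParticles:
    def test_single_stationary_particle(self):
        pts = [[(1.0, 1.0)]] * 5
        (track,) = tracking.link_particles(pts, max_disp=2.4)
        assert len(track) == 5
        assert track.path_length == 0.0

    def test_jump_beyond_max_disp_splits_track(self):
        pts = [
            [(1.0, 1.0)], [(1.1, 1.0)], [(8.0, 8.0)], [(8.1, 8.0)]
        ]
        tracks = tracking.link_particles(pts, max_disp=2.4)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [2, 2]

    def test_every_detection_in_exactly_one_track(self):
        rng = np.random.default_rng(3)
        pts = [rng.uniform(0, 10, size=(4, 2)) for _ in range(6)]
        tracks = tracking.link_particles(pts, max_disp=3.0)
        counts = {t: 0 for t in range(6)}
        for tr in tracks:
            for f in tr.frames:
                counts[int(f)] += 1
        assert all(counts[t] == len(pts[t]) for t in range(6))

    def test_crossing_particles_match_exhaustive_oracle(self):
        # 3 particles x 4 frames crossing paths
        pts = [
            np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 4.0]]),
            np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]]),
            np.array([[2.0, 2.0], [2.0, 1.0], [2.0, 3.5]]),
            np.array([[3.0, 3.0], [3.0, 0.5], [3.0, 4.0]]),
        ]
        tracks = tracking.link_particles(pts, max_disp=2.4)
        got = _links_per_pair(tracks, 4)
        for t in range(3):
            n, cost = oracle_best_matching(pts[t], pts[t + 1], 2.4)
            assert got[t][0] == n
            assert got[t][1] == pytest.approx(cost, rel=1e-9)

    def test_linking_equals_oracle_on_random_instances(self):
        # <=4 particles x 5 frames, 100 random instances
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = [
                rng.uniform(0, 6, size=(rng.integers(1, 5), 2))
                for _ in range(5)
            ]
            tracks = tracking.link_particles(pts, max_disp=2.0)
            got = _links_per_pair(tracks, 5)
            for t in range(4):
                n, cost = oracle_best_matching(pts[t], pts[t + 1], 2.0)
                assert got[t][0] == n, f"seed {seed}, pair {t}"
                assert got[t][1] == pytest.approx(cost, rel=1e-9)

    def test_memory_closes_gaps(self):
        pts = [[(1.0, 1.0)], [], [(1.2, 1.0)]]
        no_mem = tracking.link_particles(pts, max_disp=2.4, memory_frames=0)
        with_mem = tracking.link_particles(pts, max_disp=2.4, memory_frames=1)
        assert len(no_mem) == 2
        assert len(with_mem) == 1

    def test_particle_cap_enforced(self):
        pts = [np.zeros((10, 2)), np.zeros((10, 2))]
        with pytest.raises(ValueError, match="cap"):
            tracking.link_particles(pts, max_disp=1.0, particle_cap=5)


class TestTrajectoryMetrics:
    def test_constant_speed_track_is_fast(self):
        traj = Trajectory(
            0, np.arange(5), np.column_stack([np.arange(5) * 0.5, np.zeros(5)])
        )
        m = tracking.trajectory_metrics(traj, frame_interval_s=1.0)
        assert m.mean_speed_um_per_s == pytest.approx(0.5)
        assert m.fast  # > 0.3 um/s

    def test_static_track_not_motile(self):
        traj = Trajectory(0, np.arange(10), np.ones((10, 2)))
        m = tracking.trajectory_metrics(traj, 1.0)
        assert m.mean_speed_um_per_s == 0.0
        assert not m.fast and not m.motile

    def test_motile_threshold_on_path_length(self):
        # 1.3 um traveled over 60 s: motile but slow
        pos = np.column_stack([np.linspace(0, 1.3, 61), np.zeros(61)])
        m = tracking.trajectory_metrics(Trajectory(0, np.arange(61), pos), 1.0)
        assert m.motile and not m.fast

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            tracking.trajectory_metrics(
                Trajectory(0, [0], [(0.0, 0.0)]), 1.0
            )

    @pytest.mark.parametrize("speed", [0.1, 0.25, 0.5, 0.75, 1.0])
    def test_programmed_speed_recovered_within_5pct_zero_noise(self, speed):
        cfg = ss.SceneConfig(
            n_round=0, n_tubular=1, n_frames=20, noise_sd=0.0,
            jitter_sd_um=0.0, contact_fraction=0.0,
            motion_fractions=(0.0, 0.0, 1.0),
            directed_speed_um_per_s=speed, seed=4,
        )
        scene = ss.generate_scene(cfg)
        pts = []
        for t in range(cfg.n_frames):
            recs = detection.label_regions(
                detection.binarize_spots(scene.lysosome_stack[t]), 120.0
            )
            pts.append([(r.x_um, r.y_um) for r in recs])
        tracks = tracking.link_particles(pts, max_disp=2.4)
        main = max(tracks, key=len)
        m = tracking.trajectory_metrics(main, cfg.frame_interval_s)
        assert m.mean_speed_um_per_s == pytest.approx(speed, rel=0.05)

    @pytest.mark.parametrize("speed", [0.4, 1.0])
    def test_speed_recovered_within_15pct_at_snr5(self, speed):
        cfg = ss.SceneConfig(
            n_round=0, n_tubular=1, n_frames=20, noise_sd=0.2,
            jitter_sd_um=0.0, contact_fraction=0.0,
            motion_fractions=(0.0, 0.0, 1.0),
            directed_speed_um_per_s=speed, seed=4,
        )
        scene = ss.generate_scene(cfg)
        pts = []
        for t in range(cfg.n_frames):
            recs = detection.label_regions(
                detection.binarize_spots(scene.lysosome_stack[t]), 120.0
            )
            pts.append([(r.x_um, r.y_um) for r in recs])
        tracks = tracking.link_particles(pts, max_disp=2.4)
        main = max(tracks, key=len)
        m = tracking.trajectory_metrics(main, cfg.frame_interval_s)
        assert m.mean_speed_um_per_s == pytest.approx(speed, rel=0.15)


class TestTransitionSpeeds:
    @staticmethod
    def _speed_change_track():
        # steps 0..8 at 0.1 um/frame (round), steps 9.. at 0.6 (tubular)
        steps = [0.1] * 9 + [0.6] * 10
        x = np.concatenate([[0.0], np.cumsum(steps)])
        classes = ["round"] * 10 + ["tubular"] * 10
        return Trajectory(
            0, np.arange(20), np.column_stack([x, np.zeros(20)]),
            shape_classes=classes,
        )

    def test_always_round_track_has_no_events(self):
        traj = Trajectory(
            0, np.arange(5), np.zeros((5, 2)), shape_classes=["round"] * 5
        )
        assert tracking.transition_speeds(traj, 1.0) == []

    def test_constructed_round_to_tubular_event(self):
        events = tracking.transition_speeds(self._speed_change_track(), 1.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "round->tubular"
        assert ev.frame == 10
        assert ev.speed_before_um_per_s == pytest.approx(0.1)
        assert ev.speed_after_um_per_s == pytest.approx(0.6)
        assert ev.speed_before_um_per_s < ev.speed_after_um_per_s

    def test_two_alternating_changes_in_order(self):
        classes = ["round"] * 6 + ["tubular"] * 6 + ["round"] * 6
        pos = np.column_stack([np.arange(18) * 0.2, np.zeros(18)])
        events = tracking.transition_speeds(
            Trajectory(0, np.arange(18), pos, shape_classes=classes), 1.0
        )
        assert [e.direction for e in events] == [
            "round->tubular", "tubular->round"
        ]
        assert events[0].frame < events[1].frame

    def test_event_near_track_end_dropped_with_warning(self, caplog):
        import logging

        classes = ["round", "tubular", "tubular", "tubular"]
        pos = np.column_stack([np.arange(4) * 0.2, np.zeros(4)])
        with caplog.at_level(logging.WARNING):
            events = tracking.transition_speeds(
                Trajectory(0, np.arange(4), pos, shape_classes=classes), 1.0
            )
        assert events == []
        assert any("dropped" in r.message for r in caplog.records)
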