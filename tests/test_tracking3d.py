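"""3-D reconstruction: triangulation, association, gap bridging, role labels."""

import itertools

import numpy as np
import pytest

from delaysync.pipeline import make_trial
from delaysync.synthetic_data import (
    SWEEP_4S_SCHEDULE,
    Signal,
    project_scene,
)
from delaysync.sysid_freq import identify_frequency_domain
from delaysync.tracking3d import (
    AssociationConfig,
    KalmanConfig,
    Track3D,
    associate_frame,
    bridge_dropouts,
    segment_roles,
    triangulate,
)


def brute_force_assignment(detections, cameras, sigma):
    """Global-minimum assignment oracle: try every complete assignment of
    camera-1 detections to cross-camera combinations and every unmatched
    subset, minimizing total reprojection error."""
    n1 = len(detections[0])
    others = detections[1:]
    per_det = []
    for i in range(n1):
        opts = [(None, np.inf)]  # unmatched carries a large fixed cost
        for combo in itertools.product(*[range(len(d)) for d in others]):
            obs = [detections[0][i]] + [others[c][j] for c, j in enumerate(combo)]
            try:
                _, err = triangulate(obs, cameras)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if err < sigma:
                opts.append((combo, err))
        per_det.append(opts)
    best, best_cost = None, (-1, 0.0)
    for choice in itertools.product(*per_det):
        used = set()
        cost, valid, matched = 0.0, True, 0
        for combo, err in choice:
            if combo is None:
                continue
            for c, j in enumerate(combo):
                if (c, j) in used:
                    valid = False
                    break
                used.add((c, j))
            if not valid:
                break
            cost += err
            matched += 1
        if valid and (best is None or (matched, -cost) > best_cost):
            best, best_cost = choice, (matched, -cost)
    return best


def two_agent_scene(noise=0.0, seed=0, n_frames=30):
    t = np.arange(n_frames) / 120
    tr1 = np.stack(
        [0.1 * np.sin(3 * t), 0.05 * np.cos(4 * t), 0.15 + 0.02 * t], axis=1
    )
    tr2 = np.stack(
        [-0.1 + 0 * t, 0.1 * np.sin(2 * t), 0.1 + 0.01 * t], axis=1
    )
    return [tr1, tr2]


class TestTriangulate:
    def test_noise_free_roundtrip(self, cameras):
        X = np.array([0.07, -0.03, 0.12])
        obs = [cam.project(X)[0] for cam in cameras]
        Xr, err = triangulate(obs, cameras)
        assert np.linalg.norm(Xr - X) < 1e-10
        assert err < 1e-8

    def test_mixed_agents_give_large_error(self, cameras):
        A = np.array([0.2, 0.0, 0.1])
        B = np.array([-0.2, 0.1, 0.3])
        obs = [cameras[0].project(A)[0], cameras[1].project(B)[0], cameras[2].project(A)[0]]
        _, err = triangulate(obs, cameras)
        assert err > 10 * AssociationConfig().sigma

    def test_needs_two_cameras(self, cameras):
        with pytest.raises(ValueError):
            triangulate([cameras[0].project(np.zeros(3))[0], None, None], cameras)

    def test_noisy_error_below_monte_carlo_bound(self, cameras, rng):
        """0.5 px pixel noise: 3-D error stays within the MC-derived bound."""
        X = np.array([0.05, 0.02, 0.2])
        clean = [cam.project(X)[0] for cam in cameras]
        errs = []
        for _ in range(200):
            obs = [p + rng.normal(0, 0.5, 2) for p in clean]
            Xr, _ = triangulate(obs, cameras)
            errs.append(np.linalg.norm(Xr - X))
        # bound: 5x the MC mean of an independent replicate set
        errs2 = []
        for _ in range(200):
            obs = [p + rng.normal(0, 0.5, 2) for p in clean]
            Xr, _ = triangulate(obs, cameras)
            errs2.append(np.linalg.norm(Xr - X))
        assert np.max(errs) < 5 * np.mean(errs2) + 1e-6


class TestAssociation:
    def test_single_agent_noise_free(self, cameras):
        frames = project_scene(two_agent_scene()[:1], cameras, seed=0)
        res = associate_frame(frames.points[0], cameras, AssociationConfig())
        assert res[0] is not None and res[0]["error"] < 1e-6

    def test_sigma_zero_unmatches_everything(self, cameras):
        frames = project_scene(two_agent_scene(), cameras, seed=0)
        res = associate_frame(frames.points[0], cameras, AssociationConfig(sigma=0.0))
        assert all(r is None for r in res)

    def test_matches_brute_force_on_small_frames(self, cameras):
        cfg = AssociationConfig(sigma=3.0)
        frames = project_scene(
            two_agent_scene(), cameras, pixel_noise_sd=0.5, seed=7
        )
        for k in range(len(frames)):
            greedy = associate_frame(frames.points[k], cameras, cfg)
            oracle = brute_force_assignment(frames.points[k], cameras, cfg.sigma)
            for g, o in zip(greedy, oracle):
                if g is None:
                    assert o[0] is None
                else:
                    assert g["combo"] == o[0]

    def test_identity_recovery_above_99_percent(self, cameras):
        tracks = two_agent_scene(n_frames=120)
        frames = project_scene(tracks, cameras, pixel_noise_sd=0.5, seed=1)
        cfg = AssociationConfig(sigma=3.0)
        ok = total = 0
        for k in range(len(frames)):
            ids1 = frames.truth_ids[k][0]
            for i, r in enumerate(associate_frame(frames.points[k], cameras, cfg)):
                if r is None:
                    continue
                total += 1
                truth = tracks[ids1[i]][k]
                ok += np.linalg.norm(r["point"] - truth) < 0.02
        assert total > 0 and ok / total > 0.99


class TestKalmanBridging:
    def test_constant_velocity_gap_filled(self):
        n = 60
        t = np.arange(n) / 60
        pos = np.stack([0.5 * t, -0.2 * t, 0.1 + 0 * t], axis=1)
        valid = np.ones(n, bool)
        valid[30:33] = False
        cfg = KalmanConfig()
        out = bridge_dropouts(Track3D(t=t, positions=pos, valid=valid), cfg)
        assert out.imputed[30:33].all()
        assert np.abs(out.positions[30:33] - pos[30:33]).max() < 2 * cfg.epsilon

    def test_infinite_measurement_noise_ignores_data(self):
        """epsilon -> infinity: the filter never corrects, so a gap is filled
        by extrapolating the initial straight line even though intervening
        measurements bent away from it."""
        n = 60
        t = np.arange(n) / 60
        x = t.copy()
        x[10:] = t[10:] + 0.5 * (t[10:] - t[10]) ** 2  # bends upward
        pos = np.stack([x, 0 * t, 0 * t], axis=1)
        valid = np.ones(n, bool)
        valid[40:44] = False
        blind = bridge_dropouts(
            Track3D(t=t, positions=pos, valid=valid),
            KalmanConfig(epsilon=1e9, epsilon_a=1e-6),
        )
        # ignores the bend: continues the init line x = t
        assert np.abs(blind.positions[40:44, 0] - t[40:44]).max() < 1e-3
        aware = bridge_dropouts(
            Track3D(t=t, positions=pos, valid=valid), KalmanConfig()
        )
        # with finite noise scales the bend is followed instead
        assert np.abs(aware.positions[40:44, 0] - x[40:44]).max() < np.abs(
            blind.positions[40:44, 0] - x[40:44]
        ).max()

    def test_filtering_leaves_identified_delay_unchanged(self, model_3p3z):
        """Kalman smoothing on a clean track shifts the delay by < 2 ms.

        The filter's noise scales (epsilon = 0.2, epsilon_a = 0.8) are
        detection-accuracy scales, appropriate where trajectory excursions
        are hundreds of units (pixels); the track is expressed at that scale.
        """
        px_per_m = 3000.0
        stim, resp = make_trial(model_3p3z, SWEEP_4S_SCHEDULE, 4.0)
        n = len(resp)
        t = np.arange(n) / resp.fs
        track = Track3D(
            t=t,
            positions=np.stack([px_per_m * resp.samples, 0 * t, 0 * t], axis=1),
            valid=np.ones(n, bool),
        )
        # drop a few frames so the filter actually intervenes
        track.valid[200:204] = False
        filt = bridge_dropouts(track, KalmanConfig())
        filt_x = Signal(filt.positions[:, 0] / px_per_m, fs=resp.fs)
        raw_model, _ = identify_frequency_domain(stim, resp, orders=[(3, 3)])
        filt_model, _ = identify_frequency_domain(stim, filt_x, orders=[(3, 3)])
        assert abs(raw_model.tau - filt_model.tau) < 0.002


class TestSegmentRoles:
    def test_single_track_is_solo(self, model_3p3z):
        stim, resp = make_trial(model_3p3z, SWEEP_4S_SCHEDULE, 4.0)
        n = len(resp)
        t = np.arange(n) / resp.fs
        tr = Track3D(
            t=t,
            positions=np.stack([resp.samples, 0 * t, 0 * t], axis=1),
            valid=np.ones(n, bool),
        )
        assert segment_roles([tr]) == ["solo"]

    def test_shared_stimulus_labels_group(self, model_3p3z, model_2p1z):
        stim, r1 = make_trial(model_3p3z, SWEEP_4S_SCHEDULE, 4.0, snr=50, seed=1)
        _, r2 = make_trial(model_2p1z, SWEEP_4S_SCHEDULE, 4.0, snr=50, seed=2)
        n = len(r1)
        t = np.arange(n) / r1.fs
        tracks = [
            Track3D(
                t=t,
                positions=np.stack([r.samples, 0 * t, 0 * t], axis=1),
                valid=np.ones(n, bool),
                label=i,
            )
            for i, r in enumerate((r1, r2))
        ]
        assert segment_roles(tracks, band_hz=(0.0, 5.0)) == ["group", "group"]

    def test_independent_noise_tracks_are_solo(self, rng):
        n = 480
        t = np.arange(n) / 120
        tracks = [
            Track3D(
                t=t,
                positions=np.stack([rng.normal(0, 1, n), 0 * t, 0 * t], axis=1),
                valid=np.ones(n, bool),
                label=i,
            )
            for i in range(2)
        ]
        assert segment_roles(tracks) == ["solo", "solo"]
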