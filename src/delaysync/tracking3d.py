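"""Multi-agent 3-D reconstruction from multi-camera pixel detections.

Data association enumerates, for every detection in camera 1, all
c = m^(N_c - 1) combinations of detections in the remaining cameras,
triangulates each combination by DLT, and accepts the minimum-reprojection-
error combination when that error is below the desired accuracy sigma.
Transient dropouts in the reconstructed tracks are bridged by a per-axis
constant-acceleration Kalman filter, and tracks are segmented into solo and
group roles by pairwise magnitude-squared coherence of their x coordinates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_data import CameraModel, DetectionFrames, Signal

__all__ = [
    "AssociationConfig",
    "KalmanConfig",
    "Track3D",
    "triangulate",
    "associate_frame",
    "associate_scene",
    "bridge_dropouts",
    "segment_roles",
]


@dataclass
class AssociationConfig:
    """sigma: desired reprojection accuracy in pixels."""

    sigma: float = 3.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class KalmanConfig:
    """Position noise scale epsilon and acceleration noise scale epsilon_a."""

    epsilon: float = 0.2
    epsilon_a: float = 0.8

    def __post_init__(self):
        if self.epsilon <= 0 or self.epsilon_a <= 0:
            raise ValueError("noise scales must be positive")


@dataclass
class Track3D:
    """Reconstructed 3-D trajectory with per-sample validity flags."""

    t: np.ndarray
    positions: np.ndarray  # (n, 3); rows with valid=False are ignored
    valid: np.ndarray
    label: int = 0
    imputed: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time base must be strictly increasing")
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros_like(self.valid)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def x_signal(self) -> Signal:
        return Signal(samples=self.positions[:, 0], fs=self.fs, t0=float(self.t[0]))


def triangulate(
    observations: list[np.ndarray | None], cameras: list[CameraModel]
) -> tuple[np.ndarray, float]:
    """Linear (DLT) triangulation of one 2-D point per observing camera.

    ``observations[c]`` is the pixel point seen by camera c or None.
    Returns the 3-D point and the mean Euclidean reprojection error in
    pixels over the observing cameras.
    """
    rows = []
    used = []
    for obs, cam in zip(observations, cameras):
        if obs is None:
            continue
        u, v = float(obs[0]), float(obs[1])
        P = cam.P
        rows.append(u * P[2] - P[0])
        rows.append(v * P[2] - P[1])
        used.append((obs, cam))
    if len(used) < 2:
        raise ValueError("triangulation needs at least two observing cameras")
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise np.linalg.LinAlgError("rank-deficient triangulation (parallel rays)")
    Xh = vt[-1]
    if abs(Xh[3]) < 1e-14:
        raise np.linalg.LinAlgError("point at infinity")
    X = Xh[:3] / Xh[3]
    errs = []
    for obs, cam in used:
        uv, ok = cam.project(X)
        errs.append(np.linalg.norm(uv - np.asarray(obs, dtype=float)) if ok else np.inf)
    return X, float(np.mean(errs))


def associate_frame(
    detections: list[np.ndarray],
    cameras: list[CameraModel],
    cfg: AssociationConfig,
) -> list[dict | None]:
    """Associate each camera-1 detection with one detection per other camera.

    All cross-camera combinations are triangulated and reprojected; the
    minimum-error combination is kept if its error is below sigma.  Each
    non-camera-1 detection is used at most once, assigned greedily in order
    of ascending reprojection error.  Returns one entry per camera-1
    detection: a dict with the chosen combination, 3-D point and error, or
    None if unmatched.
    """
    cam1 = detections[0]
    n1 = len(cam1)
    others = detections[1:]

    candidates = []  # (error, cam1 index, combo indices, X)
    for i in range(n1):
        pools = []
        for dets in others:
            idxs = list(range(len(dets)))
            pools.append(idxs if idxs else [None])
        for combo in itertools.product(*pools):
            obs = [cam1[i]] + [
                others[c][j] if j is not None else None for c, j in enumerate(combo)
            ]
            try:
                X, err = triangulate(obs, cameras)
            except (ValueError, np.linalg.LinAlgError):
                continue
            candidates.append((err, i, combo, X))

    candidates.sort(key=lambda c: c[0])
    assigned: list[dict | None] = [None] * n1
    used = [set() for _ in others]
    for err, i, combo, X in candidates:
        if assigned[i] is not None or err >= cfg.sigma:
            continue
        if any(j is not None and j in used[c] for c, j in enumerate(combo)):
            continue
        assigned[i] = {"combo": combo, "point": X, "error": err}
        for c, j in enumerate(combo):
            if j is not None:
                used[c].add(j)
    return assigned


def associate_scene(
    frames: DetectionFrames,
    cameras: list[CameraModel],
    cfg: AssociationConfig,
    n_agents: int,
) -> list[Track3D]:
    """Frame-by-frame association into fixed-identity tracks.

    Identities follow camera-1 detection order within each frame, matched to
    the previous frame's reconstructed points by nearest neighbor.  Intended
    for the small synthetic scenes used in testing, not general tracking.
    """
    n_t = len(frames)
    pos = np.full((n_t, n_agents, 3), np.nan)
    valid = np.zeros((n_t, n_agents), dtype=bool)
    last = [None] * n_agents
    for k in range(n_t):
        res = associate_frame(frames.points[k], cameras, cfg)
        pts = [r["point"] for r in res if r is not None]
        taken = set()
        for X in pts:
            # match to nearest previously seen identity, else first free slot
            best, best_d = None, np.inf
            for a in range(n_agents):
                if a in taken:
                    continue
                d = 1e3 if last[a] is None else np.linalg.norm(X - last[a])
                if d < best_d:
                    best, best_d = a, d
            if best is not None:
                pos[k, best] = X
                valid[k, best] = True
                last[best] = X
                taken.add(best)
    t = frames.t
    return [
        Track3D(t=t, positions=pos[:, a], valid=valid[:, a], label=a)
        for a in range(n_agents)
    ]


def _kalman_matrices(dt: float, cfg: KalmanConfig):
    F = np.array([[1.0, dt, dt * dt / 2], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    g = np.array([dt * dt / 2, dt, 1.0])
    Q = cfg.epsilon_a**2 * np.outer(g, g)
    H = np.array([[1.0, 0.0, 0.0]])
    R = np.array([[cfg.epsilon**2]])
    return F, Q, H, R


def bridge_dropouts(track: Track3D, cfg: KalmanConfig) -> Track3D:
    """Fill dropout gaps by per-axis constant-acceleration Kalman prediction.

    Measurement noise covariance is epsilon^2, process noise epsilon_a^2 on
    the acceleration channel.  The filter runs along the whole track but
    only transient dropouts receive its output: measured samples pass
    through unchanged (bridging, not smoothing), gap samples are filled
    with the prediction and flagged as imputed.  A gap before the second
    valid sample is left unfilled.
    """
    first = np.flatnonzero(track.valid)
    if first.size < 2:
        raise ValueError("track needs at least two valid samples before a gap")
    dt = 1.0 / track.fs
    F, Q, H, R = _kalman_matrices(dt, cfg)
    n = len(track.t)
    out = track.positions.copy()
    imputed = track.imputed.copy()
    new_valid = track.valid.copy()

    start = first[1]  # initialize with the first two valid samples
    for axis in range(3):
        z = track.positions[:, axis]
        i0, i1 = first[0], first[1]
        v0 = (z[i1] - z[i0]) / ((i1 - i0) * dt)
        x = np.array([z[i1], v0, 0.0])
        P = 10.0 * Q + np.diag([0.0, 0.0, cfg.epsilon_a**2])
        for k in range(start + 1, n):
            x = F @ x
            P = F @ P @ F.T + Q
            if track.valid[k]:
                y = z[k] - H @ x
                S = H @ P @ H.T + R
                K = P @ H.T @ np.linalg.inv(S)
                x = x + (K @ y).ravel()
                P = (np.eye(3) - K @ H) @ P
            else:
                out[k, axis] = x[0]
                imputed[k] = True
                new_valid[k] = True
    return Track3D(
        t=track.t,
        positions=out,
        valid=new_valid,
        label=track.label,
        imputed=imputed,
    )


def segment_roles(
    tracks: list[Track3D],
    band_hz: tuple[float, float] = (0.0, 5.0),
    threshold: float = 0.6,
) -> list[str]:
    """Label each track 'group' or 'solo' by pairwise x-coordinate coherence.

    A track is 'group' when the mean magnitude-squared coherence of its x
    coordinate with any concurrent track exceeds the threshold over the
    band; isolated or too-short tracks are 'solo'.
    """
    labels = ["solo"] * len(tracks)
    if len(tracks) < 2:
        return labels
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            both = tracks[i].valid & tracks[j].valid
            n_common = int(both.sum())
            # half-record segments: slow tracking dynamics leak across
            # segment edges and deflate coherence when segments are short
            nper = n_common // 2
            if n_common < 32 or nper < 8:
                warnings.warn(
                    "tracks too short for a coherence window; labeling solo",
                    RuntimeWarning,
                )
                continue
            fs = tracks[i].fs
            xi = tracks[i].positions[both, 0]
            xj = tracks[j].positions[both, 0]
            f, coh = sps.coherence(
                xi, xj, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2
            )
            sel = (f > 0) & (f >= band_hz[0]) & (f <= band_hz[1])
            if sel.any() and float(np.mean(coh[sel])) > threshold:
                labels[i] = labels[j] = "group"
    return labels
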