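"""Delayed attraction-repulsion swarm model and its mean-field reduction.

Each of N planar agents integrates

    dx_i/dt = -(1/N) * sum_{j != i} (alpha x_i(t) - beta x_j(t - tau_ij))
              - grad_i A^r,

where alpha weights the agent's own (egocentric) position, beta the delayed
neighbor positions, and A^r is a short-range exponential repulsion acting on
the weighted difference r_ij = ||alpha x_i - beta x_j(t - tau_ij)||:

    -grad_i A^r = sum_j (alpha B_r / D_r) exp(-r_ij / D_r)
                  * (alpha x_i - beta x_j(t - tau_ij)) / r_ij.

Averaging over agents and delays collapses the swarm center C(t) onto the
scalar distributed-delay equation

    dC/dt = -alpha C(t) + beta * integral C(t - tau) g(tau) dtau,

with g the delay density.  Both levels are integrated by fixed-step explicit
Euler with constant pre-history, delays quantized to the step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import roots_genlaguerre

from .delay_dist import ShiftedGamma

__all__ = [
    "SwarmParams",
    "DelayMatrix",
    "SwarmTrajectory",
    "interaction_drift",
    "simulate_swarm",
    "swarm_center",
    "simulate_meanfield",
    "meanfield_delay_atoms",
    "delay_matrix_from_dist",
]

_DIVERGENCE_NORM = 1e6
#: trailing-window relative drift below this counts as "settled"
SETTLE_TOL = 1e-3


@dataclass
class SwarmParams:
    alpha: float
    beta: float
    B_r: float = 0.0
    D_r: float = 1.0
    N: int = 30

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("need at least two agents")
        if self.D_r <= 0 or self.B_r < 0:
            raise ValueError("need D_r > 0 and B_r >= 0")


@dataclass
class DelayMatrix:
    """Pairwise delays tau_ij (delay agent i applies to neighbor j).

    ``mode`` records how the matrix was sampled: ``per_pair`` (i.i.d. per
    ordered pair) or ``per_agent_observer`` (tau_ij = tau_i for all j).
    """

    tau: np.ndarray
    mode: str = "per_pair"

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 2 or self.tau.shape[0] != self.tau.shape[1]:
            raise ValueError("delay matrix must be square")
        off = ~np.eye(self.tau.shape[0], dtype=bool)
        if np.any(self.tau[off] < 0):
            raise ValueError("delays must be nonnegative")


def delay_matrix_from_dist(
    dist: ShiftedGamma, N: int, seed: int = 0, mode: str = "per_pair"
) -> DelayMatrix:
    """Sample a delay matrix from a shifted gamma distribution."""
    rng = np.random.default_rng(seed)
    if mode == "per_pair":
        tau = dist.tau_m + rng.gamma(dist.m, 1.0 / dist.a, size=(N, N))
    elif mode == "per_agent_observer":
        tau_i = dist.tau_m + rng.gamma(dist.m, 1.0 / dist.a, size=N)
        tau = np.tile(tau_i[:, None], (1, N))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    np.fill_diagonal(tau, 0.0)
    return DelayMatrix(tau=tau, mode=mode)


@dataclass
class SwarmTrajectory:
    t: np.ndarray
    positions: np.ndarray  # (n_steps, N, 2)
    params: SwarmParams
    delays: DelayMatrix
    diverged: bool = False
    truncated_at: float | None = None


def _drift(
    history: np.ndarray,
    k: int,
    delay_steps: np.ndarray,
    params: SwarmParams,
) -> np.ndarray:
    """Drift of every agent at history index k (vectorized over agent pairs)."""
    N = params.N
    idx = np.arange(N)
    xd = history[k - delay_steps, idx[None, :], :]  # x_j(t - tau_ij), (N, N, 2)
    diff = params.alpha * history[k][:, None, :] - params.beta * xd
    diff[idx, idx, :] = 0.0
    drift = -diff.sum(axis=1) / N
    if params.B_r > 0:
        r = np.linalg.norm(diff, axis=2)
        r[idx, idx] = np.inf
        w = (params.alpha * params.B_r / params.D_r) * np.exp(-r / params.D_r) / r
        w[r < 1e-9] = 0.0  # guard near-coincident weighted positions
        drift += (w[:, :, None] * diff).sum(axis=1)
    return drift


def interaction_drift(
    history: np.ndarray,
    params: SwarmParams,
    delays: DelayMatrix,
    dt: float,
    t_index: int | None = None,
) -> np.ndarray:
    """Velocity of every agent given a position history on a dt grid.

    ``history`` is (n_hist, N, 2) with the last row the current state (or
    row ``t_index`` if given).  Delays are quantized to the dt grid; the
    history must reach back at least max(tau)/dt steps.
    """
    k = history.shape[0] - 1 if t_index is None else t_index
    d = np.maximum(np.round(delays.tau / dt).astype(int), 0)
    np.fill_diagonal(d, 0)
    if k - d.max() < 0:
        raise ValueError("history does not cover the largest delay")
    return _drift(history, k, d, params)


def simulate_swarm(
    params: SwarmParams,
    delays: DelayMatrix,
    init_positions: np.ndarray,
    T: float,
    dt: float,
    seed: int = 0,
) -> SwarmTrajectory:
    """Fixed-step explicit Euler integration with constant pre-history.

    Pre-history is x_i(t < 0) = x_i(0).  A state norm above 1e6 (or any
    non-finite value) flags divergence and truncates the run.
    """
    x0 = np.asarray(init_positions, dtype=float)
    if x0.shape != (params.N, 2):
        raise ValueError(f"init_positions must have shape ({params.N}, 2)")
    pos_tau = delays.tau[delays.tau > 0]
    if pos_tau.size and dt > pos_tau.min() + 1e-12:
        warnings.warn(
            "dt exceeds the smallest positive delay; delays are quantized to dt",
            RuntimeWarning,
        )
    d = np.maximum(np.round(delays.tau / dt).astype(int), 0)
    np.fill_diagonal(d, 0)
    H = int(d.max())
    n = int(round(T / dt))
    X = np.empty((n + 1 + H, params.N, 2))
    X[: H + 1] = x0

    diverged = False
    trunc = None
    for k in range(H, H + n):
        v = _drift(X, k, d, params)
        X[k + 1] = X[k] + dt * v
        if not np.all(np.isfinite(X[k + 1])) or np.max(np.abs(X[k + 1])) > _DIVERGENCE_NORM:
            diverged = True
            trunc = (k + 1 - H) * dt
            X[k + 2 :] = X[k + 1]
            n = k + 1 - H
            X = X[: H + n + 1]
            break
    t = np.arange(n + 1) * dt
    return SwarmTrajectory(
        t=t,
        positions=X[H:],
        params=params,
        delays=delays,
        diverged=diverged,
        truncated_at=trunc,
    )


def swarm_center(traj: SwarmTrajectory) -> tuple[np.ndarray, np.ndarray, bool]:
    """Swarm barycenter C(t), its norm, and a settling verdict.

    The swarm center is judged settled when the trailing 20% of ||C(t)||
    drifts by less than SETTLE_TOL relative to its mean (and the run did
    not diverge).
    """
    C = traj.positions.mean(axis=1)
    norm = np.linalg.norm(C, axis=1)
    tail = norm[int(0.8 * len(norm)) :]
    scale = max(float(np.mean(tail)), 1e-12)
    settled = (not traj.diverged) and float(np.ptp(tail)) / scale < SETTLE_TOL
    return C, norm, settled


def meanfield_delay_atoms(dist: ShiftedGamma, Q: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature of the delay density into Q atoms (delays, weights).

    Uses generalized Gauss-Laguerre nodes, exact for the gamma kernel:
    integral f(tau) g(tau) dtau = sum_q w_q f(tau_m + s_q / a).
    """
    x, w = roots_genlaguerre(Q, dist.m - 1.0)
    if not np.all(np.isfinite(w)):
        raise ValueError("quadrature weights overflow; shape m too large for Q atoms")
    # raw weights sum to Gamma(m); normalizing by the sum is exact and avoids
    # overflow of Gamma(m) itself for large shapes
    return dist.tau_m + x / dist.a, w / w.sum()


def simulate_meanfield(
    alpha: float,
    beta: float,
    dist: ShiftedGamma,
    C0: float = 1.0,
    T: float = 50.0,
    dt: float | None = None,
    Q: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler integration of dC/dt = -alpha C + beta * sum_q w_q C(t - tau_q).

    Constant pre-history C(t <= 0) = C0.  Returns (t, C).
    """
    taus, w = meanfield_delay_atoms(dist, Q=Q)
    if dt is None:
        # explicit Euler: keep rate*dt small so the decay error stays ~1%
        dt = min(
            dist.tau_m / 10.0 if dist.tau_m > 0 else dist.mean / 20.0,
            0.004 / max(abs(alpha), abs(beta), 1.0),
        )
    d = np.maximum(np.round(taus / dt).astype(int), 1)
    H = int(d.max())
    n = int(round(T / dt))
    C = np.empty(n + 1 + H)
    C[: H + 1] = C0
    for k in range(H, H + n):
        cbar = float(np.dot(w, C[k - d]))
        C[k + 1] = C[k] + dt * (-alpha * C[k] + beta * cbar)
        if not np.isfinite(C[k + 1]) or abs(C[k + 1]) > _DIVERGENCE_NORM:
            C[k + 2 :] = C[k + 1]
            break
    t = np.arange(n + 1) * dt
    return t, C[H:]
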