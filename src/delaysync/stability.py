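"""Mean-field linear stability of the distributed-delay swarm center.

The scalar mean-field equation dC/dt = -alpha C + beta * int C(t-tau) g(tau)
has characteristic equation

    F(lambda) = lambda + alpha - beta exp(-lambda tau_m) a^m/(a+lambda)^m = 0.

Stability is lost when a root crosses the imaginary axis.  Two crossing
mechanisms exist: a real root through lambda = 0 (on the line alpha = beta)
and Hopf crossings at lambda = +/- i omega.  Setting lambda = i omega and
theta = atan(omega/a), the Hopf locus solves

    alpha(omega) = -omega / tan(omega tau_m + m theta)
    beta(omega)  = -omega / (cos^m(theta) sin(omega tau_m + m theta)).

The two published rearrangements of this locus disagree in the sign of the
m*theta term inside alpha's tangent; rather than trusting either, both are
evaluated and every candidate point is validated against F(i omega) = 0
(which is linear in (alpha, beta), so the validated solve is exact).  For
the fitted delay distributions the Hopf locus lies strictly above the
diagonal (any imaginary-axis crossing needs beta >= sqrt(alpha^2+omega^2) /
cos^m(theta) > alpha), so in the positive quadrant the operative stability
boundary is the lambda = 0 line; region classification therefore counts
right-half-plane roots of F by the argument principle rather than testing
sides of the Hopf curve alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delay_dist import ShiftedGamma
from .swarm_dde import meanfield_delay_atoms

__all__ = [
    "StabilityContour",
    "char_residual",
    "hopf_contour",
    "classify_stability",
    "rhp_root_count",
    "stability_boundary_beta",
    "region_map",
]

RESIDUAL_TOL = 1e-8


def char_residual(lam, alpha: float, beta: float, dist: ShiftedGamma):
    """Literal left-hand side of the characteristic equation F(lambda)."""
    lam = np.asarray(lam, dtype=complex)
    if np.any(np.abs(lam + dist.a) < 1e-12):
        raise ValueError("characteristic function has a branch pole at lambda = -a")
    g = np.exp(-lam * dist.tau_m) * (dist.a / (dist.a + lam)) ** dist.m
    out = lam + alpha - beta * g
    return out if out.ndim else complex(out)


@dataclass
class StabilityContour:
    """Parametric Hopf locus (alpha(omega), beta(omega)) for one distribution."""

    omega: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    residual: np.ndarray
    dist: ShiftedGamma
    branch: np.ndarray  # which printed rearrangement each point matched

    def primary_branch(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(omega, alpha, beta) of the lowest-frequency positive-quadrant branch.

        The Hopf locus repeats in higher phase windows; the first branch is
        the one that bounds the stable region from above in beta.
        """
        sel = np.flatnonzero((self.alpha > 0) & (self.beta > 0))
        if sel.size == 0:
            raise ValueError("no contour points in the positive quadrant")
        # first contiguous run of omega-ordered indices
        breaks = np.flatnonzero(np.diff(sel) > 1)
        end = sel.size if breaks.size == 0 else breaks[0] + 1
        idx = sel[:end]
        return self.omega[idx], self.alpha[idx], self.beta[idx]

    def beta_at(self, alpha: float) -> float:
        """Hopf beta at given alpha on the primary positive-quadrant branch."""
        _, a, b = self.primary_branch()
        order = np.argsort(a)
        return float(np.interp(alpha, a[order], b[order]))


def _exact_hopf_point(omega: float, dist: ShiftedGamma) -> tuple[float, float]:
    """(alpha, beta) solving F(i omega) = 0 — linear in the two unknowns."""
    g = np.exp(-1j * omega * dist.tau_m) * (dist.a / (dist.a + 1j * omega)) ** dist.m
    if abs(g.imag) < 1e-300:
        return np.nan, np.nan
    beta = omega / g.imag
    alpha = beta * g.real
    return float(alpha), float(beta)


def hopf_contour(
    dist: ShiftedGamma,
    omega_grid: np.ndarray | None = None,
    beta_max: float = 1e4,
) -> StabilityContour:
    """Residual-validated Hopf boundary over an omega grid.

    Both printed closed forms (differing in the sign of the m*atan(omega/a)
    term inside alpha's tangent) are computed; a candidate is retained from
    whichever form satisfies |F(i omega)| < 1e-8, and points where neither
    passes are resolved by the exact linear solve in (alpha, beta).  Points
    with unbounded beta are dropped.
    """
    if omega_grid is None:
        omega_grid = np.logspace(-3, np.log10(50.0), 400)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0):
        raise ValueError("omega grid must be positive")

    th = np.arctan(omega_grid / dist.a)
    phase_plus = omega_grid * dist.tau_m + dist.m * th
    phase_minus = omega_grid * dist.tau_m - dist.m * th
    cosm = np.cos(th) ** dist.m

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_p = -omega_grid / np.tan(phase_plus)
        beta_p = -omega_grid / (cosm * np.sin(phase_plus))
        alpha_m = -omega_grid / np.tan(phase_minus)
        beta_m = beta_p  # the printed beta form already carries the + sign

    oms, als, bes, res, branch = [], [], [], [], []
    for i, om in enumerate(omega_grid):
        chosen = None
        for name, al, be in (("plus", alpha_p[i], beta_p[i]), ("minus", alpha_m[i], beta_m[i])):
            if not (np.isfinite(al) and np.isfinite(be)):
                continue
            r = abs(char_residual(1j * om, al, be, dist))
            if r < RESIDUAL_TOL:
                chosen = (name, al, be, r)
                break
        if chosen is None:
            al, be = _exact_hopf_point(om, dist)
            if not (np.isfinite(al) and np.isfinite(be)):
                continue
            r = abs(char_residual(1j * om, al, be, dist))
            if r >= RESIDUAL_TOL:
                continue
            chosen = ("solve", al, be, r)
        name, al, be, r = chosen
        if abs(be) > beta_max:
            continue
        oms.append(om)
        als.append(al)
        bes.append(be)
        res.append(r)
        branch.append(name)

    if not oms:
        raise RuntimeError(
            "no validated contour points; diagnostic: "
            f"omega range [{omega_grid.min()}, {omega_grid.max()}], dist={dist}"
        )
    return StabilityContour(
        omega=np.array(oms),
        alpha=np.array(als),
        beta=np.array(bes),
        residual=np.array(res),
        dist=dist,
        branch=np.array(branch),
    )


def _meanfield_run(alpha, beta, dist, T, dt, Q=50):
    """Euler mean-field run from C0=1; returns (|C| max over run, trailing max)."""
    taus, w = meanfield_delay_atoms(dist, Q=Q)
    d = np.maximum(np.round(taus / dt).astype(int), 1)
    H = int(d.max())
    n = int(round(T / dt))
    C = np.empty(n + 1 + H)
    C[: H + 1] = 1.0
    peak = 1.0
    for k in range(H, H + n):
        cbar = float(np.dot(w, C[k - d]))
        C[k + 1] = C[k] + dt * (-alpha * C[k] + beta * cbar)
        a = abs(C[k + 1])
        if a > peak:
            peak = a
        if a > 1e7 or not np.isfinite(a):
            return peak, a
    tail = np.abs(C[H + int(0.8 * n) :])
    return peak, float(tail.max())


def classify_stability(
    alpha: float,
    beta: float,
    dist: ShiftedGamma,
    T_factor: float = 200.0,
) -> str:
    """Verdict from the mean-field DDE oracle: 'stable'/'unstable'/'indeterminate'.

    Integrates from C0 = 1 for T_factor characteristic times (1/max(|alpha|,
    |beta|, 1)); stable if the trailing-window max falls below 0.5, unstable
    if |C| exceeds 10 at any point.
    """
    rate = max(abs(alpha), abs(beta), 1.0)
    T = T_factor / rate
    T = max(T, 3.0 * dist.mean)  # cover at least a few delay spans
    dt = min(
        dist.tau_m / 10.0 if dist.tau_m > 0 else dist.mean / 20.0,
        0.1 / rate,
    )
    peak, tail_max = _meanfield_run(alpha, beta, dist, T, dt)
    if peak > 10.0:
        return "unstable"
    if tail_max < 0.5:
        return "stable"
    return "indeterminate"


def rhp_root_count(
    alpha: float,
    beta: float,
    dist: ShiftedGamma,
    n_points: int = 4000,
) -> int:
    """Number of right-half-plane roots of F by the argument principle.

    Integrates the winding of F along the boundary of the half-disc
    {Re lambda >= 0, |lambda| <= R} with R = |alpha| + |beta| + 1 (all RHP
    roots satisfy |lambda| <= |alpha| + |beta| since |G| <= 1 there).
    Unreliable when a root sits on the imaginary axis (boundary cases).
    """
    R = abs(alpha) + abs(beta) + 1.0
    # counterclockwise: down the imaginary axis, then the right semicircle
    y = np.linspace(R, -R, n_points)
    seg1 = 1j * y
    th = np.linspace(-np.pi / 2, np.pi / 2, n_points)
    seg2 = R * np.exp(1j * th)
    lam = np.concatenate([seg1, seg2])
    vals = char_residual(lam, alpha, beta, dist)
    ang = np.unwrap(np.angle(vals))
    winding = (ang[-1] - ang[0]) / (2 * np.pi)
    return int(np.rint(winding))


def stability_boundary_beta(alpha: float, dist: ShiftedGamma, contour=None) -> float:
    """beta at which stability is first lost at fixed alpha > 0.

    The operative boundary is the lower envelope of the lambda = 0 line
    (beta = alpha) and the Hopf locus.
    """
    if contour is None:
        contour = hopf_contour(dist)
    return float(min(alpha, contour.beta_at(alpha)))


def region_map(
    dist_solo: ShiftedGamma,
    dist_group: ShiftedGamma,
    alpha_range: tuple[float, float] = (0.25, 10.0),
    beta_range: tuple[float, float] = (0.25, 10.0),
    resolution: int = 12,
) -> dict:
    """Per-cell stability verdicts for both distributions plus both contours.

    Every cell gets a DDE-oracle verdict and an analytic verdict (argument-
    principle root count); the returned frame also marks the set difference
    (stable under the group distribution, unstable under solo).
    """
    if alpha_range[0] <= 0 or beta_range[0] <= 0:
        raise ValueError("ranges must be positive")
    alphas = np.linspace(*alpha_range, resolution)
    betas = np.linspace(*beta_range, resolution)
    rows = []
    for al in alphas:
        for be in betas:
            row = {"alpha": al, "beta": be}
            for tag, dist in (("solo", dist_solo), ("group", dist_group)):
                row[f"verdict_{tag}"] = classify_stability(al, be, dist)
                row[f"analytic_{tag}"] = (
                    "stable" if rhp_root_count(al, be, dist) == 0 else "unstable"
                )
            rows.append(row)
    grid = pd.DataFrame(rows)
    grid["group_only_stable"] = (grid.verdict_group == "stable") & (
        grid.verdict_solo == "unstable"
    )
    return {
        "grid": grid,
        "contour_solo": hopf_contour(dist_solo),
        "contour_group": hopf_contour(dist_group),
    }
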