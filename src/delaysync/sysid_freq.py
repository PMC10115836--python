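"""Frequency-domain identification of a transfer function plus transport delay.

Given a stimulus/response signal pair, the chain is:

1. Welch auto-/cross-spectra and magnitude-squared coherence
   gamma^2(f) = |P_xy|^2 / (P_x P_y); the band where gamma^2 > 0.6 marks a
   credible linear relation.
2. A chirp-Z transform (CZT) zoomed onto that band gives an empirical
   frequency response H_hat(f) = CZT(resp) / CZT(stim) on a grid much finer
   than the raw FFT allows for short records.
3. For every candidate model order, delay kind (pure transport delay
   exp(-s tau) or first-order lag 1/(1+tau s)) and tau on a 1 ms grid over
   [0, 200] ms, the delay is divided out of H_hat and a rational transfer
   function is fitted to the remainder by Sanathanan-Koerner iteratively
   reweighted complex least squares.  Candidates are scored by FIT / MSE /
   FPE on the coherent band and the global best is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_data import Signal, TransferFunctionModel

__all__ = [
    "SpectraPair",
    "EmpiricalFRF",
    "FitCriteria",
    "IdentificationError",
    "estimate_spectra",
    "czt_spectrum",
    "empirical_frf",
    "fit_tf_with_delay",
    "score_model",
    "identify_frequency_domain",
    "DEFAULT_DELAY_GRID",
    "COHERENCE_THRESHOLD",
    "DEFAULT_BAND",
]

COHERENCE_THRESHOLD = 0.6
#: 1 ms steps over [0, 200] ms
DEFAULT_DELAY_GRID = np.arange(0.0, 0.2005, 0.001)
#: default identification band (Hz) for the triangular-sweep records;
#: the low edge respects T_rec > 2*pi/omega_min for records down to ~3.9 s
DEFAULT_BAND = (0.25, 3.0)


class IdentificationError(RuntimeError):
    """Raised when no candidate model reaches an acceptable fit."""


@dataclass
class SpectraPair:
    """Welch spectra of an input/output pair plus coherence."""

    f: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pxy: np.ndarray
    coherence: np.ndarray
    n_segments: int


@dataclass
class EmpiricalFRF:
    """Empirical frequency response on a CZT grid with a coherent-band mask.

    ``weight`` carries the relative stimulus spectral amplitude per grid
    point; the rational fit uses it for weighted least squares (the FRF
    variance per point scales as 1/|CZT(stim)|^2 under output noise).
    """

    f: np.ndarray
    H: np.ndarray
    mask: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self):
        if self.weight is None:
            self.weight = np.ones_like(self.f)

    @property
    def f_band(self) -> np.ndarray:
        return self.f[self.mask]

    @property
    def H_band(self) -> np.ndarray:
        return self.H[self.mask]


@dataclass
class FitCriteria:
    """Model-selection criteria for one candidate structure."""

    fit_percent: float
    mse: float
    fpe: float
    delay_s: float
    n_poles: int
    n_zeros: int
    delay_kind: str


def _welch_nperseg(n: int, fs: float = 0.0) -> int:
    """Welch segment length: about one second, kept between n/4 and n/2.

    Tracking impulse responses ring for a substantial fraction of a second;
    segments much shorter than that deflate the coherence of perfectly
    linear records through convolution leakage across segment edges.
    """
    return int(max(8, min(n // 2, max(n // 4, round(fs)))))


def estimate_spectra(x: Signal, y: Signal) -> SpectraPair:
    """Welch-averaged auto/cross spectra and magnitude-squared coherence."""
    if len(x) != len(y) or abs(x.fs - y.fs) > 1e-9 * x.fs:
        raise ValueError("signals must share length and sampling rate")
    nper = _welch_nperseg(len(x), x.fs)
    noverlap = nper // 2
    kwargs = dict(fs=x.fs, window="hann", nperseg=nper, noverlap=noverlap)
    f, pxx = sps.welch(x.samples, **kwargs)
    _, pyy = sps.welch(y.samples, **kwargs)
    _, pxy = sps.csd(x.samples, y.samples, **kwargs)
    denom = pxx * pyy
    coh = np.zeros_like(pxx)
    ok = denom > 0
    coh[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    coh = np.clip(coh, 0.0, 1.0)
    n_seg = 1 + max(0, (len(x) - nper) // (nper - noverlap))
    return SpectraPair(f=f, Pxx=pxx, Pyy=pyy, Pxy=pxy, coherence=coh, n_segments=n_seg)


def czt_spectrum(sig: Signal, f1: float, f2: float, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Z-transform on K points uniformly spaced on the arc from f1 to f2 Hz.

    Matches the FFT bins wherever the grids coincide.
    """
    if not (0 <= f1 < f2):
        raise ValueError("need 0 <= f1 < f2")
    if f2 > sig.fs / 2:
        raise ValueError("f2 exceeds the Nyquist frequency")
    if K < 8:
        raise ValueError("K must be >= 8")
    step = (f2 - f1) / (K - 1)
    w = np.exp(-2j * np.pi * step / sig.fs)
    a = np.exp(2j * np.pi * f1 / sig.fs)
    spec = sps.czt(sig.samples, m=K, w=w, a=a)
    f = f1 + step * np.arange(K)
    return f, spec


def empirical_frf(
    stim: Signal,
    resp: Signal,
    band: tuple[float, float] = DEFAULT_BAND,
    K: int | None = None,
    coherence_threshold: float = COHERENCE_THRESHOLD,
    stim_floor_rel: float = 0.1,
) -> EmpiricalFRF:
    """Empirical FRF H_hat = CZT(resp)/CZT(stim) on the requested band.

    By default the CZT grid is snapped to the record's own Fourier bins
    (spacing 1/T_rec): for records holding whole stimulus periods those are
    the leakage-free frequencies, while values between bins are dominated by
    spectral interpolation of neighboring lines.  Pass ``K`` explicitly for
    a finer zoom grid.  The retained mask is the largest contiguous run
    where the Welch coherence (interpolated onto the grid) exceeds the
    threshold; points where |CZT(stim)| falls below a relative floor are
    masked out.  Requires T_rec > 2*pi/omega_min for the low band edge.
    """
    f1, f2 = band
    if stim.duration * f1 < 1.0 - 1e-9:  # T_rec must cover one period of f_min
        raise ValueError(
            f"record length {stim.duration:.2f}s too short for f_min={f1}Hz "
            "(need T_rec > 2*pi/omega_min)"
        )
    if K is None:
        # snap the grid to the record's Fourier bins inside the band
        T = stim.duration
        k1 = int(np.ceil(f1 * T - 1e-9))
        k2 = int(np.floor(f2 * T + 1e-9))
        if k2 - k1 < 2:
            raise ValueError("band too narrow for the record's bin spacing")
        f1, f2 = k1 / T, k2 / T
        K = k2 - k1 + 1
    f, S = czt_spectrum(stim, f1, f2, K)
    _, R = czt_spectrum(resp, f1, f2, K)

    floor = stim_floor_rel * np.max(np.abs(S))
    ok = np.abs(S) > floor
    H = np.zeros(K, dtype=complex)
    H[ok] = R[ok] / S[ok]

    spec = estimate_spectra(stim, resp)
    # the DC bin's coherence is identically ~0 for zero-mean signals and
    # would drag down interpolated values across the lowest Welch bin width
    coh_src = spec.coherence.copy()
    if len(coh_src) > 1:
        coh_src[0] = coh_src[1]
    coh = np.interp(f, spec.f, coh_src)
    # contiguity applies to the coherence band; the stimulus-support floor
    # then drops individual weakly excited points inside it
    mask = _largest_run(coh > coherence_threshold) & ok
    weight = np.abs(S) / np.max(np.abs(S))
    return EmpiricalFRF(f=f, H=H, mask=mask, weight=weight)


def _largest_run(flags: np.ndarray) -> np.ndarray:
    """Mask of the largest contiguous True run."""
    best_len, best_start, cur_len, cur_start = 0, 0, 0, 0
    for i, v in enumerate(flags):
        if v:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    out = np.zeros_like(flags, dtype=bool)
    out[best_start : best_start + best_len] = True
    return out


def _fit_rational_sk(
    omega: np.ndarray,
    H: np.ndarray,
    n_poles: int,
    n_zeros: int,
    max_iter: int = 20,
    tol: float = 1e-8,
    base_weight: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sanathanan-Koerner rational fit of H(j*omega), monic denominator.

    Frequencies are scaled to unit magnitude for conditioning; falls back to
    the single (unweighted) Levy solve if the iteration does not converge.
    """
    w0 = np.median(omega[omega > 0]) if np.any(omega > 0) else 1.0
    s = 1j * omega / w0

    # columns: num coeffs (desc powers, nz+1) then den coeffs d_1..d_np
    V_num = np.column_stack([s ** (n_zeros - k) for k in range(n_zeros + 1)])
    V_den = np.column_stack([s ** (n_poles - k) for k in range(1, n_poles + 1)]) \
        if n_poles > 0 else np.zeros((len(s), 0), dtype=complex)
    rhs_base = H * s**n_poles

    w_base = np.ones(len(s)) if base_weight is None else np.asarray(base_weight)
    weight = w_base.copy()
    prev = None
    best = None  # (true weighted residual, num_s, den_s)
    for _ in range(max_iter):
        A = np.hstack([V_num, -H[:, None] * V_den]) * weight[:, None]
        b = rhs_base * weight
        Ar = np.vstack([A.real, A.imag])
        br = np.concatenate([b.real, b.imag])
        theta, *_ = np.linalg.lstsq(Ar, br, rcond=None)
        num_s = theta[: n_zeros + 1]
        den_s = np.concatenate([[1.0], theta[n_zeros + 1 :]])
        # SK iterations are not monotone; keep the iterate with the smallest
        # true (not Levy-linearized) weighted residual
        dval = np.polyval(den_s, s)
        resid = float(
            np.sum(
                (w_base * np.abs(H - np.polyval(num_s, s) / np.where(dval == 0, 1e-300, dval))) ** 2
            )
        )
        if best is None or resid < best[0]:
            best = (resid, num_s.copy(), den_s.copy())
        if prev is not None and np.linalg.norm(theta - prev) <= tol * (
            1 + np.linalg.norm(theta)
        ):
            break
        prev = theta
        dmag = np.abs(dval)
        weight = w_base / np.maximum(dmag, 1e-12)
    num_s, den_s = best[1], best[2]

    # unscale: coefficient of s^k was fitted for (s/w0)^k
    num = num_s * w0 ** -(n_zeros - np.arange(n_zeros + 1))
    den = den_s * w0 ** -(n_poles - np.arange(n_poles + 1))
    # renormalize monic in true s and clear scaling of the whole fraction
    num = num / den[0]
    den = den / den[0]
    return np.real(num), np.real(den)


def score_model(frf: EmpiricalFRF, model: TransferFunctionModel) -> FitCriteria:
    """FIT / MSE / FPE of a model against the FRF on the coherent band.

    FIT = 100*(1 - ||H - G|| / ||H - mean(H)||);  MSE = mean |H - G|^2;
    FPE = MSE * (1 + p/K) / (1 - p/K) with p = n_poles + n_zeros + 1 free
    parameters and K band points.
    """
    if not np.any(frf.mask):
        raise IdentificationError("coherent band is empty")
    f = frf.f_band
    H = frf.H_band
    K = len(f)
    p = model.n_poles + model.n_zeros + 1
    if p >= K:
        raise ValueError("FPE undefined: p >= number of band points")
    G = model.frequency_response(2 * np.pi * f)
    err = np.linalg.norm(H - G)
    base = np.linalg.norm(H - np.mean(H))
    if base == 0:
        raise ValueError("FRF constant over the band; FIT normalization undefined")
    fit = 100.0 * (1.0 - err / base)
    mse = float(np.mean(np.abs(H - G) ** 2))
    fpe = mse * (1.0 + p / K) / (1.0 - p / K)
    return FitCriteria(
        fit_percent=float(fit),
        mse=mse,
        fpe=float(fpe),
        delay_s=model.tau,
        n_poles=model.n_poles,
        n_zeros=model.n_zeros,
        delay_kind=model.delay_kind,
    )


def _compensate_delay(f: np.ndarray, H: np.ndarray, tau: float, kind: str) -> np.ndarray:
    s = 2j * np.pi * f
    if kind == "pure":
        return H * np.exp(s * tau)
    return H * (1.0 + tau * s)


#: FIT differences below this (percentage points) count as ties for ranking.
_FIT_TIE_TOL = 0.01


def fit_tf_with_delay(
    frf: EmpiricalFRF,
    orders: list[tuple[int, int]] = ((2, 1), (3, 3), (4, 3)),
    delay_grid: np.ndarray | None = None,
    kinds: tuple[str, ...] = ("pure", "linear_approx"),
) -> tuple[TransferFunctionModel, list[FitCriteria]]:
    """Grid search over (order, delay kind, tau); SK rational fit per point.

    For each candidate the delay is divided out of the FRF, the rational
    remainder fitted, and the full model scored on the coherent band.
    Returns the winning model and one ranked FitCriteria entry per
    (order, kind) combination (its best delay).  Ranking is by maximum FIT
    with near-ties (< 0.01 points) broken by minimum FPE.
    """
    if delay_grid is None:
        delay_grid = DEFAULT_DELAY_GRID
    delay_grid = np.asarray(delay_grid, dtype=float)
    if np.any(delay_grid < 0) or np.any(delay_grid > 0.2 + 1e-12):
        raise ValueError("delay grid must lie within [0, 0.2] s")
    if not np.any(frf.mask):
        raise IdentificationError("coherent band is empty")

    f = frf.f_band
    H = frf.H_band
    w_band = frf.weight[frf.mask]
    omega = 2 * np.pi * f
    sub = EmpiricalFRF(
        f=f, H=H, mask=np.ones(len(f), dtype=bool), weight=w_band
    )

    entries: list[tuple[FitCriteria, TransferFunctionModel]] = []
    for (n_p, n_z) in orders:
        if n_z > n_p:
            raise ValueError("candidate models must be proper (n_zeros <= n_poles)")
        for kind in kinds:
            best: tuple[FitCriteria, TransferFunctionModel] | None = None
            for tau in delay_grid:
                Hc = _compensate_delay(f, H, tau, kind)
                num, den = _fit_rational_sk(omega, Hc, n_p, n_z, base_weight=w_band)
                model = TransferFunctionModel(
                    num=num, den=den, delay_kind=kind, tau=float(tau)
                )
                crit = score_model(sub, model)
                if best is None or _better(crit, best[0]):
                    best = (crit, model)
            entries.append(best)

    entries.sort(key=lambda e: (-e[0].fit_percent, e[0].fpe))
    ranked = [e[0] for e in entries]
    winner = entries[0]
    for crit, model in entries[1:]:
        if _better(crit, winner[0]):
            winner = (crit, model)
    if winner[0].fit_percent < 0:
        raise IdentificationError("all candidate fits below the FIT floor")
    return winner[1], ranked


def _better(a: FitCriteria, b: FitCriteria) -> bool:
    """a beats b: higher FIT, with near-ties broken by lower FPE."""
    if a.fit_percent > b.fit_percent + _FIT_TIE_TOL:
        return True
    if b.fit_percent > a.fit_percent + _FIT_TIE_TOL:
        return False
    return a.fpe < b.fpe


def steady_state_fit(
    stim: Signal, resp: Signal, model: TransferFunctionModel
) -> float:
    """Output fit (percent) of the model's periodic steady-state prediction.

    Predicts the response as the inverse FFT of G(j*omega) applied to the
    stimulus spectrum (the record is treated as one period of a periodic
    excitation) and scores it with the normalized-error fit: 100 is a
    perfect prediction, 0 no better than the response mean.
    """
    y = resp.samples
    n = len(y)
    X = np.fft.rfft(stim.samples)
    omega = 2 * np.pi * np.fft.rfftfreq(n, 1.0 / stim.fs)
    yh = np.fft.irfft(model.frequency_response(omega) * X, n)
    base = np.linalg.norm(y - np.mean(y))
    if base == 0:
        raise ValueError("constant response; fit normalization undefined")
    return float(100.0 * (1.0 - np.linalg.norm(y - yh) / base))


def identify_frequency_domain(
    stim: Signal,
    resp: Signal,
    band: tuple[float, float] = DEFAULT_BAND,
    orders: list[tuple[int, int]] = ((2, 1), (3, 3), (4, 3)),
    delay_grid: np.ndarray | None = None,
    kinds: tuple[str, ...] = ("pure",),
    K: int | None = None,
) -> tuple[TransferFunctionModel, list[FitCriteria]]:
    """Full frequency-domain identification of one stimulus/response record.

    The rational part is fitted on the coherent-band FRF exactly as in
    :func:`fit_tf_with_delay`, but the (order, kind, tau) winner is selected
    by the steady-state output fit against the measured response: the
    time-domain comparison uses every sample of the record and so
    discriminates the transport delay far more sharply than the handful of
    coherent FRF points can.  Returns the winning model and per-(order,
    kind) FitCriteria (FRF-based, Table-style) ranked by FIT then FPE.
    """
    if delay_grid is None:
        delay_grid = DEFAULT_DELAY_GRID
    frf = empirical_frf(stim, resp, band=band, K=K)
    if not np.any(frf.mask):
        raise IdentificationError("coherent band is empty")
    f = frf.f_band
    H = frf.H_band
    w_band = frf.weight[frf.mask]
    omega = 2 * np.pi * f
    sub = EmpiricalFRF(f=f, H=H, mask=np.ones(len(f), dtype=bool), weight=w_band)

    n = len(resp)
    X = np.fft.rfft(stim.samples)
    om_bins = 2 * np.pi * np.fft.rfftfreq(n, 1.0 / stim.fs)
    y = resp.samples
    base = np.linalg.norm(y - np.mean(y))

    entries = []  # (ss_fit, FitCriteria, model) per (order, kind)
    for (n_p, n_z) in orders:
        for kind in kinds:
            best = None
            for tau in delay_grid:
                Hc = _compensate_delay(f, H, tau, kind)
                num, den = _fit_rational_sk(omega, Hc, n_p, n_z, base_weight=w_band)
                model = TransferFunctionModel(
                    num=num, den=den, delay_kind=kind, tau=float(tau)
                )
                yh = np.fft.irfft(model.frequency_response(om_bins) * X, n)
                ss = 100.0 * (1.0 - np.linalg.norm(y - yh) / base)
                if best is None or ss > best[0]:
                    best = (ss, model)
            ss, model = best
            entries.append((ss, score_model(sub, model), model))

    entries.sort(key=lambda e: (-e[1].fit_percent, e[1].fpe))
    ranked = [e[1] for e in entries]
    winner = entries[0]
    for e in entries[1:]:
        if e[0] > winner[0] + _FIT_TIE_TOL or (
            abs(e[0] - winner[0]) <= _FIT_TIE_TOL and e[1].fpe < winner[1].fpe
        ):
            winner = e
    if winner[0] < 0:
        raise IdentificationError("all candidate fits below the FIT floor")
    return winner[2], ranked
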