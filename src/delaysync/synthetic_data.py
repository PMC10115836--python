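"""Synthetic inputs for the delay-identification pipeline.

Everything the analysis consumes can be generated here with known ground
truth: a triangular-sweep stimulus (odd harmonics only, rich low-frequency
content), responder trajectories produced by low-order rational transfer
functions with transport delays, additive white Gaussian measurement noise
at a controlled amplitude signal-to-noise ratio, delay populations drawn
from shifted gamma distributions, and multi-camera pixel detections of 3-D
scenes with dropouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Signal",
    "TransferFunctionModel",
    "TriangularSchedule",
    "CameraModel",
    "DetectionFrames",
    "generate_triangular_stimulus",
    "simulate_responder",
    "sample_delay_population",
    "project_scene",
    "default_cameras",
    "DEFAULT_SCHEDULE",
    "SWEEP_4S_SCHEDULE",
    "SWEEP_1200MS_SCHEDULE",
]


@dataclass
class Signal:
    """Uniformly sampled 1-D time series (position, arbitrary length unit)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a Signal needs at least two samples")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class TransferFunctionModel:
    """Rational transfer function plus a transport-delay model.

    ``num``/``den`` are polynomial coefficients in descending powers of s.
    ``delay_kind`` selects how the latency tau enters: ``"pure"`` is the
    exact transport delay exp(-s*tau); ``"linear_approx"`` the first-order
    lag 1/(1 + tau*s).
    """

    num: np.ndarray
    den: np.ndarray
    delay_kind: str = "pure"
    tau: float = 0.0

    def __post_init__(self):
        self.num = np.atleast_1d(np.asarray(self.num, dtype=float))
        self.den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if self.den[0] == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        if len(self.num) > len(self.den):
            raise ValueError("model must be proper (num degree <= den degree)")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.delay_kind not in ("pure", "linear_approx"):
            raise ValueError(f"unknown delay_kind {self.delay_kind!r}")

    @property
    def n_poles(self) -> int:
        return len(self.den) - 1

    @property
    def n_zeros(self) -> int:
        return len(self.num) - 1

    def rational_response(self, omega: np.ndarray) -> np.ndarray:
        """G_e(j*omega) of the rational part only."""
        s = 1j * np.asarray(omega, dtype=float)
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def frequency_response(self, omega: np.ndarray) -> np.ndarray:
        """Full response including the delay model M(s, tau)."""
        s = 1j * np.asarray(omega, dtype=float)
        g = self.rational_response(omega)
        if self.tau == 0:
            return g
        if self.delay_kind == "pure":
            return g * np.exp(-s * self.tau)
        return g / (1.0 + self.tau * s)

    def is_stable(self) -> bool:
        return bool(np.all(np.real(np.roots(self.den)) < 0))


# The transfer functions the worked identification examples are built on:
# a 3-pole/3-zero model with a 15 ms pure transport delay and a 2-pole/1-zero
# model with a 40 ms delay.
def example_responder_3p3z() -> TransferFunctionModel:
    return TransferFunctionModel(
        num=[0.7377, 0.5992, 1.175, 0.2213],
        den=[1.0, 0.544, 1.85, 0.2594],
        delay_kind="pure",
        tau=0.015,
    )


def example_responder_2p1z() -> TransferFunctionModel:
    return TransferFunctionModel(
        num=[-5.462, 39.42],
        den=[1.0, 4.471, 75.86],
        delay_kind="pure",
        tau=0.040,
    )


@dataclass
class TriangularSchedule:
    """Sequence of (half_period_s, amplitude) triangular segments at rate fs.

    Each segment contributes one full zero-mean period: 0 -> +A over h/2,
    +A -> -A over h, -A -> 0 over h/2 (total 2*h). That waveform is
    half-wave antisymmetric, so its spectrum contains odd harmonics only.
    """

    segments: list[tuple[float, float]]
    fs: float = 120.0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for h, amp in self.segments:
            if h <= 0 or amp < 0:
                raise ValueError("half-periods must be > 0 and amplitudes >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def total_duration(self) -> float:
        return 2.0 * sum(h for h, _ in self.segments)

    def value_at(self, t: float) -> float:
        """Stimulus position at time t (schedule repeats cyclically)."""
        t = float(t) % self.total_duration
        for h, amp in self.segments:
            period = 2.0 * h
            if t < period:
                # piecewise-linear odd triangle over one period
                if t < h / 2:
                    return amp * (2.0 * t / h)
                if t < 3 * h / 2:
                    return amp * (2.0 - 2.0 * t / h)
                return amp * (2.0 * t / h - 4.0)
            t -= period
        return 0.0  # pragma: no cover


#: Default schedule: half-periods spanning fundamentals 0.25-2 Hz, 0.1 m peak.
DEFAULT_SCHEDULE = TriangularSchedule(
    segments=[(2.0, 0.1), (1.0, 0.1), (0.5, 0.1), (0.25, 0.1)], fs=120.0
)

#: 4-second sweep used for the frequency-domain identification experiments
#: (fundamentals 0.5, 1.0, 1.67 and 2.5 Hz inside a 4 s record at 120 Hz).
SWEEP_4S_SCHEDULE = TriangularSchedule(
    segments=[(1.0, 0.1), (0.5, 0.1), (0.3, 0.1), (0.2, 0.1)], fs=120.0
)

#: 1.2-second sweep for the short-record (time-domain) experiments at 1 kHz.
SWEEP_1200MS_SCHEDULE = TriangularSchedule(
    segments=[(0.3, 0.1), (0.2, 0.1), (0.1, 0.1)], fs=1000.0
)


def generate_triangular_stimulus(
    schedule: TriangularSchedule, duration: float, t_shift: float = 0.0
) -> Signal:
    """Piecewise-linear zig-zag stimulus concatenating the schedule segments.

    The schedule repeats cyclically if ``duration`` exceeds its total length.
    ``t_shift`` evaluates the (periodic) waveform at t - t_shift, which
    realizes a transport-delayed copy of the stimulus exactly.
    """
    if duration < 2.0 * schedule.segments[0][0]:
        raise ValueError("duration must cover at least the first full segment")
    n = int(round(duration * schedule.fs))
    t = np.arange(n) / schedule.fs

    # vectorized evaluation of the per-segment ramps
    total = schedule.total_duration
    tm = (t - t_shift) % total
    y = np.zeros(n)
    offset = 0.0
    for h, amp in schedule.segments:
        period = 2.0 * h
        in_seg = (tm >= offset) & (tm < offset + period)
        u = tm[in_seg] - offset
        seg = np.where(
            u < h / 2,
            2.0 * u / h,
            np.where(u < 3 * h / 2, 2.0 - 2.0 * u / h, 2.0 * u / h - 4.0),
        )
        y[in_seg] = amp * seg
        offset += period
    return Signal(samples=y, fs=schedule.fs)


def _fractional_delay(y: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """Shift y by tau seconds via quintic spline interpolation.

    Pre-history (t < 0) is zero.  Spline order keeps the interpolation
    error orders of magnitude below the 1 ms identification grid for the
    low-pass signals produced here.
    """
    if tau == 0:
        return y.copy()
    if not np.all(np.isfinite(y)):
        return y.copy()  # diverged response; delaying it is meaningless
    from scipy.interpolate import make_interp_spline

    n = y.size
    t = np.arange(n) / fs
    spl = make_interp_spline(t, y, k=min(5, n - 1))
    tq = t - tau
    out = np.where(tq >= 0, spl(np.maximum(tq, 0.0)), 0.0)
    return out


def simulate_responder(
    model: TransferFunctionModel,
    stimulus: Signal,
    snr: float | None = None,
    seed: int = 0,
    hold: str = "foh",
) -> Signal:
    """LTI response of the rational part, delayed, with optional output noise.

    The rational part is discretized at the stimulus rate (first-order hold
    by default, which is exact for the piecewise-linear stimuli produced
    here; ``hold="zoh"`` for staircase actuation).  A ``pure`` delay is
    applied as an exact transport delay via fractional-sample interpolation;
    ``linear_approx`` cascades a first-order lag into the rational part.
    White Gaussian noise is added to the output only, scaled so the realized
    RMS(Y)/RMS(w) equals ``snr`` exactly.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    if model.tau >= stimulus.duration:
        raise ValueError("tau must be shorter than the record")
    if not model.is_stable():
        warnings.warn("responder model is unstable; output may diverge", RuntimeWarning)

    num, den = model.num, model.den
    if model.delay_kind == "linear_approx" and model.tau > 0:
        den = np.polymul(den, [model.tau, 1.0])

    if len(den) == 1:
        y = (num[0] / den[0]) * stimulus.samples  # static gain
    else:
        sysd = sps.cont2discrete((num, den), 1.0 / stimulus.fs, method=hold)
        _, y = sps.dlsim((sysd[0].ravel(), sysd[1].ravel(), sysd[2]), stimulus.samples)
        y = np.asarray(y).ravel()

    if model.delay_kind == "pure":
        y = _fractional_delay(y, stimulus.fs, model.tau)

    if snr is not None:
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(y.size)
        rms_y = np.sqrt(np.mean(y**2))
        w *= rms_y / (snr * np.sqrt(np.mean(w**2)))
        y = y + w
    return Signal(samples=y, fs=stimulus.fs, t0=stimulus.t0)


def steady_state_response(
    model: TransferFunctionModel, schedule: TriangularSchedule, duration: float
) -> tuple[Signal, Signal]:
    """Exact periodic steady-state stimulus/response pair.

    For a record holding a whole number of stimulus periods, the steady
    state of a stable LTI responder is itself periodic, and its samples are
    obtained exactly by multiplying the stimulus spectrum with the model's
    continuous frequency response at the record's Fourier bins.  This is the
    trial generator for identification experiments: it emulates an animal
    already engaged in tracking when the recording window starts, with no
    startup transient and no interpolation error in the transport delay.
    """
    total = schedule.total_duration
    cycles = duration / total
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError(
            "duration must hold a whole number of schedule periods "
            f"({duration} s vs period {total} s)"
        )
    stim = generate_triangular_stimulus(schedule, duration)
    n = len(stim)
    X = np.fft.rfft(stim.samples)
    omega = 2 * np.pi * np.fft.rfftfreq(n, 1.0 / schedule.fs)
    y = np.fft.irfft(model.frequency_response(omega) * X, n)
    return stim, Signal(samples=y, fs=schedule.fs)


def add_output_noise(sig: Signal, snr: float, seed: int = 0) -> Signal:
    """Add white Gaussian noise scaled so RMS(signal)/RMS(noise) = snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(len(sig))
    rms = np.sqrt(np.mean(sig.samples**2))
    w *= rms / (snr * np.sqrt(np.mean(w**2)))
    return Signal(samples=sig.samples + w, fs=sig.fs, t0=sig.t0)


def sample_delay_population(dist, n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. draws from a shifted gamma delay distribution (all >= tau_m)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return dist.tau_m + rng.gamma(dist.m, 1.0 / dist.a, size=n)


# ---------------------------------------------------------------------------
# synthetic multi-camera scene
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """Pinhole camera: 3x4 projection matrix in pixel units."""

    P: np.ndarray
    width: int = 1280
    height: int = 1024

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float).reshape(3, 4)
        if abs(np.linalg.det(self.P[:, :3])) < 1e-12:
            raise ValueError("left 3x3 block of P must be nonsingular")

    def project(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project (..., 3) world points; returns pixels and a validity mask."""
        X = np.asarray(X, dtype=float)
        Xh = np.concatenate([X, np.ones(X.shape[:-1] + (1,))], axis=-1)
        x = Xh @ self.P.T
        w = x[..., 2]
        valid = w > 1e-9
        uv = np.full(X.shape[:-1] + (2,), np.nan)
        uv[valid] = x[valid][..., :2] / w[valid, None]
        return uv, valid


def default_cameras(
    radius: float = 1.5,
    angles_deg: tuple[float, ...] = (0.0, 50.0, 120.0),
    focal_px: float = 1100.0,
    width: int = 1280,
    height: int = 1024,
) -> list[CameraModel]:
    """Cameras on an arc looking at the origin (50/70 degree separations)."""
    cams = []
    for ang in angles_deg:
        a = np.deg2rad(ang)
        c = radius * np.array([np.sin(a), -np.cos(a), 0.0])  # camera center
        z = -c / np.linalg.norm(c)  # optical axis toward origin
        up = np.array([0.0, 0.0, 1.0])
        x_axis = np.cross(z, up)
        x_axis /= np.linalg.norm(x_axis)
        y_axis = np.cross(z, x_axis)
        R = np.stack([x_axis, y_axis, z])
        K = np.array(
            [[focal_px, 0, width / 2], [0, focal_px, height / 2], [0, 0, 1.0]]
        )
        P = K @ np.hstack([R, -R @ c[:, None]])
        cams.append(CameraModel(P=P, width=width, height=height))
    return cams


@dataclass
class DetectionFrames:
    """Per-frame, per-camera 2-D pixel detections with ground-truth labels.

    ``points[t][c]`` is an (k, 2) array of pixel coordinates for frame t and
    camera c; ``truth_ids[t][c]`` holds the generating agent index of each
    detection (testing only — the association step never reads it).
    """

    t: np.ndarray
    points: list[list[np.ndarray]]
    truth_ids: list[list[np.ndarray]]
    n_cameras: int

    def __len__(self) -> int:
        return len(self.points)


def project_scene(
    trajectories: list[np.ndarray],
    cameras: list[CameraModel],
    pixel_noise_sd: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    fs: float = 120.0,
) -> DetectionFrames:
    """Pinhole projection of 3-D tracks into every camera.

    Adds Gaussian pixel noise and Bernoulli dropouts; points behind a camera
    are marked missing for that camera.  Ground-truth identities are kept in
    a side channel for oracle tests.
    """
    if len(cameras) < 2:
        raise ValueError("need at least two cameras")
    n_t = trajectories[0].shape[0]
    if any(tr.shape[0] != n_t for tr in trajectories):
        raise ValueError("all tracks must share a time base")
    rng = np.random.default_rng(seed)
    X = np.stack(trajectories)  # (n_agents, n_t, 3)

    points: list[list[np.ndarray]] = []
    ids: list[list[np.ndarray]] = []
    for k in range(n_t):
        frame_pts, frame_ids = [], []
        for cam in cameras:
            uv, valid = cam.project(X[:, k, :])
            keep = valid & (rng.random(len(trajectories)) >= dropout_rate)
            uv = uv[keep]
            if pixel_noise_sd > 0 and uv.size:
                uv = uv + rng.normal(0.0, pixel_noise_sd, size=uv.shape)
            frame_pts.append(uv)
            frame_ids.append(np.flatnonzero(keep))
        points.append(frame_pts)
        ids.append(frame_ids)
    return DetectionFrames(
        t=np.arange(n_t) / fs, points=points, truth_ids=ids, n_cameras=len(cameras)
    )
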