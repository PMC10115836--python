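"""Generators: triangular stimuli, LTI responders, delay populations, scenes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from delaysync.delay_dist import ShiftedGamma
from delaysync.synthetic_data import (
    Signal,
    TransferFunctionModel,
    TriangularSchedule,
    add_output_noise,
    default_cameras,
    generate_triangular_stimulus,
    project_scene,
    sample_delay_population,
    simulate_responder,
    steady_state_response,
)


def harmonic_power(sig: Signal, f0: float, k: int) -> float:
    """Power at the k-th harmonic of f0 via the record's Fourier bins."""
    spec = np.abs(np.fft.rfft(sig.samples)) ** 2
    f = np.fft.rfftfreq(len(sig), 1.0 / sig.fs)
    idx = int(round(k * f0 * len(sig) / sig.fs))
    return spec[idx]


class TestTriangularStimulus:
    def test_only_odd_harmonics(self):
        sched = TriangularSchedule(segments=[(1.0, 1.0)], fs=120.0)
        sig = generate_triangular_stimulus(sched, 10.0)  # 5 whole periods
        f0 = 0.5  # fundamental of a 2 s period
        odd = sum(harmonic_power(sig, f0, k) for k in (1, 3, 5, 7))
        even = sum(harmonic_power(sig, f0, k) for k in (2, 4, 6, 8))
        assert even < 1e-10 * odd

    def test_zero_amplitude_gives_zero_signal(self):
        sched = TriangularSchedule(segments=[(1.0, 0.0)], fs=100.0)
        sig = generate_triangular_stimulus(sched, 4.0)
        assert np.all(sig.samples == 0.0)

    def test_zero_mean_over_whole_periods(self):
        sched = TriangularSchedule(
            segments=[(2.0, 0.1), (1.0, 0.2), (0.5, 0.05)], fs=120.0
        )
        sig = generate_triangular_stimulus(sched, sched.total_duration)
        assert abs(np.mean(sig.samples)) < 1e-12

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            TriangularSchedule(segments=[], fs=100.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        halves=st.lists(
            st.floats(min_value=0.1, max_value=2.0), min_size=1, max_size=4
        ),
        amp=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_matches_per_sample_oracle(self, halves, amp):
        """Vectorized generation equals the brute-force per-sample ramps."""
        sched = TriangularSchedule(segments=[(h, amp) for h in halves], fs=60.0)
        duration = min(2.0 * sched.total_duration, 10.0)
        if duration < 2.0 * halves[0]:
            duration = 2.0 * halves[0]
        sig = generate_triangular_stimulus(sched, duration)
        oracle = np.array([sched.value_at(tk) for tk in sig.t])
        np.testing.assert_allclose(sig.samples, oracle, atol=1e-12)


class TestSimulateResponder:
    def test_identity_model_passthrough(self, sweep_4s):
        stim = generate_triangular_stimulus(sweep_4s, 4.0)
        ident = TransferFunctionModel(num=[1.0], den=[1.0], tau=0.0)
        out = simulate_responder(ident, stim)
        np.testing.assert_allclose(out.samples, stim.samples)

    def test_pure_delay_is_sample_shift(self, sweep_4s):
        sched = TriangularSchedule(segments=sweep_4s.segments, fs=100.0)
        stim = generate_triangular_stimulus(sched, 4.0)
        delayed = simulate_responder(
            TransferFunctionModel(num=[1.0], den=[1.0], tau=0.1), stim
        )
        np.testing.assert_allclose(
            delayed.samples[10:], stim.samples[:-10], atol=1e-9
        )

    @pytest.mark.parametrize("with_delay", [False, True])
    def test_matches_rk4_ode_oracle(self, model_3p3z, sweep_4s, with_delay):
        """Discretized simulation vs an independent RK4 integration.

        The hold-equivalent integration of the rational part is essentially
        exact for the piecewise-linear stimulus; realizing the transport
        delay by interpolating the sampled output adds a small additional
        error, so the delayed comparison carries a looser bound.
        """
        from scipy.signal import tf2ss

        tau = model_3p3z.tau if with_delay else 0.0
        model = TransferFunctionModel(
            num=model_3p3z.num, den=model_3p3z.den, tau=tau
        )
        stim = generate_triangular_stimulus(sweep_4s, 4.0)
        resp = simulate_responder(model, stim)

        A, B, C, D = tf2ss(model.num, model.den)
        sub = 20  # RK4 substeps per sample
        h = 1.0 / (stim.fs * sub)

        def u(t):
            return sweep_4s.value_at(t - tau) if t >= tau else 0.0

        x = np.zeros(A.shape[0])
        C1, D1 = C.ravel(), float(D.ravel()[0])

        def read_out(xv, uv):
            return float(C1 @ xv + D1 * uv)

        oracle = np.zeros(len(stim))
        oracle[0] = read_out(x, u(0.0))
        t = 0.0
        for k in range(1, len(stim)):
            for _ in range(sub):
                k1 = A @ x + (B * u(t)).ravel()
                k2 = A @ (x + h / 2 * k1) + (B * u(t + h / 2)).ravel()
                k3 = A @ (x + h / 2 * k2) + (B * u(t + h / 2)).ravel()
                k4 = A @ (x + h * k3) + (B * u(t + h)).ravel()
                x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            oracle[k] = read_out(x, u(t))
        err = np.linalg.norm(resp.samples - oracle) / np.linalg.norm(oracle)
        assert err < (5e-3 if with_delay else 1e-4)

    def test_linearity_of_noise_free_response(self, model_3p3z, sweep_4s):
        stim = generate_triangular_stimulus(sweep_4s, 4.0)
        scaled = Signal(samples=3.7 * stim.samples, fs=stim.fs)
        y1 = simulate_responder(model_3p3z, stim).samples
        y2 = simulate_responder(model_3p3z, scaled).samples
        np.testing.assert_allclose(y2, 3.7 * y1, rtol=1e-9, atol=1e-12)

    def test_snr_contract_exact(self, model_3p3z, sweep_4s):
        stim = generate_triangular_stimulus(sweep_4s, 12.0)
        clean = simulate_responder(model_3p3z, stim).samples
        noisy = simulate_responder(model_3p3z, stim, snr=7.5, seed=3).samples
        w = noisy - clean
        realized = np.sqrt(np.mean(clean**2)) / np.sqrt(np.mean(w**2))
        assert abs(realized / 7.5 - 1.0) < 0.01

    def test_invalid_snr_rejected(self, model_3p3z, sweep_4s):
        stim = generate_triangular_stimulus(sweep_4s, 4.0)
        with pytest.raises(ValueError):
            simulate_responder(model_3p3z, stim, snr=-1.0)

    def test_unstable_model_warns(self, sweep_4s):
        stim = generate_triangular_stimulus(sweep_4s, 4.0)
        unstable = TransferFunctionModel(num=[1.0], den=[1.0, -1.0], tau=0.0)
        with pytest.warns(RuntimeWarning):
            simulate_responder(unstable, stim)

    def test_steady_state_matches_warm_simulation(self, model_3p3z, sweep_4s):
        """Closed-form periodic steady state equals a long warmed-up run."""
        stim_ss, resp_ss = steady_state_response(model_3p3z, sweep_4s, 4.0)
        long = generate_triangular_stimulus(sweep_4s, 15 * 4.0)
        warm = simulate_responder(model_3p3z, long).samples[-len(stim_ss):]
        err = np.linalg.norm(resp_ss.samples - warm) / np.linalg.norm(warm)
        assert err < 1e-3


class TestDelayPopulation:
    def test_mean_matches_group_fit(self):
        dist = ShiftedGamma(m=4.0, a=5.1, tau_m=0.0)
        draws = sample_delay_population(dist, 100_000, seed=1)
        se = dist.std / np.sqrt(draws.size)
        assert abs(draws.mean() - 4.0 / 5.1) < 3 * se

    def test_variance_matches_solo_fit(self):
        dist = ShiftedGamma(m=3.5, a=12.0, tau_m=0.0)
        draws = sample_delay_population(dist, 100_000, seed=2)
        assert abs(np.var(draws) / (3.5 / 12.0**2) - 1.0) < 0.05

    def test_support_respects_minimal_delay(self):
        dist = ShiftedGamma(m=2.0, a=3.0, tau_m=1.5)
        draws = sample_delay_population(dist, 10_000, seed=3)
        assert np.all(draws >= dist.tau_m)

    def test_empirical_cdf_converges(self):
        dist = ShiftedGamma(m=4.0, a=5.1, tau_m=4.1)
        draws = sample_delay_population(dist, 20_000, seed=4)
        ks = stats.kstest(draws, dist.cdf)
        assert ks.statistic < 0.02


class TestProjectScene:
    def test_full_dropout_empties_frames(self, cameras, rng):
        track = rng.normal(0, 0.1, size=(20, 3))
        frames = project_scene([track], cameras, dropout_rate=1.0, seed=0)
        assert all(len(pts) == 0 for frame in frames.points for pts in frame)

    def test_point_behind_camera_marked_missing(self, cameras):
        # far behind camera 1 (which sits at radius 1.5 on the -y side)
        track = np.tile(np.array([0.0, -5.0, 0.0]), (5, 1))
        frames = project_scene([track], cameras, seed=0)
        assert all(len(frame[0]) == 0 for frame in frames.points)

    def test_requires_two_cameras(self, cameras):
        with pytest.raises(ValueError):
            project_scene([np.zeros((3, 3))], cameras[:1])
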