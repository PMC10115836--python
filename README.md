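# delaysync

Visuomotor delay identification and delayed-swarm stability analysis.

Flying insects track moving visual targets with a sensorimotor latency of
tens of milliseconds, and that latency varies across individuals. This
package implements, end to end on synthetic data with known ground truth,
the computational chain used to quantify such delays and to ask what a
population of heterogeneous delays does to a visually interconnected swarm:

1. **Stimulus and trial synthesis** — triangular-sweep stimulus signals
   (odd harmonics only), responder trajectories from low-order rational
   transfer functions G(s) with transport delays e^(−sτ), output noise at a
   controlled amplitude SNR, and multi-camera pixel detections of 3-D
   scenes (`delaysync.synthetic_data`).
2. **3-D tracking** — DLT triangulation, combinatorial data association by
   minimum reprojection error, Kalman bridging of detection dropouts, and
   solo/group segmentation by pairwise coherence (`delaysync.tracking3d`).
3. **System identification** — frequency domain for records longer than
   1.5 s: Welch coherence γ²(f) = |P_xy|²/(P_x P_y), a chirp-Z-transform
   frequency response Ĥ(f) on the coherent band (γ² > 0.6), and a grid
   search over transport delays τ ∈ [0, 200] ms (1 ms steps) with a
   Sanathanan–Koerner rational fit per candidate, scored by FIT/MSE/FPE
   (`delaysync.sysid_freq`); time domain for shorter records: ARX least
   squares with a sample-delay grid (`delaysync.sysid_time`).
4. **Delay populations** — shifted gamma distributions
   g(τ) = a^m/Γ(m) (τ−τ_m)^(m−1) e^(−a(τ−τ_m)), with moments E = m/a,
   V = m/a², Laplace transform a^m/(a+λ)^m, and maximum-likelihood fitting
   (`delaysync.delay_dist`).
5. **Swarm model** — N planar agents with
   ẋ_i = −(1/N) Σ_j (α x_i − β x_j(t−τ_ij)) plus a short-range exponential
   repulsion, its scalar mean-field reduction
   Ċ = −αC + β ∫ C(t−τ) g(τ) dτ, and the Hopf stability boundary of the
   characteristic equation λ + α − β e^(−λτ_m) a^m/(a+λ)^m = 0
   (`delaysync.swarm_dde`, `delaysync.stability`).
6. **Pipeline** — seeded population replicas: draw delays, synthesize
   trials, identify, fit the delay distribution, map stability
   (`delaysync.pipeline`), with a thin `delaysync` command-line interface.

It is intended for researchers in collective animal behavior and swarm
robotics who want a tested, reproducible reference implementation of this
analysis chain, or who want to benchmark identification choices against
known ground truth.

## Worked example

Identify the tracking dynamics of a synthetic responder — a 3-pole/3-zero
transfer function with a 15 ms transport delay — from a 4 s steady-state
tracking record at 120 Hz:

```python
from delaysync.synthetic_data import example_responder_3p3z, SWEEP_4S_SCHEDULE
from delaysync.pipeline import make_trial
from delaysync.sysid_freq import identify_frequency_domain

model = example_responder_3p3z()          # 3 poles, 3 zeros, 15 ms delay
stim, resp = make_trial(model, SWEEP_4S_SCHEDULE, duration=4.0)
best, ranked = identify_frequency_domain(stim, resp, orders=[(2, 1), (3, 3), (4, 3)])
print(f"winner: {best.n_poles} poles / {best.n_zeros} zeros, delay = {1000*best.tau:.0f} ms")
for r in ranked:
    print(f"  ({r.n_poles},{r.n_zeros})  FIT {r.fit_percent:7.2f}%   FPE {r.fpe:.2e}   delay {1000*r.delay_s:.0f} ms")
```

prints

```
winner: 3 poles / 3 zeros, delay = 15 ms
  (3,3)  FIT  100.00%   FPE 4.68e-29   delay 15 ms
  (4,3)  FIT   99.98%   FPE 2.74e-09   delay 16 ms
  (2,1)  FIT   29.91%   FPE 1.40e-02   delay 17 ms
```

The true structure wins with an essentially perfect band fit and the exact
generating delay; the over-parameterized candidate matches the band almost
as well (hence the FPE penalty matters), and the under-parameterized one
cannot reproduce the response. With measurement noise at amplitude SNR 10
the identified model still reproduces the noise-free trajectory to a median
fit of ~99% over seeded replicates, and identified delays stay within a few
milliseconds of truth.

A full population replica (50 trials, SNR 20, frequency/time-domain routing
by record length, shifted-gamma fit of the identified delays, report files
and figures):

```bash
delaysync replicate --n-trials 50 --snr 20 --seed 0 --out out/
```

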