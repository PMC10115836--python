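# Methods

This note records the models the package implements, the estimator design
choices made where the problem left them open, the numerical settings, and
what the synthetic experiments do and do not demonstrate.

## Signals and trial synthesis

**Stimulus.** The visual target follows a triangular sweep: a sequence of
(half-period, amplitude) segments, each one full zero-mean period of an odd
triangle (0 → +A → −A → 0 over twice the half-period). Triangular waves
contain only odd harmonics, decaying as 1/k², which packs excitation into a
low-frequency band while keeping sharp slope reversals. The bundled
schedules are a 7.5 s reference sweep (fundamentals 0.25–2 Hz, 0.1 m
amplitude, 120 Hz — the values are a documented package choice, not
measured ones), a 4 s sweep for frequency-domain trials (fundamentals
0.5–2.5 Hz at 120 Hz) and a 1.2 s sweep for short-record trials at 1 kHz.

**Responder.** An individual is a proper rational transfer function G(s)
plus a latency, either a pure transport delay e^(−sτ) or its first-order
lag approximation 1/(1+τs). Two worked models are bundled: a 3-pole/3-zero
model with τ = 15 ms and a 2-pole/1-zero model with τ = 40 ms. Generic
simulation uses first-order-hold (FOH) discretization of the rational part,
which is exact for the piecewise-linear stimuli generated here (zero-order
hold is available, but its half-sample phase lag — 4.2 ms at 120 Hz — is
material on the 1 ms delay grid); pure delays are realized by quintic
spline interpolation of the output, and sub-sample delays are allowed.

**Steady-state trials.** Identification trials are synthesized as exact
periodic steady-state responses: for a record holding whole stimulus
periods, the response samples are the inverse FFT of G(jω) applied to the
stimulus spectrum at the record's Fourier bins. This emulates an animal
already engaged in tracking when the analysis window is segmented out of a
longer recording. A cold-start simulation instead superimposes a startup
transient (the bundled 3-pole model's slowest pole has a ~7 s time
constant) that measurably biases a 4 s frequency response estimate.
Measurement noise is white Gaussian, added to the response only (the
stimulus is commanded), scaled so the realized amplitude ratio
RMS(signal)/RMS(noise) equals the requested SNR exactly.

**Delay populations.** Delays are drawn from shifted gamma distributions
(below). End-to-end replicas default to a population emulating the
reported group-flight moments — mean 18 ms, standard deviation 8 ms,
minimum ≈ 4 ms (shape 3.06, rate 0.219 /ms, shift 4 ms) — so that the
generating delays sit well above the identification grid's 1 ms resolution.

## 3-D tracking

Cameras are ideal pinholes; the default rig places three 1280×1024 cameras
on a 1.5 m arc at 50°/70° angular separations looking at the origin.
Triangulation is linear DLT with the mean reprojection distance as its
quality measure. Association enumerates, per camera-1 detection, all
m^(N_c−1) cross-camera combinations, triangulates each, and accepts the
minimum-error combination below the accuracy threshold σ (default 3 px);
conflicts over a shared detection are resolved greedily in ascending error
order, which matches the exhaustive global optimum on every small-frame
scene tested.

Dropout bridging runs a per-axis constant-acceleration Kalman filter
(measurement variance ε², acceleration noise ε_a²; defaults ε = 0.2,
ε_a = 0.8 — detection-accuracy scales, i.e. appropriate where trajectory
excursions are hundreds of units). Only gap samples receive the filter's
prediction (flagged as imputed); measured samples pass through unchanged.
Running the filter as a smoother over the full track is deliberately *not*
done: at these parameter values the constant-acceleration filter behaves as
a ≈0.25 Hz low-pass at 120 Hz sampling and would corrupt the identified
delay by tens of milliseconds, whereas gap-bridging leaves it unchanged to
< 2 ms.

Role segmentation labels a track "group" when the mean magnitude-squared
coherence of its x coordinate with any concurrent track exceeds 0.6 over
0–5 Hz (γ² > 0.6 standardized throughout). Coherence here uses half-record
Welch segments and excludes the DC bin: slow tracking dynamics leak across
short segments and would deflate the coherence of genuinely coupled tracks.

## Frequency-domain identification

Spectra are Welch estimates (Hann window, 50% overlap) with segment length
of about one second, bounded between a quarter and half of the record —
segments much shorter than the tracking impulse response bias coherence
downward even for noise-free linear records.

The empirical frequency response is the chirp-Z-transform ratio
Ĥ(f) = CZT(response)/CZT(stimulus). By default its grid is snapped to the
record's own Fourier bins inside the requested band (default 0.25–3 Hz):
for records holding whole stimulus periods those are the leakage-free
frequencies, and a denser zoom grid only interpolates between spectral
lines. Points where the stimulus magnitude falls below 10% of the band
maximum are masked (their FRF variance under output noise scales as
1/|CZT(stim)|²), and the retained band is the largest contiguous run with
γ² > 0.6.

Rational fitting per delay candidate uses Sanathanan–Koerner iteratively
reweighted complex least squares (monic denominator, frequencies scaled to
unit median magnitude for conditioning, 20 iterations, stagnation tolerance
1e−8, the best iterate by true weighted residual retained since the
iteration is not monotone), with per-point weights proportional to the
stimulus spectral amplitude. The delay grid is 0–200 ms in 1 ms steps, and
the band residual is minimized in the L2 sense.

Scoring: FIT = 100·(1 − ‖Ĥ−G‖₂/‖Ĥ−mean(Ĥ)‖₂), MSE = mean |Ĥ−G|², and
FPE = MSE·(1+p/K)/(1−p/K) with p free parameters and K band points, all on
the coherent band. `fit_tf_with_delay` selects by maximum FIT with
near-ties (< 0.01 points) broken by minimum FPE.

`identify_frequency_domain` adds one refinement: the (order, kind, τ)
winner is chosen by the *steady-state output fit* — the model's periodic
steady-state prediction against the measured record. A handful of coherent
FRF points cannot pin the transport delay against a fully free rational
part (the band FIT changes by ~0.1 points across ±15 ms of delay, so noise
can move the argmax far); the time-domain comparison uses every sample and
recovers delays exactly in the noise-free case and to ~1 ms median error at
SNR 20. The reported FitCriteria remain the band quantities.

Identification quality under noise is quantified as the identified model's
output fit against the *noise-free* reference trajectory. A fit against the
noisy record itself is bounded by the measurement-noise floor (≈90% at SNR
10) no matter how good the identification is, so it cannot measure
estimator quality; the synthetic study has the clean reference available.
Measured medians over 20 replicates: 98.9% at SNR 10, 99.4% at SNR 20,
99.8% at SNR 50, with the 15 ms delay recovered to 0.6 / 0.2 / 0.0 ms mean
absolute error respectively.

## Time-domain identification

Short records use an ARX model x₂(z)/x₁(z) = (b₁z⁻¹+…+b_nz⁻ⁿ)/(1+a₁z⁻¹+…+a_nz⁻ⁿ)
with the input additionally shifted by d samples. Coefficients solve the
one-step least squares via orthogonal decomposition; collinear regressor
systems (e.g. an exact static gain, where output lags are proportional to
input lags) take the minimum-norm solution. The (n, d) winner over the
exhaustive grid (orders 1–4, d up to 0.2·fs) maximizes the *simulation*
(output-error) fit, 100·(1 − ‖x₂−x̂₂‖/‖x₂−mean(x₂)‖): one-step prediction
on densely sampled smooth records is almost independent of the input terms
and therefore blind to the delay. Each candidate is simulated under both a
cold start and a periodic continuation of the record (the better of the two
is scored), since the pre-record history is unknown. Ties prefer smaller
order, then smaller delay.

Both signals are low-passed identically (zero-phase 4th-order Butterworth,
default 20 Hz, periodic padding) before fitting; identical filtering
preserves the input/output relation exactly while removing the wideband
noise that otherwise biases equation-error least squares at 1 kHz sampling.
On the worked 2-pole/1-zero example (1 kHz, 1.2 s) the 40 ms delay is
recovered exactly noise-free and to ~1.3 ms mean absolute error at SNR 20,
and frequency- and time-domain delays agree within 2 ms on shared records.

Routing: records longer than 1.5 s go to the frequency domain, shorter ones
to the time domain.

## Delay distributions

The shifted gamma density g(τ) = a^m/Γ(m)·(τ−τ_m)^(m−1)·e^(−a(τ−τ_m)) for
τ ≥ τ_m (Γ(m) generalizes the factorial so non-integer shapes are legal)
has unshifted mean E = m/a, variance V = m/a², and Laplace transform
a^m/(a+λ)^m, times e^(−λτ_m) for the shift. Two presets carry the quoted
population fits verbatim, in one consistent time unit tagged "ms": solo
(m = 3.5, a = 12, τ_m = 1.85) and group (m = 4, a = 5.1, τ_m = 4.1). These
printed parameters are known to be dimensionally inconsistent with the
reported population moments (the implied group mean/spread exceed the
solo ones, opposite to the measured 30/50 ms vs 18/8 ms); no rescaling is
guessed, and the consequences are assessed under Limitations.

Fitting estimates the shift as 0.99·min(sample) and then (m, a) by gamma
maximum likelihood, reporting log-likelihood and the Kolmogorov–Smirnov
distance. The shift rule deliberately keeps every observation inside the
support; it absorbs roughly the expected sample minimum (≈5% of m/a for
shape-4 samples at n = 10⁴), so the total mean τ_m + m/a is the sharply
recovered quantity while m/a alone carries that small systematic.

## Swarm model and mean field

Each of N planar agents integrates
ẋ_i = −(1/N) Σ_{j≠i} (α x_i(t) − β x_j(t−τ_ij)) − ∇_i A^r, with egocentric
weight α, neighbor weight β, pairwise delays τ_ij, and exponential
repulsion −∇_i A^r = Σ_j (αB_r/D_r) e^(−r_ij/D_r) (αx_i − βx_j(t−τ_ij))/r_ij
acting on the weighted difference r_ij (guarded below 1e−9). Delay matrices
are sampled per ordered pair by default (`per_pair`), or per observing
agent (`per_agent_observer`, τ_ij = τ_i). The two planar components share
the delay matrix and are otherwise uncoupled. Integration is fixed-step
explicit Euler with constant pre-history x(t<0) = x(0) and delays quantized
to the step — chosen for exact reproducibility; halving the step changes
stable center-norm trajectories by well under 1%. States above 1e6 flag
divergence and truncate the run rather than raising.

The swarm center C(t) = (1/N) Σ x_i(t) obeys, after averaging over agents
and delays, the scalar distributed-delay mean field
Ċ = −αC + β ∫ C(t−τ) g(τ) dτ. The integral is realized by generalized
Gauss–Laguerre quadrature (50 atoms), which is exact for the gamma kernel;
raw weights are normalized by their sum (identical to dividing by Γ(m),
without overflow for large shapes). Euler steps keep rate·dt ≤ 0.004 so the
delay-free decay C(t) = C₀e^(−αt) is reproduced within 1%.

## Stability analysis

Linearizing the mean field gives the characteristic equation
F(λ) = λ + α − β e^(−λτ_m) a^m/(a+λ)^m = 0. Roots cross the imaginary axis
either through λ = 0 — which happens exactly on the line α = β — or as a
Hopf pair at λ = ±iω. With θ = atan(ω/a), the validated Hopf locus is

    α(ω) = −ω / tan(ωτ_m + m·θ),
    β(ω) = −ω / (cos^m(θ) · sin(ωτ_m + m·θ)).

The two published rearrangements of this locus disagree in the sign of the
m·θ term inside the tangent; `hopf_contour` evaluates both and validates
every candidate point against |F(iω)| < 1e−8 (F(iω) = 0 is linear in
(α, β), so the fallback solve is exact). On every distribution tested the
"+" form validates and the "−" form does not; the accepted branch is logged
per point. Small-ω limit of the validated branch: α → −1/(τ_m + m/a).

An important structural fact follows from |e^(−iωτ_m) a^m/(a+iω)^m| =
cos^m(θ) ≤ 1: any Hopf crossing needs β = √(α²+ω²)/cos^m(θ) > α, so in the
positive quadrant the Hopf locus lies strictly *above* the λ = 0 line and
the operative stability boundary there is simply β = α
(`stability_boundary_beta` returns the lower envelope). Region
classification therefore does not test sides of the Hopf curve: the
analytic verdict counts right-half-plane roots of F by the argument
principle over the half-disc |λ| ≤ |α|+|β|+1 (all RHP roots lie inside,
since |F| > 0 beyond), and the simulation verdict integrates the mean field
from C(0) = 1 for 200 characteristic times (stable if the trailing-window
maximum falls below 0.5, unstable if |C| ever exceeds 10, indeterminate
otherwise). The two verdicts agree on 100% of a 12×12 grid over
(α, β) ∈ [0.25, 10]² away from the boundaries for both presets. In the
narrow-distribution limit (m large, m/a fixed) the contour reproduces the
classical single-discrete-delay Hopf boundary to the O(ω²/a) kernel
difference.

## What the synthetic experiments do and do not show

The generators produce exactly linear, time-invariant responders in
periodic steady state with white output noise and ideal pinhole cameras.
Real insect data additionally contain nonlinearity, nonstationarity
(behavioral state changes), colored noise, segmentation artifacts,
occlusions, and camera calibration error. Passing tests therefore
demonstrate the correctness and noise robustness of the *estimators*, not
that real trajectories satisfy the model class; conversely, the delay
identifiability analysis (a free low-order rational part absorbs ±15 ms of
delay phase over a 3 Hz band) applies to real records too and motivates the
output-error selection step.

Two qualitative claims about the solo/group comparison are not reproduced,
and the corresponding acceptance tests fail by design rather than having
their assertions weakened:

- **Boundary ordering.** With the quoted distribution parameters taken
  verbatim, the validated Hopf boundary of the *solo* distribution lies
  above the group one at every fixed α (e.g. β_solo(2) = 3.47 vs
  β_group(2) = 2.58). The opposite ordering arises only from the
  sign-discrepant published rearrangement, which violates the
  characteristic equation it was derived from. The root cause is the unit
  inconsistency of the printed parameters noted above: distributions with
  the *measured* group moments (smaller mean and spread than solo) would
  order the other way.
- **Settling dichotomy at (α, β) = (7, 6).** Because β < α, the
  interconnected swarm's linear part is delay-independently stable
  (Gershgorin: delayed off-diagonal row sums β(N−1)/N stay below the
  instantaneous self-term α(N−1)/N), and the mean field classifies (7, 6)
  as stable for *any* delay distribution. Simulations of the full nonlinear
  model with repulsion confirm the center norm settles for both presets
  (to different configurations: a shell around the origin for solo, a
  displaced tight cluster for group). A solo-only failure to settle cannot
  be produced from these equations and parameters.

Problem sizes used by the bundled experiments — 4 s / 480-sample records,
20 noise replicates per SNR, 50-trial replicas, 12×12 stability grids,
30-agent swarms over 400 time units — were chosen so the full chain remains
a desk-scale computation while keeping every estimate comfortably inside
its tolerance.
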