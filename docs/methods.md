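# Methods

`spikeforce` trains a leaky integrate-and-fire (LIF) spiking recurrent
network and its parameter-matched instantaneous firing-rate reduction on
the same dynamical-system task, with identical random structure and
identical FORCE hyperparameters, and compares what the two networks learn.
This note records the models, the numerical choices, and what the shipped
experiments do and do not show.

## Network models

**Spiking network.** N LIF neurons with membrane time constant τ_m,
threshold v_th, reset v_reset, refractory period τ_ref:

    τ_m dv_i/dt = −v_i + I_i,    v_i ≥ v_th ⇒ spike, v_i ← v_reset

Spikes drive a double-exponential synapse (rise τ_r, decay τ_d):

    dh_i/dt = −h_i/τ_r + (1/(τ_r τ_d)) Σ_k δ(t − t_ik)
    dr_i/dt = −r_i/τ_d + h_i

The postsynaptic currents r form the *neural basis*; the network output is
the linear readout x̂ = φᵀ r. Each neuron receives

    I_i = I_bias + Σ_j (G ω0 + Q η φᵀ)_ij r_j

with a sparse Gaussian reservoir ω0 (entries N(0, 1/(N p²)), kept with
probability p), a feedback encoder η with Uniform(−1,1) entries, and
strength knobs G (chaos) and Q (feedback). The learned part Q η φᵀ is rank
M and is never materialized as an N×N matrix.

**Rate network.** Identical in every parameter and random draw, except
that spiking is replaced by the steady-state transfer function (f–I curve)
of the same neuron,

    R(I) = [τ_ref − τ_m ln((I − v_th)/(I − v_reset))]⁻¹  for I > v_th, else 0,

which drives the same synaptic filter. The denominator uses τ_ref (the
refractory period enters the inter-spike interval additively); with the
default constants τ_r = τ_ref = 2 ms the distinction is invisible, but it
matters for other parameter sets.

Defaults (mV/ms): τ_r = 2, τ_d = 20, τ_m = 10, τ_ref = 2, v_reset = −65,
v_th = −40, I_bias = −40 (the rheobase, with unit resistance absorbed).

**Units of the basis.** Neuron constants are held in milliseconds (their
customary display units), but the synaptic filter carries a factor 1000 so
that r is a firing rate in spikes/second — numerically identical to
integrating the filter equations in SI seconds. This is the scale on which
the FORCE learning rates α below are meaningful: with r in spikes/ms the
effective ridge penalty λ = 1/α would be ~10⁶ too strong and no decoder
would ever leave zero at the standard α values.

**Ignition.** With I_bias exactly at rheobase, an idle network is a fixed
point: sub-threshold voltages never cross threshold, and a rate network
with r = 0 feeds itself zero rate forever (and recursive least squares
cannot leave it, since P r = 0). Fresh states are therefore ignited:
LIF voltages start Uniform(v_reset, +30 mV) — a fraction of neurons above
threshold, the customary desynchronized start for FORCE-trained spiking
reservoirs — and the rate network's postsynaptic currents start
Uniform(0, 100) spikes/s. Both draws are seeded; a matched pair shares
every other random draw (reservoir, encoders, state seed).

## FORCE training

The decoder is learned online by recursive least squares. With basis
sample r and error e = x̂ − x:

    P ← P − (P r)(P r)ᵀ / (1 + rᵀ P r),    φ ← φ − (P r) eᵀ

initialized as φ = 0, P = α I. P is updated before φ within one step.
The rank-1 update is exactly symmetric, so round-off asymmetry in P grows
only at ~1e-16 per update; the compiled loop re-symmetrizes P every 100
updates (the numpy reference implementation does so every update). α acts
as a learning rate
and equals 1/λ of the equivalent batch ridge problem; on a fixed basis the
RLS decoder is identical to the ridge solution (tested to 1e-8).

Training runs in three phases: *pre* (φ = 0, spontaneous chaotic
dynamics), *learn* (RLS every Δt_RLS, instantaneous basis sample, no
averaging between updates), *post* (φ frozen — all test errors are
computed here). The supervisor clock starts at learn onset and continues
through the post phase, so periodic tasks should train for a whole number
of periods. External inputs (the pitchfork kick signal) are injected as
additive currents through a dedicated Uniform(−1,1) encoder scaled by Q,
share the supervisor clock, and are zero during the pre phase.

**RLS interval.** The package default for the 5 Hz sine task is
Δt_RLS = 0.25 ms (the value the published protocols print for that task).
Coarser intervals leave a deterministic frequency bias in the learned
oscillator: in this implementation the rate network's post-training error
grows from ~2e-5 at 0.25–1 ms to ~5e-3 at 5 ms (integrated squared error
over 0.4 s). The scaling experiments, whose interval the published
protocols leave open, use 1 ms; so does the decoder-correlation scan,
where 0.25 ms and 1 ms give indistinguishable convergence and 1 ms
quarters the update cost.

## Tasks (synthetic supervisors)

All targets are generated on the integration grid (dt = 0.05 ms by
default; generators accept coarser grids and linear resampling):

- **sine** — 5 Hz, unit amplitude (the workhorse task).
- **product** — product of 1 Hz and 2 Hz sines.
- **fourier** — 9 modes sin(nπt), frequencies 0.5–4.5 Hz.
- **ode2joy** — 5 note components (G, F, E, D, C); the opening bar is
  encoded as E-E-F-G quarter notes at 1 s beats of a 4 s bar, each the
  positive half of a 2 Hz sine (half notes would use 1 Hz). The published
  task description names the notes but not their order; any fixed 4 s
  five-component pulse train preserves the task structure. Optionally an HDTS clock (16
  sequential |sin| pulses partitioning the bar) is appended.
- **pitchfork** — γx' = rx − x³ + p(t) with r = 1, γ = 0.01 s; kicks
  p(t) are square pulses, gaps U(0.1, 0.5) s, widths U(0.005, 0.01) s,
  heights N(0, 2²). The kick train doubles as the network input.
- **lorenz** — classic parameters ρ = 28, σ = 10, β = 8/3 (an alternative
  printed set σ = 5, β = 7/3 is reachable through `LorenzSpec`); forward
  Euler by default, RK4 behind a flag.

What the generators emulate is the *task structure* only: they carry no
measurement noise, no trial-to-trial jitter, no non-stationarity. All
trial-to-trial variability in the experiments originates in the spiking
mechanism itself, which is exactly the quantity under study; passing tests
say nothing about robustness to noisy or drifting real-world supervisors.

## Analyses

- **Test error** E = (1/M) Σ_i ∫ (x̂_i − x_i)² dt (dt in seconds, not
  normalized by duration); RMSE is the time-and-dimension-averaged root.
- **Convergence.** A network counts as converged when E is below 1% of
  the integrated target power over the same window. The absolute
  thresholds printed alongside the published protocols (5e-6/5e-5) are
  inconsistent with the spiking variance floor those same protocols
  report (~1e-3 per unit time, which lower-bounds any spiking network's
  unaligned MSE); the relative criterion separates locked oscillators
  (0.1–1% of target power) from failed cells (~100%) unambiguously. The
  absolute constants remain available in `spikeforce.force`.
- **Decoder correlation** — Pearson correlation over all N×M entries with
  grand means (affine-invariant).
- **Decoder swapping** — the four combinations {spiking, rate} ×
  {φ_S, φ_R} run without learning, each continuing from the end-of-training
  state of its own network kind. Swapped decoders reproduce the task with
  a slight time dilation/contraction, so multi-period L2 windows against
  the undilated target accumulate phase error; judge swapped runs on
  amplitude/frequency/waveform, or on short windows.
- **Trial alignment** — periodic test output is cut into period windows;
  each window is circularly rolled so its maximum lands at the expected
  peak time (0.05 s for the 5 Hz task). Spiking readouts are first
  smoothed by a circular 0.025 s boxcar to locate the peak; the unsmoothed
  samples are rolled. Rolling never alters the multiset of values in a
  window.
- **Bias–variance decomposition** over aligned trials x̂_j:
  Bias² = time-average of (mean_j x̂_j − x)²; Var = cross-trial average of
  the per-trial time-averaged squared deviation from the trial mean (the
  1/n_rep-inside convention, which makes Bias² + Var exactly the mean
  time-averaged squared error; the printed formula omits the 1/n_rep).
  Reported proportion: Var/(Bias² + Var).
- **Scaling fits** — least squares on (log10 N, log10 RMSE) using every
  repetition as a point; non-positive RMSEs excluded with a warning.
- **Return maps** — smoothing by a 21-step moving average, local maxima
  via `scipy.signal.argrelextrema` with a ±10000-step neighbourhood,
  successive-maximum pairs returned.

## Numerical choices

- Forward Euler at dt = 0.05 ms for every network simulation; the spike's
  synaptic effect is the exact integral of the delta drive (h jumps by
  1000/(τ_r τ_d)), so it is step-size independent.
- Threshold crossing is detected after the voltage update; reset happens
  the same step; the voltage is clamped at v_reset for the whole
  refractory window (consecutive spikes are ≥ τ_ref apart by
  construction).
- The transfer function maps I ≤ v_th + 1e-12 mV to zero, absorbing the
  logarithmic singularity while changing rates by < 1e-9 of the maximum.
- The static reservoir matvec — the runtime bottleneck — runs as a dense
  float32 BLAS product (at p = 0.3–0.4 the matrix is effectively dense and
  SIMD beats sparse gathers ~2×); all state, decoder, and RLS arithmetic
  is float64. The float32 rounding acts as a ~1e-7 relative perturbation
  of the chaotic reservoir drive and is invisible at the precision of any
  reported quantity; spiking runs remain bit-reproducible for a fixed
  seed on a given BLAS.
- Row balancing subtracts each row's nonzero-entry mean from the nonzero
  entries only, giving exact zero row sums while preserving the sparsity
  pattern (balancing over all entries would densify the matrix). The
  slow-learning interchangeability experiments run unbalanced reservoirs;
  the fast-learning and scaling protocols run balanced ones, matching the
  respective published protocols.

## Shipped experiment scales

CI-sized presets (`*_small`) and the acceptance script run desk-scale
versions of the protocols; `*_native` presets carry the full published
sizes (40×40 grids, 21 seeds, N up to 25 600) and are meant for a cluster.
The desk-scale choices:

- scaling: sizes {200, 400, 800, 1600}, 2–3 seeds each, T_train = 5 s,
  T_test = 0.4 s, (Q,G) = (20, 0.125), Δt_RLS = 1 ms, row balanced; the
  spiking exponent is fitted at α = 5e-6 and the rate exponent at
  α = 5e-4 (rate networks are most efficient at faster learning);
- decoder-correlation scan: three cells (20, 0.125), (25, 0.15),
  (28, 0.17) at N = 2000, α = 5e-6, T_train = 2 s, Δt_RLS = 1 ms,
  unbalanced;
- cross-trial variance: a row-balanced spiking network at (25, 0.15)
  trained 2 s at Δt_RLS = 0.25 ms; 50 aligned repetitions (10 s) in the
  acceptance script, 20 in the test suite.

At these seed counts the per-size RMSE scatter (~0.25 dex, driven by
occasional small-N networks that fail to phase-lock) leaves a standard
error of roughly ±0.15 on the scaling exponent, and the measured spiking
slope tends to land near −0.6 rather than −0.5; the cross-trial variance
of a single trained network varies by ±40% across seeds. The
decoder-correlation scan reports the best of three cells where the
published figure optimized over 1600, so its value is a lower bound on
the attainable correlation.

## Known limitations

- Only the LIF neuron and its f–I reduction are implemented (no
  conductance synapses, no other neuron models).
- The rate network is a *single-neuron, instantaneous* reduction; it
  reproduces cross-trial mean behaviour of the driven spiking network but
  not spike-time clustering effects (peaks/troughs in cross-trial mean
  currents), which is part of the scientific point.
- Chaotic tasks (Lorenz) are reproduced in distribution (return maps),
  not trajectory-wise; trained chaotic outputs diverge from the target
  after the feedback is frozen.
- `ExperimentConfig` sweeps run serially; cells are independent and
  deterministic per seed, so sharding across processes is trivial but not
  built in.
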