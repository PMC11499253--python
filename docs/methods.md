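# Methods

This note records the models implemented in `linedyn`, the assumptions
behind them, the defaults of the synthetic-data generator, and the numerical
choices made where the underlying methodology is open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The rSLDS and its inference

The generative model is a recurrent switching linear dynamical system: a
discrete state `z_t ∈ {1..K}` selects a linear dynamics matrix for the
continuous latents `x_t ∈ R^D`, observations are linear-Gaussian in `x_t`,
and the transition probabilities depend on the current latent through a
softmax (`R x_t + r + P[z_t]`). With `K = 1` this reduces to a standard
linear dynamical system.

Inference (`linedyn.rslds`) is a structured EM scheme:

1. **Discrete E-step** — per-frame state log-likelihoods of the current
   smoothed latent path under each state's dynamics, combined with the
   recurrent transition logits, run through HMM forward–backward.
2. **Continuous E-step** — a Kalman/RTS smoother with per-frame dynamics
   blended by the discrete posteriors (a Gaussian structured approximation;
   exact for `K = 1`).
3. **M-steps** — closed-form weighted regressions for `(A_k, b_k, Q_k)`
   from the smoothed second moments, closed-form emissions `(C, d, S)` with
   diagonal observation noise, and a multinomial-logistic fit of the
   transition parameters on the Viterbi-style state path.

Initialization is PCA for the emissions/latents and k-means on
`[x, dx]` for the discrete path; multiple restarts keep the best objective.
The objective recorded per iteration is the Kalman-filter marginal
likelihood under the blended dynamics — a surrogate for the ELBO that is
monitored for improvement rather than guaranteed monotone; the test suite
asserts improvement from initialization and absence of catastrophic
decreases. States occupied on fewer than `min_state_frac` of frames are
pruned with a warning. Fitted eigenvalues with `|lam| ≥ 1` are capped at a
tau ceiling of 1e5 frames and flagged unstable.

Latents are identified only up to an invertible linear map, so every
quantitative check in the package compares eigenvalue spectra, mode
correlations, or subspace geometry — never raw latent coordinates.

**Time constants and score.** `tau = |1/log|lam||` per eigenvalue, in
frames, divided by the frame rate for seconds. Complex conjugate pairs
contribute two equal taus from the shared magnitude, so a rotational plane
scores `log2(tau1/tau2) = 0` — the correct "no dominant slow mode" answer.
(A deduplicated per-pair listing would leave the score undefined for a
2-D fit with a complex pair.) When `K > 1` the score is taken from the
state housing the overall slowest dimension.

**Forward-simulation accuracy.** From each frame's posterior latent the
model is rolled forward `Δt` frames under the most likely state's dynamics;
`1 − minmax-normalized MSE` gives the bounded per-frame accuracy and the
mean per-dimension Pearson R² the variance-explained summary.

**Perturbation fitting.** `fit_excluding_windows` fits on the data outside
the perturbation windows plus a 20-s post-window margin (the smoother runs
per contiguous segment), then freezes the parameters, infers latents for
the whole session, and forward-simulates from each window's end state
through the post-window period. The pooled cvR² against the inferred
latents measures whether the model predicts the relaxation it never saw.

**Attractor-line distance.** The attractor line of the slowest state is
the set of latent points whose fast eigen-mode coordinates sit at their
fixed-point values. Distances are reported in units of each fast mode's
*stationary* innovation spread, `sd = innovation_sd / sqrt(1 − |lam|²)` —
the natural width of the noise band the trajectory occupies around the
line. A trajectory is "back on the attractor" when it re-enters twice that
band; a per-step innovation unit would declare even the unperturbed
trajectory permanently off the line (its stationary fluctuation is several
per-step sd wide).

## Synthetic-data generator

The generator (`linedyn.synthetic`) emulates a 10-minute mating-assay
session at 10 Hz with 100 neurons.

**Bout structure.** An appetitive sniffing phase (~40 s) precedes
copulation bouts (mounts escalating to intromissions) at a roughly
stationary rate; durations and inter-bout intervals are log-normal with a
13.7-s mean copulation IBI (dispersion sigma 0.35 log-units for IBIs, 0.25
for durations). Sniff bouts are interleaved in longer IBIs. Escalation
ordering (sniff before first mount before first intromission) holds by
construction.

**Latents.** The receptive regime has three dimensions: a slow integrator
(tau 100 s) charged mainly by sustained drive during copulation plus small
onset kicks; a contact-locked fast dimension (tau 2.5 s) tracking the bout
envelope; and a transient fast dimension (tau 5 s) kicked at contact onsets
with random sign per event. The unreceptive regime has two equal fast
dimensions (tau 1.5 s, comparable to indicator decay) driven by
random-signed contact kicks and innovation noise — fast dynamics
time-locked to behaviour, with no integration.

Several of these choices are identifiability-driven and were settled with
an OLS-on-true-latents oracle during design:

- *Why a contact-locked fast dimension?* The slow dimension's sustained
  bout drive is unmodelled input to the (input-free) rSLDS. Its
  within-bout charging correlates the input with the state and inflates
  the fitted slow tau by 50–100% unless a fast dimension tracks the bout
  envelope, in which case the joint fit attributes the input through that
  dimension's coupling and the slow eigenvalue is recovered with ~12%
  median error.
- *Why random-signed transient kicks?* Positive-only kicks arrive at
  activity troughs (just after the IBI decay), which biases fast AR
  coefficients downward by an amount that depends on event rate and
  splits nominally equal spectra. Random signs (mixed excited/suppressed
  transient responses, as in real populations) remove the correlation.
- *Why tau 1.5 s in the unreceptive regime?* The Fisher floor for an AR
  eigenvalue at `T = 6000` frames is `sqrt((1+a)/((1−a)T))`; at tau 5 s
  the resulting score noise makes occasional spurious "slow modes"
  unavoidable, while at 1.5 s the unreceptive score stays below 0.2 in
  every session.
- *Why a stationary bout rate and moderate IBI dispersion?* Escalating or
  strongly clustered input has low-frequency power that an input-free fit
  absorbs into the dynamics, again inflating the slow tau.

**Emissions.** `y = C x + d + noise` with sparse Gaussian loadings
(default 30% zeros), emission noise sd 0.3, then per-neuron z-scoring
(matching the preprocessing applied to extracted traces). Calcium-kernel
convolution is deliberately absent: the pipeline consumes extracted,
deconvolved traces.

**Female behaviour.** During each copulation bout the female accepts
(lordose/wiggle) with probability `sigmoid(gain · (x_slow − threshold))`
on the raw slow-latent level (threshold 1.5 latent units ≈ mid-ramp), or
resists (dart/kick); appetitive bouts fill the gaps. Across sessions the
acceptance fraction therefore tracks the slow-latent level, which the
pipeline can recover.

**Perturbations.** A kick vector (by default orthogonal to the slow
dimension) is held on during each window, with the same innovation-noise
stream as the unperturbed simulation, so the paired difference of the two
runs is the exact deterministic kick response. `suppress_bouts` removes
male bouts during windows and a recovery margin, emulating the behavioural
pause that accompanies a remote interruption of mating.

**What the generator does not emulate:** photon/indicator noise structure
(noise is white Gaussian), calcium-kernel temporal smearing, cell-to-cell
correlated noise, drift/bleaching, pose-level behaviour, or cross-day
registration error. Passing tests therefore demonstrate correctness of the
analysis chain under the stated linear-Gaussian conditions, not robustness
to every artefact of real recordings.

## Single-cell metrics

- **Choice probability** — ROC area of 1-s binned responses during two
  behaviours (equal to Mann-Whitney U/(nm), tie-corrected). The null
  permutes the behaviour assignment of the binned samples (bout-level
  permutation yields too few distinct values under the 2-sigma rule when
  bouts are few); tuned = CP outside [0.3, 0.7] and more than 2 shuffle
  s.d. from the shuffle mean.
- **ACHW** — autocorrelation `r_k = c_k/c_0` with `c_k` the 1/T-normalized
  lagged covariance; the half-width is the linearly interpolated lag where
  `r` reaches 0.5, censored (and flagged) at a 100-s maximum lag.
  Affine-invariant by construction.
- **GLMs** — per-neuron ridge regression on lagged binary indicators of
  male sniff/mount/intromission over a 10-s window (filter length
  `10·frame_rate + 1`); the coupled variant adds the simultaneous activity
  of all other neurons (self excluded). Ridge strength is chosen by nested
  CV on a log grid when not given. Folds are frame-interleaved: with the
  session-long ramp, contiguous held-out blocks sit at activity levels the
  regressors cannot encode and drive R² negative for reasons unrelated to
  model quality.
- **Decoder** — bouts merged within 5 s into trials, trials split into
  folds, training frames class-balanced (chance 0.5), linear SVM, F1 on
  held-out frames; the control refits after randomly reassigning class
  labels to whole bouts.
- **Photometry** — `Fn = 100·(F470 − F405fit)/F405fit` with the isosbestic
  channel fit by least squares (scale + offset); a precomputed fit can be
  supplied. Peri-event averages z-score each event window against a
  −5 to −3 s baseline with a 1e-6 sd floor (flagged when engaged).

## Integrator model

The slow-dimension series is regressed as
`x_t = a x_{t−1} + b + W u_t + eps` with `u` the three binary male
behaviour indicators (no kernel convolution; optional smoothing is exposed
but off). Least squares with contiguous-fold cvR²; `tau` from `a`; `W`
unconstrained in sign; OLS standard errors reported. With all-zero inputs
the model collapses to AR(1) and is flagged.

## FORCE network

A tanh rate network `tau dx/dt = −x + g (J r) + H(t)` with `g = 1.5`,
`tau = 0.5 s`, Euler `dt = 0.05 s`, and readout `z = J r`. The full
recurrent matrix is trained by recursive least squares against target
traces. Training passes are **teacher-forced**: because an exact solution
has `J r = f`, the recurrent drive is clamped to the targets while RLS
fits `J` along the visited states; the reported per-unit reconstruction r²
comes from a final learning-off pass under the same protocol. Fully
autonomous (closed-loop) rollouts are available via `ForceRNN.generate`;
over hundreds of seconds they accumulate drift away from the training
trajectory, which is the known cost of reproducing long non-periodic
trajectories with RLS-trained recurrent weights. Fixed/slow-point analysis
minimizes `q = ½‖dx/dt‖²` (L-BFGS with analytic gradients) from visited or
supplied initial states, deduplicates within a radius, and classifies
points by the Jacobian spectrum; `tol` accepts fixed points, `slow_tol`
the looser slow points. The gain can either multiply the summed recurrent
input (`gain_mode="sum"`, as typeset in the governing equation) or scale
`J` at initialization (`"matrix"`, the common construction); both are
provided.

## Spiking network

1,000 current-based LIF neurons (`tau_m = 20 ms`, threshold 0.1, reset 0),
feedback inhibition from one graded unit driven by the population mean
rate (`tau_I = 50 ms`, gain `g_inh = 4.25`), recurrent gain `g = 2.5`.
A 200-neuron subnetwork has 12% recurrent density (vs 1%) with weights
`U(0, 1/sqrt(N_p))` and synaptic time constant 20 s (vs 100 ms). Euler
integration at 1 ms with a small Gaussian membrane noise; the noise enters
the derivative (per-step sd `noise_scale · dt/tau_m`, `noise_scale = 0.2`)
— injecting N(0,1)/5 directly per 1-ms step would make the membrane a
random walk with stationary sd ≈ 0.6, six times threshold, and the network
would spike continuously.

Spikes contribute a fixed 1-ms pulse area (`spike_width/tau`) to the
synaptic and inhibitory low-passes, independent of `dt`, so halving the
integration step changes the population trajectories by well under 5% RMS.
The inner loop maintains the recurrent drive `W p` event-driven — two
per-group decay accumulators plus sparse column updates on spikes —
algebraically identical to the full matvec at a fraction of the cost.

**Stimulus calibration.** The external input is 20 one-second pulses,
amplitude 2.0, driving a random 25% of each subpopulation through uniform
weights. The inter-stimulus interval defaults to 2.5 s: the ramp
observable is the synaptic activation that *persists* between pulses, and
with `tau_s = 20 s` an ISI comparable to `tau_s` (e.g. 10 s) drives the
per-pulse balance to equilibrium within ~5 pulses — feedback inhibition at
the stated gains prevents the recurrent regime that would otherwise keep
the ramp going — after which rank statistics ride on noise. An ISI well
inside `tau_s` keeps every one of the 20 increments above the noise floor
and the ramp strictly monotone. Both ISI and width remain configuration
knobs. In `subnetwork_summary`, hold values below 1% of the mean pulse
peak count as fully decayed (zero persistence) before the Spearman ramp
statistic: without the floor, the "abolished ramp" statistic of the
hypothesis-1 network is a rank correlation of ~1e-7 numerical residue and
exceeds 0.3 by pure chance in ~10% of runs.

Hypothesis manipulations: `h1` sets the subnetwork synaptic time constant
to 100 ms (removes the integrator); `h2` halves the external input gain of
the subnetwork and raises the rest by 50% (reweights input instead).

## Pipeline and formats

Rasters travel as HDF5 (`raster` dataset + `frame_rate` attribute), NPZ,
or headerless CSV; bout tables as CSV (`actor, behavior, start_frame,
stop_frame`; half-open 0-based frame intervals). Rows with NaNs are
dropped with a warning; un-z-scored rasters are z-scored with a warning;
constant neurons are flagged. NWB reading is not included — sessions from
public archives should be exported to one of the supported formats first.
`run_pipeline` chains simulate → single-cell metrics → rSLDS → integrator
→ decoder, records per-stage status, wall time and seeds in a manifest,
and skips stages whose dependencies failed. All randomness flows through
seeded generators with per-component substreams, so a manifest fully
determines its outputs.

## Problem sizes

Default study conditions are 10-minute sessions (6,000 frames) with 100
neurons; recovery studies use 20 sessions per regime; the GLM coupling
contrast uses 20-neuron, 5-minute sessions over 20 seeds; FORCE
reconstruction uses a 200-s session; the spiking contrast simulates the
full 1,000-neuron network over the 20-pulse protocol for 20 seeds per
condition. These sizes keep the complete test suite and the acceptance
script to a few minutes each on one CPU while leaving every statistical
margin comfortable.

## Known limitations

- The structured EM is a Gaussian approximation; no guarantee of ELBO
  monotonicity, and `K > 1` fits depend on initialization (restarts
  mitigate).
- Unmodelled, state-correlated input biases input-free AR estimates — a
  property of the estimation problem, not of this implementation; the
  generator documents how its defaults avoid the worst of it, and real
  analyses should consider the input-driven integrator fit alongside the
  input-free rSLDS.
- FORCE autonomous generation drifts over long horizons (see above).
- The LIF model reads the spike indicator as a fixed-area pulse; absolute
  rates depend on the Euler step only through threshold-crossing timing.
- `select_model_order` scores by held-out filter likelihood, which on
  short sessions can prefer smaller `D` than the generative one when a
  dimension carries little variance.
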