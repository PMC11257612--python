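# Methods

This note documents the models, estimators and numerical choices behind
`chemoinfo`: what is computed, under which assumptions, and what the
synthetic-data tests do and do not establish.

## The estimation problems

A bacterium climbing a static exponential gradient `c(x) = c0 exp(g x)`
cares about the behaviorally-relevant signal — the rate of change of
log-concentration along its own path,

    s(t) = d log c / dt = g * vx(t),

with `vx` the up-gradient velocity.  In shallow gradients `s` is well
approximated as a stationary Gaussian process with autocovariance
`g^2 sigma_v^2 exp(-|u|/tau_v)`; `sigma_v^2` is the variance of `vx` and
`tau_v` its correlation time (set by run duration, tumble persistence and
rotational diffusion).

Two observers try to estimate `s(t)` causally:

1. **Physical limit.**  An ideal sensor sees every ligand molecule arriving
   at the receptor array: a Poisson process with rate `r(t) = k_D c(t)`,
   `k_D = 4 D l` for an absorbing disk of radius `l` (converted to
   s^-1 uM^-1 with 602.214 molecules/um^3/uM).  With many arrivals per
   correlation time the count noise is Gaussian:
   `(r - r0)/r0 = x + xi/sqrt(r0)`, where `x = log(c/c0)` integrates `s` and
   `xi` is unit white noise.
2. **Kinase channel.**  An *E. coli* cell sees only its CheA kinase
   activity, modeled by linear response with an adaptive (zero-integral)
   kernel `K_r(t) = G_r[(1/tau_1) e^{-t/tau_1} - (1/tau_2) e^{-t/tau_2}]`
   plus internal Ornstein-Uhlenbeck noise with autocovariance
   `D_n tau_n exp(-|u|/tau_n)`.  The prefactor convention is `D_n tau_n`
   (stationary variance), matching the "diffusivity" reading of `D_n` and
   giving an activity s.d. of ~0.084 at the measured medians, the scale of
   the recorded slow fluctuations.  `tau_1 = 0` is used in all information
   calculations (the measured tau_1 mostly reflects reporter kinetics);
   `tau_1 > 0` is supported in simulation and fitting.

Sensing accuracy is the transfer-entropy rate from signal to observations,
which for Gaussian processes equals a predictive-information decay rate and
depends only on the squared correlation `rho^2` between `s` and its optimal
causal estimate:

    Idot = (1/tau_v) * rho^2 / (1 - rho^2)   [nats/s].

This exact form is used throughout; the small-`rho^2` linearization is
`rho^2/tau_v`.  Bits are nats/ln 2 at the interface.  Efficiency is
`eta = Idot_a / Idot_r`, and the dimensionless SNRs are
`gamma_r = 2 r0 g^2 sigma_v^2 tau_v^3` and
`gamma_a = (G_r^2/D_n) r0^2 g^2 sigma_v^2 tau_v`.

## Solving the filters

Both problems are linear-Gaussian with rational spectra, solved two
independent ways:

* **Riccati (primary).**  Steady-state Kalman-Bucy filtering.  Physical
  limit: state `(s, x)`, observation `x` in white noise of spectral density
  `1/r0`.  Kinase channel: state `(s, x, m, n)` with `m` the adaptation
  state driven by the *observed* noisy input, so the arrival noise appears
  in both the process and the observation — a correlated-noise generalized
  CARE, solved with `scipy.linalg.solve_continuous_are(..., s=...)`.
  States are rescaled to unit natural magnitude for conditioning.  The pure
  integrator `dx = s dt` is nudged by a leak of 1e-9/tau_v (the CARE
  solver needs the marginal mode strictly detectable; the effect on the
  posterior variance is < 1e-14 relative, verified by a test).
* **Spectral factorization (oracle).**  Causal Wiener filtering by
  Wiener-Hopf factorization of the observation spectrum, done on polynomial
  coefficients: transfer-function numerators are interpolated exactly by
  FFT on a circle, the spectrum's numerator is factored by root splitting,
  the signal-innovation cross spectrum is partial-fractioned, and the
  causal part integrated in closed form over residue pairs.  This route
  needs strictly Hurwitz dynamics, so it runs with a 1e-8/tau_v integrator
  leak.  Riccati and spectral posterior variances agree to ~1e-12 relative
  on a (c0, g) grid; the test tolerance is 1e-6.

Useful limits, all verified by tests: `Idot_r -> gamma_r/(4 tau_v)` as
`gamma_r -> 0`; `Idot_a -> Idot_r` as `D_n -> 0`; and in the internal-
noise-dominated regime `Idot_a -> gamma_a/(4 tau_v)` — the latter only
under its own assumptions (`tau_2 ~ tau_n` much longer than `tau_v`); at
the measured `tau_2 = 7.4 s`, `tau_n = 8.7 s` the exact solution sits a few
percent below the asymptote.  `Idot_a/g^2` is constant to <0.1% up to
0.05 mm^-1, while `Idot_r/g^2` carries a sqrt(gamma_r)-order correction and
decreases markedly with g — the saturation of the physical limit.  The
shallow-gradient limit is evaluated at g = 1e-3 mm^-1: deep in the g^2
regime for the ratio, while keeping `1 - posterior_var/sigma_s^2` far above
double-precision round-off (at 1e-6 mm^-1 that difference would lose half
its digits).

Published population-median parameters ship with the package
(`params_published.yaml`).  The capture constant is carried as the rounded
1.2e5 s^-1 uM^-1 that the downstream numbers use; first-principles
`capture_rate_constant(800, 0.06)` gives 1.156e5.  Only the gain G_r*k_D is
background-specific (3.2, 2.28, 0.251 at 0.1, 1, 10 uM); the remaining
parameters vary weakly with background and the 1 uM medians are reused —
the same construction as the model curves in the comparison figures.
The steady-state activity a0 = 0.3 is a conventional adapted value; it does
not enter the information rates.

## Synthetic data

The generators emulate the three calibration experiments; their defaults
are the experimental conditions (500 tracks of 60 s at 20 Hz; 10 up + 10
down steps of 30 s with 7.5 s imaged baseline, 65 s unimaged recovery,
0.75 s frames; 50 noise traces of 1200 s at 1 Hz with measurement noise
s.d. 0.02).

* **Tracks** are 2D run-tumble kinematics: exponential run/tumble dwell
  times, wrapped-Cauchy reorientations with mean cosine 0.33, rotational
  diffusion 0.062 rad^2/s during runs.  Only the `vx` statistics matter
  downstream, so swimming speed and mean run duration are *calibrated* so
  that the data-analysis chain itself (tumble detection, median-Prun
  binning, duration-weighted ACF, exponential fit) recovers the target
  (sigma_v^2, tau_v) on a population with the default heterogeneity; the
  calibration iterates generator-vs-pipeline three times and centers with a
  final six-seed average.  Emergent V(t) is close to, but not exactly, a
  single exponential (tumble dwells add a fast component) — which is why
  calibration against the pipeline, not against naive formulas, is needed.
* **Cell-to-cell variability** is lognormal with independent marginals.
  Motility varies along the run-fraction axis (mean run duration cv 0.15,
  common tumble duration) plus an independent speed cv of 0.10, so that
  binning cells by Prun selects cells with similar run statistics — the
  premise of the median-Prun analysis.  Kinase parameters vary with cv
  0.10-0.20.  Real populations are, if anything, broader; passing recovery
  tests therefore demonstrates correctness of the estimators under
  moderate, well-specified heterogeneity, not robustness to arbitrary
  phenotype distributions.
* **Step responses** simulate each cell continuously through the whole
  alternating protocol (adaptation continues through unimaged gaps) and
  sample only imaged frames.  Steps are +-8% of background: responses
  ~0.18 activity units, a sizable fraction of the dynamic range as in the
  recordings, still linear.  The generator's kinase uses the measured fast
  lobe tau_1 = 0.5 s (CheY-CheZ relaxation); concentration inputs are
  piecewise constant, for which the exponential-state updates are exact at
  the sample times.
* **Noise traces** use the exact discrete OU update (valid at any dt) plus
  white measurement noise; filtered arrival noise is an order of magnitude
  smaller and off by default.

What the generators do not emulate: localization noise and tracking
losses in the tracks (a truncation mode approximates short trajectories),
photobleaching and image-level artifacts in FRET, ligand consumption, and
any correlation between swimming and signaling phenotypes (independence is
also assumed by the population-variability analysis).

## Estimation pipeline

All fits are Gaussian-likelihood MAP with log-uniform priors (+-3 decades
around moment-based guesses), multi-start Nelder-Mead, and uncertainties
from an affine-invariant ensemble sampler (32 walkers, 2000 steps, half
burn-in, acceptance fraction checked against [0.1, 0.7]); everything is
seeded.  Parameter-specific points:

* **Velocity ACF.**  Tumbles are detected by speed drops (< 0.5 x median)
  or turn-rate spikes (> 6 rad/s), candidates merged across < 0.1 s gaps;
  cells need >= 2 tumbles; the median-Prun bin is +-0.01.  The pooled,
  duration-weighted ACF is fit over lags [2*dt, 10 s].  The likelihood uses
  the exact Bartlett covariance of an exponential-ACF estimate
  (`(sig2^2 tau/T)[e^{-|t-s|/tau}(1+|t-s|/tau) + e^{-(t+s)/tau}(1+(t+s)/tau)]`),
  built from a first-pass fit and iterated once.  This matters: ACF errors
  are strongly lag-correlated, and a diagonal likelihood at these data
  sizes yields tau_v estimates with ~7% scatter and heavy tails along a
  (variance, correlation-time) valley; the GLS form reduces the scatter to
  ~2%.  The reported uncertainty is a cell-level bootstrap of the pooled
  estimator, which also captures the random composition of the Prun bin.
* **Step responses.**  Per cell, repeats are baseline-aligned on the
  pre-step window and averaged per direction; up and down are fit jointly
  with shared (G_r k_D, tau_1, tau_2), tau_2 > tau_1 enforced through the
  prior, tau_1 restricted to the physically known sub-second window
  [0.05, 2] s (at 0.75-s sampling an unbounded tau_1 admits a degenerate
  large-tau_1/inflated-gain branch).  The likelihood uses the full residual
  covariance of a baseline-subtracted repeat average under an OU-plus-white
  noise model estimated from the dataset itself: subtracting the
  per-direction mean response from every block leaves pure-noise residuals
  on the full 37.5-s imaged grid (long enough to identify the slow
  correlation time), whose same-block covariance is (1 - 1/n_rep) times
  the noise covariance; the pooled matrix is least-squares fitted with
  `var_slow e^{-|u|/tau} + var_white delta`.  This covariance matters
  because the slow kinase noise (tau_n ~ 8.7 s) mimics the adaptation
  decay (tau_2 ~ 7.4 s).  Per-cell tau_2 posteriors remain ~30% wide and
  the gain MAPs carry a small (~5%) upward bias from the asymmetric
  tau_1-gain ridge — information limits of the 0.75-s protocol, consistent
  with the reported population-level precision.  The onset frame (valve
  switch mid-frame) is excluded.
* **Kinase noise.**  The marginal likelihood of (D_n, tau_n, a0) is the
  exact scalar Kalman filter of an OU state observed in white noise
  (numba-compiled; verified against the dense-covariance Gaussian
  likelihood to 1e-8 on small instances).  MAP estimates carry the usual
  small downward finite-record bias on tau_n (~2-3% at 1200 s).
* **MWC gain.**  (G_inf, K_i) minimize squared *log*-gain residuals,
  weighted by relative measurement error; the weighted form is what
  reproduces the reported gain-curve parameters (the unweighted fit lands
  at 3.12/0.77 instead of 3.5/0.83).
* **Aggregation.**  Population medians of per-cell MAPs; variance
  `(1/N)(1.4826 mad(MAPs))^2 + (1/N^2) sum_k sigma_k^2` with per-cell
  sigma from 1.4826 x mad of posterior samples.  Derived quantities get
  first-order error propagation with independent errors and
  central-difference gradients.  Population variability of eta is
  propagated by Monte-Carlo with independent lognormal marginals (in place
  of a maximum-likelihood treatment; the assumption of uncorrelated
  swimming, response and noise parameters is shared).

## Chemotaxis simulations

Agents run-and-tumble in 2D; each carries an online optimal estimator —
the exported steady-state Kalman-Bucy filter integrated as a state-space
recursion (Euler at dt = 0.01 s <= 0.01 tau_v), not a truncated-kernel
convolution.  Ideal agents observe the Gaussianized arrival rate; E. coli
agents observe their own simulated kinase activity (adaptive response with
tau_1 = 0, internal OU noise, arrival noise entering both the adaptation
state and the activity).  Agents experience the idealized local signal
`s = g vx`; absolute concentration enters only through r0, so the domain is
unbounded and the |log c| excursion is checked against the linearization
assumption (warning beyond 1).

The tumble hazard is `lambda0 max(0, 1 - beta * shat)`.  Both agent types
use the same dimensionless modulation depth, `beta = 0.5/std(shat)`, per
condition.  In this matched, weak-modulation family the linear-response
drift is proportional to the estimator-signal correlation, and the
square-root information-drift relation `va/vr = sqrt(Idot_a/Idot_r)` holds
within simulation error at every tested gradient.  A drift-*maximizing*
hazard (available as an option) sits in the saturated, effectively
bang-bang regime: it climbs ~3x faster but deliberately breaks the
linear-response premise, and the square-root relation degrades to ~0.6-0.75
of the predicted ratio — the relation is a statement about matched
near-linear policies, not about arbitrary ones.

The estimator-correlation oracle runs with an exactly-OU velocity
(`signal_model="ou"`), for which the filter's assumptions hold and the
empirical rho^2 reproduces the analytic value to within Monte-Carlo error.
Run-tumble velocities have only approximately exponential autocovariance,
so their empirical correlations track the analytic rho^2 more loosely
(~20%).

## Problem sizes and determinism

Default analysis sizes are the experimental ones (above); the drift
comparison uses 500 agents x 500 s per condition at five gradients.  All
randomness flows from explicit integer seeds (numpy `SeedSequence` for
stage separation; the ensemble sampler is seeded through its internal
RandomState), and every generator records its seed and parameters in the
output metadata.  Reports from the orchestration layer are byte-identical
across reruns with the same configuration.

## Known limitations

* The kinase filter treats the activity trace as continuously observed;
  finite frame rates enter only through the simulated experiments.
* The Gaussian arrival approximation requires r0*dt >> 1 per bin; at the
  measured backgrounds r0 >= 1.2e4/s this is comfortably satisfied.
* eta rests on the re-derived causal-filter solutions; the shallow-limit
  value at 1 uM (0.0142) and the printed population-median inputs
  reproduce the reported efficiency, but at the steepest gradient the
  exact solution gives 0.1206, i.e. the reported one-significant-figure
  0.1.
* Per-cell tau_2 and gain estimates are noisy at the protocol's
  information limit; population medians over 30 cells carry ~5-8%
  sampling scatter.
* The drift relation is established for the matched-modulation policy
  family in shallow-to-moderate gradients; strongly saturated policies or
  very steep gradients leave its domain of validity.  Even within it, the
  measured va/vr sits on average ~5-10% below sqrt(Idot_a/Idot_r) — a
  small systematic from the run-tumble velocity not being exactly OU and
  from the finite modulation depth — comparable to the per-condition
  simulation SEMs at the default ensemble sizes.
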