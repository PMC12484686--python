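# Methods

## The system

A circadian clock drives a downstream reporter ("output") whose synthesis
rate is a periodic function of the clock state.  Molecular noise in the
clock makes every cycle of the output a little longer or shorter; the
quantity of interest is the coefficient of variation (CV = SD/mean) of the
output's oscillation period, and how it depends on the *waveform* of the
clock-to-output regulation.

Two model levels are implemented.

**Goodwin clock + reporter** (`models.simulate_goodwin_output`): the
three-variable transcriptional–translational negative feedback loop —
mRNA u, cytosolic protein v, nuclear protein w with Hill repression
1/(1 + w^m) — plus a reporter x synthesized at rate α + β·g(w) and degraded
at rate k.  Gaussian white noise of intensity ε√D enters the u (gene
expression) equation only.  The clock equations carry a 1/τ time rescaling,
τ being the free-running period of the unscaled deterministic loop, so one
clock cycle spans ≈ 1 time unit ("one day").  We take the noise term as
printed in the rescaled equations (ξ δ-correlated in rescaled time), giving
an Euler–Maruyama u-increment τ·ε√D·√Δt·N(0,1).

The Hill coefficient is m = 10 with k_u = k_v = k_w = 0.1: the smallest
round value above the classical oscillation threshold (m > 8 for equal
degradation rates).  The measured unscaled period is then 39.73 time units,
matching the τ = 39.7 used throughout, which is why we believe m = 10 is
the right closure of this otherwise under-determined parameter.  τ is
always *measured* (`measure_deterministic_period`), never assumed.

**Phase oscillator + reporter** (`models.simulate_phase_output`): the
generic reduction θ' = ω + ε√D·ξ(t), x' = α + β·f(θ) − k·x, with f a
truncated Fourier series Σᵢ (Aᵢ cos iθ + Bᵢ sin iθ).  The biological
constraint α + β f(θ) ≥ 0 is checked on a dense θ grid plus the
Cauchy–Schwarz bound |f| ≤ √(H·Σrᵢ²).  Coefficients are conventionally
normalized to Σᵢ(Aᵢ² + Bᵢ²) = 1; every CV measure in this package is
exactly invariant under coefficient rescaling (the reporter is a linear
filter of the drive, so rescaling f is an affine map of x that moves no
marker), so normalization matters only for reporting and for the sampling
bounds.

Both systems are integrated by Euler–Maruyama with Δt = 10⁻³ (configurable);
period statistics discard t < 100 in the canonical runs.

## Period definitions

`periodstats` supports two cycle markers.

*Threshold (checkpoint) periods*: upward crossings of a fixed threshold —
the midpoint (max+min)/2 of the **noiseless** limit cycle — linearly
interpolated, with same-direction crossings closer than 0.25τ merged
(keep-first) to suppress noise-induced double counts.  The noiseless cycle
defines the threshold so that the crossing acts as a fixed checkpoint in
the sense of circadian gating.

*Peak periods*: one dominant local maximum per cycle, found by sequential
tracking: seed at the highest maximum in the first 1.5τ, then repeatedly
take the highest local maximum within ±0.2τ of (previous marker + τ),
falling back to the nearest maximum within ±τ/2, and refine each marker by
a three-point quadratic fit.  The tracking window is the load-bearing
convention: molecular noise splits flat peaks into clusters of micro-maxima,
and many multi-harmonic waveforms carry secondary bumps half a cycle away,
so naive local-maximum detection (or windows anchored to threshold
crossings, whose boundaries can land on a peak) produces spurious
double-counted or family-switched intervals.  The ±0.2τ half-width covers
many standard deviations of per-cycle period jitter at clock-level CV
(~3% of τ) while excluding secondary peak families; it also reproduces the
reference values of the sinusoidal case.  When a cycle has no detectable
peak at all (possible under very sharp Goodwin regulation, where the
noise-amplified spike height of a weak cycle can vanish), the tracker skips
one period, and interval statistics exclude intervals outside
[0.4τ, 1.6τ] — a skipped beat is a missing marker, not a double-length
period.

## Closed-form CV (`analyticcv`)

For the phase model the period CV at a fixed checkpoint has the weak-noise
form CV = (ε/τ)·√(R_ΘΘ + R_hh + 2R_Θh) + O(ε²), with

* R_ΘΘ = Dτ²/(2πω), the system-level phase variance — checkpoint- and
  waveform-independent;
* R_hh, the amplitude-deviation autocorrelation, and R_Θh, the
  phase–amplitude cross term (the only possibly negative one), which are
  explicit double/single sums over the harmonics of f involving the
  low-pass amplitudes √(rᵢ²/(k² + (iω)²)) and phase offsets
  Φᵢ(t_cp) = iωt_cp + arctan((kAᵢ − iωBᵢ)/(iωAᵢ + kBᵢ)) + (π/2)(1 − sgn(iωAᵢ + kBᵢ)).

Conventions: sgn(0) = +1 (the correction vanishes, continuous with the
limit from above); the checkpoint t_cp is the upward midpoint crossing of
the noiseless limit cycle, and when several exist per period the one with
the steepest slope is used (it maximizes the common denominator
Σᵢ iω√(rᵢ²/(k²+(iω)²))·cos Φᵢ, i.e. the best-conditioned checkpoint); the
harmonic sums truncate exactly at the function's harmonic count.  α and β
do not appear anywhere — the analytical counterpart of the simulation
observation that basal synthesis rate and coupling strength leave the CV
unchanged.  The implementation is validated against direct simulation:
threshold-CV estimates approach the closed form as ε shrinks
(ε ∈ {0.2, 0.1, 0.05} in `numeric_vs_analytic`; the check compares the
endpoints, because at these waveforms the systematic deviation is already
below the Monte-Carlo floor of the intermediate runs).  The numeric side
must track a *single* crossing family (`crossing_times(select="tracked")`)
when the waveform crosses its midpoint more than once per cycle — mixing
crossing families inflates the measured CV several-fold and is a
measurement artifact, not period variability.  As a spot check, for the
evolutionary optimum below, simulation gives 2.477 ± 0.028% against 2.509%
analytic at ε = 0.1.

A compiled evaluator (`AnalyticCVEvaluator`, ~3 µs/call) re-implements the
same composition with a 96-point grid plus Newton refinement for the
extrema and crossings; it agrees with the scipy/brentq reference path to
~10⁻⁴ pp and powers the samplers.

## The simulation CV evaluator: frozen paths and common random numbers

`SimulationCVEvaluator` exploits two structural facts: the phase path θ(t)
does not depend on f, and x is *linear* in the drive.  One noise
realization is drawn per evaluator (from its seed), the reporter responses
to cos(iθ(t)), sin(iθ(t)) and the constant drive are integrated once, and
any coefficient vector is then scored by linearly combining those basis
responses — exactly equal to simulating that function on that path.  Every
candidate (and the sine reference) is therefore evaluated under common
random numbers, which removes most Monte-Carlo noise from *comparisons*
between functions.  This matters: the CV differences that decide
"is any random function below the sine?" are a few hundredths of a
percentage point, far below independent-run noise at any affordable run
length.  Peak detection inside the evaluator runs on a 5-fold-thinned
series (verified to reproduce full-resolution marker times to ~0.01 pp;
10-fold thinning is biased on flat peaks and is not used).  Where a
comparison is borderline, experiments re-score the candidates on a longer
common path (up to 20 000 intervals; "two-stage precision").

## Sampling regulatory-function space (`search`)

* *Random scan*: coefficients uniform on [−1,1]^(2H), all-zero draws
  rejected.
* *Gibbs sampling*: the Methods-style grid Gibbs chain — coordinates
  x₁..x_{2H} on [−1,1]; each update evaluates exp(−CV) at the N+1 grid
  points xᵢ = −1 + 2j/N and samples by exact cumulative-weight inversion
  (no Metropolis step); one sample recorded per full sweep; burn-in
  discarded.  CV enters the weight in **percent** units (a fractional CV
  gives a nearly flat weight that cannot shift the distribution); the
  switch is exposed as `GibbsConfig.cv_units`.  Coordinates are *not*
  renormalized inside the chain — both evaluators are coefficient-scale
  invariant, so this is exact, and normalization is applied in reporting.
* *Evolutionary minimization*: population 64, Gaussian mutation σ = 0.05,
  top-quarter truncation selection, elitism, 300 generations (settings are
  repo choices, documented as non-canonical).

Desk scales: the analytic chain runs 101 000 sweeps at N = 100 (full scale
is 10⁷ at N = 1000); the simulation chain runs 6 000 sweeps at N = 20 with
a 150-interval chain evaluator and precise re-scoring of the retained
samples (full scale is 21 000 at N = 50).  Scaled-down chains estimate the
same stationary quantities with wider error bars; `ExperimentConfig.scale`
multiplies chain lengths and simulated periods only, never Δt or model
parameters.

## What the generators emulate — and what they do not

All data are generated by the models themselves; there is no external
dataset.  The phase model is the generic abstraction of *any*
self-sustained clock near its limit cycle with weak white phase noise: its
conclusions transfer to real circadian systems only insofar as (i) the
clock noise is approximately Gaussian and delta-correlated, (ii) the
output is well described by a single linear production–degradation stage,
and (iii) noise in the output stage itself (ignored here: x carries no
intrinsic noise term) is subdominant.  Real reporter data additionally
carry measurement noise, trends and finite sampling, none of which are
modelled; passing tests therefore validate the mathematics and the
estimators, not the biology.

## Numerical choices and degenerate inputs

Δt = 10⁻³ everywhere the canonical figures are quoted; transient discard
t < 100 for canonical runs, 5 time units inside the simulation-Gibbs chain
evaluator (the reporter relaxes at rate k = 10, and the phase model has no
slower mode).  Run lengths: ≥4000 intervals for the single-function
reference CVs (CV standard error ≈ CV/√(2n) ≈ 0.03 pp), 500-interval scans
with 20 000-interval re-scoring for comparisons.  All-zero coefficient
vectors are invalid for normalization and get zero weight (CV = ∞ sentinel)
inside chains; a checkpoint at exactly zero slope raises an
ill-conditioned-checkpoint error in the public API and maps to zero weight
in the samplers; a negative radicand (impossible in exact arithmetic,
guarded anyway) is reported, never silently NaN.

## Known limitations and open conventions

* The ±0.2τ tracking window and the skipped-beat exclusion are repo
  conventions; period definitions for strongly multimodal waveforms are
  intrinsically ambiguous, and CV values for such functions (a few percent
  of random 5-harmonic draws) depend visibly on the convention.
* The sine-dominance *fractions* from the Gibbs chains are sharp functions
  of the reference value: the analytic chain's retained distribution is
  continuous near 2.70%, so the fraction above the sine CV moves from
  ~92% to ~98% as the reference moves from 2.70 to the exact 2.676.  We
  compare against the exact value.  Equivalently, the simulation chain
  piles mass within ±0.05 pp of the sine value, so its below-sine fraction
  is sensitive to chain scale and grid resolution.
* The evolutionary optimum of the closed-form CV in 5-harmonic space is
  *not* a pure sine: it keeps a dominant fundamental with harmonic powers
  decreasing monotonically (≈ [0.45, 0.26, 0.17, 0.11, 0.01]) and beats
  the sine's threshold CV (2.48% vs 2.68% at ε = 0.1, confirmed by direct
  simulation).  Under the *peak* period definition the same function loses
  its advantage (2.68% vs sine 2.63%), i.e. which waveform is "best"
  depends mildly on the checkpoint convention; sine-like waveforms are
  robustly near-optimal under both.
* Gillespie-style intrinsic-noise simulation, entrainment by external
  cycles, and O(ε²) corrections to the CV expansion are out of scope.
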