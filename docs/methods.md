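# Methods

## The model

The package treats the transformation of a substrate under chronic stress as
a single controlling conversion variable α(t) ∈ [0, 1) obeying the
generalized autocatalytic rate law

    dα/dt = k · α^(1−1/θ) · (1−α)^(1+1/θ),    k > 0, θ > 0.

θ interpolates between two classical kinetic regimes: θ → ∞ recovers the
logistic (Prout–Tompkins) equation dα/dt = kα(1−α), and θ = 1 gives
second-order kinetics k(1−α)². The explicit solution is

    α/(1−α) = [1 + k(t − t_o)/θ]^θ,

where the integration constant t_o is the median time (α = ½ at t = t_o).
Pinning zero conversion at t = 0 requires t_o = θ/k — note, *not* t_o = 0:
substituting t_o = 0 leaves α(0) = ½. With that choice the bracket collapses
to t/τ with τ = θ/k, and the solution is the log-logistic CDF

    α(t) = (t/τ)^θ / [1 + (t/τ)^θ],    S(t) = 1 − α(t) = 1 / [1 + (t/τ)^θ],

the Hill / median-effect curve. τ is the median response time; θ the
sigmoid steepness. All evaluators use `expit` of θ·log(t/τ) so extreme
arguments neither overflow nor lose the boundary values (survival is exactly
1 at t = 0 for any θ > 0). The rate form diverges as α → 0 for finite θ, so
boundary times are only ever evaluated through the closed forms; the rate
function rejects α ∈ {0, 1}.

## Dose dependence

Concentration enters through the modified Haber rule: at a fixed effect
level, (C − C₀)^β · t = 1/κ. Pegging the effect at α = ½ gives
τ = [κ(C − C₀)^β]^(−1) and k = κθ(C − C₀)^β. β is a *user input*, not a
fitted quantity: β = −1 (beneficial agent; τ grows linearly with dose) is
the regime relevant to antioxidants, and the data available here cannot
identify departures from it. C₀ defaults to 0, the convention used
throughout the mixture development. The Haber coefficient κ (units
1/(h·(wt.%)^β)) and the linear potency slope κᵢ (h per wt.%; τ = τ₀ + κᵢCᵢ)
are deliberately distinct named quantities — the same Greek letter is
conventionally overloaded — with explicit converters (reciprocal for β = −1,
C₀ = 0). A `HaberLaw` stores its own β, so coefficients fitted under
different exponents cannot be silently compared.

## Mixtures

All mixture rules assume every component follows a Hill law with one shared
θ; heterogeneous shapes have no entry point in the API. With τᵢ the time
constant agent i would give acting alone at its dosed concentration:

* independent chemical action: rate constants add, τ_mix = [Σ 1/τᵢ]^(−1)
  (this is *not* Bliss-style response multiplication, which is out of
  scope);
* Concentration Addition: τ_mix = [Σ τᵢ^(−1/β)]^(−β), a power mean of order
  −1/β — a plain sum for β = −1, the harmonic form (identical to
  independent action) for β = 1;
* Plackett–Hewlett: τ_mix = [Σ τᵢ^(−1/βλ)]^(−βλ). λ = 1 is CA; λ > 1 with
  β = −1 bows the isobole toward the origin (synergy).

The binary forms are extended to any number of components by extending the
sums. The synergy rule used for the amine/phenolic antioxidant pair is the
β = −1, λ = 2 case on top of the substrate baseline:
τ_mix = τ₀ + (Σ √τᵢ)². The baseline sits *outside* the synergy term — the
design-table arithmetic settles this (τ₀ + (√0.748 + √2.351)² = 11.41 h for
the 0.167/0.083 wt.% blend, matching the published fitted value), though it
is an interpretation rather than an explicit statement in the source data.
`synergy_tau_with_baseline` accepts zero component contributions (an absent
agent drops out); the general `ph_mixture_tau` rejects zero τᵢ because
τᵢ^(−1/βλ) is singular there — a documented asymmetry.

## Curve fitting (level 1)

A monitor trace is modelled as σ(t) = σ_min + m·t + P·α(t; τ, θ): baseline
offset, linear drift compensation, and a scaled Hill rise. The model is
linear in (σ_min, m, P) given (τ, θ), so fits use variable projection: the
nonlinear search runs over log τ (and log θ when free) with the linear
block solved exactly by `numpy.linalg.lstsq` at every step, and the
Levenberg–Marquardt tolerances set to 1e-12. Initialization: σ_min from the
first signal decile, drift from a line through the first 20% of points, τ
from the half-rise time of the detrended signal, θ from 3.45. Because the
profiled objective can hold spurious negative-amplitude minima when the
starting τ is far off, the search multi-starts from the heuristic plus τ₀ ∈
{0.15, 0.3, 0.5, 0.75}·t_max and keeps the best solution with P > 0 and
τ ∈ (0, 2·t_max]; seeded jittered restarts are a last resort, so fits are
deterministic given the seed. A curve whose detrended rise is below 0.1% of
the signal range is rejected up front as non-sigmoidal (pure drift), and a
converged fit with non-positive amplitude or out-of-window τ raises rather
than returning nonsense. Standard errors come from the Gauss–Newton
covariance s²(JᵀJ)^(−1) of the full (unprofiled) model.

A shared shape across n curves is estimated by profiling: bounded scalar
minimization over θ (tolerance 1e-6) with per-curve τ re-optimized (warm-
started) inside, then a joint 4n+1-parameter covariance for the θ standard
error. At least two curves are required — a shared parameter is undefined
for one.

## Dose regression (level 2)

τ₀ is pinned to the observed neat-substrate τ, not estimated: the reference
analysis reports the neat row reproduced exactly, and freeing τ₀ would let
the weakest-identified slopes absorb baseline error. Potency slopes are
then estimated by unweighted least squares in one of two schemes:

* `records_used="single"` (default): each κᵢ is a through-origin slope over
  that agent's single-agent rows only; every mixture row is *predicted*.
  This is the scheme that reproduces the published fitted column of the
  study design table (all 22 rows within 1.5%); back-calculating that
  column shows the single-dose slopes (≈ 4.48, 0.88, 28.32 h/wt.%) applied
  unchanged to the blends.
* `records_used="all"`: one simultaneous nonlinear fit of all κᵢ over every
  non-neat row, mixture rows included. This pulls slopes toward the blend
  data (e.g. the phenolic's slope moves by ~3%) and is the right choice
  when blends are the prediction target.

Replicate standard deviations are *not* used as weights: several printed
sds are 0.00, making inverse-variance weighting ill-posed. Every agent must
appear in at least one single-agent row (otherwise its slope is flagged
unidentifiable); a negative fitted slope is kept but flagged — the agent
behaves as a destabilizer. λ is fixed (default 2) rather than estimated;
the identity of synergistic pairs is an input.

Percent differences use the observed τ as denominator.

## Synthetic data

`generate_curve` draws equally spaced samples of the forward model
σ_min + m·t + P·α(t) plus additive Gaussian noise of sd `noise_frac·P`;
`generate_design` draws n_rep Gaussian replicates of the model τ per
composition and stores their mean and ddof-1 sd. Defaults are chosen to
emulate the study conditions: σ_min = 5 µS/cm, drift 0.1 µS/cm/h, rise
P = 100 µS/cm, θ = 3.45, 200 points per curve, 1% signal noise; designs use
the study grid (neat + 12 singles + 9 binaries capped at 0.25 wt.% total),
triplicates, and 0.3 h replicate noise on τ — the scale of the printed
replicate sds. Both generators take one integer seed
(`numpy.random.default_rng`) and are bit-reproducible.

What the generators do *not* emulate: heteroscedastic replicate variance
(the real data's sds range from 0.00 to 0.93 h), non-uniform sampling
cadence, autocorrelated drift, and any actual oxidation chemistry. Passing
recovery tests therefore demonstrate estimator correctness under the
assumed noise model, not robustness to instrument artifacts.

A note on slope recovery: with the study dose grid and 0.3 h replicate
noise, every slope carries roughly the same *absolute* standard error
(≈ 0.8 h/wt.%, set by the grid and the noisy baseline), so the dominant
agent is recovered to a few percent relative while slopes of order 1 h/wt.%
are noise-dominated. The recovery tests assert exactly this.

## Problem sizes and numerical choices

The test suite and the acceptance script use 6 curves × 200 points for
shared-shape studies (50 replications), 100 seeds for scalar Monte-Carlo
checks, and the 22-row design table for regression checks; the full suite
runs in well under a minute on one core. The ODE cross-check integrates the
rate law with DOP853 at rtol 1e-10 / atol 1e-22 — the absolute tolerance
must sit far below the smallest conversion on the grid (≈ 1e-16 for θ = 8
at t = 0.01τ) or the integrator rounds away the induction period. Isobole
evaluation, mixture algebra and dose maps are closed-form and exact to
floating point.

## Known limitations

* β and C₀ are inputs; nothing here estimates them, and the shipped design
  data could not identify them anyway.
* The per-curve τ window (0, 2·t_max] means a run truncated well before its
  induction rise is rejected rather than extrapolated.
* Synergy handling covers flagged *pairs*; a three-way synergistic blend
  would need the general Plackett–Hewlett form wired into `predict_tau`.
* The shared-θ profile assumes curves are independent; a common drift
  artifact across channels would bias θ without inflating its reported
  standard error.
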