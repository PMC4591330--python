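# Methods

This note records the models, parameter choices and numerical decisions
behind `glaucodrive`, in the spirit of a statistical package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The survival model

The endpoint is the first motor-vehicle collision (MVC); subjects without an
event are censored at their last follow-up visit, and only measurements
taken before the event enter the analysis. Covariates are measured at
6-monthly visits and treated as piecewise-constant (last observation carried
forward), which turns each subject's follow-up into counting-process
episodes `(start, stop]` with the event flag on the terminal episode.

The hazard is Weibull proportional-hazards,

    h(t | x) = λ p t^(p−1) exp(x(t)'β),   λ > 0, p > 0,

with log likelihood over episodes

    Σ_i [ d_i (log λ + log p + (p−1) log stop_i + x_i'β)
          − exp(x_i'β) λ (stop_i^p − start_i^p) ].

Two exactness properties follow from this form and are enforced by tests:
the likelihood is invariant to subdividing any episode at an interior time
(to 1e-10 relative), and tied event times need no Breslow/Efron correction
because the hazard is parametric. Time is years since study entry (the
follow-up clock, not age), and subjects enter at t = 0 with no delayed
entry.

**Standardization.** Covariates are z-scored with the baseline-visit mean
and SD across subjects — not pooled visit-level moments — so "per 1 SD" has
a fixed meaning over follow-up. Covariates for which lower values are worse
(curve coherence, binocular SAP sensitivity, MOCA) are negated after
z-scoring, so every reported hazard ratio reads "per 1 SD worse" and
HR > 1 always means higher risk with worse performance.

**Optimization.** The likelihood is maximized over (β, log λ, log p) —
log-transformed scale and shape keep positivity without constraints — by
L-BFGS-B with the analytic gradient, started from shape ∈ {0.5, 1, 2} to
guard against local optima, keeping the best optimum. The parameter
covariance is the inverse observed information (numerical Hessian at the
optimum); Wald intervals and p-values follow. Non-convergence (gradient
norm above tolerance) is surfaced as a warning carrying the norm, and the
flag is stored on the results object. A fit with zero events raises
immediately rather than returning a degenerate optimum.

## Driving-simulator metrics

**Curve coherence** searches non-negative delay shifts only — the driver
lags the road, never the reverse — with a default window of 5 s of samples;
both are configurable. At each shift the correlation uses means and SDs
recomputed on the overlapping window with population (1/n) normalization,
the standard normalized cross-correlation; this guarantees the exact-match
⇒ 1 anchor that defines the metric. The "spatial shift" is implemented as a
sample-index shift, which equates space with time under the constant-speed
assumption of the simulated drive. Constant (zero-SD) signals raise a
degenerate-input error rather than returning NaN.

**Reaction times.** The mean reaction time at each contrast is the
arithmetic mean of response latencies; misses (no press before the display
timeout) are excluded from the mean — no ceiling imputation — and reported
separately as per-contrast miss rates, since the source protocol is silent
on their handling. The corrected reaction time is `rt_low − rt_high`
exactly, so the corrected RT of group means equals the group mean of
per-subject corrected RTs. The false-positive rate divides spurious presses
by stimuli presented (not by press opportunities), so it can exceed 1. When
attributing raw button presses, a press belongs to the earliest unanswered
stimulus on screen at press time; otherwise it is spurious.

**Display contrast.** Displayed luminance is the alpha blend
`α·symbol + (1−α)·background` with a pure-white symbol. Given the
low-contrast stimulus (α = 0.1) at Michelson contrast 0.04, the implied
background is root-solved (Brent) and the high-contrast (α = 0.9) value
follows; the acceptance script recomputes this chain.

## Perimetry

Binocular sensitivity uses the perimetric dB convention `S = 10^(dB/10)`
(1/Lambert; an alternate base would be a one-line change) and the quadratic
summation `sqrt(S_L² + S_R²)`, giving the closed-form +5·log10(2) ≈ 1.505 dB
gain for equal eyes and identity for a blind eye (encoded −∞ dB, linear
sensitivity floored at 0). The mean is over all 52 non-blind-spot 24-2
locations; whether a central subset would be preferable is untestable
without the original data, so the full grid is used. Reliability thresholds
are strict inequalities ("more than" 33% / 33% / 15%), so boundary values
are retained.

## The synthetic cohort

The generator emulates the study conditions: 117 glaucoma drivers and 50
controls, visits every 0.5 y, follow-up drawn N(2.1, 0.5²) y (truncated
below at one visit interval), censoring at the last visit. Each subject
carries a latent driving ability, linear in time (`intercept ~ N(0, 1)`,
slope `~ N(−0.17, 0.15²)` per year for glaucoma; controls at
`N(0.45, 0.2²)` with slope `~ N(0, 0.05²)`). Every metric mean is affine in
current ability with Gaussian noise — the simplest mechanism producing the
assumed proportional-hazards structure — with means and spreads set from
the study's printed baseline table (e.g. low-contrast RT 0.95 − 0.75·ability
± 0.10 s) and the glaucoma slope set so the last-visit glaucoma-vs-control
contrast in low-contrast RT (≈1.22 vs 0.61 s) emerges at the default
follow-up.

Event times are exact draws from the model being fitted: the hazard uses
the *observed* per-visit metrics (z-scored against the nominal baseline
moments implied by the affine model), held piecewise-constant, and an
Exponential(1) draw is inverted through the accumulated interval cumulative
hazards — no discretization bias, and no errors-in-variables attenuation,
so downstream estimation is a well-specified recovery problem. Defaults:
shape p = 1 (the source analysis states no shape), a single true effect of
ln 2.19 per SD worse low-contrast RT, and scale λ = 0.0372/y frozen from
the packaged Monte-Carlo calibration (`calibrate_scale`) against the 9.4%
(11/117) event fraction. Controls contribute no hazard (the study observed
no control MVCs). Only the first MVC per subject is generated; recurrent
events are out of scope.

Reaction-time draws in the stimulus-log generator are lognormal (σ = 0.25)
around the ability-implied mean — a modelling choice; the true latency
distribution is not documented. One protocol inconsistency is resolved in
favour of the stated stimulus count: with ~5 stimuli per contrast in a
4-minute drive, inter-onset gaps of U(3, 6) s after each resolution cannot
fill the drive, so the generator emits the configured count with compliant
gaps and display times rather than filling the full duration.

What the generator does *not* emulate: skewed/heavy-tailed metric
distributions (UFOV and mileage are strongly right-skewed in practice;
here they are clipped Gaussians), learning effects across visits, missed
visits and irregular scheduling, measurement error correlated across
metrics beyond the shared latent ability, and informative censoring.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the stated mechanism, not robustness to real-data
pathologies.

All randomness flows from one root seed through named substreams
(subject-, road-, telemetry-, stimulus-level), so a fixed (config, seed)
reproduces the cohort byte-for-byte and any component in isolation.

## Model evaluation

Royston's D-based R²_D is used (the D variant; the source analysis names
only "Royston"): subjects' prognostic indices x'β — baseline covariate
vectors, since a time-dependent PI is undefined in the D framework — are
ranked, mapped to expected normal order statistics by Blom's approximation
Φ⁻¹((r − 3/8)/(n + 1/4)), scaled by κ = √(8/π), and the survival model is
refitted on that single regressor; its coefficient is D and
R²_D = (D²/κ²)/(π²/6 + D²/κ²). A constant PI (null model) returns R² = 0
with a degenerate flag. R²_D is invariant to affine covariate rescaling by
construction (ranks only).

Group tables use the Wilcoxon rank-sum test for continuous variables (the
source names only Fisher's exact, which applies to its categoricals) and
Fisher's exact test for 2×2 tables; r×c tables beyond 2×2 fall back to
Pearson chi-squared, as no exact r×c routine is available in the stack.

## Problem sizes and tolerances

Closed-form anchors are asserted to 1e-10–1e-12; likelihood-invariance to
1e-10 relative. Stochastic checks run at the study scale (117 subjects,
~9% events): hazard-ratio recovery uses 200 replicate cohorts (median HR
within [1.8, 2.7] of the true 2.19 and 90–99% Wald coverage), Royston
monotonicity 50 replicates per effect size, and the event-fraction
calibration check 60 replicates against a binomial band. These sizes keep
the full suite and pipeline at desk scale (a few minutes on one CPU) while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Wald intervals with ~11 events are approximate; profile-likelihood
  intervals would be preferable near the boundary but are not implemented.
* The multivariable fits inherit strong collinearity from the single latent
  ability driving all metrics, so individual adjusted HRs on simulated data
  are noisy — as in any cohort whose predictors share one cause.
* `kaplan_meier` delegates to lifelines; only the parametric model is
  authored here.
* The pipeline's `fit` stage uses the per-visit covariate table (the values
  that drive the generating hazard); metrics recomputed from raw telemetry
  in the `metrics` stage demonstrate the measurement chain and would yield
  attenuated effects if fitted, exactly as real remeasured data would.
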