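# Methods

## The paradigm and the decision model

Each trial of the paradigm shows a static face-and-object image and then a
random-dot motion probe; the observer judges the global motion direction
(two-alternative forced choice). Responses are recoded to a congruence
axis: "toward" means motion in the direction the face gazes (toward the
object), and signed coherence is positive in that direction. A gaze-induced
motion aftereffect shows up as a positive shift of the point of subjective
equality (PSE): extra toward-motion is needed before the probe looks
directionally balanced.

The observer model is a two-parameter logistic in signed coherence `x`
(percent):

    f(x) = exp((x − x_c) / b) / (1 + exp((x − x_c) / b))

with central point `x_c` (the PSE, % coherence) and scale `b` (% coherence;
smaller is steeper). The generative model used for simulation extends this
with an optional lapse rate λ — response probability
λ/2 + (1 − λ)·f(x) — but the analysis-side fit is the pure two-parameter
curve: a lapse-contaminated subject fits poorly and is handled by the R²
screen, mirroring how the original workflow absorbs such misfit. Fitting
is unweighted least squares on the seven condensed per-coherence
proportions, started from the unbiased values x_c = b = 0.5.

## Modules and the flow of data

`schedule` builds the session (7 coherence levels × 10 trials, face side
balanced within level, one flat shuffle cut into 7 contiguous blocks);
`rdk` simulates the dot stimulus and validates its realized net drift;
`observer` generates synthetic cohorts; `psychometric` condenses and fits;
`screening` applies the exclusion procedure; `inference` runs the group
tests; `io_report` reads/writes all tables and composes the pipeline. The
behavioral analysis consumes *nominal* coherence — the dot simulator is a
validation and export tool, not a pipeline stage, matching the original
analysis where only nominal coherence enters the statistics.

The package's functions and the `gazemae` command-line entry point
(simulate / rdk / fit / analyze / report) are the interface; the CLI is a
thin layer over the library.

## Stimulus simulation

Defaults reproduce the study stimulus: 400 dots of 2 px in a 230 × 230 px
field, 2 px/frame, 12-frame lifetime (200 ms at 60 Hz), 1.0 s duration.
Decisions the stimulus description leaves open are resolved as follows:

- **Coherent-subset membership** is assigned once (round(|c|/100 × 400)
  dots) and preserved through rebirths, keeping the per-frame coherent
  count exact.
- **Noise dots** redraw a uniform heading on [0, 2π) every frame
  (direction-noise rule) and move at the common speed.
- **Edges** wrap toroidally, preserving dot count and density; **reborn**
  dots appear at a uniform random position with age 0, and initial ages
  are staggered uniformly over [0, lifetime) so rebirths never
  synchronize.

The net-drift validator averages frame-to-frame horizontal displacement
over all dot-frames, excluding rebirth jumps and undoing wraparound by the
minimal toroidal image (valid because speed ≪ field/2). Its expectation is
c/100 × speed, e.g. +0.6 px/frame at +30 % coherence.

## Synthetic cohorts: what the generator emulates

Per subject, the true PSE is Normal(mean_shift, between_subject_sd) and
the slope Normal(slope_mean, slope_sd) truncated positive. Per-experiment
presets encode the study hypothesis: mean_shift = 1.36 % only for a
sighted agent with the probe on the line of sight, 0 otherwise — the shift
is a free population parameter, not hard-coded behavior. Configured
fractions of subjects are non-compliant (respond by fair coin flip,
independent of the stimulus — the simplest mechanism that triggers the
performance exclusion) or fail the attention check.

Defaults and their calibration:

- `mean_shift = 1.36 %` (on-sight sighted preset): the published group
  mean for that condition.
- `slope_mean = 4 %`, `slope_sd = 1 %`, and `between_subject_sd = 2.1 %`:
  calibrated jointly against the published SEMs. Fitting 70-trial sessions
  adds measurement noise of ~1.9 % SD to each estimated x_c at these
  slopes, so the observed SD of fitted central points is
  √(2.1² + 1.9²) ≈ 2.8 % — the SEM of ≈ 0.38 % at n = 55 that the study
  reports — and the observed effect size in the on-sight regime is ≈ 0.48.
  A markedly shallower slope would make measurement noise alone exceed the
  published total spread, which is how the calibration pins the slope
  scale.
- `frac_noncompliant = 0.35`, `frac_imc_fail = 0.17`: the published
  average exclusion rate is 47 % with about 75 % of exclusions due to
  performance; 0.35 reproduces the performance share directly, and 0.17
  solves the independent-flag union 1 − 0.65 × 0.83 × (1 − r_fit) ≈ 0.47
  for the remainder (attention-check failure rates of this size are
  common in online testing).
- `lapse = 0`: the analysis fit has no lapse parameter; the generator's
  lapse exists to probe fit robustness, not as a default condition.

What the generator does **not** emulate: reaction times, sequential
effects, learning or fatigue across blocks, retinotopic detail of the
adapting image, and any dependence of the response on the actual dot
trajectories (responses depend on nominal coherence only). Passing tests
therefore certify the analysis chain — schedule balance, fit correctness,
exclusion logic, test calibration — not the perceptual realism of
simulated observers.

## Numerical choices

- **Optimizer**: `scipy.optimize.least_squares` (trust-region reflective)
  with analytic Jacobian, bounds x_c ∈ [−100, 100], b ∈ (0, 10⁴], and
  tolerances 10⁻¹². The study's start (0.5, 0.5) runs first; a data-driven
  start (interpolated 0.5-crossing, scale = span/8) runs second; a fixed
  restart grid runs only if neither converges. The lowest SSE wins;
  restart order is fixed, so fits are reproducible. On 7-point datasets
  this reaches the global minimum found by an exhaustive refined grid
  search (verified to 10⁻⁶ in the tests).
- **b > 0 by bounds**: the sigmoid with negative b duplicates the
  parameter space; a genuinely reversed observer fits badly and is removed
  by the R² screen.
- **R²** is 1 − SSE/SStot about the mean of the seven proportions
  (standard curve-fitting-tool convention, unadjusted). Degenerate data
  with SStot = 0 get R² = 1 for a zero-residual fit and −∞ otherwise;
  non-convergent fits count as fit-screen failures.
- **Screening boundaries are strict**: accuracy exactly 0.80 and R²
  exactly 0.90 are included ("below" thresholds).
- **Exclusion-rate rounding** is round-half-up to the nearest integer
  percent.
- **t-test**: t = mean/(sd/√n) with sample sd; p two-tailed from the
  central t distribution; Bonferroni multiplies by the family size (5
  probe positions) and caps at 1. Cohen's d = mean/sd ≡ t/√n.
- **0 %-coherence trials** contribute a proportion to the fit but have no
  defined correctness and never enter the performance screen.
- **Seeding**: one master seed; per-subject streams derived via
  `numpy.random.SeedSequence.spawn`, so cohorts are reproducible and
  subjects independent.

## Simulation sizes used in validation

The validation suite and the acceptance script choose problem sizes that
keep Monte Carlo error well inside the effects being checked: type-I
calibration uses 300–500 replicate null families of 5 experiments × 8
subjects × 70 trials (family-wise expectation 1 − 0.99⁵ ≈ 4.9 %, checked
within 3 binomial SEs); the power check draws 600 replicate cohorts of 55
true central points at d = 0.48 and compares to the analytic noncentral-t
power, isolating the inference chain from psychometric measurement noise
(which the analytic oracle deliberately excludes — the full-pipeline
counterpart is the qualitative family-pattern check); parameter recovery
and the study-scale family summaries use 100-subject cohorts, averaged
over 8 replicate families in the acceptance script so single-cohort
sampling noise does not dominate the reported numbers.

## Known limitations

- The t-test's normality assumption is inherited from the original
  analysis; fitted central points at 10 trials/condition are only
  approximately normal, and at very small n the corrected test runs
  slightly conservative in our calibration runs.
- The exclusion procedure is selection on noisy statistics; it is unbiased
  for the group mean under the symmetric generative model used here, but
  real-data asymmetries (e.g., lapse correlated with bias) could couple
  screening to the estimate. The generator's lapse knob exists to explore
  exactly that.
- The reader supports externally deposited trial tables via `column_map`,
  but no analysis here depends on any external dataset.
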