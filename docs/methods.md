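# Methods

This note documents the statistical machinery, the simulator, the
calibration of its fixed constants, the numerical choices, and the
limits of what the synthetic tests can show.

## Trial tables

All analyses operate on per-trial 2AFC records: subject label, stimulus
class (S1/S2), response class (S1/S2), ordinal confidence 1..K, and
decision RT in ms. Correctness is always derived as stimulus ==
response, never stored independently. `trial_index` is the 1-based file
(or simulation) order within subject; the odd/even split-half uses its
parity, since no finer timestamp is available in the supported CSV
dialect. RT units are taken as given in the file; a scalar multiplier
is exposed for seconds-coded datasets rather than any auto-detection,
because silently misreading the RT unit would corrupt every downstream
quantity.

## Secondary variables and type-2 ROC

A secondary variable is reduced to ordinal levels 1..K with "high"
always meaning "suggests a correct response": confidence is used as
recorded; RT is discretized into K quantile bins *descending* (fastest
bin = level K), so a fast-error regime shows up honestly as type-2
AUC < 0.5 instead of being re-oriented away; composite logits are
binned ascending. Quantile cutoffs use linear interpolation (type 7,
the default of mainstream statistical environments). Ties at a cutoff
fall to the lower level — deterministic and reproducible, at the cost
of slightly uneven bins on heavily tied data. Fewer distinct values
than bins merge bins with a warning; the reported K is the number of
levels actually realized.

The type-2 curve takes K−1 cutoffs from stringent (level K alone
counts as "high") to lenient (levels ≥ 2); AUC is the trapezoid over
those points plus (0,0) and (1,1). AUC is invariant to strictly
monotone relabeling of levels, and equals a brute-force
cutoff-enumeration oracle to 1e-12 in the tests.

## Meta-d′ maximum likelihood fit

Counts enter in the standard nR_S1/nR_S2 layout (per stimulus:
response S1 with levels K..1, then response S2 with levels 1..K).
Every cell receives padding 1/(2K) before fitting — the convention
that keeps sparse subjects finite; the padding scheme is an assumption
(the analysis tradition it follows does not pin it down) and is
configurable. Type-1 indices are d′ = z(HR) − z(FAR) and
c = −(z(HR)+z(FAR))/2.

The meta-level model: stimulus distributions N(∓meta-d′/2, 1), the
meta-level type-1 criterion fixed at meta-c = c′·meta-d′ with
c′ = c/d′ (the canonical criterion linkage of the original
maximum-likelihood method; a single meta-d′, not response-specific
ones), and K−1 free type-2 criteria on each side. Predicted level
probabilities are ratios of Gaussian-CDF differences to the response
probability; the likelihood is the multinomial over levels within each
stimulus × response cell. Criteria are parameterized as ordered
cumulative log-increments around meta-c, making every parameter vector
feasible; optimization is L-BFGS-B from a deterministic start
(meta-d′ at d′, criteria at empirical cumulative-rate z-scores) with
gradient tolerance 1e-6. `converged` is the optimizer's success flag —
a well-defined boolean, because non-convergence is an exclusion
category. Meta-d′ is never clamped at zero; negative values are
meaningful for RT. Probabilities are floored at 1e-12 inside the log.

Subject exclusion follows two rules: any non-convergent fit, or any
d′ or meta-d′ outside [−1, 4] (endpoints inclusive; "outside the
range" is read as the strict exterior).

## Composite variable

Per subject, `correct ~ confidence + RT + confidence×RT` by
maximum-likelihood logistic regression on *raw* (undiscretized,
unstandardized) predictors; the linear predictor is then quantile-binned
(into the dataset's K for empirical tables, 10 for the simulation) and
treated like any other secondary variable. The construction is
deliberately in-sample — the same trials fit and score the logit — so
at small n the composite can beat its own ingredients through
overfitting; the tests document that this excess vanishes as n grows.
Complete or quasi-separation (detected from the fitter's warnings or
absurd standardized coefficients) triggers a ridge-stabilized refit
(L2 strength 1e-4) and a flag. Subjects with fewer than 20 trials or
without both correct and incorrect responses are unfittable. With the
interaction in the model and uncentered predictors, the RT main effect
is the slope at confidence = 0; the interpretable quantity is the
marginal RT effect at typical confidence.

## Reliability, disattenuation, meta-analysis

Split-half: trials partitioned by parity of trial_index; binning and
meta-d′ fitting run independently within each half; subjects with an
unfittable or non-convergent half are dropped and logged. Spearman–
Brown full-length reliability is 2r/(1+r); the screen threshold
defaults to 0.45. Disattenuation r_xy/√(r_xx·r_yy) is clamped to
[−1, 1] with an over-correction flag. Partial correlation uses the
first-order closed form with a Fisher-z CI on n−4 degrees of freedom.

Random-effects pooling: Fisher-z per study with sampling variance
1/(n−3), DerSimonian–Laird moment estimator for the between-study
variance τ², inverse-variance weights 1/(1/(n−3)+τ²), pooled z
back-transformed with a 95% normal CI. DL-on-z is the field default
when the estimator is unstated; the implementation is cross-checked in
the tests against an independently coded DL computation and against
statsmodels' `combine_effects`.

## The 2DSD simulator

Evidence for target and distractor evolves as two independent streams
with per-step (1 ms) Normal(drift, s) increments; the decision variable
is their difference, so its increment SD is s√2. Per trial, each
stream's drift is drawn Normal(ν, η); the relative-evidence start point
is Uniform(−s_z/2, +s_z/2) around the midpoint of boundaries at ±a/2.
First crossing gives the choice and decision time; RT = decision steps
+ t_er. Accumulation continues, boundary-free, for T_pd further steps
(drawn in closed form as a single Gaussian, which is exact because no
boundary applies); raw confidence is the relative evidence in favor of
the chosen option at decision + T_pd. With T_pd = 0 confidence
degenerates to the boundary reached (plus overshoot) and carries no
correctness information — the tests assert this limit. Trials that
never cross within 3000 steps are censored; censored trials and trials
with RT > 3000 ms (non-decision time included — an assumption, exposed
as a parameter) are excluded.

Per condition, raw confidence and RT are each discretized into 10
quantile levels, condition by condition; the composite logistic
regression sees the raw (continuous) confidence and RT.

### Condition grid and calibration

The manipulation grid crosses ν_target ∈ {0.004, 0.007, 0.010, 0.014,
0.020} (near-chance to near-perfect type-1 performance, d′ ≈ 0.4–3.0),
η ∈ {0.002, 0.012} and s_z ∈ {0.5, 2.0}, with ν_distractor = 0,
s = 0.1/step per stream, t_er = 300 steps. The two remaining constants
were fixed by a one-off calibration at 20,000 trials/condition
(`calibrate_defaults`): the boundary a = 2.257 makes the grid-average
d′ equal 1.13, and the post-decisional window T_pd = 16 makes the
grid-average confidence meta-d′ equal 0.81. Both targets, and the
procedure of tuning exactly these two constants to them, define the
simulation study; the calibration is not re-run by any pipeline.

The grid's value lists were chosen once, against the study's stated
behavioral envelope: the low-η/high-s_z cells produce fast errors and
RT meta-d′ down to ≈ −0.9; the high-η/low-s_z cells produce slow
errors and RT meta-d′ up to ≈ +0.65, crossing the ≈ 0.5 mark typical
of human data; and every cell's confidence meta-d′ stays bounded away
from zero (≥ ≈ 0.2), which keeps per-condition ratio statistics
estimable at the default problem size. Under this grid the maximum
over conditions of the composite/confidence meta-d′ ratio is ≈ 1.17:
in the strongest slow-error cells RT carries roughly two-thirds as
much type-2 information as confidence and the two are only partially
redundant, so the logistic combination gains well over 8%. A grid in
which that ceiling is materially lower would require either weaker
drift-rate variability (sacrificing the RT meta-d′ envelope) or a
different allocation of confidence information across cells than this
parameterization produces.

### Problem sizes and seeds

Default analyses use 20,000 counterbalanced trials per condition, a
size at which the grid averages are stable to ≈ ±0.01 and the full
grid (simulation + 60 meta-d′ fits + 20 logistic fits) runs in well
under a minute on one CPU; qualitative pattern checks (folded-X,
inverted-U) use 50,000 trials. One master seed spawns an independent
substream per condition; identical seeds reproduce every summary CSV
byte-for-byte. The target/distractor assignment is counterbalanced
exactly (n/2 each) and shuffled within the sequence so parity-based
split-halves stay balanced.

## What the synthetic data does and does not show

The generator reproduces the structural phenomena the analyses are
built to detect: graded confidence with tunable type-2 sensitivity,
slow- and fast-error RT regimes, the folded-X confidence pattern, the
confidence-RT interaction with inverted-U accuracy at low confidence,
and between-subject heterogeneity. It does *not* model: a shared
metacognitive-quality factor across subjects (so cross-subject
correlations between confidence- and RT-based meta-d′ can take either
sign in synthetic "datasets", unlike the positive correlations typical
of humans); confidence-stage noise or biases separate from evidence;
confidence-RT causal links (confidence as a stopping signal); lapses,
motor noise, or non-stationarity. Passing tests on synthetic data
therefore validate the estimators and pipelines, not any claim about
human behavior.

## Known limitations

- The meta-d′ optimizer is local; the deterministic start makes fits
  reproducible, and the tests verify the optimum dominates random
  feasible parameter vectors, but global optimality is not guaranteed
  for pathological count patterns.
- Quantile binning of heavily tied data (e.g. re-binning an ordinal
  scale into itself) can merge levels; pipelines therefore use ordinal
  confidence directly and reserve binning for continuous variables.
- Equal-width accuracy-by-RT bins are per subject, so bin widths are
  not comparable across subjects with different RT ranges (by design,
  to normalize individual RT distributions).
- The mixed-effects logistic analysis of correctness is out of scope;
  `export_glmm_table` emits the model-ready long table instead.
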