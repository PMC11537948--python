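# Methods

## Model

A positive body-composition outcome *y* (e.g. fat-mass index, kg/m²)
measured at age *t* is modelled as Box-Cox-Cole-Green,
`y ~ BCCG(L(t), M(t), S(t))`: the power-transformed ratio to the median,
`z = ((y/M)^L − 1)/(L·S)` (log branch at L = 0), is standard normal.
M is the median, S approximately the coefficient of variation, and L the
Box-Cox power that absorbs age-varying skewness.  Centile and z-score
machinery lives in `lmsref.bccg`.

Two conventions follow published LMS reference practice:

- **Truncation is ignored.**  For L ≠ 0 the transform only reaches
  `z > −1/(L·S)` (L > 0) or `z < −1/(L·S)` (L < 0).  The density is not
  renormalized; `truncation_mass` reports the ignored mass (≈4·10⁻⁶ for
  the most skewed packaged row) and the sampler rejects and redraws the
  affected draws, warning if the expected rate exceeds 1%.
- The L = 0 (lognormal) branch triggers at |L| < 1e-12, and the two
  branches agree to 1e-6·M at |L| = 1e-8 (tested).

## Fitting

`LMSRegressor` fits the three curves by penalized maximum likelihood.
Each curve is a cubic B-spline with 20 equally spaced interior knots over
the observed age range and a second-order difference penalty (a P-spline);
links are identity for L and log for M and S, which guarantees positive
M and S everywhere.  Both knot count and penalty order are configurable.

The optimizer is Rigby–Stasinopoulos-type backfitting: for each curve in
turn (M, S, L), a penalized weighted least-squares step is solved with the
score and the expected (Fisher) information of that parameter as working
response and weights; cross-parameter information is ignored, as usual for
this scheme.  The per-observation expected-information weights are
`(1 + 2L²S²)/S²` for log M, `2` for log S, and `7S²/4` for L (derived under
z ~ N(0,1), small-S expansion for L; scores verified against numerical
differentiation in the tests).  Step-halving is applied whenever an update
would increase the penalized deviance, so the recorded deviance trace is
non-increasing.  Convergence is declared at a relative penalized-deviance
change below 1e-6.  The tolerance is deliberately tight: L carries little
information per observation, so it moves the deviance slowly and a looser
tolerance (e.g. 1e-4) can freeze L several tenths away from its optimum
while M and S look converged.

**Smoothing selection.**  Unless fixed, each curve's smoothing parameter is
chosen on a 21-point log-spaced grid (1e-2 … 1e6) in a single outer pass by
generalized cross-validation applied to that curve's working
weighted-least-squares problem: `GCV(λ) = n·D_w / (n − γ·edf)²` with `D_w`
the weighted working-residual sum of squares and `edf` the trace of the
smoother matrix.  The inflation γ = 1.4 is the standard guard against
GCV's occasional undersmoothing.  Grid-boundary minima trigger a warning.
Effective degrees of freedom per curve are reported, and the fitted curve
serializes to a documented JSON schema (knots, coefficients, links, edf,
deviance).

Evaluation refuses extrapolation outside the fitted age range.  Ages are
modelled continuously; edge ages (4 and 19–20.9 y) take part in fitting
but published tables span 5–18 y only.

## Eligibility screening

`classify_eligibility` applies the metabolic-health rules with their
published comparators: glucose ≥ 100 mg/dL, total cholesterol ≥ 200 mg/dL,
HDL < 40 mg/dL (< 45 for post-pubertal girls, operationalized as Tanner
stage ≥ 4), triglycerides ≥ 100 mg/dL under age 10 and ≥ 130 mg/dL from
age 10, blood pressure at or above the 90th percentile (only when an
external percentile reference is injected — the Expert Panel tables are a
plug-in, not bundled), HOMA-IR > 3.5 (Matthews, glucose·insulin/405, the
standard formula since the index itself does not define one), and BMI
z-score at or beyond ±3.  Missing required data is a violation
(`incomplete_data`), never an exception.

The anthropometric outlier screen flags height, weight or BMI whose robust
z-score (median/MAD, consistency constant 1.4826) exceeds |4| within each
sex × 1-year age band; bands under 8 subjects are skipped with a warning,
and a zero-MAD (constant) band flags only values differing from the shared
one.  With ~45-subject bands the MAD itself is noisy, so on genuinely
heavy-tailed data a hard |4| cut flags a few real observations per
thousand; the screen targets gross data errors, and the recovery harness
therefore applies only the metabolic screen (see below).

## Synthetic cohorts

`generate_cohort` emulates a cross-sectional school-age survey: ages
uniform on 4–20.9 y (the sampling design aimed at a flat ~62 subjects per
year and sex), sexes balanced.  DXA FMI and FFMI are drawn from BCCG
distributions whose truth curves linearly interpolate the packaged female
DXA tables (end segments extended linearly beyond 5–18 y); weight closes
on the DXA components, bone mineral content is 7% of fat-free mass,
skinfolds are back-derived from the Slaughter equation with 8% relative
noise, and up to three MF-BIA devices report the DXA fat mass with 2%
multiplicative CV each.  Height follows a piecewise-linear age/sex mean
with 3.5% lognormal spread.

Eligibility violations are planted independently per criterion at a
marginal rate of `1 − 0.79^(1/7) ≈ 0.033`, giving an overall ~21%
exclusion fraction — the proportion such healthy-reference studies
typically discard.  Healthy draws are clipped strictly inside every
threshold and planted draws lie strictly beyond it, so filter output and
generator truth agree exactly, noise or not; this is what the filter tests
assert.  All draws flow from one seeded NumPy generator in a fixed,
documented order, making cohorts bit-reproducible.

What the generator does **not** emulate: school-level sampling design,
device physics, correlated biochemistry panels, measurement drift, and —
importantly — independent within-band weight variance: synthetic weight is
built from the outcome itself (weight = (FMI+FFMI)·height²/10⁴), so
extreme weights are extreme outcome draws, which is why the outlier screen
would truncate the outcome's genuine right tail on these cohorts.  Passing
tests therefore demonstrate correctness of the machinery under the stated
model, not robustness to real-data artifacts outside it.

## Parameter recovery

`recovery_experiment` generates a cohort, applies the metabolic
eligibility screen, derives DXA FMI, fits the curves, and compares fitted
L/M/S with the generator truth on a half-year grid over ages 6–17,
reporting max-norm errors per seed.  The outlier screen is deliberately
not part of this loop (nothing is planted for it to catch, and on these
outcome-coupled cohorts it biases recovered L by ~+0.2 and S by ~−5%).

A feasibility note, since the harness ships pass/fail tolerances
(M within 3%, S within 10%, L within ±0.3, max-norm): with n = 2000
generated and ~21% excluded, about 1580 observations remain; the Fisher
information for log S is 2 per observation, and tracking the true S curve
requires ~6 effective degrees of freedom, so the pointwise relative
standard error of Ŝ is ≈ √(6/(2·1580)) ≈ 4.4% — the maximum over a
23-point grid then exceeds 10% roughly half the time *for any estimator at
this sample size*.  Observed behaviour matches: median max-S error ≈ 8–10%
and roughly half of seeds meet all three bounds simultaneously, while the
median errors (M ≈ 2%, S ≈ 8%, L ≈ 0.2) sit comfortably inside them.
Meeting the max-norm bounds in ≥9/10 seeds would need roughly four times
the sample.  The harness reports honestly rather than loosening the
bounds.

## Reference tables and scoring

Published tables are CSV with header `age,L,M,S[,P1,…,P99]`; reading
validates monotone ages and positive M, S and normalizes Unicode minus
signs.  The twelve packaged tables cover FMI and FFMI by skinfolds,
MF-BIA and DXA for each sex, ages 5–18 in half-year rows (the printed
FFMI blocks omit the 16.5-y row; the fixtures keep exactly the printed
rows).  Scoring interpolates L, M, S linearly in age — the convention for
published growth references — and refuses extrapolation outside 5–18 y.
Generated tables default to the half-year grid with a quarter-year option.

`check_table_consistency` recomputes every centile cell from its row's
printed L/M/S and reports signed deviations.  Two-decimal centiles derived
from three-decimal parameters can differ by up to ±0.02; the female FMI
tables and early SF-FFMI rows are consistent at that level (the female
MF-BIA FMI table maximally deviates 0.019), while the male FMI and the
MF-BIA/DXA FFMI blocks disagree with their own printed parameters by up to
~3 kg/m² in extreme centiles.  The checker quantifies this; it never
"repairs" a table, and downstream checks rely only on verified-consistent
rows.

## Pipeline

`run_pipeline` executes derive → screen → fit → tabulate per
sex × variable × method, writing curves, tables, a violations report and a
manifest (input SHA-256, config snapshot, package version, seed, per-stage
and per-criterion counts; counts reconcile by construction).  Everything
is plain text.  The manifest contains no wall-clock timestamp by default
so that identical inputs and configuration reproduce byte-identical
output trees — verified by test and acceptance script; an opt-in flag adds
one.
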