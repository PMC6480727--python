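# Methods

## The question and the data

The package operationalises a simple question from differential
psychology: when school grades are regressed on cognitive ability, does
allowing *curvilinear* terms change the verdict that the g-factor beats
specific ability tests?  The reference cohort is n = 219 students (mean
age 16.03, SD 1.49) with three ability tests from the Wilde Intelligence
Test battery — Unfolding (figural/spatial), Analogies (verbal), Number
Series (numerical reasoning) — and grades in math, German, English and
sports coded 1–6 (6 best).  Only the cohort's moment summary (means, SDs,
Pearson correlations with Fisher 95% CIs) was ever published; the
per-subject data were not.  `curvegrade.datasets` embeds that summary and
every moment-based computation in the package can run from it directly.

Two wrinkles in the published record are handled explicitly:

* the math grade's mean and SD were never printed (only its correlations
  with the tests and with g); the generator adopts mean 3.80, SD 0.94,
  mirroring the two printed academic grades, and flags them `assumed`;
* the grade coding is 1–6 while the scaling center of 3 was motivated as
  the theoretical midpoint of a 1–5 scale; the package treats 1–6 as the
  data coding and 3 as the scaling center and does not attempt to
  reconcile the two.

## g scoring

One common factor is extracted from the 3×3 test correlation matrix by
iterated principal axis factoring: communalities start at squared
multiple correlations, the diagonal is replaced by the current
communalities, the leading eigenpair is taken, `λ = sqrt(eig)·v` with the
sign fixed so `Σλ ≥ 0`, and `h² = λ²` until the largest communality
change falls below 1e-10 (cap 10 000 iterations; each iteration is one
small eigendecomposition).  The tolerance is deliberately much tighter
than the conventional 1e-3..1e-6 because for exactly three indicators the
model is exactly identified and the converged solution must match the
closed-form triad loadings `λ₁ = sqrt(r₁₂ r₁₃ / r₂₃)` to 1e-6 — the
independent oracle in the test suite.  Convergence of the communality
iteration is linear and genuinely slow for weak correlation structures
(thousands of iterations for loadings near 0.2), which is why the cap is
generous; the cost is microseconds per iteration.  Heywood cases
(h² > 1) are clamped to 1, flagged and warned about rather than aborted.

Factor scores are regression (Thurstone) estimates `w = R⁻¹λ` applied to
z-scored tests.  The score method is a package choice (the source
analysis did not state one); it is supported by the model-implied score
SD `sqrt(λ′R⁻¹λ) = 0.805`, which reproduces the published 0.81, and by
the implied score–test correlation `λ_j / 0.805 ≈ 0.71` for Unfolding,
also as published.  Scores are computed from internally z-scored inputs,
so they are invariant to affine rescaling of the raw tests.  For
polynomial modelling the g score is rescaled to center 3 / SD 1 exactly
like the specific tests.

## Linear baselines

Each grade is regressed on g alone and on the three tests.  Two routes
produce identical results (cross-checked to 1e-10): ordinary least
squares on rows (statsmodels backend) and the normal-equation solution
from a moment summary, `β = R_xx⁻¹ r_xy`, `R² = r_xy′β`,
`b_q = β_q·sd_y/sd_x_q`, `sr²_q = β_q²/(R_xx⁻¹)_qq`,
`se(β_q) = sqrt((1−R²)(R_xx⁻¹)_qq/(n−k−1))` with t-based 95% CIs.
Adjusted R² uses `1 − (1−R²)(n−1)/(n−k−1)` with k counting non-intercept
terms.  Reconstruction from the printed correlations reproduces the
printed regression tables within ±0.01 (the inputs are rounded to two
decimals).  The printed R² confidence intervals came from an unstated
method; the package instead provides a seeded nonparametric case-resampling
bootstrap (percentile, default 2000 reps) and does not attempt to match
those printed intervals.  Significance stars are two-sided t at
α = .05/.01 with no multiplicity correction, mirroring conventional
reporting.  Sports is processed by the baselines and then dropped from
the polynomial stage (its validities are ≈ 0).

## Fractional-polynomial search

For one grade and predictors `x_q` (scaled space, all values > 0) the
candidate family is

    y_i = β₀ + Σ_q ( β_q x_iq + β_qq x_iq^{p_q} ) + ε_i

with per-predictor degrees from a configurable grid, default
{0, 0.5, 1, 1.5, …, 5}.  Degree 1 would duplicate the linear column and
degree 0 the intercept, so both mean "linear only" and are reported as 1;
the default grid therefore has 11 states per predictor (1331 specs for
three predictors, 11 for g alone) of which the duplicates collapse to
1000 (resp. 10) distinct models before fitting.  The step, maximum and
inclusion of the linear state are configurable; a 0.25-step grid without
the linear state gives the 20³ = 8000 combinations sometimes quoted for
this family.

Each candidate is scored by leave-one-out cross-validation.  The exact
hat-matrix identity `e_(−i) = e_i/(1 − h_ii)` replaces the n explicit
refits; an explicit-refit route is retained and the two are required to
agree to 1e-8 (they agree to ~1e-14 in practice).  The selection
criterion is the **median** of the n absolute out-of-sample errors — the
error distribution is right-skewed, many small errors and a few large
ones, so the median is the more representative location.  Outputs keep
the conventional "RMSE" label for this quantity for comparability, but
all internal naming says what it is.  Ties are broken by (1) fewer power
terms, (2) lower summed degree, (3) lexicographic degree tuple; the
ranking is fully deterministic (no randomness anywhere in evaluation).
The selected model's R²/adjusted R² come from a refit on the complete
sample.  The all-linear model's criterion and rank are always recorded as
the reference point.

A known statistical limitation, measured while validating the package:
under a *purely linear* truth the median criterion barely separates the
nested candidates.  Every grid model contains the linear terms, so all
are nearly unbiased and differ only by an O(k/n) overfitting penalty; the
median's sampling noise dominates that penalty at every n tried (2000 to
10 000), leaving the linear model's rank broadly dispersed rather than
concentrated at the top.  Ranking by the *mean* absolute deviation does
show the expected complexity ordering.  Consequence: a top rank for a
curvilinear model is evidence that curvature helps prediction, but a
mid-field rank for the linear model must not be read as evidence of
curvature.  Recovery of a *present* curvilinear signal is reliable: a
quadratic Analogies effect of 0.1 grade points per squared scaled unit
(noise SD 0.8, n = 2000) is selected as curvilinear in ≥ 90% of seeds.

## Synthetic cohorts

The generator draws test scores from a multivariate normal with the
published means/SDs/correlations, rejecting rows with any marginal
|z| > 2.9 (the truncation keeps population-scaled values ≥ 0.1, so every
fractional power is defined; its attenuation of correlations is well
under the 0.02 fidelity budget verified at n = 100 000).  Printed
correlation matrices rounded to two decimals can be indefinite; inputs
are repaired by eigenvalue clipping at 1e-8 with re-normalisation to unit
diagonal, and the repair is logged.  Grades are produced per outcome as
`β₀ + Σ_q (b_q x_q + b_qq x_q^{p_q}) + ε`, ε Gaussian, evaluated on
predictors scaled with the *population* moments — the same variable space
the analysis works in, so a generated degree means what the search
estimates.  Optionally grades are rounded half-away-from-zero and clamped
to 1..6.

The default spec reproduces the study conditions: n = 219 and, for each
grade, linear coefficients `R_xx⁻¹ r_xy` from the published validities,
an intercept hitting the published grade mean and noise matching the
published linear R².  All randomness flows from one seed through one
`numpy` Generator; identical specs give byte-identical cohorts.

What the generator does *not* emulate: non-Gaussian score distributions,
measurement unreliability of the tests, selection effects in real school
samples, and any true curvilinearity unless explicitly specified.
Passing recovery tests therefore show that the machinery detects what it
models, not that the reference cohort's relations are truly curvilinear.

Analysis-side scaling is refitted on each sample; a truncated draw can
then land marginally below 0 in sample-scaled units.  The library
surfaces this as a hard error listing the offending subjects (fractional
powers would be undefined); the pipeline and the simulation experiments
use the documented clamp-at-1e-6 policy so a single boundary subject does
not abort a run, and log the policy.

## Pipeline and artifacts

`run_pipeline` chains: (optional) simulation → descriptive moments table
with Fisher CIs → g scoring → scaling → linear baselines for all four
grades → drop sports → polynomial searches (g-only and three-test) for
math/German/English → best-model comparison table → response curves of
the selected models.  Response curves evaluate a fitted model along one
predictor over scaled values 1..5 (±2 SD around the center, inside the
positive domain; 101 points) with the others fixed at 3.  All artifacts
are plain text (TSV/CSV/JSON); the manifest stores a SHA-256 per file and
identical config + seed reproduce byte-identical bundles.  With a
moments-only input the polynomial stages are skipped with an explicit
"raw data required" notice.  Problem sizes used in the validation suite —
n = 219 for study-scale runs, n = 2000 for 20-seed recovery experiments,
n = 100 000 for moment-fidelity checks — were chosen as the smallest
sizes at which the corresponding population quantities are resolvable.

## Known limitations

* Missing data are a hard error everywhere (complete cases only; silent
  imputation would change the moments being reproduced).
* No polychoric/ordinal correlation option: grades are consumed as
  numeric and never rescaled.
* Reconstruction from printed (2-decimal) inputs carries an irreducible
  ±0.01 budget; e.g. the PAF eigenvalue recomputes to 1.121 against a
  printed 1.13.
* The median-criterion null behaviour described above.
* No regularisation, interactions, information-criterion selection or
  nested double cross-validation — the family is main-effect fractional
  polynomials selected by single-level LOO, by design.
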