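# Methods

`surveyfuse` implements unilateral statistical matching (data fusion) for
health surveys: a small *donor* file observes common variables X (self-
reported demographics, behaviour, declared condition statuses) together
with specific variables Y (clinical measurements and condition flags),
while a large *recipient* file observes only X. The package transfers the
specific block to the recipients, quantifies the quality of that transfer,
propagates its uncertainty, and measures what the fusion buys for
prevalence estimation.

## Model and assumptions

The statistical foundation is the conditional-independence / predictive-
relevance assumption: given X, no further variable carries information
about Y, i.e. Y = i(X) + ε with i the imputation rule and ε pure noise.
All engines target the conditional distribution f(Y | X) estimated on
donors, and the objective is *stochastic* simulation of instances — never
conditional-mean imputation, which would improve pointwise accuracy at the
cost of distorting distributions and associations.

Three engines estimate i(X):

* **Hot deck (kNN)** — Gower mixed distance in X-space (range-normalised
  absolute difference for continuous, mismatch for categorical variables,
  equal weights by default, configurable); the entire specific block of
  one donor among the k nearest is transferred, preserving within-donor
  associations. Ties are broken uniformly at random (implemented by a
  seeded random permutation of the donor order before a stable
  nearest-neighbour search). k = 1 is the classical single hot deck; the
  MI variant redraws uniformly among the k nearest (default k = 10).
  When donors are re-imputed for validation, a unit may not donate to
  itself ("leave-own-record-out" by origin identifier) — otherwise
  nearest-neighbour validation is trivially perfect.
* **Sequential regression** — a chain of submodels, one per specific
  variable, each regressing the outcome on common variables and earlier
  outcomes: linear with normal residual draws for continuous outcomes,
  binary or multicategory logistic draws for categorical ones, and
  *derived* variables (BMI = weight / height²) computed by formula.
  Candidate predictor sets follow two rules: epidemiological sense
  (a forced-in core, e.g. the declared treatment status for the treated
  measure, age and adiposity for blood pressure) and statistical
  significance (backward elimination by Wald group tests at α = 0.05).
  Proper multiple imputation additionally draws the residual variance
  from its scaled chi-square posterior and the coefficients from their
  normal approximation before each imputation.
* **Data augmentation** — all features (continuous variables plus
  reference-dropped indicators for categoricals) embedded in one joint
  latent-normal vector; the chain alternates an I-step (recipients' Y
  features drawn from their conditional normal given X and current
  parameters) and a P-step (mean and covariance drawn from the
  normal–inverse-Wishart posterior under the Jeffreys prior), so retained
  imputations carry parameter uncertainty. Defaults: burn-in 500,
  spacing 100 between retained draws (both configurable; the scaled
  experiments use 100/20). Categorical specifics are decoded by a
  *stochastic* draw over the clipped, normalised indicator scores: a
  deterministic round-to-most-probable would be a conditional-mode rule,
  which the stochastic-simulation objective excludes.

Quasi-separated logistic submodels (rare outcomes in small donor
resamples) fall back from Newton to BFGS with a pseudo-inverse Hessian
(ridge 1e-6) for the sampling covariance; degenerate outcomes with a
single observed level are an error.

## Validation suite

Quality is judged on donors only: their specific block is re-imputed from
their common block and compared with the observed values through eight
statistics. The suite averages univariate comparisons rather than testing
a global multivariate hypothesis, and every statistic is an independent
function so alternative operationalisations can be swapped in.

| statistic | construction | orientation |
|---|---|---|
| ASLm | mean achieved significance level of two-sample equal-means tests (Welch, closed form) and equal-proportions chi-square tests | higher |
| ASLs | mean ASL of equal-spread tests (Levene-type: Welch on absolute deviations from the group mean) | higher |
| ACDi | mean absolute difference of pairwise associations among specific variables (Pearson for continuous pairs, Spearman when an ordered/binary categorical is involved, Cramér's V for nominal pairs) | lower |
| ACDe | same over specific-by-common pairs | lower |
| WC | congruence <S1,S2>/(‖S1‖‖S2‖) of the centred cross-product matrices of the full fused block (X and Y, indicator-coded), raw scale | higher |
| ASD | mean of the two-sample Kolmogorov–Smirnov statistic (continuous) and total-variation distance (categorical) | lower |
| TAU | mean of Cohen's kappa (categorical) and 1 − MSE/Var(observed) floored at 0 (continuous) | higher |
| RndRes | mean ASL of no-association tests between imputation residuals and each common variable (correlation t-test; one-way ANOVA across levels) | higher |

Including the common block in WC makes it sensitive to the preservation
of specific-by-common covariance — the aspect a joint probabilistic model
is best at and matching noise destroys; computed on the raw scale, large-
variance clinical variables weigh in proportion to their share of total
scatter. Perfect imputation attains (1, 1, 0, 0, 1, 0, 1, 1), with RndRes
flagged degenerate (constant residuals).

## Multiple imputation and pooling

Any engine can be repeated m times (independent seeded runs; parameter
draws enabled for the regression chain; m spaced draws of one chain for
DA). Estimates are computed per completed table and pooled by the
within/between decomposition: qbar = mean, W = mean sampling variance,
B = between-imputation variance (divisor m − 1), T = W + (1 + 1/m)B. For
a prevalence on n rows the within-variance is binomial p(1 − p)/n.
Concatenation of the m files is offered as an export, but pooled
per-imputation inference is the default analysis route. No small-sample
degrees-of-freedom correction is applied to intervals; the coverage
experiment therefore uses m = 10, where the normal-quantile interval is
adequate.

## Synthetic populations

Because the original microdata are under a research agreement, the
package ships a generator that emulates their structure with known ground
truth. The generating chain mirrors the imputation chain (demographics →
height → weight → BMI → waist → blood pressure → cholesterol → glucose →
conditions), which makes parameter recovery a fair test of the sequential
engine. Realistic features deliberately included:

* right-skewed gamma residuals for weight and glucose;
* a latent "metabolic" factor loading on waist, systolic BP, cholesterol
  and glucose residuals — the residual correlations real risk factors
  show beyond their measured predictors, which a curated regression chain
  partly misses but a joint covariance model retains;
* terminal-digit preference: blood pressure heaps on multiples of 10/5/2,
  anthropometry and self-reports on whole and five-unit values — the
  feature that separates transferred real values from smooth parametric
  draws in marginal-distribution comparisons;
* biased, noisy self-reports of height (over-reported) and weight
  (under-reported), plus a gender-by-age interaction in height;
* declared condition statuses derived from the true state: treatment
  declarations discretise the underlying clinical value, while declared
  diabetes/CVD reflect diagnosis awareness (sensitivity 0.75/0.80, small
  false-positive rates) — self-reported conditions exist in *both* files,
  and their high predictive value is what makes fused prevalence
  estimates more precise than donor-only ones;
* diabetes generated with a steep fasting-glucose slope (the condition is
  clinically defined by glucose), cardiovascular disease from the
  standard risk factors (age, BMI, BP, cholesterol, sex, activity,
  smoking, education).

Default magnitudes are plausible for an adult European population
(condition prevalences ≈ 12% CVD, ≈ 7% diabetes, ≈ 5% hyperglycemia) but
are fixtures for testing, never estimates of any real population. What
the generator does **not** emulate: survey design weights and clustering,
item nonresponse outside the specific block, panel attrition, and
real-world inconsistencies between questionnaire waves — so green tests
show the machinery is correct under its stated assumptions, not that any
particular real fusion is valid.

A null variant (`PopulationParams.without_cross_links`) severs every link
between the clinical block and the observables; on it no method can beat
the marginal predictor, which calibrates the accuracy statistic.

## Experiment designs and problem sizes

* **Method comparison**: populations of 4600 with the design's donor
  fraction (≈ 600 donors); engines fitted on bootstrap resamples of the
  donor file and validated by re-imputing the original donors; 50
  resamples, m = 5, repeated over five master seeds. The comparison
  scores the clinical measurement block; condition flags belong to the
  application layer. At this scale the expected profile emerges: the
  regression chain is most accurate (TAU), the hot deck matches marginal
  distributions best (ASD), data augmentation preserves the multivariate
  pattern best (WC) and the pairwise correlations, and MI variants are
  more stable than their single-imputation counterparts.
* **Prevalence / SD ratio**: the full design (11614 respondents, 1508
  donors), m = 20 sequential-regression imputations of the full chain,
  prevalences pooled over donors plus completed recipients, globally and
  by sex, age group and physical activity; the SD ratio (donor SD /
  fused SD) exceeds one throughout, typically 1.2–2.2.
* **Coverage**: 200 replications at population size 2000 (20% donors),
  m = 10; pooled 95% intervals cover the true CVD prevalence ≈ 95% of
  the time.
* **Parameter recovery**: donor files of 2000 complete records,
  digit-preference rounding disabled (it is an errors-in-variables
  corruption that attenuates the blood-pressure coefficients), selection
  off, submodels matching the generating terms; every coefficient is
  recovered within three reported standard errors in at least four of
  five replicates.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.Generator` seeded via
  `SeedSequence`; identical seeds give byte-identical outputs, including
  across the bootstrap harness (per-iteration spawned seeds).
* Degenerate bootstrap resamples (vanishing outcome level, singular fit)
  are rejected and redrawn with a counter; more than 20 consecutive
  failures abort.
* Non-positive-definite scatter in the DA chain is repaired by escalating
  ridge inflation on the Cholesky factor.
* Identical two-sample inputs short-circuit to p = 1; zero-variance
  variables are skipped with a warning and recorded in the detail tables.
* The TAU floor (default 0) stops hopeless variables from dominating the
  average; unfloored values are available via the `floor` argument.

## Known limitations

* Survey design weights and primary-sampling-unit structure are out of
  scope; all proportions are unweighted.
* The DA engine's latent-normal indicator treatment of categoricals is a
  simplification of a general-location model; ordered categoricals are
  treated as nominal indicators inside DA.
* Backward elimination is greedy and refits from scratch; with many
  candidate terms on small donors it can be slow and order-dependent.
* The validation suite's concrete test choices (Welch, Levene-type,
  chi-square, KS/total variation, kappa, congruence) are one reasonable
  operationalisation of the eight criteria; orientations are recorded in
  every report so alternatives can be swapped without breaking consumers.
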