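# Methods

## Overview

The package standardizes hospital-acquired infection (HAI) rates by indirect
standardization: a count-regression model fitted on a reference cohort of
well-performing hospitals predicts, for every ward record in a national
registry, how many infections of a given type (RTI, UTI, SSI, BSI) would be
expected given the ward's attributes and patient volume. The standardized
infection ratio (SIR) is the ratio of observed to expected counts, reported
nationally and per stratum of ward type or hospital attribute, with a
calibration correction factor applied to the denominator for the corrected
SIR.

## Data model

The unit of analysis is one ward of one hospital over one surveillance
period (typically a year). Each record carries:

* five categorical attributes — ward type (9 levels), hospital expertise
  (6), affiliation (3), teaching status (2), accreditation grade (3);
* nineteen continuous utilization / case-mix measures (active beds, average
  length of stay, bed-turnover rate, nurse-to-bed ratio, device/catheter/
  ventilator days, mean patient age, male-to-female ratio, bed occupancy
  rate, several infection- and mortality-derived ratios);
* the number of hospitalizations (the exposure), and one observed infection
  count per infection type.

Categorical predictors are reference-coded against declared level orderings
(first level = reference) so that coefficients estimated on the cohort
transfer unambiguously to the full registry; a design/term mismatch at
prediction time is an error, never a silent coercion.

## Count models

All count parts use a log link with the natural log of hospitalizations as
a fixed offset, making each model a rate model. Three families are fitted:

1. **Poisson** — baseline; its score equations force ΣE = ΣO on the
   training data when an intercept is present.
2. **NB2 negative binomial** — variance μ(1 + αμ) with dispersion α
   estimated by maximum likelihood. When α̂ collapses to the Poisson
   boundary the fit is reported with α = 0, the Poisson log-likelihood and
   a boundary flag; the dispersion parameter is still counted in the AIC
   penalty so family comparisons stay like for like.
3. **Hurdle negative binomial** — a logistic model for whether any
   infection occurs (coefficients γ on the log-odds of a *positive* count;
   no offset, since the hurdle is a reporting/occurrence process) and a
   zero-truncated NB2 for the positive counts (coefficients β, dispersion
   α, with the offset). The likelihood factorizes, so the two parts are
   maximized separately: the binary part by logistic regression, the
   truncated part by L-BFGS with analytic gradients, with the dispersion
   optimized as log α to enforce positivity. Standard errors come from the
   observed information (numerical Hessian; delta method for α). The
   predicted mean is the full hurdle mean E = P(positive) · μ / (1 − NB₀(μ, α)).

Overdispersion is assessed by the Cameron–Trivedi auxiliary regression
(regress ((y − μ̂)² − y)/μ̂ on μ̂ without intercept; one-sided p < 0.05 on a
positive slope flags overdispersion, so the nominal type-I error is 5%).
Zero excess is flagged when observed zeros exceed the Poisson-predicted
zero count Σ exp(−μ̂ᵢ) by more than 20%.

Numerical choices: truncated-NB optimization uses ftol 1e-13 / gtol 1e-8,
starting values from a Poisson fit on the positive records and a
method-of-moments dispersion; convergence is judged by the gradient
(inf-norm < 1e-3) rather than the optimizer's line-search status alone, with
one restart from α₀ = 0.5 if needed. Quasi-separation in the logistic part
falls back from Newton to BFGS. Degenerate inputs (all-zero or all-positive
responses for the hurdle, rank-deficient designs) raise informative errors.

## Cohort definition

Well-performing hospitals are those with (1) excellent or grade-1
accreditation and (2) a pooled HAI rate — all four infection types summed
over all wards, divided by total hospitalizations — inside an inclusive
4–15% window. Hospitals below the window plausibly under-report; hospitals
above it are outliers. Both filters act on whole hospitals; records missing
a required predictor (by default the surgery-to-surgery-bed ratio) are then
dropped individually, with every stage's attrition counted. The categorical
composition of the cohort versus the full registry is reported with a
chi-square homogeneity statistic; because the cohort is a subset of the
registry, the test contrasts the cohort with its complement (the excluded
records), which is the correctly calibrated two-sample comparison, while
the reported proportions are cohort vs full. The statistic is diagnostic
only and never drives selection.

## Selection and validation

Candidates pass a univariable NB screen (Wald p < .20 for any term of the
candidate; non-convergent screens retain the candidate conservatively).
The cohort is split 70/30 at the record level (a hospital-level split is
available); the split is a deterministic function of the seed. Within each
family, bidirectional stepwise AIC runs from the intercept-plus-offset
model, evaluating every single-term addition and removal per step and
applying the best AIC-decreasing move; categorical terms move as whole
blocks. The final model per infection type is the candidate with the lowest
test RMSE, ties broken by fewer parameters and then by simpler family.

Validation metrics: McFadden, Cox–Snell and Nagelkerke pseudo-R² (the null
is the intercept-plus-offset model of the same family fitted to the
evaluation records — the offset is data, not explanatory content), and
MSE/RMSE on the untransformed count scale. On held-out data the trained
model's log-likelihood is evaluated at its fitted parameters (no refit), so
test metrics measure transfer. "Total" metrics pool train and test records.

## Standardization

SIR = O/E per stratum, with exact Poisson (Garwood) 95% intervals treating
E as fixed: low = qGamma(α/2; O)/E (0 when O = 0), high =
qGamma(1 − α/2; O + 1)/E. Strata with E below a minimum-expected threshold
(default 1.0, the NHSN-style convention) are suppressed rather than
reported. The correction factor is the closed-form no-intercept
least-squares slope Σ(OP)/Σ(P²) estimated per infection type on the
calibration cohort's record-level (O, P) pairs; the corrected SIR is
O/(CF·E) and its interval is the exact Poisson interval divided by CF·E,
the CF treated as a known constant (no CF-uncertainty propagation).

## Synthetic registry

The generator emulates the structure of a national annual surveillance
registry without claiming fidelity to any real one:

* **Scale** — 863 hospitals × 4 wards ≈ 3450 records by default, yearly
  ward exposures uniform on [200, 3000] hospitalizations.
* **Counts** — hurdle-NB: a logistic hurdle (default log-odds 0.9 of any
  infection, higher in ICU and burn wards) and a zero-truncated NB2 with
  dispersion α = 0.8 whose mean is proportional to exposure. Defaults give
  a pooled HAI rate near 8% (mid-range of the well-performing window),
  roughly 30% zero counts per infection type, and strong overdispersion.
  Setting the hurdle coefficients to `None` disables the hurdle and draws
  plain NB2 counts with mean exactly μ·exposure, which is used where an
  exactly exposure-proportional mean is needed (e.g. planted-signal tests).
* **Covariates** — categorical marginals loosely matching a national
  hospital registry (85% general, 72% government, 70% teaching, 82%
  grade-1); mean patient age truncated-normal (40.02, SD 23.56) on
  [0, 100]; utilization measures log-normal around typical magnitudes;
  about 3% of records missing the surgery-to-surgery-bed ratio to exercise
  the missing-data drop.
* **Truth** — the generating coefficients and per-record mean / zero
  probability are returned, enabling parameter-recovery, coverage and
  null-calibration tests.

Zero-truncated draws use exact inverse-CDF sampling through the untruncated
NB quantile function. Counts are capped at the record's exposure to keep
the registry internally consistent; at the default rates the cap binds with
negligible probability.

What the generator does **not** emulate: within-hospital correlation beyond
shared hospital attributes, secular trends, reporting artefacts
(underreporting, duplicate records), linkage errors between data systems,
or any real marginal joint distribution of the 24 predictors. Passing tests
therefore demonstrate correctness of the estimators and pipeline under the
assumed data-generating process, not epidemiological validity on any real
registry — whose headline SIR values are in any case functions of
unavailable data.

## Test problem sizes

The statistical acceptance tests use simulation sizes chosen to make each
property sharp while keeping the suite quick on a single CPU: n = 5000
records for single-shot parameter recovery and SIR null calibration (100
replicates), n = 2000 for Wald-coverage (200 replicates), stepwise
consistency (50) and planted-signal (50) experiments, n = 1000 × 500
replicates for overdispersion-test calibration, and n = 300 × 200
replicates for the univariable-screen retention rate.

## Known limitations

* "Generalized negative binomial" is implemented as NB2; NB-P or other
  generalizations are out of scope.
* The hurdle's binary part carries no exposure offset; wards with very
  different volumes share the same occurrence model unless volume-related
  predictors are included.
* The correction factor is a single multiplicative constant per infection
  type; it cannot repair stratum-specific miscalibration.
* Record-level 70/30 splitting ignores hospital clustering by default
  (hospital-level splitting is available via `SplitSpec(unit="hospital")`).
* No zero-inflated (mixture) models, no robust/sandwich standard errors,
  no procedure-specific SSI stratification.
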