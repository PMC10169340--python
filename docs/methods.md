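# Methods

## The temporal-regularity statistic

A patient's temporal regularity (TR) is the coefficient of variation of
the gaps, in whole days, between consecutive qualifying primary-care
visits. Qualifying means: delivered by a family physician, lasting at
least 5 minutes (roughly the mean visit duration; shorter contacts are
mostly administrative), any modality, inside the two-year study window
(2018-01-01 to 2019-12-31, closed at day resolution). Multiple qualifying
visits on one day collapse to a single date — a zero-day gap would make the
COV ill-behaved, and nothing meaningful distinguishes two same-day
contacts at this resolution. At least three distinct dates (two gaps) are
required; that is also an eligibility criterion, so every scored patient
has a defined TR.

The COV uses the sample standard deviation (n−1 denominator) by default.
With per-patient gap counts in the single digits the choice is material and
no convention is universal, so the population variant is one flag away
(`ddof=0`, exposed through `RunConfig.sd_ddof`). TR = 0 if and only if the
gaps are exactly equal; the statistic is invariant to rescaling the gaps
and to the calendar placement of the series.

TR is strongly non-normal in practice (right-skewed, bounded below), which
the package verifies with a Jarque–Bera test, JB = n/6·(S² + (K−3)²/4)
with moment-based skewness S and kurtosis K against χ²(2), plus Q-Q pairs
for plotting; the log transform is also reported. The modelling therefore
uses a dichotomy rather than a linear model on TR: the *least-regular
quintile*, TR at or above the empirical 80th percentile
(linear-interpolation quantile, flag inclusive at the threshold), or a
fixed threshold (default 1.2, the quintile boundary of the reference
cohort). The inclusive ≥ rule means threshold ties are always flagged, so
with heavy ties slightly more than 20% can be flagged.

## Cohort construction

Eligibility filters run in a fixed order — age 40+ (age anchored to 2015,
the patient-characteristics reference year, i.e. birth year ≤ 1975), at
least one index condition (heart failure, COPD, diabetes) coded during
2016–2019, at least three qualifying visit dates, and no hemodialysis
procedure during 2015–2019 (dialysis patients see physicians so regularly
that TR is meaningless for them). The retained set is order-invariant (the
filters are independent predicates); only the attrition log depends on the
order, and each step's removal count is logged.

Condition phenotyping uses named ICD code lists with include and "BUT NOT"
exclude patterns under a small grammar: literal codes, `x`-suffix prefixes
(matching the bare root too, since real data contain un-suffixed codes),
bare three-character roots, and inclusive root ranges. Matching is
case-insensitive; a code matches a list iff it matches an include pattern
and no exclude pattern. The shipped lists live in a human-editable YAML
resource (`temporeg/data/code_lists.yaml`). One list (cancer) contains a
six-prefix exclusion block (209.4x–209.9x) expressed as prefixes because
its natural range form has decimal endpoints the root-range grammar does
not cover. Kidney function is taken from labs, not codes: the category
(60+/45–59/30–44/<30) comes from the lowest eGFR in 2018–2019, falling
back to 2016–2017, then imputing the modal category 60+. Smoking comes
from the demographics record, never from codes.

## The risk model

The least-regular flag is modelled by maximum-likelihood logistic
regression with indicator encoding against fixed reference levels (age
40–49, female, general population, Central region, highest SES, eGFR 60+,
condition absent). Fitting is IRLS with step-halving, which guarantees a
non-increasing deviance trace; convergence is declared when the deviance
changes by less than 1e-10, tight enough that the intercept score equation
(sum of fitted probabilities = number of events) holds to better than
1e-8. Wald standard errors come from the observed information at the
optimum; 95% CIs use z = 1.96; no multiplicity adjustment is applied, and
p-values are marked at 0.05 and 0.001 in the summary table. Separation is
detected by a coefficient-magnitude bound (default |β| > 15): the fit is
returned with `converged=False` and a warning rather than an exception,
since quasi-separation of a rare condition in a small cohort should not
abort a run. Rank-deficient designs raise an error naming the collinear
terms; indicator columns that are identically zero are dropped with a
warning beforehand. The c-statistic is computed in-sample by the rank
(Mann–Whitney) method with ties counted one half — in-sample because the
model's role is case-mix adjustment on the same population, not external
prediction. Bivariate (single-predictor) models are fitted per predictor,
and a failure in one predictor's model is recorded without aborting the
others.

## Clinic profiling

Per clinic, O is the count of flagged patients and E the sum of the
adjusted model's predicted probabilities; O/E is reported for clinics with
at least 30 patients (smaller clinics are listed as excluded). Since the
model is fit with an intercept by ML on the profiled population, ΣE = ΣO
exactly, so the E-weighted mean O/E over all clinics is identically 1 —
the package treats this as a correctness invariant (tolerance 1e-8), and
it also means O/E ratios are interpretable as relative to the system
average. The "as expected" band 0.90–1.10 is inclusive at both bounds.
Raw ratios are reported without shrinkage, matching standard O/E practice;
an exact-Poisson CI per clinic is available behind a flag but excluded
from the default replication output, which carries no uncertainty
intervals.

## The synthetic generator

The generator emulates the study conditions of a reference HMO cohort of
70,095 patients aged 40+ with an index chronic condition; its defaults are
that cohort's published marginal profile.

* **Demographics.** Age bands, sex, ethnic group, region, SES group and
  eGFR category are drawn from the reference marginal counts (SES and
  ethnic counts are internally inconsistent in the published profile and
  are renormalised to probabilities); birth year is uniform within band,
  SES decile uniform within group.
* **Conditions.** Flags are independent Bernoulli draws at the reference
  prevalences — except the index triple (HF, COPD, diabetes), which is
  drawn from the independent law *conditioned on at least one present*,
  with pre-conditioning probabilities solved by fixed point so that the
  post-conditioning marginals equal the configured prevalences (otherwise
  conditioning would inflate diabetes from 0.78 to ~0.90 among eligibles).
  The joint comorbidity structure of real data is not modelled; this is a
  documented limitation — passing tests show marginals and the specified
  effect pathway are right, not that covariate correlations are realistic.
  Flagged conditions emit 1+Poisson(0.8) diagnosis records with concrete
  codes drawn from each list's expanded pattern set, so the matcher is
  exercised end to end. Headache carries a prevalence but no code list and
  no model term, and sleep disorders a code list but no prevalence; both
  are carried as-is.
* **Visits.** Each eligible patient gets N ~ Poisson(12) (truncated ≥ 3)
  qualifying visits per two years — every two months on average, matching
  the illustrative six-visits-per-year patient. Gaps are gamma with shape
  k = 1/cov² (interval COV exactly the target; equal gaps at target 0),
  rescaled to span the window and rounded to whole days. Durations of
  qualifying visits are lognormal (median 5 min) conditioned ≥ 5; decoy
  visits — short contacts and non-family-physician encounters — are added
  separately so the 5-minute filter has work to do without thinning the
  calibrated series. Planned-ineligible fractions of patients fail exactly
  one filter each (too young, no index condition, a hemodialysis history,
  under three visits), making the attrition log checkable.
* **The effect pathway.** Each patient's linear predictor is built from
  ground-truth log odds ratios (defaults: the reference cohort's adjusted
  ORs) using the same design encoding the risk model uses, plus a
  clinic-level N(0, σ) effect (default σ = 0.3, giving an O/E spread of
  the magnitude seen in practice; σ = 0 yields a null calibration
  cohort). The target COV is chosen so that P(sample COV ≥ 1.2) equals
  logistic(logit(0.20) + lp + clinic effect). Because the sample COV of a
  handful of integer-day gaps has no usable closed form, this map is
  calibrated by Monte Carlo: a lookup table over a target-COV grid,
  40,000 replicates per point, simulated with the *same* measurement
  pipeline the scorer applies (day rounding, same-day collapse,
  eligibility conditioning) — day rounding alone visibly shrinks the
  sample COV at high visit density, so calibrating against anything else
  would bias the link. The curve uses a fixed internal seed (it is part of
  the mechanism, shared by all user seeds), is forced monotone, cached per
  configuration, and inverted by linear interpolation with clamping at the
  grid ends. The realised flag is then Bernoulli with exactly the modelled
  probability, which is what makes ground-truth coefficient recovery a
  fair test of the whole pipeline.
* **Determinism.** One global seed expands into fixed per-table
  substreams (`numpy` `default_rng([seed, stream])`); identical
  configuration and seed give byte-identical CSV output.

## Problem sizes and numerical choices

Validation runs use deliberately moderate sizes: marginal calibration at
n = 10,000 (3 binomial SEs), coefficient-recovery coverage over 20 seeds
at n = 20,000 with σ_clinic = 0 and the fixed 1.2 threshold (the
threshold at which the ground-truth link is defined; the empirical
quintile threshold differs from 1.2 only by sampling noise), the O/E
identity at n = 5,000 with 50 clinics, and profiling power at n = 4,000
with 40 clinics over clinic-effect SDs {0, 0.3, 0.6} × 10 seeds. Windows
are closed at day resolution throughout the builder; the generator's
window is half-open (visits land on days 0..728).

Known limitations: conditions are marginally calibrated but uncorrelated;
visit counts are independent of covariates (in reality sicker patients
visit more); every simulated series starts at the window start; and the
O/E profile carries no uncertainty quantification by default.
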