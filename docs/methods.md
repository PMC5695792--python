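# Methods

`statinadh` re-implements, as a tested pipeline, a claims-based analysis of
secondary statin non-adherence: cohort construction from pharmacy/laboratory/
coding claims, percent-days-covered (PDC) outcomes, dimension reduction of
baseline counts by nonnegative matrix factorization (NMF), staged prediction
of disease risk and adherence with cross-validation, and linkage of predicted
adherence to cholesterol change and cardiovascular-hospitalization survival.
A synthetic claims generator with recorded ground truth makes every stage
testable by parameter recovery.

## Data model and time

All dates are integer month indices (claims-style month truncation). Each
patient's *threshold month* is the month of the first statin fill flagged as
a first prescription; baseline data precede it, outcomes follow it. Day
arithmetic uses a uniform 30 days/month, because the source representation
carries no day-level information. A consequence worth noting: "at least one
year of follow-up" (365 days) requires 13 observed months, since 12 months
is 360 days under this convention; the simulator therefore draws per-patient
follow-up from 13 months upward.

Follow-up ends at the last recorded data element of any kind (lab, drug, or
code), the same definition used for the PDC denominator, so a patient who
leaves the system stops contributing observation time consistently across
outcomes.

## Cohort filters

Patients are retained when they are treatment-naive (no statin fill in the
12 months before threshold, which subsumes the additional 6-month prior-fill
exclusion), their first fill falls in the prescribing window, age at
threshold is 18-65, the first fill's duration is one of 30/60/90/180 days,
and follow-up is at least 365 days. Filters apply in that order and the
exclusion tally is order-dependent (a patient failing two rules counts under
the first); the tally plus the retained count always partitions the input.

## Baseline predictors

- **Count matrix**: occurrences of each code/drug/lab token in the 6 months
  up to and including the threshold month. Variables seen in fewer than 100
  patients are dropped (`min_patients`, configurable); column order is
  lexicographic. The raw-collection windows differ by kind (12 months for
  codes and drugs, 24 for labs) and govern the per-kind interaction totals
  and lab recency; the count-matrix window is separately configurable
  because the two window conventions genuinely conflict in the source
  description. The threshold statin fill itself falls inside the count
  window; the pipeline excludes statin codes from the matrix since that
  column would duplicate the first-fill characteristics.
- **Baseline labs**: most recent value per analyte at or before threshold,
  no older than 24 months; ties within a month break by file order (last
  record wins), which is documented rather than meaningful.
- **Prior PDC**: for each non-statin drug with its first fill at least 2
  months before threshold, total days supplied before threshold divided by
  days from first fill to threshold, capped at 1. Statins never appear.
- **Interaction counts**: pre-threshold event totals by kind, used in every
  model to control for how intensively a patient touches the system.

## PDC and outcome definitions

PDC is the literal supplied-days ratio: total statin days supplied (any
statin) over follow-up days, capped at 1 — not a union of covered days. The
package ships two oracles: a day-by-day enumeration of the same ratio (the
test oracle, which must agree exactly) and a pill-carry-over coverage
simulation that documents how the ratio differs on overlapping schedules or
supply running past the end of follow-up. Adherent means PDC > 0.8,
strictly. The follow-up variant excludes the first prescription's pills and
starts when that first supply ends; it is missing only when that window is
empty. The cap at 1 follows the pharmacy-quality convention for a
proportion; whether the original analysis capped is unknowable from the
text, so the uncapped ratio is available for prior PDC via `cap=False`.

Lipid change compares the last value at or before threshold with the first
value at least 2 months after; "decreased" is a strict inequality.
Hospitalization outcomes take the first in-group coded event after
threshold (groups: MI, stroke, CAD, kidney disease, each code mapped to at
most one group), censored at end of follow-up; the composite used for
linkage is the earliest of MI/stroke/CAD, while the risk-model label
additionally folds in kidney disease.

## NMF

The patients x variables count matrix X is factored as X ~ S Lᵀ by
multiplicative updates for the squared Frobenius objective, from a seeded
uniform random initialization, recording the objective each iteration (the
update guarantees it is non-increasing; tests assert this across seeds).
Defaults: K = 30, `tol = 1e-5` relative, `max_iter = 500`, raw counts
(a `log1p` transform is available but off, keeping the canonical count
input). After convergence each loading column is scaled to unit L2 norm and
final scores are the per-row nonnegative least squares (NNLS) projection
onto the fixed loadings. This makes in-sample re-scoring bit-consistent
with the fit and makes scoring new patients the identical operation; the
NNLS step can only lower the objective and is appended to the trace. No
row/column pre-normalization is applied by default — the factorization's
input is deliberately the count matrix itself. No rank selection is
performed; K is a config choice.

## Disease-risk model

Hospitalization outcomes are rare and related, so the per-outcome logistic
coefficient vectors are shrunk toward a shared mean: outcome g has
coefficients beta_g = mu + delta_g, with ridge penalties lam_dev·Σ‖delta_g‖²
and lam_mean·‖mu‖² (intercepts unpenalized), fitted jointly by L-BFGS on the
summed deviances with analytic gradients, features standardized on training
statistics. Two limits anchor the design and are tested numerically: as
lam_dev → ∞ the outcomes coalesce onto one common coefficient vector, and as
both penalties → 0 the fit decouples into independent logistic regressions.
An outcome with no positive cases in a training fold simply shrinks to the
shared mean rather than failing. The default label is any-group event within
1 year; a 3-year horizon is a config switch. Penalties are chosen per
training fold by 5-fold inner cross-validation on log-loss over a small
grid; a fixed pair can be supplied to skip the search (the pipeline's CLI
does so for speed). All risk scores are out-of-fold from 30 patient-level
folds; the composite risk is 1 − Π(1 − p_g).

This model is this package's own strength-borrowing construction; it
implements the stated goal of sharing information across related rare
outcomes, not any particular published estimator.

## Adherence model

A random forest (default 500 trees, √p features per split, unlimited depth,
seeded; all exposed in `AdherenceModelSpec`) is trained per fold of a
30-fold split on demographics, statin characteristics, interaction counts,
composite disease risk, factor scores and baseline lab values; pooled
out-of-fold probabilities give the cross-validated ROC and c-statistic. The
c-statistic is computed from the Mann-Whitney rank statistic and is tested
to agree with trapezoidal ROC integration to 1e-10. Missing numeric
features are imputed by the training fold's median with a missingness
indicator appended — claims data are sparse by nature and the indicator
preserves the missingness signal.

`min_samples_leaf` defaults to 1 but matters for calibration experiments:
with fully grown trees a weak single-covariate signal produces noisy
probability rankings that understate the family's attainable AUC; the
planted-signal validation uses a leaf size of 25 (probability-forest style)
for that reason.

Variable importance is leave-one-covariate-out with a full cross-validated
refit (ΔAUC = AUC(all) − AUC(without)), supporting named column groups so a
whole factor or variable family can be withheld as a unit. The first-refill
variant adds the observed first-refill indicator and predicts the
recomputed follow-up-window label; because a patient with no refill has a
follow-up PDC of zero by construction, the indicator carries information
beyond baseline covariates whenever never-refilling is non-negligible.
Per-factor associations are single-factor logistic regressions adjusted for
all patient/statin covariates and composite disease risk, reporting sign
and Wald p; degenerate designs are flagged not estimable rather than
raised.

## Linkage

Pearson correlation relates predicted adherence to the magnitude of
cholesterol lowering (positive r = more lowering; the raw-delta correlation
is also emitted). Cox proportional-hazards models (lifelines, small ridge
stabilizer) per diagnosis group and composite include predicted adherence
on its natural 0-1 probability scale — hazard ratios are per full unit of
predicted adherence — plus predicted disease risk and patient/statin
covariates; groups without events are skipped with a notice. Tertiles of
predicted adherence are display-only (Kaplan-Meier curves with a 2-df
log-rank test); a tertile emptied by heavily tied scores is reported, not
an error. The Cox route is cross-checked in tests against a direct Breslow
partial-likelihood maximization on small data (coefficients agree to 1e-3).

One identifiability caveat the synthetic experiments make visible: if
simulated adherence is driven *only* by covariates that also enter the Cox
adjustment, the predicted-adherence hazard ratio is unidentifiable after
adjustment. The examples therefore route part of the propensity through a
latent phenotype, mirroring the realistic situation where a
high-dimensional predictor carries information beyond the few adjustment
covariates.

## Synthetic generator: what it emulates, and what it does not

Generated per cohort: month-truncated events; a threshold month per patient
with a first fill of 30/60/90/180 days; baseline code/drug/lab events drawn
Poisson with rate = latent intensities · nonnegative loadings (so the count
matrix has true NMF rank at most the latent dimension; loadings are sparse
with a small cross-loading probability, and the loading scale is calibrated
so the mean events-per-patient matches `events_per_patient`); monthly
post-threshold refills as independent Bernoulli draws at a logistic
propensity of named covariates (age, sex, tobacco, standardized latent
intensities); LDL trajectories whose post-threshold drop is
`lipid_effect` · realized adherence plus measurement noise; and one
exponential event clock per diagnosis group with hazard scaled by
exp(factor effects + `adherence_event_coefficient` · realized adherence),
censored at the last observed month (13 to `months_followup` months,
uniform). Identical configs (including seed) reproduce byte-identical
outputs; configs implying negative rates or scales are rejected.

Defaults are chosen as plausible for a statin-initiation claims cohort:
ages normal(50, 9) clipped to 18-65, 24 months of baseline history, up to
60 months of follow-up, ~40 baseline events per patient, 40 mg/dL mean LDL
drop per unit adherence with ~12 mg/dL measurement noise, and a
2e-4/day per-group baseline event hazard (a few percent per year).

Not emulated: real NDC/ICD/HCPCS vocabularies (tokens are synthetic),
primary non-adherence (never-filled prescriptions are out of scope by
design), stockpiling or dose changes, within-patient refill autocorrelation
(refills are conditionally independent given the propensity), seasonal or
calendar effects, and informative censoring beyond uniform follow-up
length. Passing recovery tests therefore show the pipeline measures what it
claims under the generative assumptions the analysis itself makes — not
that those assumptions hold in any particular health system's data.

## Problem sizes used in validation

The recovery experiments run at sizes where their statistical claims are
sharp but the whole suite stays quick: 1000 random schedules for the PDC
oracle; 2000 patients x 300 variables with 5 latent factors for NMF
recovery (mean matched cosine > 0.8); 2000 patients for null calibration
(CV AUC 0.5 ± 0.04) and the Bayes-gap experiment (gap < 0.05 at a Bayes AUC
of ~0.75); 2000 patients and 5 seeds for leave-one-out importance; 20
replicates of 20 000 patients for Cox coverage of a −0.3 log-HR; and 10 000
patients for correlation recovery at a population r of 0.15 (within ±0.03,
about three Fisher standard errors). The end-to-end pipeline demonstration
uses 3000 patients, 15 factors, 30 folds and 150 trees.

## Known limitations

- The NMF optimum is local; different seeds give different (equally valid)
  factor bases. Recovery tests match columns by assignment for this reason.
- The hierarchical-logistic penalty grid is small by default; extreme
  regimes may prefer values outside it.
- PDC's supplied-days ratio overstates coverage on overlapping schedules
  relative to day-coverage; this is the definition, and the contrast oracle
  quantifies it.
- With month-only dates, all within-month ordering is a documented
  convention (file order), not information.
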