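# Methods

## Evaluation model

The package evaluates binary risk stratification by **lift**: the
ratio of outcome prevalence in a flagged high-risk group to prevalence
in the whole evaluation population. For a flagged set of coverage *c*
(fraction flagged), lift = PPV / prevalence, and the identities
`lift × coverage = recall` and `lift ≤ min(1/prevalence, 1/coverage)`
hold by construction; they are asserted globally over every emitted
result.

A score-based model is compared with a rule-based risk factor at
**equal coverage**, per held-out fold: the factor's coverage observed
in that test fold sizes the model's top-k group (k = max(1,
round(c·n)), half-up; ties broken by descending score then ascending
person id). Matching per fold rather than at the pooled coverage keeps
the two groups comparable within each evaluation population. Fold-wise
lifts are summarized as mean ± 1.96·sd/√n (normal approximation across
folds, lower bound clipped at 0 for lifts), and the one-sided
Mann-Whitney U test (alternative: factor lifts stochastically *less*
than model lifts) gives the significance of the model's advantage —
exact enumeration when both samples have ≤ 8 tie-free values,
tie-corrected normal approximation otherwise; a zero-variance pooled
sample returns p = 1 (no evidence). A paired one-sided bootstrap
(default 1,000 resamples, seeded) is provided for comparing paired
metric vectors, with p = the proportion of resamples whose mean
difference is ≤ 0.

The **combined** high-risk set keeps every factor-positive individual
and fills with the highest-scoring factor-negative individuals up to a
target coverage; it is a superset of the factor's set, monotone in the
target, and reduces to the factor's set when the target equals its
coverage. Tracing the combined lift over a coverage grid (default:
factor coverage to 30% in 1-point steps) and taking the grid argmax
gives the "max combined lift" summary; each grid point also carries a
rank-test p-value against the factor-alone fold lifts. The
**candidate coverage range** utility inverts the lift-coverage curve:
the largest grid coverage (default 0.5%–100% in 0.5% steps) at which
mean out-of-fold lift stays at or above a reference lift, or none if
no coverage qualifies.

## Cohort construction and leakage control

Prediction is anchored at an **index date**. Cases: exactly 12 (or 36)
calendar months before the first recorded malignancy concept, found
through the descendant closure of the malignancy root in the concept
hierarchy; month arithmetic is calendar-based with day clamping
(Mar 31 − 1 month → Feb 28/29). Controls carry no malignancy concept
anywhere in their record, so the control set is identical across
per-cancer cohorts built from one population; their index is 24 months
before their last recorded condition — a washout against undiagnosed
cases — shifted a further 24 months back in the 36-month setting.
Eligibility requires ≥ 5 unique (concept, date) pairs strictly before
the index. All comparisons are half-open: "before index" means
`event_date < index_date`, so an event on the index date never enters
a feature, a flag, or the eligibility count.

A case whose earliest malignancy concept maps to a *different* cancer
category (or to no category) is excluded from the cohort under
evaluation entirely — it is neither a case of this type nor an
eligible control. Unknown concepts (id 0) are dropped before any
counting.

## Risk model

Features are binary presence/absence of each condition concept
strictly before the member's index date, as a sparse matrix with fixed
recorded column order; demographic features are deliberately excluded
so the evaluation isolates the condition-history signal. Scoring uses
stratified 5-fold cross-validation: cases and controls are shuffled
separately with the given seed and dealt round-robin (per-fold class
counts differ by ≤ 1), and each member is scored once, by the model
trained on the other folds. Backends are registered by name:
gradient-boosted trees (xgboost; default 150 trees, depth 3, learning
rate 0.1, hist method — sized for synthetic cohorts of a few thousand
members, not tuned claims) and L2 logistic regression (C = 1). Fitted
per-fold models are retained for attribution.

## Attribution ranking

Per fold, each test individual's margin prediction is decomposed into
additive per-feature contributions: exact TreeSHAP via xgboost's
`pred_contribs` for tree backends (additivity is verified against the
margin per individual, tolerance 1e−5 relative), and the closed-form
linear decomposition coef × (x − train mean) for the logistic backend.
The fold-level score of a feature is the **sum of signed
contributions** over the fold's test individuals, so features whose
contributions flip sign across individuals cancel toward zero; fold
scores are dense-ranked (1 = largest) and the final ordering averages
ranks across folds, ties broken by ascending feature id.

The default ranking key is the **magnitude** of the signed sum. This
is a deliberate design choice: for exact additive attributions, the
expected per-feature sum over a population drawn from the background
distribution is zero, so the sign of the realized sum carries sampling
noise plus implementation drift (tree attributions with
hessian-weighted cover systematically push informative features
negative under class imbalance), while the magnitude tracks
consistent, directionally stable contributions. Ordering on the raw
signed value is available (`by_absolute=False`).

## Synthetic data generator

The generator emulates the structure of an OMOP-shaped EHR + genomics
cohort at desk scale. Per person: a birth date (ages uniform on 30–85
at the study end unless an age-window factor reshapes the
distribution), background condition events from a homogeneous Poisson
process (default 2 events/person-year over 12 years of follow-up,
concepts uniform over a 200-concept vocabulary), and risk-factor flags
drawn independently at their configured prevalences. Cancer assignment
multiplies a base hazard by the relative risk of each factor carried,
with the base calibrated so the marginal prevalence matches the
configured value under independence — hence the closed-form factor
lift `r / (1 + f(r − 1))` that the tests and the acceptance script
recover empirically. Cases receive a malignancy concept event on the
ground-truth diagnosis date (uniform in the last five follow-up years,
leaving enough history for eligibility) and additional *signature*
concept events inside the 36-month prediagnostic window, implemented
as Poisson thinning-up: everyone accrues each signature concept at a
base rate, cases accrue extra events in-window so the within-window
rate is the configured multiple of baseline.

Default study conditions: one cancer type at 2% prevalence (a
deliberate scale-up from rare-cancer rates so desk-scale Monte-Carlo
estimates are stable); four signature concepts at rate ratio 5 with
base rate 0.02/person-year (≈ 17% pre-index presence — sparse binary
features, the regime real condition vocabularies live in); planted
factors mirroring a pancreatic-cancer comparison: carrier (1%
prevalence, RR 5), any-site family history (20%, RR 0.8),
site-specific family history (2%, RR 4.4), and new-onset diabetes
(13%, RR 0.95). New-onset diabetes plants a first type-2-diabetes
diagnosis with no prior antidiabetic exposure, plus an equal-sized
background group whose diagnosis is *preceded* by a drug exposure and
therefore must not be flagged. A configurable fraction of
family-history flags can be randomly dropped to emulate survey
underreporting (default 0). Given a fixed config and seed, output is
byte-identical across runs.

What the generator does **not** emulate — and hence what passing tests
do not certify about real data: realistic vocabularies and coding
practice, visit structure, care-utilization correlations between
conditions, informative censoring, demographic confounding of factor
prevalence, or the strength of real prediagnostic signal. With the
default modest signature signal the planted strong factors beat the
model at matched coverage; the pipeline measures that honestly rather
than presuming the model wins. The ambiguous "NOD with age ≥ 60"
variant is implemented as age at the index date, not at diabetes
onset.

## Numerical conventions and degenerate inputs

- AUROC is the probability a random case outranks a random control,
  ties counted ½; single-class input is an error.
- An empty flagged set makes lift *undefined* (error) — deliberately
  distinct from a flagged set containing no cases (lift 0).
- Folds where a factor flags nobody are dropped from the comparison
  with a warning; all folds dropped is an error.
- Combined-curve grid targets below a fold's factor coverage are
  clamped up to it, so factor positives are always retained in full.
- Dates are strict ISO-8601 on disk; mixed formats are rejected on
  read rather than guessed. CSV and Parquet round-trip exactly.
- Fold CIs require ≥ 2 values; zero variance collapses the interval to
  a point.

## Problem sizes

Tests and the reproduction script run on simulated populations of
1,500–20,000 persons (100,000 for the closed-form factor-lift check),
20 replicates for signal-recovery checks, and 200+ replicates for null
calibration — sizes chosen so Monte-Carlo standard errors are small
relative to the tested effects while the whole suite completes in a
couple of minutes on one CPU.

## Known limitations

- Multiple cancer types are assigned sequentially, so a person can be
  a case of at most one type; with several high-prevalence types the
  later types' realized prevalences shift slightly.
- At most one age-window factor per configuration (the age
  distribution is reshaped to honor its prevalence exactly).
- The lift comparison treats the held-out folds as simple random
  samples of the evaluation population; no reweighting to external
  population structure is provided.
- Calibration of scores, decision-curve analysis and cost-effectiveness
  are out of scope; lift, coverage, PPV and recall are the only
  reported operating characteristics.
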