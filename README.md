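# ehrlift

Leakage-safe evaluation of EHR-based cancer risk models against the
traditional risk factors used in screening guidelines, on synthetic
OMOP-style populations with known planted structure.

## The problem

Screening guidelines identify high-risk individuals with narrow
criteria — an age threshold, smoking history, a pathogenic germline
variant, family history. A risk model trained on longitudinal
diagnosis histories can, in principle, flag a high-risk group of *any*
size. The fair comparison between the two is made at **equal
coverage**: if a risk factor flags 1% of the population, threshold the
model's scores so it also flags 1%, and compare the **lift** of the
two groups,

    lift = Pr(case | flagged) / Pr(case)  =  PPV / prevalence,

with coverage = flagged fraction and the identity
`lift × coverage = recall`. A lift of 4.8 means the flagged group is
4.8-fold enriched in true future cases relative to population
screening.

Real EHR + genomics cohorts of this kind are access-restricted, so the
package ships a synthetic-data generator whose planted structure makes
every downstream stage testable against closed-form expectations: a
risk factor planted with prevalence *f* and relative risk *r* has
expected lift `r / (1 + f(r − 1))` — e.g. `f = 0.01, r = 5` gives
4.81.

## What the pipeline does

1. **`simulate`** — OMOP-style tables (`person`,
   `condition_occurrence`, `drug_exposure`, `concept_ancestor`,
   `cancer_mapping`) with planted cancer cases, prediagnostic
   *signature* conditions at a configurable rate ratio, and risk
   factors (carrier status, family history, new-onset diabetes,
   condition sets, age windows).
2. **`cohort`** — malignancy detection through the concept hierarchy's
   descendant closure; case index date exactly 12 (or 36) calendar
   months before first diagnosis; control index 24 months before the
   last recorded condition (washout); eligibility ≥ 5 deduplicated
   condition occurrences strictly before index. All model inputs
   strictly predate the index date.
3. **`features` / `model`** — sparse binary condition-presence
   features; stratified 5-fold cross-validation with out-of-fold
   scoring (`OutOfFoldRiskScorer`, xgboost or penalized logistic
   backends); the held-out folds serve as hypothetical general
   populations.
4. **`risk_factors`** — flags for age windows, condition sets via
   descendant closure, new-onset diabetes with medication washout, and
   static attributes (carrier, survey flags).
5. **`enrichment`** — per-fold coverage-matched lift comparison with
   fold CIs and a one-sided Mann-Whitney test; combined
   risk-factor + model high-risk sets across a coverage grid with the
   max-lift point; candidate coverage ranges; counterfactual flagging
   summaries.
6. **`attribution`** — per-fold signed Shapley-style attribution sums
   with cross-fold rank averaging.

## Worked example

```python
import ehrlift as el
from ehrlift.pipeline import run_study, comparison_table

config = el.SimulationConfig(n_persons=20_000, seed=1)
result = run_study(config, with_attributions=True)

print(f"cohort: {len(result.cohort)} members, "
      f"{int(result.cohort['label'].sum())} cases")
print(f"mean out-of-fold AUROC: {result.mean_oof_auroc:.3f}")
table = comparison_table(result.comparisons)
cols = ["risk_factor", "coverage", "lift_rf", "lift_ehr",
        "p_ehr_gt_rf", "max_combined_lift"]
print(table[cols].round(3).to_string(index=False))
print("top attribution features:")
print(result.attribution_ranking.head(4)[["feature", "mean_rank"]]
      .to_string(index=False))
```

prints

```
cohort: 20000 members, 409 cases
mean out-of-fold AUROC: 0.615
        risk_factor  coverage  lift_rf  lift_ehr  p_ehr_gt_rf  max_combined_lift
            carrier     0.011    3.216     1.783        0.925              3.080
 family_history_any     0.199    0.942     1.698        0.004              1.271
family_history_site     0.021    4.325     2.364        0.992              4.382
                nod     0.127    0.828     1.776        0.004              1.327
top attribution features:
 feature  mean_rank
    7004        1.6
    7003        2.2
    7001        3.4
    7002        4.0
```

Reading the numbers: the planted carrier factor (prevalence ~1%,
relative risk 5) achieves lift 3.2 in this realization; the model,
thresholded to the same 1.1% coverage, reaches 1.8 — with the default
modest signature signal the strong planted factors beat the model at
their own coverage (one-sided p values near 1), while the model beats
the *uninformative* factors (any-site family history, new-onset
diabetes; p ≈ 0.004). Combining each factor with the model
(`max_combined_lift`) keeps all factor-positives and fills with
top-scoring factor-negatives. The four planted signature concepts
(7001–7004) occupy the top attribution ranks.

## Command line

```bash
ehrlift simulate-population --n-persons 20000 --seed 1 --out data/
ehrlift evaluate --data data/ --scores scores.csv --cohort cohort.csv \
    --risk-factors rf.yaml --out report.json
```

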