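"""End-to-end orchestration: simulate → cohort → score → evaluate.

Convenience layer used by the CLI and the reproduction script; each
step is the corresponding module's public function, composed with no
extra logic beyond translating the simulation's risk-factor specs into
flag definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import simulate
from .attribution import aggregate_ranks, compute_attributions
from .cohort import build_cohort
from .enrichment import ComparisonResult, evaluate_risk_factor
from .features import FeatureMatrix, build_feature_matrix
from .model import OutOfFoldRiskScorer, auroc
from .risk_factors import (
    RiskFactorFlag,
    flag_age_window,
    flag_attribute,
    flag_condition_set,
    flag_new_onset_diabetes,
)
from .simulate import PopulationTables, SimulationConfig


def flags_for_simulated_rfs(
    config: SimulationConfig,
    tables: PopulationTables,
    cohort: pd.DataFrame,
) -> dict[str, RiskFactorFlag]:
    """Derive each planted risk factor's flag from the generated tables.

    The flags are computed from the tables exactly as they would be on
    real data — attributes, hierarchy closures, diagnosis/medication
    timing — never from the generator's ground truth.
    """
    flags: dict[str, RiskFactorFlag] = {}
    for spec in config.rf_specs:
        if spec.kind in ("carrier", "family_history"):
            flags[spec.name] = flag_attribute(
                tables.persons, spec.attribute_column(), cohort, name=spec.name
            )
        elif spec.kind == "condition_set":
            flags[spec.name] = flag_condition_set(
                tables.events, tables.hierarchy, [spec.root_concept], cohort,
                name=spec.name,
            )
        elif spec.kind == "nod":
            flags[spec.name] = flag_new_onset_diabetes(
                tables.events,
                tables.drug_exposures,
                cohort,
                diabetes_concepts=[simulate.DIABETES_ROOT, simulate.T2D_CONCEPT],
                diabetes_drug_concepts=[simulate.METFORMIN_CONCEPT],
                name=spec.name,
            )
        elif spec.kind == "age_window":
            flags[spec.name] = flag_age_window(
                tables.persons, cohort, spec.min_age, spec.max_age, name=spec.name
            )
    return flags


@dataclass
class StudyResult:
    """Everything one simulated study produces."""

    tables: PopulationTables
    cohort: pd.DataFrame
    features: FeatureMatrix
    scorer: OutOfFoldRiskScorer
    scored: pd.DataFrame
    flags: dict[str, RiskFactorFlag]
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)
    attribution_ranking: pd.DataFrame | None = None

    @property
    def mean_oof_auroc(self) -> float:
        per_fold = [
            auroc(g["score"], g["label"])
            for _, g in self.scored.groupby("fold_id")
        ]
        return float(sum(per_fold) / len(per_fold))


def run_study(
    config: SimulationConfig,
    cancer_type: str | None = None,
    model: str = "xgboost",
    n_splits: int = 5,
    evaluate_flags: bool = True,
    with_attributions: bool = False,
) -> StudyResult:
    """Simulate one population and run the full evaluation pipeline."""
    tables = simulate.generate_population(config)
    if cancer_type is None:
        cancer_type = next(iter(config.cancer_prevalence))
    cohort = build_cohort(
        tables.persons,
        tables.events,
        tables.hierarchy,
        tables.cancer_mapping,
        cancer_type,
        horizon_months=config.horizon_months,
        malignancy_roots=[simulate.MALIGNANCY_ROOT],
    )
    features = build_feature_matrix(cohort, tables.events)
    scorer = OutOfFoldRiskScorer(
        model=model, n_splits=n_splits, random_state=config.seed
    ).fit(features, cohort)
    flags = flags_for_simulated_rfs(config, tables, cohort)
    result = StudyResult(
        tables=tables,
        cohort=cohort,
        features=features,
        scorer=scorer,
        scored=scorer.scored_,
        flags=flags,
    )
    if evaluate_flags:
        for name, rf in flags.items():
            if rf.flags.sum() == 0:
                continue
            result.comparisons[name] = evaluate_risk_factor(scorer.scored_, rf)
    if with_attributions:
        matrices = compute_attributions(scorer.models_, features, scorer.fold_ids_)
        result.attribution_ranking = aggregate_ranks(matrices)
    return result


def comparison_table(comparisons: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Summary table: one row per risk factor, mirroring the report layout."""
    rows = []
    for name, c in comparisons.items():
        rows.append(
            {
                "risk_factor": name,
                "coverage": c.rf_coverage,
                "lift_rf": c.rf_ci[0],
                "lift_rf_lo": c.rf_ci[1],
                "lift_rf_hi": c.rf_ci[2],
                "lift_ehr": c.ehr_ci[0],
                "lift_ehr_lo": c.ehr_ci[1],
                "lift_ehr_hi": c.ehr_ci[2],
                "p_ehr_gt_rf": c.mann_whitney_p,
                "max_combined_lift": (
                    c.max_combined.mean_lift if c.max_combined else None
                ),
                "max_combined_coverage": (
                    c.max_combined.target_coverage if c.max_combined else None
                ),
            }
        )
    return pd.DataFrame(rows)
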