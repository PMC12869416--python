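"""Traditional screening risk-factor flags, evaluated at the index date.

Each flag is a boolean per cohort member and may depend only on data
strictly before that member's index date (or on static person
attributes). Flags are the comparison arm for the EHR model: a flag's
*coverage* — the fraction of the evaluation population it marks — is
the coverage at which the model is asked to compete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import descendant_closure

logger = logging.getLogger(__name__)


@dataclass
class RiskFactorFlag:
    """Named boolean criterion over a cohort."""

    name: str
    flags: pd.Series  # index: person_id, dtype bool
    definition: dict[str, Any] = field(default_factory=dict)

    def coverage(self) -> float:
        return float(self.flags.mean())

    def values_for(self, person_ids) -> np.ndarray:
        return self.flags.reindex(person_ids).to_numpy(dtype=bool)

    def __and__(self, other: "RiskFactorFlag") -> "RiskFactorFlag":
        combined = self.flags.reindex(self.flags.index) & other.flags.reindex(
            self.flags.index
        )
        return RiskFactorFlag(
            name=f"{self.name}_and_{other.name}",
            flags=combined.astype(bool),
            definition={"kind": "all", "components": [self.definition, other.definition]},
        )

    def __or__(self, other: "RiskFactorFlag") -> "RiskFactorFlag":
        combined = self.flags.reindex(self.flags.index) | other.flags.reindex(
            self.flags.index
        )
        return RiskFactorFlag(
            name=f"{self.name}_or_{other.name}",
            flags=combined.astype(bool),
            definition={"kind": "any", "components": [self.definition, other.definition]},
        )


def _age_years_at(birth: pd.Series, index: pd.Series) -> np.ndarray:
    """Whole-year age at the index date (birthday-not-yet-reached aware)."""
    b, i = pd.DatetimeIndex(birth), pd.DatetimeIndex(index)
    age = i.year - b.year
    before_birthday = (i.month < b.month) | ((i.month == b.month) & (i.day < b.day))
    return (age - before_birthday.astype(int)).to_numpy()


def flag_age_window(
    persons: pd.DataFrame,
    cohort: pd.DataFrame,
    min_age: int,
    max_age: int | None = None,
    name: str | None = None,
) -> RiskFactorFlag:
    """Age at index inside the closed whole-year window [min_age, max_age].

    A printed window like "40–74" is inclusive on both ends; an
    unbounded window ("45+") passes ``max_age=None``.
    """
    merged = cohort.merge(
        persons[["person_id", "birth_date"]], on="person_id", how="left"
    )
    missing = merged.loc[merged["birth_date"].isna(), "person_id"]
    if len(missing):
        raise ValueError(
            f"missing birth dates for persons {missing.tolist()[:10]}"
        )
    age = _age_years_at(merged["birth_date"], merged["index_date"])
    ok = age >= min_age
    if max_age is not None:
        ok &= age <= max_age
    label = name or (f"age_{min_age}_{max_age}" if max_age is not None else f"age_{min_age}plus")
    return RiskFactorFlag(
        name=label,
        flags=pd.Series(ok, index=merged["person_id"].to_numpy()),
        definition={"kind": "age_window", "min_age": min_age, "max_age": max_age},
    )


def flag_condition_set(
    events: pd.DataFrame,
    hierarchy: pd.DataFrame,
    root_concepts: Iterable[int],
    cohort: pd.DataFrame,
    name: str = "condition_set",
) -> RiskFactorFlag:
    """Any event with a concept in the roots' descendant closure before index."""
    closure = descendant_closure(hierarchy, root_concepts)
    if not closure:
        raise ValueError("descendant closure of root concepts is empty")
    merged = events[events["concept_id"].isin(closure)].merge(
        cohort[["person_id", "index_date"]], on="person_id", how="inner"
    )
    hits = set(
        merged.loc[merged["event_date"] < merged["index_date"], "person_id"]
    )
    flags = pd.Series(
        cohort["person_id"].isin(hits).to_numpy(),
        index=cohort["person_id"].to_numpy(),
    )
    return RiskFactorFlag(
        name=name,
        flags=flags,
        definition={"kind": "condition_set", "roots": sorted(int(r) for r in root_concepts)},
    )


def flag_new_onset_diabetes(
    events: pd.DataFrame,
    drug_exposures: pd.DataFrame,
    cohort: pd.DataFrame,
    diabetes_concepts: Iterable[int],
    diabetes_drug_concepts: Iterable[int],
    min_age: int | None = None,
    persons: pd.DataFrame | None = None,
    name: str | None = None,
) -> RiskFactorFlag:
    """First T2D diagnosis before index with no earlier antidiabetic drug.

    The medication washout spans all time before the *first diagnosis*
    (not before the index): an exposure anywhere before the first T2D
    record disqualifies. ``min_age`` adds an age-at-index constraint
    (the "NOD60" variant).
    """
    diabetes_concepts = set(int(c) for c in diabetes_concepts)
    drug_concepts = set(int(c) for c in diabetes_drug_concepts)

    dx = events[events["concept_id"].isin(diabetes_concepts)]
    first_dx = dx.groupby("person_id")["event_date"].min()

    merged = cohort[["person_id", "index_date"]].merge(
        first_dx.rename("first_dx"), left_on="person_id", right_index=True, how="left"
    )
    ok = merged["first_dx"].notna() & (merged["first_dx"] < merged["index_date"])

    meds = drug_exposures[
        drug_exposures["drug_concept_id"].isin(drug_concepts)
    ]
    first_med = meds.groupby("person_id")["exposure_date"].min()
    merged = merged.merge(
        first_med.rename("first_med"), left_on="person_id", right_index=True, how="left"
    )
    prior_med = merged["first_med"].notna() & (
        merged["first_med"] < merged["first_dx"]
    )
    ok &= ~prior_med

    if min_age is not None:
        if persons is None:
            raise ValueError("persons table required when min_age is given")
        age_flag = flag_age_window(persons, cohort, min_age)
        ok &= pd.Series(age_flag.values_for(merged["person_id"]))

    label = name or ("nod" if min_age is None else f"nod{min_age}")
    return RiskFactorFlag(
        name=label,
        flags=pd.Series(ok.to_numpy(dtype=bool), index=merged["person_id"].to_numpy()),
        definition={
            "kind": "nod",
            "diabetes_concepts": sorted(diabetes_concepts),
            "drug_concepts": sorted(drug_concepts),
            "min_age": min_age,
        },
    )


def flag_attribute(
    persons: pd.DataFrame,
    attribute_name: str,
    cohort: pd.DataFrame,
    name: str | None = None,
) -> RiskFactorFlag:
    """Pass through a static boolean person attribute (carrier, survey flags).

    Missing values count as False; their number is logged as a
    missingness report rather than silently ignored.
    """
    if attribute_name not in persons.columns:
        raise KeyError(
            f"unknown attribute {attribute_name!r}; available: "
            f"{sorted(c for c in persons.columns if c != 'person_id')}"
        )
    values = persons.set_index("person_id")[attribute_name].reindex(
        cohort["person_id"]
    )
    n_missing = int(values.isna().sum())
    if n_missing:
        logger.info(
            "attribute %r missing for %d of %d cohort members; treated as False",
            attribute_name, n_missing, len(values),
        )
    flags = values.notna() & values.eq(True)
    flags.index = cohort["person_id"].to_numpy()
    return RiskFactorFlag(
        name=name or attribute_name,
        flags=flags,
        definition={"kind": "attribute", "attribute": attribute_name,
                    "n_missing": n_missing},
    )


def flags_from_spec(
    spec: Mapping[str, Any],
    persons: pd.DataFrame,
    events: pd.DataFrame,
    drug_exposures: pd.DataFrame,
    hierarchy: pd.DataFrame,
    cohort: pd.DataFrame,
) -> RiskFactorFlag:
    """Build a flag from a declarative spec dict.

    ``{"name", "kind": age_window|condition_set|nod|attribute|all|any,
    ...kind parameters, "components": [...]}``; ``all``/``any`` combine
    component specs elementwise.
    """
    kind = spec["kind"]
    name = spec.get("name")
    if kind == "age_window":
        return flag_age_window(
            persons, cohort, spec["min_age"], spec.get("max_age"), name=name
        )
    if kind == "condition_set":
        return flag_condition_set(
            events, hierarchy, spec["roots"], cohort, name=name or "condition_set"
        )
    if kind == "nod":
        return flag_new_onset_diabetes(
            events,
            drug_exposures,
            cohort,
            spec["diabetes_concepts"],
            spec["drug_concepts"],
            min_age=spec.get("min_age"),
            persons=persons,
            name=name,
        )
    if kind == "attribute":
        return flag_attribute(persons, spec["attribute"], cohort, name=name)
    if kind in ("all", "any"):
        parts = [
            flags_from_spec(c, persons, events, drug_exposures, hierarchy, cohort)
            for c in spec["components"]
        ]
        out = parts[0]
        for part in parts[1:]:
            out = (out & part) if kind == "all" else (out | part)
        if name:
            out.name = name
        return out
    raise ValueError(f"unknown risk-factor kind {kind!r}")
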