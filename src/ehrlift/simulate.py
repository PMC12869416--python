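"""Synthetic OMOP-style population generator with planted ground truth.

Real EHR-plus-genomics cohorts of the kind used to evaluate cancer risk
models (longitudinal condition histories, germline carrier status,
family-history survey flags) are access-restricted. This module
generates populations with the same table shapes — ``person``,
``condition_occurrence``, ``drug_exposure``, ``concept_ancestor``,
``cancer_mapping`` — and *known* planted structure, so every downstream
stage (cohort phenotyping, out-of-fold scoring, lift evaluation) can be
tested against closed-form expectations.

Planted structure
-----------------
* Cancer cases are assigned per person from a base hazard multiplied by
  the relative risk of each risk factor the person carries. With a
  factor of prevalence ``f`` and relative risk ``r``, the factor's
  expected lift over the whole population is ``r / (1 + f(r - 1))``.
* Cases carry a malignancy condition event on their (ground-truth)
  diagnosis date, and *signature* condition concepts occur at an
  elevated rate inside a prediagnostic window before that date —
  background events everywhere else are a homogeneous Poisson process.
* Risk factors of kind ``carrier`` / ``family_history`` are person
  attributes; ``condition_set`` plants a diagnosis concept from a
  dedicated hierarchy subtree; ``nod`` plants a first type-2-diabetes
  diagnosis with no prior antidiabetic drug exposure; ``age_window``
  shapes the age distribution so the window holds the configured
  population fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dates import parse_iso_dates

# Fixed concept ids used by the generator. The malignancy root and the
# type-2-diabetes / metformin ids follow OMOP conventions so fixtures
# read naturally; everything else lives in reserved synthetic ranges.
MALIGNANCY_ROOT = 443392
CANCER_CONCEPT_BASE = 443400  # per-cancer-type leaf concepts
DIABETES_ROOT = 201820
T2D_CONCEPT = 201826
METFORMIN_CONCEPT = 1503297
BACKGROUND_CONCEPT_BASE = 3001
DAYS_PER_YEAR = 365.2425

RF_KINDS = ("carrier", "family_history", "condition_set", "age_window", "nod")


@dataclass(frozen=True)
class RiskFactorSpec:
    """One planted risk factor.

    Parameters
    ----------
    name:
        Identifier; for ``family_history`` kinds it doubles as the
        person-attribute column (``family_history_any`` /
        ``family_history_site``) unless ``attribute`` is given.
    kind:
        One of ``carrier``, ``family_history``, ``condition_set``,
        ``age_window``, ``nod``.
    prevalence:
        Population fraction carrying the factor.
    relative_risk:
        Multiplier applied to the base cancer hazard of carriers.
    root_concept:
        Hierarchy subtree root for ``condition_set`` factors; the
        planted events use the root's child concept so descendant
        closure is exercised end to end.
    min_age, max_age:
        Closed whole-year age bounds for ``age_window`` factors.
    """

    name: str
    kind: str
    prevalence: float
    relative_risk: float
    root_concept: int | None = None
    min_age: int | None = None
    max_age: int | None = None
    attribute: str | None = None

    def attribute_column(self) -> str | None:
        if self.kind == "carrier":
            return "carrier"
        if self.kind == "family_history":
            return self.attribute or self.name
        return None


def _default_rf_specs() -> tuple[RiskFactorSpec, ...]:
    # Defaults mirror the pancreatic-cancer comparison conditions: a rare
    # germline carrier flag (~1% of the population, strong risk), a
    # common any-site family-history flag that is nearly uninformative,
    # a rarer site-specific family-history flag, and new-onset diabetes.
    return (
        RiskFactorSpec("carrier", "carrier", 0.01, 5.0),
        RiskFactorSpec("family_history_any", "family_history", 0.20, 0.8),
        RiskFactorSpec("family_history_site", "family_history", 0.02, 4.4),
        RiskFactorSpec("nod", "nod", 0.13, 0.95),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic population."""

    n_persons: int = 10_000
    cancer_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"pancreas": 0.02}
    )
    n_concepts: int = 200
    signature_concepts: Sequence[tuple[int, float]] = (
        (7001, 5.0), (7002, 5.0), (7003, 5.0), (7004, 5.0))
    signature_base_rate: float = 0.02
    signature_lead_months: int = 36
    background_event_rate: float = 2.0
    followup_years: float = 12.0
    rf_specs: Sequence[RiskFactorSpec] = field(default_factory=_default_rf_specs)
    horizon_months: int = 12
    seed: int = 0
    study_end: str = "2020-01-01"
    age_range: tuple[int, int] = (30, 85)
    min_history_years: float = 7.0
    fh_drop_rate: float = 0.0


def validate_config(config: SimulationConfig) -> None:
    """Raise ``ValueError`` naming the offending field if invalid."""
    if config.n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    for cancer_type, prev in config.cancer_prevalence.items():
        if not 0.0 <= prev <= 1.0:
            raise ValueError(
                f"cancer_prevalence[{cancer_type!r}] must be in [0, 1], got {prev}"
            )
    if config.n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    if config.background_event_rate < 0:
        raise ValueError("background_event_rate must be >= 0")
    if config.signature_base_rate < 0:
        raise ValueError("signature_base_rate must be >= 0")
    if config.followup_years <= 0:
        raise ValueError("followup_years must be > 0")
    if config.horizon_months not in (12, 36):
        raise ValueError("horizon_months must be 12 or 36")
    if not 0.0 <= config.fh_drop_rate <= 1.0:
        raise ValueError("fh_drop_rate must be in [0, 1]")
    if config.min_history_years >= config.followup_years:
        raise ValueError("min_history_years must be < followup_years")
    for cid, rate in config.signature_concepts:
        if rate <= 0:
            raise ValueError(
                f"signature_concepts relative rate for concept {cid} must be > 0"
            )
    n_age = 0
    for spec in config.rf_specs:
        if spec.kind not in RF_KINDS:
            raise ValueError(
                f"rf_specs[{spec.name!r}].kind must be one of {RF_KINDS}, "
                f"got {spec.kind!r}"
            )
        if not 0.0 <= spec.prevalence <= 1.0:
            raise ValueError(
                f"rf_specs[{spec.name!r}].prevalence must be in [0, 1]"
            )
        if spec.relative_risk <= 0:
            raise ValueError(
                f"rf_specs[{spec.name!r}].relative_risk must be > 0"
            )
        if spec.kind == "condition_set" and spec.root_concept is None:
            raise ValueError(
                f"rf_specs[{spec.name!r}].root_concept required for condition_set"
            )
        if spec.kind == "age_window":
            n_age += 1
            if spec.min_age is None:
                raise ValueError(
                    f"rf_specs[{spec.name!r}].min_age required for age_window"
                )
    if n_age > 1:
        raise ValueError("rf_specs supports at most one age_window factor")


@dataclass
class PopulationTables:
    """The five OMOP-style tables plus the planted ground truth."""

    persons: pd.DataFrame
    events: pd.DataFrame
    drug_exposures: pd.DataFrame
    hierarchy: pd.DataFrame
    cancer_mapping: pd.DataFrame
    truth: pd.DataFrame

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "person": self.persons,
            "condition_occurrence": self.events,
            "drug_exposure": self.drug_exposures,
            "concept_ancestor": self.hierarchy,
            "cancer_mapping": self.cancer_mapping,
            "ground_truth": self.truth,
        }


def _sample_ages(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Continuous ages at study end; age-window factors get exact windows."""
    lo, hi = config.age_range
    n = config.n_persons
    age_specs = [s for s in config.rf_specs if s.kind == "age_window"]
    if not age_specs:
        return rng.uniform(lo, hi, n), {}
    spec = age_specs[0]
    w_lo = float(spec.min_age)
    w_hi = float(spec.max_age + 1) if spec.max_age is not None else float(hi)
    w_lo, w_hi = max(w_lo, lo), min(w_hi, hi)
    in_window = rng.random(n) < spec.prevalence
    ages = np.empty(n)
    ages[in_window] = rng.uniform(w_lo, w_hi, int(in_window.sum()))
    # sample outside the window proportionally to the two flank widths
    n_out = int((~in_window).sum())
    left, right = w_lo - lo, hi - w_hi
    total = left + right
    if total <= 0:
        raise ValueError(
            f"rf_specs[{spec.name!r}] age window covers the whole age_range"
        )
    u = rng.uniform(0, total, n_out)
    out = np.where(u < left, lo + u, w_hi + (u - left))
    ages[~in_window] = out
    return ages, {spec.name: in_window}


def generate_population(config: SimulationConfig) -> PopulationTables:
    """Generate one synthetic population; deterministic given the seed."""
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    person_id = np.arange(1, n + 1, dtype=np.int64)

    study_end = pd.Timestamp(config.study_end)
    followup_days = config.followup_years * DAYS_PER_YEAR
    study_start = study_end - pd.Timedelta(days=followup_days)

    ages, flags = _sample_ages(rng, config)
    birth_date = (study_end - pd.to_timedelta(ages * DAYS_PER_YEAR, unit="D")).floor("D")
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    for spec in config.rf_specs:
        if spec.kind != "age_window":
            flags[spec.name] = rng.random(n) < spec.prevalence

    # Per-person cancer hazard: base calibrated so the marginal prevalence
    # matches the configured value under independent risk factors.
    denom = 1.0
    for spec in config.rf_specs:
        denom *= 1.0 + spec.prevalence * (spec.relative_risk - 1.0)
    multiplier = np.ones(n)
    for spec in config.rf_specs:
        multiplier = np.where(
            flags[spec.name], multiplier * spec.relative_risk, multiplier
        )

    cancer_types = list(config.cancer_prevalence)
    true_type = np.full(n, None, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    risk_by_type = {}
    for cancer_type in cancer_types:
        base = config.cancer_prevalence[cancer_type] / denom
        p = np.clip(base * multiplier, 0.0, 0.99)
        risk_by_type[cancer_type] = p
        hit = (rng.random(n) < p) & ~assigned
        true_type[hit] = cancer_type
        assigned |= hit

    is_case = assigned
    dx_offset = rng.uniform(
        config.min_history_years * DAYS_PER_YEAR, followup_days, n
    )
    dx_date = (study_start + pd.to_timedelta(dx_offset, unit="D")).floor("D")
    true_cancer_date = pd.Series(dx_date).where(pd.Series(is_case), pd.NaT)

    frames = [
        _background_events(rng, config, person_id, followup_days, study_start),
        _signature_events(
            rng, config, person_id, is_case, dx_date, followup_days, study_start
        ),
    ]

    # malignancy event on the ground-truth diagnosis date
    type_concepts = {
        t: CANCER_CONCEPT_BASE + i for i, t in enumerate(cancer_types)
    }
    case_idx = np.flatnonzero(is_case)
    frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[case_idx],
                "concept_id": np.array(
                    [type_concepts[true_type[i]] for i in case_idx], dtype=np.int64
                ),
                "event_date": dx_date[case_idx],
            }
        )
    )

    edges = [(MALIGNANCY_ROOT, c) for c in type_concepts.values()]
    edges.append((DIABETES_ROOT, T2D_CONCEPT))

    drug_rows = []
    for spec in config.rf_specs:
        if spec.kind == "condition_set":
            child = spec.root_concept + 1
            edges.append((spec.root_concept, child))
            idx = np.flatnonzero(flags[spec.name])
            offs = rng.uniform(0, 3 * DAYS_PER_YEAR, idx.size)
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[idx],
                        "concept_id": np.int64(child),
                        "event_date": (
                            study_start + pd.to_timedelta(offs, unit="D")
                        ).floor("D"),
                    }
                )
            )
        elif spec.kind == "nod":
            idx = np.flatnonzero(flags[spec.name])
            offs = rng.uniform(DAYS_PER_YEAR, 3 * DAYS_PER_YEAR, idx.size)
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[idx],
                        "concept_id": np.int64(T2D_CONCEPT),
                        "event_date": (
                            study_start + pd.to_timedelta(offs, unit="D")
                        ).floor("D"),
                    }
                )
            )
            # background diabetes with prior medication: diagnosed T2D that
            # does NOT qualify as new-onset (drug exposure precedes diagnosis)
            bg = rng.random(n) < spec.prevalence
            bg &= ~flags[spec.name]
            bidx = np.flatnonzero(bg)
            med_offs = rng.uniform(0.5 * DAYS_PER_YEAR, 2 * DAYS_PER_YEAR, bidx.size)
            med_dates = (study_start + pd.to_timedelta(med_offs, unit="D")).floor("D")
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[bidx],
                        "concept_id": np.int64(T2D_CONCEPT),
                        "event_date": med_dates + pd.Timedelta(days=183),
                    }
                )
            )
            drug_rows.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[bidx],
                        "drug_concept_id": np.int64(METFORMIN_CONCEPT),
                        "exposure_date": med_dates,
                    }
                )
            )

    frames = [f for f in frames if len(f)]
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(
            {
                "person_id": pd.Series(dtype=np.int64),
                "concept_id": pd.Series(dtype=np.int64),
                "event_date": pd.Series(dtype="datetime64[ns]"),
            }
        )
    events = events.drop_duplicates(["person_id", "concept_id", "event_date"])
    events = events.sort_values(
        ["person_id", "event_date", "concept_id"], ignore_index=True
    )

    drug_exposures = (
        pd.concat(drug_rows, ignore_index=True)
        if drug_rows
        else pd.DataFrame(
            {
                "person_id": pd.Series(dtype=np.int64),
                "drug_concept_id": pd.Series(dtype=np.int64),
                "exposure_date": pd.Series(dtype="datetime64[ns]"),
            }
        )
    )
    drug_exposures = drug_exposures.sort_values(
        ["person_id", "exposure_date"], ignore_index=True
    )

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "birth_date": birth_date,
            "sex": sex,
            "carrier": _attribute(flags, config, "carrier", n),
            "family_history_any": _attribute(
                flags, config, "family_history_any", n, rng=rng,
                drop_rate=config.fh_drop_rate,
            ),
            "family_history_site": _attribute(
                flags, config, "family_history_site", n, rng=rng,
                drop_rate=config.fh_drop_rate,
            ),
            "true_cancer_date": true_cancer_date.values,
            "true_cancer_type": pd.Series(true_type, dtype=object).where(
                pd.Series(true_type).notna(), np.nan
            ),
        }
    )

    truth = pd.DataFrame({"person_id": person_id, "is_case": is_case})
    for name, flag in flags.items():
        truth[f"rf_{name}"] = flag
    for cancer_type, p in risk_by_type.items():
        truth[f"risk_{cancer_type}"] = p

    hierarchy = pd.DataFrame(
        sorted(set(edges)), columns=["parent_concept_id", "child_concept_id"]
    ).astype(np.int64)
    cancer_mapping = pd.DataFrame(
        {
            "concept_id": list(type_concepts.values()),
            "category": list(type_concepts.keys()),
        }
    ).astype({"concept_id": np.int64})

    return PopulationTables(
        persons=persons,
        events=events,
        drug_exposures=drug_exposures,
        hierarchy=hierarchy,
        cancer_mapping=cancer_mapping,
        truth=truth,
    )


def _attribute(flags, config, column, n, rng=None, drop_rate=0.0):
    for spec in config.rf_specs:
        if spec.attribute_column() == column:
            observed = flags[spec.name].copy()
            if drop_rate > 0 and rng is not None:
                observed &= rng.random(n) >= drop_rate
            return observed
    return np.zeros(n, dtype=bool)


def _background_events(rng, config, person_id, followup_days, study_start):
    counts = rng.poisson(config.background_event_rate * config.followup_years,
                         person_id.size)
    pid = np.repeat(person_id, counts)
    offs = rng.uniform(0, followup_days, pid.size)
    concepts = BACKGROUND_CONCEPT_BASE + rng.integers(
        0, config.n_concepts, pid.size, dtype=np.int64
    )
    return pd.DataFrame(
        {
            "person_id": pid,
            "concept_id": concepts,
            "event_date": (study_start + pd.to_timedelta(offs, unit="D")).floor("D"),
        }
    )


def _signature_events(
    rng, config, person_id, is_case, dx_date, followup_days, study_start
):
    """Signature concepts: Poisson everywhere, thinned-up inside the window.

    Everyone accrues each signature concept at ``signature_base_rate``;
    cases accrue additional events inside ``(dx − lead, dx)`` so the
    within-window rate is ``relative_rate ×`` the baseline.
    """
    lead_days = config.signature_lead_months / 12.0 * DAYS_PER_YEAR
    frames = []
    n = person_id.size
    case_idx = np.flatnonzero(is_case)
    dx_off_days = (
        (pd.DatetimeIndex(dx_date) - study_start) / pd.Timedelta(days=1)
    ).to_numpy()
    for concept_id, rel_rate in config.signature_concepts:
        base_counts = rng.poisson(
            config.signature_base_rate * config.followup_years, n
        )
        pid = np.repeat(person_id, base_counts)
        offs = rng.uniform(0, followup_days, pid.size)
        frames.append((pid, np.int64(concept_id), offs))
        if case_idx.size and rel_rate != 1.0:
            extra_mean = config.signature_base_rate * (rel_rate - 1.0) * (
                lead_days / DAYS_PER_YEAR
            )
            extra_counts = rng.poisson(max(extra_mean, 0.0), case_idx.size)
            pid_x = np.repeat(person_id[case_idx], extra_counts)
            lo = np.repeat(dx_off_days[case_idx] - lead_days, extra_counts)
            width = rng.uniform(0, lead_days, pid_x.size)
            frames.append((pid_x, np.int64(concept_id), lo + width))
    parts = [
        pd.DataFrame(
            {
                "person_id": pid,
                "concept_id": cid,
                "event_date": (study_start + pd.to_timedelta(offs, unit="D")).floor("D"),
            }
        )
        for pid, cid, offs in frames
    ]
    return (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=["person_id", "concept_id", "event_date"])
    )


# ---------------------------------------------------------------------------
# table I/O

_DATE_COLUMNS = {
    "person": ["birth_date", "true_cancer_date"],
    "condition_occurrence": ["event_date"],
    "drug_exposure": ["exposure_date"],
    "concept_ancestor": [],
    "cancer_mapping": [],
    "ground_truth": [],
}

_DATA_DICTIONARY = """\
# Data dictionary

All dates are ISO-8601 (YYYY-MM-DD). Identifiers are integers.

## person
- person_id: unique person identifier
- birth_date: date of birth
- sex: F or M
- carrier: pathogenic-variant carrier status (boolean attribute)
- family_history_any: any-site family-history survey flag
- family_history_site: site-specific family-history survey flag
- true_cancer_date: ground-truth diagnosis date (empty for non-cases)
- true_cancer_type: ground-truth cancer category (empty for non-cases)

## condition_occurrence
- person_id, concept_id, event_date: one dated diagnosis code
  (deduplicated on the full triple)

## drug_exposure
- person_id, drug_concept_id, exposure_date

## concept_ancestor
- parent_concept_id, child_concept_id: one direct is-a edge

## cancer_mapping
- concept_id, category: malignancy concept to cancer-type category

## ground_truth
- person_id, is_case, rf_<name> planted flags, risk_<type> assigned
  per-person cancer probabilities (simulation internals, not inputs
  to any model)
"""


def write_tables(
    tables: PopulationTables | Mapping[str, pd.DataFrame],
    directory: str | Path,
    format: str = "csv",
) -> dict[str, Path]:
    """Write population tables as CSV or Parquet plus a data dictionary."""
    if format not in ("csv", "parquet"):
        raise ValueError(f"format must be 'csv' or 'parquet', got {format!r}")
    mapping = tables.as_dict() if isinstance(tables, PopulationTables) else tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in mapping.items():
        path = directory / f"{name}.{format}"
        if format == "csv":
            out = df.copy()
            for col in _DATE_COLUMNS.get(name, []):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            out.to_csv(path, index=False)
        else:
            df.to_parquet(path, index=False)
        paths[name] = path
    dict_path = directory / "data_dictionary.md"
    dict_path.write_text(_DATA_DICTIONARY)
    paths["data_dictionary"] = dict_path
    return paths


def read_tables(directory: str | Path, format: str = "csv") -> PopulationTables:
    """Read tables written by :func:`write_tables` (exact round trip)."""
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    names = [
        "person",
        "condition_occurrence",
        "drug_exposure",
        "concept_ancestor",
        "cancer_mapping",
        "ground_truth",
    ]
    for name in names:
        path = directory / f"{name}.{format}"
        if format == "csv":
            df = pd.read_csv(path)
            for col in _DATE_COLUMNS[name]:
                df[col] = parse_iso_dates(df[col], col)
        else:
            df = pd.read_parquet(path)
        if name == "person" and "true_cancer_type" in df:
            # normalize missingness marker across dialects (None vs NaN)
            df["true_cancer_type"] = df["true_cancer_type"].where(
                df["true_cancer_type"].notna(), np.nan
            )
        frames[name] = df
    return PopulationTables(
        persons=frames["person"],
        events=frames["condition_occurrence"],
        drug_exposures=frames["drug_exposure"],
        hierarchy=frames["concept_ancestor"],
        cancer_mapping=frames["cancer_mapping"],
        truth=frames["ground_truth"],
    )
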