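"""Cohort phenotyping: malignancy detection, index dates, eligibility.

The prediction task is framed prospectively. For a case, the *index
date* — the moment at which the model pretends to make its prediction —
is placed exactly ``horizon_months`` calendar months before the first
recorded cancer diagnosis; every model input must strictly predate it,
so diagnostic workup around the diagnosis cannot leak into features.
Controls, who have no malignancy concept anywhere in their record, get
an index 24 months before their last recorded condition (a washout that
reduces contamination by not-yet-diagnosed cases); for the 36-month
horizon both indexes shift a further 24 months into the past.
Eligibility requires at least five non-duplicate condition occurrences
— unique (concept, date) pairs — strictly before the index date.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from ._dates import add_months

ELIGIBILITY_MIN_CONDITIONS = 5
CONTROL_WASHOUT_MONTHS = 24


def descendant_closure(
    hierarchy: pd.DataFrame, roots: Iterable[int]
) -> set[int]:
    """Roots plus every concept transitively reachable through child edges.

    ``hierarchy`` holds direct (parent_concept_id, child_concept_id)
    edges. Raises on cyclic hierarchies (naming a cycle member) and on
    roots absent from the graph.
    """
    graph = nx.DiGraph()
    graph.add_edges_from(
        zip(
            hierarchy["parent_concept_id"].astype(int),
            hierarchy["child_concept_id"].astype(int),
        )
    )
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(
            f"concept hierarchy contains a cycle through concept {cycle[0][0]}"
        )
    roots = set(int(r) for r in roots)
    unknown = roots - set(graph.nodes)
    if unknown:
        raise KeyError(f"root concepts not present in hierarchy: {sorted(unknown)}")
    closure = set(roots)
    for root in roots:
        closure |= nx.descendants(graph, root)
    return closure


def first_cancer_date(
    events: pd.DataFrame, malignancy_set: set[int], person_id: int
) -> pd.Timestamp | None:
    """Earliest event date of any malignancy concept; None if none."""
    sub = events[
        (events["person_id"] == person_id)
        & events["concept_id"].isin(malignancy_set)
    ]
    if sub.empty:
        return None
    return sub["event_date"].min()


def case_index_date(first_dx: dt.date | pd.Timestamp, horizon_months: int) -> pd.Timestamp:
    """Index exactly ``horizon_months`` calendar months before diagnosis."""
    if horizon_months not in (12, 36):
        raise ValueError(f"horizon_months must be 12 or 36, got {horizon_months}")
    return add_months(first_dx, -horizon_months)


def control_index_date(
    events: pd.DataFrame | pd.Series, horizon_months: int
) -> pd.Timestamp:
    """Washout index: last condition − 24 months (−48 for 36-month horizon)."""
    if horizon_months not in (12, 36):
        raise ValueError(f"horizon_months must be 12 or 36, got {horizon_months}")
    dates = events["event_date"] if isinstance(events, pd.DataFrame) else events
    if len(dates) == 0:
        raise ValueError("control has no condition events; index date undefined")
    shift = CONTROL_WASHOUT_MONTHS + (horizon_months - 12)
    return add_months(dates.max(), -shift)


def eligibility(
    events: pd.DataFrame, index_date: dt.date | pd.Timestamp
) -> bool:
    """True iff ≥ 5 unique (concept, date) pairs strictly before the index."""
    before = events[events["event_date"] < pd.Timestamp(index_date)]
    n = len(before[["concept_id", "event_date"]].drop_duplicates())
    return n >= ELIGIBILITY_MIN_CONDITIONS


def build_cohort(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    hierarchy: pd.DataFrame,
    mapping: pd.DataFrame,
    cancer_type: str,
    horizon_months: int = 12,
    malignancy_roots: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Assemble the case/control cohort for one cancer type.

    Cases are persons whose *earliest* malignancy concept maps to
    ``cancer_type``; persons whose earliest malignancy maps to another
    category (or to none) are excluded from this cohort entirely —
    controls must carry no malignancy concept at all, so the control
    set is shared across all per-type cohorts built from the same
    population. Both arms are filtered by the five-condition
    eligibility rule, evaluated on (concept, date)-deduplicated events
    with unknown concepts (id 0) removed.

    Parameters
    ----------
    mapping:
        Two columns, ``concept_id`` and ``category``.
    malignancy_roots:
        Hierarchy roots whose descendant closure defines "malignancy
        concept". Defaults to the concepts listed in ``mapping``
        (closure-expanded through the hierarchy).

    Returns
    -------
    DataFrame with columns person_id, label (1 case / 0 control),
    cancer_type, index_date, horizon_months.
    """
    categories = set(mapping["category"])
    if cancer_type not in categories:
        raise KeyError(
            f"cancer_type {cancer_type!r} not present in mapping categories "
            f"{sorted(categories)}"
        )
    concept_to_category = dict(
        zip(mapping["concept_id"].astype(int), mapping["category"])
    )
    if malignancy_roots is not None:
        malignancy_set = descendant_closure(hierarchy, malignancy_roots)
    else:
        hier_nodes = set(hierarchy["parent_concept_id"]) | set(
            hierarchy["child_concept_id"]
        )
        in_hier = [c for c in concept_to_category if c in hier_nodes]
        malignancy_set = set(concept_to_category)
        if in_hier:
            malignancy_set |= descendant_closure(hierarchy, in_hier)

    events = events[events["concept_id"] != 0]
    events = events.drop_duplicates(["person_id", "concept_id", "event_date"])

    mal = events[events["concept_id"].isin(malignancy_set)]
    # earliest malignancy event per person; ties on date broken by the
    # smallest concept id for determinism
    mal = mal.sort_values(["person_id", "event_date", "concept_id"])
    first_mal = mal.groupby("person_id", sort=True).first()

    rows = []
    events_by_person = dict(tuple(events.groupby("person_id", sort=True)))
    for person in persons.itertuples(index=False):
        pid = person.person_id
        ev = events_by_person.get(pid)
        if ev is None or ev.empty:
            continue  # no record at all: fails eligibility regardless
        if pid in first_mal.index:
            first_row = first_mal.loc[pid]
            category = concept_to_category.get(
                int(first_row["concept_id"]), "unmapped"
            )
            if category != cancer_type:
                continue  # case of another (or unmapped) category: excluded
            index_date = case_index_date(first_row["event_date"], horizon_months)
            label = 1
        else:
            index_date = control_index_date(ev, horizon_months)
            label = 0
        if not eligibility(ev, index_date):
            continue
        rows.append(
            (pid, label, cancer_type if label else None, index_date, horizon_months)
        )
    cohort = pd.DataFrame(
        rows,
        columns=["person_id", "label", "cancer_type", "index_date", "horizon_months"],
    )
    if not cohort.empty:
        cohort = cohort.astype(
            {"person_id": np.int64, "label": np.int64, "horizon_months": np.int64}
        )
    return cohort
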