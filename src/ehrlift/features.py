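"""Binary condition-presence feature construction.

Each cohort member is represented by a sparse binary vector over the
condition vocabulary: 1 iff at least one event of that concept occurs
strictly before the member's index date. Unknown concepts (id 0) never
become columns, and events on or after the index contribute nothing —
the leakage boundary is enforced here, not left to upstream filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class FeatureMatrix:
    """Sparse binary design matrix with its column bookkeeping."""

    X: sp.csr_matrix
    columns: np.ndarray  # concept ids, fixed order
    person_ids: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.sparse.from_spmatrix(
            self.X, index=self.person_ids, columns=self.columns
        )


def build_feature_matrix(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    vocabulary: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Presence/absence of each concept strictly before each index date.

    ``vocabulary`` fixes the admissible concepts and their column order;
    by default it is every concept observed in ``events`` except the
    unknown concept 0, in ascending id order.
    """
    events = events[events["concept_id"] != 0]
    if vocabulary is None:
        vocabulary = np.sort(events["concept_id"].unique())
    else:
        vocabulary = np.asarray(list(vocabulary), dtype=np.int64)
        if (vocabulary == 0).any():
            raise ValueError("vocabulary must not contain the unknown concept 0")
    col_index = {c: j for j, c in enumerate(vocabulary)}

    merged = events.merge(
        cohort[["person_id", "index_date"]], on="person_id", how="inner"
    )
    merged = merged[merged["event_date"] < merged["index_date"]]
    merged = merged[merged["concept_id"].isin(col_index)]

    row_index = {p: i for i, p in enumerate(cohort["person_id"])}
    rows = merged["person_id"].map(row_index).to_numpy()
    cols = merged["concept_id"].map(col_index).to_numpy()
    data = np.ones(len(merged), dtype=np.float32)
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cohort), len(vocabulary))
    )
    X.data[:] = 1.0  # collapse duplicate (person, concept) entries to presence
    X.sum_duplicates()
    X.data[:] = 1.0
    return FeatureMatrix(
        X=X,
        columns=np.asarray(vocabulary, dtype=np.int64),
        person_ids=cohort["person_id"].to_numpy(),
    )


class ConditionPresenceFeaturizer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper over :func:`build_feature_matrix`.

    ``fit`` learns the vocabulary (all non-zero concepts in the event
    table, ascending); ``transform`` builds the binary matrix for a
    cohort against that fixed vocabulary.
    """

    def __init__(self, vocabulary: Sequence[int] | None = None):
        self.vocabulary = vocabulary

    def fit(self, events: pd.DataFrame, y=None) -> "ConditionPresenceFeaturizer":
        if self.vocabulary is not None:
            vocab = np.asarray(list(self.vocabulary), dtype=np.int64)
        else:
            vocab = np.sort(
                events.loc[events["concept_id"] != 0, "concept_id"].unique()
            )
        self.vocabulary_ = vocab
        return self

    def transform(self, cohort_events: tuple[pd.DataFrame, pd.DataFrame]) -> FeatureMatrix:
        cohort, events = cohort_events
        return build_feature_matrix(cohort, events, self.vocabulary_)


def write_feature_matrix(fm: FeatureMatrix, directory: str | Path) -> dict[str, Path]:
    """Persist as MatrixMarket plus column/row sidecars."""
    import scipy.io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mtx = directory / "features.mtx"
    scipy.io.mmwrite(mtx, fm.X)
    cols = directory / "feature_columns.csv"
    pd.DataFrame({"concept_id": fm.columns}).to_csv(cols, index=False)
    rows = directory / "feature_rows.csv"
    pd.DataFrame({"person_id": fm.person_ids}).to_csv(rows, index=False)
    return {"matrix": mtx, "columns": cols, "rows": rows}
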