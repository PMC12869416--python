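"""Calendar-month date arithmetic shared across the package.

Index dates are defined by calendar-month offsets ("exactly 12 months
prior"), not by fixed day counts, so all shifting goes through
:func:`add_months`, which clamps the day of month when the target month
is shorter (Mar 31 − 1 month → Feb 28/29).
"""

from __future__ import annotations

import datetime as dt
import re

import pandas as pd

_ISO_DATE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def add_months(date: dt.date | pd.Timestamp, months: int) -> pd.Timestamp:
    """Shift ``date`` by ``months`` calendar months, clamping the day.

    Negative ``months`` shifts into the past. Uses pandas'
    ``DateOffset`` semantics: the day of month is preserved unless the
    target month is shorter, in which case it clamps to the last day.
    """
    ts = pd.Timestamp(date)
    if months >= 0:
        return ts + pd.DateOffset(months=months)
    return ts - pd.DateOffset(months=-months)


def parse_iso_dates(values: pd.Series, column: str) -> pd.Series:
    """Parse a string column of strict ISO-8601 ``YYYY-MM-DD`` dates.

    Mixed or non-ISO formats are rejected rather than guessed, so that
    files written by one locale cannot silently re-read as different
    dates in another.
    """
    strings = values.astype("string")
    mask = strings.notna() & ~strings.str.match(_ISO_DATE).fillna(False)
    if mask.any():
        bad = strings[mask].iloc[0]
        raise ValueError(
            f"column {column!r} must contain ISO-8601 YYYY-MM-DD dates; "
            f"got {bad!r}"
        )
    return pd.to_datetime(strings, format="%Y-%m-%d")
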