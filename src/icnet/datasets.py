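"""Packaged reference tables: the published grade-stratified contingency
counts and scale-score summary moments for the 454-student cohort.

Counts are shipped verbatim so the between-grade tests can be recomputed
without the (non-deposited) raw survey data. The ``st_sleep`` row is known
to be internally inconsistent (grade-3 counts sum to 131 against a grade
size of 121) and is excluded from exact reproduction checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compare import ContingencyTable

__all__ = [
    "load_table1_counts",
    "load_table1_summaries",
    "table1_contingency",
    "MODERATE_COUNTS",
    "INCONSISTENT_ITEMS",
]

#: Published moderate-severity headcounts out of 454 respondents.
MODERATE_COUNTS = {"moderate_depression": 54, "moderate_anxiety": 84}

#: Fixture rows whose printed counts are internally inconsistent.
INCONSISTENT_ITEMS = frozenset({"st_sleep"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("icnet.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_table1_counts() -> pd.DataFrame:
    """Grade x yes/no counts for every binary item (long format)."""
    return _read("table1_counts.csv")


def load_table1_summaries() -> pd.DataFrame:
    """Per-grade mean/SD/n of the PSS, GAD-7 and PHQ-9 totals."""
    return _read("table1_summaries.csv")


def table1_contingency(item: str) -> ContingencyTable:
    """Build the 4x2 contingency table for one published binary item."""
    counts = load_table1_counts()
    rows = counts[counts["item"] == item].sort_values("grade")
    if rows.empty:
        raise KeyError(f"no published counts for item {item!r}")
    return ContingencyTable(
        item=item,
        counts=rows[["yes", "no"]].to_numpy(),
        grades=tuple(int(g) for g in rows["grade"]),
    )
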