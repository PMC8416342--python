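"""Between-grade comparisons: chi-square homogeneity on binary items,
Kruskal-Wallis on ordinal attitude items, one-way ANOVA on scale totals.

Significance follows a Bonferroni scheme over the three content domains
(personal attitude, changed lifestyle, life dissatisfaction): main analyses
at alpha = 0.05/3 ~= 0.017 and the six pairwise grade contrasts at
alpha = 0.05/6 ~= 0.008. Chi-square tests use the Pearson statistic without
continuity correction (df = 3 designs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey import (
    ATTITUDE_COLUMNS,
    ONLINE_DIFFICULTY_COLUMNS,
    SPARE_TIME_COLUMNS,
    score_cohort,
)

__all__ = [
    "ALPHA_MAIN",
    "ALPHA_POSTHOC",
    "ContingencyTable",
    "PairwiseContrast",
    "ComparisonResult",
    "DegenerateTableError",
    "chi_square_homogeneity",
    "kruskal_wallis",
    "one_way_anova",
    "anova_from_summary",
    "row_percentage",
    "contingency_from_cohort",
    "compare_cohort",
]

ALPHA_MAIN = 0.05 / 3  # three content domains
ALPHA_POSTHOC = 0.05 / 6  # six pairwise grade contrasts


class DegenerateTableError(ValueError):
    """A contingency table with a zero marginal cannot be tested."""


@dataclass(frozen=True)
class ContingencyTable:
    """Grade x yes/no counts for one binary item."""

    item: str
    counts: np.ndarray  # shape (n_grades, 2)
    grades: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError(f"{self.item}: counts must be (grades, 2)")
        if counts.shape[0] != len(self.grades):
            raise ValueError(f"{self.item}: counts rows must match grades")
        if (counts < 0).any():
            raise ValueError(f"{self.item}: negative counts")
        if counts.sum() <= 0:
            raise DegenerateTableError(f"{self.item}: empty table")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PairwiseContrast:
    groups: tuple[int, int]
    statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    """One between-grade test: statistic, df, p, and Bonferroni flags."""

    item: str
    test: str  # "chi2", "kruskal", or "anova"
    statistic: float
    df: object  # int for chi2/KW, (int, int) for ANOVA
    p_value: float
    significant_main: bool
    posthoc: tuple[PairwiseContrast, ...] = field(default_factory=tuple)


def _result(item, test, stat, df, p, posthoc=()):
    return ComparisonResult(
        item=item,
        test=test,
        statistic=float(stat),
        df=df,
        p_value=float(p),
        significant_main=bool(p < ALPHA_MAIN),
        posthoc=tuple(posthoc),
    )


def chi_square_homogeneity(table: ContingencyTable,
                           posthoc: bool = False) -> ComparisonResult:
    """Pearson chi-square test of homogeneity, no continuity correction."""
    counts = table.counts
    if (table.row_totals == 0).any() or (table.column_totals == 0).any():
        raise DegenerateTableError(
            f"{table.item}: zero marginal makes expected counts undefined"
        )
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    contrasts = []
    if posthoc:
        for i, j in combinations(range(len(table.grades)), 2):
            sub = counts[[i, j]]
            if (sub.sum(axis=0) == 0).any():
                continue
            s2, p2, _, _ = stats.chi2_contingency(sub, correction=False)
            contrasts.append(PairwiseContrast(
                (table.grades[i], table.grades[j]), float(s2), float(p2),
                bool(p2 < ALPHA_POSTHOC)))
    return _result(table.item, "chi2", stat, int(df), p, contrasts)


def kruskal_wallis(groups: Sequence[Sequence[float]], item: str = "",
                   posthoc: bool = False) -> ComparisonResult:
    """Kruskal-Wallis H with tie correction; constant data gives H=0, p=1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(g) > 0 for g in groups) < 2:
        raise ValueError(f"{item}: need at least two non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return _result(item, "kruskal", 0.0, df, 1.0)
    stat, p = stats.kruskal(*groups)
    contrasts = []
    if posthoc:
        for i, j in combinations(range(len(groups)), 2):
            pair = np.concatenate([groups[i], groups[j]])
            if np.all(pair == pair[0]):
                contrasts.append(PairwiseContrast((i + 1, j + 1), 0.0, 1.0, False))
                continue
            s2, p2 = stats.kruskal(groups[i], groups[j])
            contrasts.append(PairwiseContrast((i + 1, j + 1), float(s2), float(p2),
                                              bool(p2 < ALPHA_POSTHOC)))
    return _result(item, "kruskal", stat, df, p, contrasts)


def one_way_anova(groups: Sequence[Sequence[float]], item: str = "",
                  posthoc: bool = False) -> ComparisonResult:
    """One-way fixed-effects ANOVA on raw data; F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError(f"{item}: each group needs n >= 2")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    msw = sum((len(g) - 1) * g.var(ddof=1) for g in groups) / (n_total - k)
    if msw == 0.0:
        means = [g.mean() for g in groups]
        if np.allclose(means, means[0]):
            raise ValueError(f"{item}: zero within-group variance and equal means; F undefined")
    stat, p = stats.f_oneway(*groups)
    contrasts = []
    if posthoc:
        for i, j in combinations(range(k), 2):
            s2, p2 = stats.f_oneway(groups[i], groups[j])
            contrasts.append(PairwiseContrast((i + 1, j + 1), float(s2), float(p2),
                                              bool(p2 < ALPHA_POSTHOC)))
    return _result(item, "anova", stat, (k - 1, n_total - k), p, contrasts)


def anova_from_summary(means: Sequence[float], sds: Sequence[float],
                       ns: Sequence[int]) -> float:
    """One-way ANOVA F from per-group summary moments (mean, SD, n).

    Algebraically identical to the raw-data F; used to check published
    statistics when only rounded summaries are available.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("need matching mean/SD/n for >=2 groups")
    k = len(means)
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ms_between = (ns * (means - grand) ** 2).sum() / (k - 1)
    ms_within = ((ns - 1) * sds ** 2).sum() / (n_total - k)
    if ms_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    return float(ms_between / ms_within)


def row_percentage(table: ContingencyTable,
                   grades: Sequence[int] | None = None) -> float:
    """Yes-percentage over a subset of grades, rounded to 1 decimal."""
    if grades is None:
        grades = table.grades
    grades = tuple(grades)
    if not grades:
        raise ValueError("empty grade subset")
    idx = [table.grades.index(g) for g in grades]
    sub = table.counts[idx]
    total = sub.sum()
    if total == 0:
        raise DegenerateTableError(f"{table.item}: no respondents in grades {grades}")
    return round(100.0 * sub[:, 0].sum() / total, 1)


def contingency_from_cohort(cohort: pd.DataFrame, item: str) -> ContingencyTable:
    """Tabulate a binary cohort column into grade x yes/no counts."""
    counts = []
    for g in (1, 2, 3, 4):
        col = cohort.loc[cohort["grade"] == g, item]
        counts.append((int((col == 1).sum()), int((col == 0).sum())))
    return ContingencyTable(item=item, counts=np.array(counts, dtype=float))


def compare_cohort(cohort: pd.DataFrame, posthoc: bool = True) -> pd.DataFrame:
    """Run the full between-grade comparison battery on a cohort.

    Binary items (dropout, spare-time, online difficulty, sex) get the
    chi-square test of homogeneity; the seven attitude items get
    Kruskal-Wallis; the three scale totals get one-way ANOVA. Returns a
    tidy frame with one row per item.
    """
    results: list[ComparisonResult] = []
    sex_tab = ContingencyTable(
        item="sex_men",
        counts=np.array([
            [int(((cohort["grade"] == g) & (cohort["sex"] == "men")).sum()),
             int(((cohort["grade"] == g) & (cohort["sex"] == "women")).sum())]
            for g in (1, 2, 3, 4)], dtype=float),
    )
    results.append(chi_square_homogeneity(sex_tab, posthoc=posthoc))
    binary_items = ("dropout",) + SPARE_TIME_COLUMNS + ONLINE_DIFFICULTY_COLUMNS
    for item in binary_items:
        results.append(chi_square_homogeneity(
            contingency_from_cohort(cohort, item), posthoc=posthoc))
    grade_groups = [cohort[cohort["grade"] == g] for g in (1, 2, 3, 4)]
    for item in ATTITUDE_COLUMNS:
        results.append(kruskal_wallis(
            [g[item].to_numpy() for g in grade_groups], item, posthoc=posthoc))
    scored = score_cohort(cohort)
    scored_groups = [scored[scored["grade"] == g] for g in (1, 2, 3, 4)]
    for item in ("pss_total", "gad7_total", "phq9_total"):
        results.append(one_way_anova(
            [g[item].to_numpy() for g in scored_groups], item, posthoc=posthoc))
    rows = []
    for r in results:
        rows.append({
            "item": r.item,
            "test": r.test,
            "statistic": r.statistic,
            "df": str(r.df),
            "p_value": r.p_value,
            "significant_main": r.significant_main,
            "significant_pairs": ";".join(
                f"{a}-{b}" for (a, b), s in
                ((c.groups, c.significant) for c in r.posthoc) if s),
        })
    return pd.DataFrame(rows)
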