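"""Coded data model for the 43-item survey and mental-health scale scoring.

The survey covers four medical-school grade cohorts and records, per
respondent: seven 5-point attitude items about the pandemic (coded -2..+2),
a binary school-dropout-intention item, the 10-item Perceived Stress Scale
(PSS, items 0..4), the 7-item Generalized Anxiety Disorder screener (GAD-7,
items 0..3), the 9-item Patient Health Questionnaire (PHQ-9, items 0..3),
six binary spare-time activity flags, and three binary online-class
difficulty flags — 43 analysis variables in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SurveyRecord",
    "ScaleDefinition",
    "ScoredScales",
    "PSS",
    "GAD7",
    "PHQ9",
    "SCALES",
    "ATTITUDE_COLUMNS",
    "PSS_COLUMNS",
    "GAD7_COLUMNS",
    "PHQ9_COLUMNS",
    "SPARE_TIME_COLUMNS",
    "SPARE_TIME_OPTIONS",
    "ONLINE_DIFFICULTY_COLUMNS",
    "ANALYSIS_COLUMNS",
    "COHORT_COLUMNS",
    "ITEM_LEVELS",
    "ValidationError",
    "score_items",
    "score_scale",
    "classify_moderate",
    "binarize_multichoice",
    "score_record",
    "score_cohort",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "validate_frame",
]


class ValidationError(ValueError):
    """A survey record or cohort file failed schema validation."""


ATTITUDE_COLUMNS = tuple(f"att{i}" for i in range(1, 8))
PSS_COLUMNS = tuple(f"pss{i}" for i in range(1, 11))
GAD7_COLUMNS = tuple(f"gad{i}" for i in range(1, 8))
PHQ9_COLUMNS = tuple(f"phq{i}" for i in range(1, 10))
SPARE_TIME_OPTIONS = ("sleep", "game", "read", "study", "exercise", "friends")
SPARE_TIME_COLUMNS = tuple(f"st_{o}" for o in SPARE_TIME_OPTIONS)
ONLINE_DIFFICULTY_COLUMNS = ("od_routine", "od_interact", "od_social")

#: The 43 analysis variables, in canonical column order.
ANALYSIS_COLUMNS = (
    ATTITUDE_COLUMNS
    + ("dropout",)
    + PSS_COLUMNS
    + GAD7_COLUMNS
    + PHQ9_COLUMNS
    + SPARE_TIME_COLUMNS
    + ONLINE_DIFFICULTY_COLUMNS
)

COHORT_COLUMNS = ("id", "grade", "sex") + ANALYSIS_COLUMNS

#: Inclusive (low, high) coding range per analysis column.
ITEM_RANGES: dict[str, tuple[int, int]] = {}
ITEM_RANGES.update({c: (-2, 2) for c in ATTITUDE_COLUMNS})
ITEM_RANGES["dropout"] = (0, 1)
ITEM_RANGES.update({c: (0, 4) for c in PSS_COLUMNS})
ITEM_RANGES.update({c: (0, 3) for c in GAD7_COLUMNS})
ITEM_RANGES.update({c: (0, 3) for c in PHQ9_COLUMNS})
ITEM_RANGES.update({c: (0, 1) for c in SPARE_TIME_COLUMNS})
ITEM_RANGES.update({c: (0, 1) for c in ONLINE_DIFFICULTY_COLUMNS})

#: Number of categorical levels per analysis column (for discrete modelling).
ITEM_LEVELS = {c: hi - lo + 1 for c, (lo, hi) in ITEM_RANGES.items()}


@dataclass(frozen=True)
class ScaleDefinition:
    """Scoring rule for one named mental-health scale.

    ``reverse_items`` holds 1-based indices of reverse-scored items: a
    reverse item with raw response ``r`` contributes ``max - r`` to the
    total. ``moderate_cutoff`` is the total at or above which the
    "moderate" flag applies; ``None`` for scales without a published
    dichotomisation (PSS).
    """

    name: str
    item_count: int
    response_range: tuple[int, int]
    reverse_items: frozenset[int] = field(default_factory=frozenset)
    moderate_cutoff: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.response_range
        if not all(1 <= i <= self.item_count for i in self.reverse_items):
            raise ValueError(f"{self.name}: reverse items outside 1..{self.item_count}")
        if self.moderate_cutoff is not None:
            if not 0 <= self.moderate_cutoff <= self.item_count * (hi - lo):
                raise ValueError(f"{self.name}: cutoff outside achievable totals")

    @property
    def total_range(self) -> tuple[int, int]:
        lo, hi = self.response_range
        span = hi - lo
        return (0, self.item_count * span) if lo == 0 else (self.item_count * lo, self.item_count * hi)


# PSS-10 standard scoring: the four positively stated items (4, 5, 7, 8)
# are reverse-coded; no dichotomisation cutoff is used.
PSS = ScaleDefinition("PSS", 10, (0, 4), frozenset({4, 5, 7, 8}))
GAD7 = ScaleDefinition("GAD7", 7, (0, 3), frozenset(), moderate_cutoff=10)
PHQ9 = ScaleDefinition("PHQ9", 9, (0, 3), frozenset(), moderate_cutoff=10)
SCALES = {"PSS": PSS, "GAD7": GAD7, "PHQ9": PHQ9}

_SCALE_FIELDS = {"PSS": "pss", "GAD7": "gad7", "PHQ9": "phq9"}


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent's grade, sex, and 43 coded analysis responses."""

    respondent_id: str
    grade: int
    sex: str
    attitude: tuple[int, ...]
    dropout_intention: int
    pss: tuple[int, ...]
    gad7: tuple[int, ...]
    phq9: tuple[int, ...]
    spare_time: tuple[int, ...]
    online_difficulty: tuple[int, ...]

    def validate(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValidationError(f"{self.respondent_id}: grade {self.grade} not in 1..4")
        if self.sex not in ("men", "women"):
            raise ValidationError(f"{self.respondent_id}: sex must be 'men' or 'women'")
        for name, value in zip(ANALYSIS_COLUMNS, self.analysis_values()):
            lo, hi = ITEM_RANGES[name]
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{self.respondent_id}: item {name} not an integer")
            if not lo <= value <= hi:
                raise ValidationError(
                    f"{self.respondent_id}: item {name}={value} outside [{lo}, {hi}]"
                )

    def analysis_values(self) -> tuple[int, ...]:
        return (
            tuple(self.attitude)
            + (self.dropout_intention,)
            + tuple(self.pss)
            + tuple(self.gad7)
            + tuple(self.phq9)
            + tuple(self.spare_time)
            + tuple(self.online_difficulty)
        )


@dataclass(frozen=True)
class ScoredScales:
    """Scale totals and moderate-severity flags for one respondent."""

    pss_total: int
    gad7_total: int
    phq9_total: int
    moderate_depression: bool
    moderate_anxiety: bool


def score_items(responses: Sequence[int], scale: ScaleDefinition,
                respondent_id: str = "?") -> int:
    """Total a scale from raw item responses, reverse-coding where defined."""
    if len(responses) != scale.item_count:
        raise ValidationError(
            f"{respondent_id}: {scale.name} expects {scale.item_count} items, "
            f"got {len(responses)}"
        )
    lo, hi = scale.response_range
    total = 0
    for idx, raw in enumerate(responses, start=1):
        if raw is None or not lo <= raw <= hi:
            raise ValidationError(
                f"{respondent_id}: {scale.name} item {idx}={raw} outside [{lo}, {hi}]"
            )
        total += (hi - raw) if idx in scale.reverse_items else raw
    return total


def score_scale(record: SurveyRecord, scale: ScaleDefinition) -> int:
    """Score one named scale for a survey record."""
    responses = getattr(record, _SCALE_FIELDS[scale.name])
    return score_items(responses, scale, record.respondent_id)


def classify_moderate(total: int, scale: ScaleDefinition) -> bool:
    """Flag a total at or above the scale's moderate-severity cutoff."""
    if scale.moderate_cutoff is None:
        raise ValueError(f"{scale.name} has no moderate-severity cutoff")
    lo, hi = scale.total_range
    if not lo <= total <= hi:
        raise ValidationError(f"{scale.name} total {total} outside [{lo}, {hi}]")
    return total >= scale.moderate_cutoff


def binarize_multichoice(selected: Iterable[str],
                         option_universe: Sequence[str]) -> tuple[int, ...]:
    """Turn a multiple-choice answer set into per-option binary flags."""
    chosen = set(selected)
    unknown = chosen - set(option_universe)
    if unknown:
        raise ValidationError(f"unknown options: {sorted(unknown)}")
    return tuple(int(o in chosen) for o in option_universe)


def score_record(record: SurveyRecord) -> ScoredScales:
    pss = score_scale(record, PSS)
    gad = score_scale(record, GAD7)
    phq = score_scale(record, PHQ9)
    return ScoredScales(
        pss_total=pss,
        gad7_total=gad,
        phq9_total=phq,
        moderate_depression=classify_moderate(phq, PHQ9),
        moderate_anxiety=classify_moderate(gad, GAD7),
    )


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score all three scales for a cohort frame.

    Returns a frame indexed like ``cohort`` with columns id, grade,
    pss_total, gad7_total, phq9_total, moderate_depression,
    moderate_anxiety.
    """
    pss_raw = cohort[list(PSS_COLUMNS)].to_numpy()
    hi = PSS.response_range[1]
    rev = [i - 1 for i in sorted(PSS.reverse_items)]
    pss_scored = pss_raw.copy()
    pss_scored[:, rev] = hi - pss_scored[:, rev]
    out = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "grade": cohort["grade"].to_numpy(),
            "pss_total": pss_scored.sum(axis=1),
            "gad7_total": cohort[list(GAD7_COLUMNS)].sum(axis=1).to_numpy(),
            "phq9_total": cohort[list(PHQ9_COLUMNS)].sum(axis=1).to_numpy(),
        },
        index=cohort.index,
    )
    out["moderate_depression"] = out["phq9_total"] >= PHQ9.moderate_cutoff
    out["moderate_anxiety"] = out["gad7_total"] >= GAD7.moderate_cutoff
    return out


# ---------------------------------------------------------------------------
# Cohort I/O

def validate_frame(frame: pd.DataFrame) -> None:
    """Validate a cohort frame; raises with row numbers on failure."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    dup = frame["id"][frame["id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated respondent ids: {sorted(set(dup))}")
    problems: list[str] = []
    if frame[list(ANALYSIS_COLUMNS) + ["grade"]].isna().any().any():
        for row, rec in frame.iterrows():
            bad = [c for c in ANALYSIS_COLUMNS if pd.isna(rec[c])]
            if bad:
                problems.append(f"row {row}: missing {bad}")
    grade_bad = ~frame["grade"].isin([1, 2, 3, 4])
    for row in frame.index[grade_bad]:
        problems.append(f"row {row}: grade {frame.loc[row, 'grade']} not in 1..4")
    for col in ANALYSIS_COLUMNS:
        lo, hi = ITEM_RANGES[col]
        bad = ~frame[col].between(lo, hi)
        for row in frame.index[bad]:
            problems.append(f"row {row}: item {col}={frame.loc[row, col]} outside [{lo}, {hi}]")
    if problems:
        raise ValidationError("; ".join(problems[:20]))


def frame_to_records(frame: pd.DataFrame) -> list[SurveyRecord]:
    records = []
    for _, r in frame.iterrows():
        rec = SurveyRecord(
            respondent_id=str(r["id"]),
            grade=int(r["grade"]),
            sex=str(r["sex"]),
            attitude=tuple(int(r[c]) for c in ATTITUDE_COLUMNS),
            dropout_intention=int(r["dropout"]),
            pss=tuple(int(r[c]) for c in PSS_COLUMNS),
            gad7=tuple(int(r[c]) for c in GAD7_COLUMNS),
            phq9=tuple(int(r[c]) for c in PHQ9_COLUMNS),
            spare_time=tuple(int(r[c]) for c in SPARE_TIME_COLUMNS),
            online_difficulty=tuple(int(r[c]) for c in ONLINE_DIFFICULTY_COLUMNS),
        )
        rec.validate()
        records.append(rec)
    return records


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"id": rec.respondent_id, "grade": rec.grade, "sex": rec.sex}
        row.update(dict(zip(ANALYSIS_COLUMNS, rec.analysis_values())))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def read_cohort(path) -> list[SurveyRecord]:
    """Read a cohort CSV into validated records.

    Validation failures are reported with 1-based data row numbers.
    """
    frame = pd.read_csv(path)
    frame.index = frame.index + 1  # header is line 1; data rows 1-based
    validate_frame(frame)
    return frame_to_records(frame)


def write_cohort(records: Sequence[SurveyRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
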