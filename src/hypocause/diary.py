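"""Domain types and CSV I/O for type 1 diabetes self-care diaries.

A *diary* is one subject's timestamped self-care record: self-monitored blood
glucose (SMBG) readings in mmol/L, quick-acting (QA, bolus) and basal insulin
doses, carbohydrate intakes, bolus-advisor records, carbohydrate-quiz
engagement events, plus static demographics — together with the subject's
labeled hypoglycemia episodes (SMBG < 4 mmol/L, a free-text reason and a
self-reported confidence 1–5).

Reasons are grouped into three analyzable cause categories — physical
ACTIVITY, FOOD-intake mistakes and MEDICATION-dosage mistakes — plus the
non-analyzed buckets OTHER and UNKNOWN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Category",
    "InsulinKind",
    "SubjectProfile",
    "GlucoseReading",
    "InsulinDose",
    "CarbIntake",
    "AdvisorRecord",
    "QuizAnswer",
    "HypoEpisode",
    "Diary",
    "DiarySchemaError",
    "DuplicateRecordError",
    "ReasonMappingError",
    "DEFAULT_REASON_MAPPING",
    "HYPO_THRESHOLD_MMOL_L",
    "read_diary_tables",
    "write_diary_tables",
    "filter_label_episodes",
    "map_reason_to_category",
]

#: Working definition of hypoglycemia: SMBG strictly below 4 mmol/L.
HYPO_THRESHOLD_MMOL_L = 4.0


class Category(str, enum.Enum):
    """Hypoglycemia cause category."""

    ACTIVITY = "ACTIVITY"
    FOOD = "FOOD"
    MEDICATION = "MEDICATION"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


#: The three categories retained for statistical and classification analysis.
ANALYSIS_CATEGORIES = (Category.ACTIVITY, Category.FOOD, Category.MEDICATION)


class InsulinKind(str, enum.Enum):
    QA = "QA"  # quick-acting (bolus)
    BASAL = "BASAL"  # long-acting background


class DiarySchemaError(ValueError):
    """A diary CSV file does not conform to the expected schema."""


class DuplicateRecordError(ValueError):
    """Two records share a primary key that must be unique."""


class ReasonMappingError(KeyError):
    """A raw reason label has no category mapping and no default is set."""


@dataclass(frozen=True)
class SubjectProfile:
    """Static demographics. Gender coding: female=0, male=1 (configurable
    upstream; only the coding direction of the fitted coefficient changes)."""

    subject_id: str
    age: float
    gender: int
    years_with_diabetes: float

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not (0 <= self.years_with_diabetes <= self.age):
            raise ValueError(
                "years_with_diabetes must lie in [0, age], got "
                f"{self.years_with_diabetes} with age {self.age}"
            )
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")


@dataclass(frozen=True, order=True)
class GlucoseReading:
    timestamp: datetime
    value: float  # mmol/L

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"glucose value must be positive, got {self.value}")


@dataclass(frozen=True, order=True)
class InsulinDose:
    timestamp: datetime
    units: float
    kind: InsulinKind = field(compare=False)

    def __post_init__(self) -> None:
        if self.units < 0:
            raise ValueError(f"insulin units must be >= 0, got {self.units}")


@dataclass(frozen=True, order=True)
class CarbIntake:
    timestamp: datetime
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError(f"carb grams must be >= 0, got {self.grams}")


@dataclass(frozen=True, order=True)
class AdvisorRecord:
    """One bolus-advisor interaction. Any numeric field may be ``None``
    (missing); ``total_ins`` is the total advised dose, ``logged_intake`` the
    dose the user actually logged."""

    timestamp: datetime
    food_ins: float | None = field(default=None, compare=False)
    corr_ins: float | None = field(default=None, compare=False)
    total_ins: float | None = field(default=None, compare=False)
    logged_intake: float | None = field(default=None, compare=False)
    iob: float | None = field(default=None, compare=False)
    allowed_bgv: float | None = field(default=None, compare=False)
    carb_cu: float | None = field(default=None, compare=False)
    meal_rise: float | None = field(default=None, compare=False)
    exercise_tag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.total_ins is not None and self.total_ins < 0:
            raise ValueError(f"total_ins must be >= 0, got {self.total_ins}")


@dataclass(frozen=True, order=True)
class QuizAnswer:
    timestamp: datetime
    points: int = field(compare=False)
    session_id: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError(f"quiz points must be >= 0, got {self.points}")


@dataclass(frozen=True, order=True)
class HypoEpisode:
    """A labeled hypoglycemia event (single-label: the first, highest-
    confidence reason is stored)."""

    timestamp: datetime
    subject_id: str = field(compare=False)
    smbg_value: float = field(compare=False)
    raw_reason: str = field(compare=False)
    confidence: int = field(compare=False)
    category: Category = field(compare=False)

    def __post_init__(self) -> None:
        if not self.smbg_value < HYPO_THRESHOLD_MMOL_L:
            raise ValueError(
                f"episode SMBG must be < {HYPO_THRESHOLD_MMOL_L} mmol/L, "
                f"got {self.smbg_value}"
            )
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence must be in 1..5, got {self.confidence}")


@dataclass
class Diary:
    """One subject's complete record; all collections kept time-sorted."""

    profile: SubjectProfile
    readings: list[GlucoseReading] = field(default_factory=list)
    qa_doses: list[InsulinDose] = field(default_factory=list)
    basal_doses: list[InsulinDose] = field(default_factory=list)
    carbs: list[CarbIntake] = field(default_factory=list)
    advisor_records: list[AdvisorRecord] = field(default_factory=list)
    quiz_answers: list[QuizAnswer] = field(default_factory=list)
    episodes: list[HypoEpisode] = field(default_factory=list)

    @property
    def subject_id(self) -> str:
        return self.profile.subject_id

    def sort(self) -> "Diary":
        for coll in (
            self.readings,
            self.qa_doses,
            self.basal_doses,
            self.carbs,
            self.advisor_records,
            self.quiz_answers,
            self.episodes,
        ):
            coll.sort(key=lambda r: r.timestamp)
        return self


# ---------------------------------------------------------------------------
# Reason → category mapping
# ---------------------------------------------------------------------------

#: Default mapping of raw reason labels to cause categories. The raw
#: vocabulary is configurable; these families cover exercise/activity,
#: carbohydrate-counting/food mistakes, and insulin-dosing mistakes, plus the
#: two non-analyzed buckets.
DEFAULT_REASON_MAPPING: dict[str, Category] = {
    "exercise or physical activity": Category.ACTIVITY,
    "unplanned physical activity": Category.ACTIVITY,
    "more active than usual": Category.ACTIVITY,
    "carbohydrate miscount": Category.FOOD,
    "overestimated carbohydrates": Category.FOOD,
    "delayed or missed meal": Category.FOOD,
    "less food than usual": Category.FOOD,
    "too much quick-acting insulin": Category.MEDICATION,
    "too much basal insulin": Category.MEDICATION,
    "insulin timing mistake": Category.MEDICATION,
    "alcohol": Category.OTHER,
    "other": Category.OTHER,
    "don't know": Category.UNKNOWN,
}


def map_reason_to_category(
    raw_reason: str,
    mapping: Mapping[str, Category] | None = None,
    default: Category | None = None,
) -> Category:
    """Map a raw reason label to a cause category.

    Matching is case-insensitive on the stripped label. An unmapped label
    falls back to ``default``; with no default a :class:`ReasonMappingError`
    naming the label is raised.
    """
    table = DEFAULT_REASON_MAPPING if mapping is None else mapping
    key = raw_reason.strip().lower()
    normalized = {k.strip().lower(): v for k, v in table.items()}
    if key in normalized:
        return normalized[key]
    if default is not None:
        return default
    raise ReasonMappingError(f"no category mapping for reason label {raw_reason!r}")


def filter_label_episodes(
    episodes: Iterable[HypoEpisode], min_confidence: int = 4
) -> list[HypoEpisode]:
    """Keep episodes usable for analysis: confidence >= ``min_confidence``
    and category one of ACTIVITY/FOOD/MEDICATION. Order is preserved."""
    return [
        e
        for e in episodes
        if e.confidence >= min_confidence and e.category in ANALYSIS_CATEGORIES
    ]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TS_FMT = "%Y-%m-%dT%H:%M:%S"

#: filename -> ordered columns
CSV_SCHEMAS: dict[str, list[str]] = {
    "subjects.csv": ["subject_id", "age", "gender", "years_with_diabetes"],
    "glucose.csv": ["subject_id", "timestamp", "value_mmol_l"],
    "insulin.csv": ["subject_id", "timestamp", "units", "kind"],
    "carbs.csv": ["subject_id", "timestamp", "grams"],
    "advisor.csv": [
        "subject_id",
        "timestamp",
        "food_ins",
        "corr_ins",
        "total_ins",
        "logged_intake",
        "iob",
        "allowed_bgv",
        "carb_cu",
        "meal_rise",
        "exercise_tag",
    ],
    "quiz.csv": ["subject_id", "timestamp", "points", "session_id"],
    "episodes.csv": [
        "subject_id",
        "timestamp",
        "smbg_value",
        "raw_reason",
        "confidence",
        "category",
    ],
}


def _parse_ts(value: str, file: str, row: int) -> datetime:
    try:
        return datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise DiarySchemaError(
            f"{file} row {row}: unparseable timestamp {value!r}"
        ) from exc


def _parse_float(value, file: str, row: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise DiarySchemaError(
            f"{file} row {row}: column {column!r} value {value!r} is not numeric"
        ) from exc


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _load(path: Path, name: str) -> pd.DataFrame:
    file = path / name
    if not file.exists():
        raise FileNotFoundError(f"required diary table missing: {file}")
    df = pd.read_csv(
        file, dtype={"subject_id": str}, keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in CSV_SCHEMAS[name] if c not in df.columns]
    if missing:
        raise DiarySchemaError(f"{name}: missing required column(s) {missing}")
    return df


def read_diary_tables(dir_path: str | Path) -> dict[str, Diary]:
    """Read the seven diary CSV tables from ``dir_path`` into one
    :class:`Diary` per subject, all collections time-sorted.

    Raises :class:`DiarySchemaError` for malformed files (never skips them
    silently) and :class:`DuplicateRecordError` for duplicated subject rows.
    """
    path = Path(dir_path)
    subjects = _load(path, "subjects.csv")
    if subjects["subject_id"].duplicated().any():
        dupes = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"]
        raise DuplicateRecordError(f"duplicated subject rows: {sorted(set(dupes))}")

    diaries: dict[str, Diary] = {}
    for _, row in subjects.iterrows():
        profile = SubjectProfile(
            subject_id=str(row["subject_id"]),
            age=_parse_float(row["age"], "subjects.csv", 0, "age"),
            gender=int(row["gender"]),
            years_with_diabetes=float(row["years_with_diabetes"]),
        )
        diaries[profile.subject_id] = Diary(profile=profile)

    def rows(name: str):
        df = _load(path, name)
        for i, row in enumerate(df.itertuples(index=False), start=1):
            sid = str(row.subject_id)
            if sid not in diaries:
                raise DiarySchemaError(
                    f"{name} row {i}: unknown subject_id {sid!r}"
                )
            yield i, sid, row

    for i, sid, row in rows("glucose.csv"):
        diaries[sid].readings.append(
            GlucoseReading(
                timestamp=_parse_ts(row.timestamp, "glucose.csv", i),
                value=_parse_float(row.value_mmol_l, "glucose.csv", i, "value_mmol_l"),
            )
        )
    for i, sid, row in rows("insulin.csv"):
        dose = InsulinDose(
            timestamp=_parse_ts(row.timestamp, "insulin.csv", i),
            units=_parse_float(row.units, "insulin.csv", i, "units"),
            kind=InsulinKind(str(row.kind)),
        )
        (diaries[sid].qa_doses if dose.kind is InsulinKind.QA else diaries[sid].basal_doses).append(dose)
    for i, sid, row in rows("carbs.csv"):
        diaries[sid].carbs.append(
            CarbIntake(
                timestamp=_parse_ts(row.timestamp, "carbs.csv", i),
                grams=_parse_float(row.grams, "carbs.csv", i, "grams"),
            )
        )
    for i, sid, row in rows("advisor.csv"):
        diaries[sid].advisor_records.append(
            AdvisorRecord(
                timestamp=_parse_ts(row.timestamp, "advisor.csv", i),
                food_ins=_opt_float(row.food_ins),
                corr_ins=_opt_float(row.corr_ins),
                total_ins=_opt_float(row.total_ins),
                logged_intake=_opt_float(row.logged_intake),
                iob=_opt_float(row.iob),
                allowed_bgv=_opt_float(row.allowed_bgv),
                carb_cu=_opt_float(row.carb_cu),
                meal_rise=_opt_float(row.meal_rise),
                exercise_tag=bool(int(row.exercise_tag)),
            )
        )
    for i, sid, row in rows("quiz.csv"):
        diaries[sid].quiz_answers.append(
            QuizAnswer(
                timestamp=_parse_ts(row.timestamp, "quiz.csv", i),
                points=int(row.points),
                session_id=str(row.session_id),
            )
        )
    for i, sid, row in rows("episodes.csv"):
        diaries[sid].episodes.append(
            HypoEpisode(
                timestamp=_parse_ts(row.timestamp, "episodes.csv", i),
                subject_id=sid,
                smbg_value=_parse_float(row.smbg_value, "episodes.csv", i, "smbg_value"),
                raw_reason=str(row.raw_reason),
                confidence=int(row.confidence),
                category=Category(str(row.category)),
            )
        )

    for diary in diaries.values():
        diary.sort()
    return diaries


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, datetime):
        return v.strftime(_TS_FMT)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_diary_tables(diaries: Mapping[str, Diary] | Sequence[Diary], dir_path: str | Path) -> list[Path]:
    """Write diaries as the seven CSV tables (stable column order, ISO-8601
    timestamps, empty field = missing). Returns the written paths."""
    if isinstance(diaries, Mapping):
        diaries = list(diaries.values())
    path = Path(dir_path)
    path.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[list[str]]] = {name: [] for name in CSV_SCHEMAS}
    for d in diaries:
        sid = d.subject_id
        p = d.profile
        tables["subjects.csv"].append([sid, _fmt(p.age), _fmt(p.gender), _fmt(p.years_with_diabetes)])
        for r in d.readings:
            tables["glucose.csv"].append([sid, _fmt(r.timestamp), _fmt(r.value)])
        for dose in sorted(d.qa_doses + d.basal_doses, key=lambda x: x.timestamp):
            tables["insulin.csv"].append([sid, _fmt(dose.timestamp), _fmt(dose.units), dose.kind.value])
        for c in d.carbs:
            tables["carbs.csv"].append([sid, _fmt(c.timestamp), _fmt(c.grams)])
        for a in d.advisor_records:
            tables["advisor.csv"].append(
                [sid, _fmt(a.timestamp)]
                + [_fmt(x) for x in (a.food_ins, a.corr_ins, a.total_ins, a.logged_intake, a.iob, a.allowed_bgv, a.carb_cu, a.meal_rise)]
                + [_fmt(a.exercise_tag)]
            )
        for q in d.quiz_answers:
            tables["quiz.csv"].append([sid, _fmt(q.timestamp), _fmt(q.points), q.session_id])
        for e in d.episodes:
            tables["episodes.csv"].append(
                [sid, _fmt(e.timestamp), _fmt(e.smbg_value), e.raw_reason, _fmt(e.confidence), e.category.value]
            )

    written = []
    for name, cols in CSV_SCHEMAS.items():
        file = path / name
        with open(file, "w", newline="") as fh:
            fh.write(",".join(cols) + "\n")
            for row in tables[name]:
                fh.write(",".join(row) + "\n")
        written.append(file)
    return written
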