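"""The BEST diary instrument: item definitions, scoring and diary I/O.

The BEST (Bronchiectasis Exacerbation and Symptom Tool) is a six-item daily
diary covering breathlessness (MRC dyspnoea scale), fatigue, sputum volume,
sputum colour (Murray scale plus haemoptysis), cough and cold/flu symptoms.
Each item is an ordinal scale; the daily total ranges 0-26, higher meaning
worse symptoms.
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ItemDefinition",
    "ITEMS",
    "ITEM_NAMES",
    "MAX_TOTAL",
    "DiaryEntry",
    "PatientDiary",
    "DiaryValidationError",
    "DiaryFormatError",
    "score_entry",
    "validate_entry",
    "ml_to_volume_category",
    "read_diary_csv",
    "write_diary_csv",
    "read_anchors_csv",
    "write_anchors_csv",
    "DIARY_COLUMNS",
    "ANCHOR_COLUMNS",
]


@dataclass(frozen=True)
class ItemDefinition:
    """One diary item: its permitted ordinal levels and their wording."""

    name: str
    allowed_levels: frozenset[int]
    level_labels: dict[int, str] = field(default_factory=dict)

    @property
    def max_level(self) -> int:
        return max(self.allowed_levels)


ITEMS: tuple[ItemDefinition, ...] = (
    ItemDefinition(
        "breathlessness",
        frozenset({0, 1, 2, 3, 4}),
        {
            0: "None",
            1: "Breathlessness when hurrying or walking up a slight hill",
            2: "Have to walk slowly on level ground or stop for breath",
            3: "Can walk less than 100 m before having to stop",
            4: "Breathless when washing or dressing",
        },
    ),
    ItemDefinition(
        "fatigue",
        frozenset({0, 1, 2, 3, 4}),
        {
            0: "I do not feel tired",
            1: "I feel a little tired",
            2: "I feel tired but can still do the things I would like to do",
            3: "Tiredness is stopping me from doing some things I want to do",
            4: "I am so tired I am unable to carry out my usual daily activities",
        },
    ),
    ItemDefinition(
        "sputum_volume",
        frozenset({0, 1, 2, 3, 4}),
        {
            0: "No sputum",
            1: "Less than a teaspoon",
            2: "Teaspoon to an eggcup",
            3: "Egg-cup to a cup",
            4: "More than a cup",
        },
    ),
    ItemDefinition(
        "sputum_colour",
        frozenset({0, 1, 2, 3, 4, 5}),
        {
            0: "No sputum",
            1: "White",
            2: "Yellow",
            3: "Green",
            4: "Dark Green",
            5: "Blood stained",
        },
    ),
    ItemDefinition(
        "cough",
        frozenset({0, 1, 2, 3, 4}),
        {0: "None", 1: "Mild", 2: "Moderate", 3: "Severe", 4: "Very severe"},
    ),
    # Levels 3 and 4 are not defined on the card (printed blank) and are
    # rejected unless lenient handling is requested.
    ItemDefinition(
        "cold_flu",
        frozenset({0, 1, 2, 5}),
        {
            0: "None",
            1: "Sore throat, sore muscles, or runny nose",
            2: "Fever/high temperature or shivers",
            5: "I feel like I have an infection",
        },
    ),
)

ITEM_NAMES: tuple[str, ...] = tuple(item.name for item in ITEMS)
ITEM_BY_NAME: dict[str, ItemDefinition] = {item.name: item for item in ITEMS}

#: Maximum daily total (sum of per-item maxima).
MAX_TOTAL: int = sum(item.max_level for item in ITEMS)
assert MAX_TOTAL == 26

# Sputum volume equivalences, in millilitres, as explained to patients.
TEASPOON_ML = 5.0
TABLESPOON_ML = 15.0
EGGCUP_ML = 45.0
CUP_ML = 250.0

DIARY_COLUMNS = [
    "patient_id",
    "date",
    "breathlessness",
    "fatigue",
    "sputum_volume",
    "sputum_colour",
    "cough",
    "cold_flu",
    "reported_flag",
    "antibiotic_start",
]

ANCHOR_COLUMNS = [
    "patient_id",
    "visit",
    "sgrq_total",
    "sgrq_symptom",
    "cat",
    "lcq",
    "six_mwt_m",
]

ANCHOR_VISITS = {"baseline", "exac_start", "exac_end", "end_of_study"}


class DiaryValidationError(ValueError):
    """A diary record violated the instrument's definition.

    ``errors`` carries the complete list of violations, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


class DiaryFormatError(ValueError):
    """A diary or anchor file could not be parsed."""


@dataclass(frozen=True, order=True)
class DiaryEntry:
    """One patient-day of the diary."""

    patient_id: str
    day: dt.date
    breathlessness: int
    fatigue: int
    sputum_volume: int
    sputum_colour: int
    cough: int
    cold_flu: int
    reported_flag: bool = False
    antibiotic_start: bool = False

    def item_scores(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in ITEM_NAMES)

    @property
    def total(self) -> int:
        return sum(self.item_scores())


def score_entry(entry: DiaryEntry) -> int:
    """Daily BEST total: the sum of the six item scores (0-26)."""
    for item in ITEMS:
        value = getattr(entry, item.name)
        if value not in item.allowed_levels:
            raise DiaryValidationError(
                [
                    f"{item.name} level {value} not defined "
                    f"(allowed: {sorted(item.allowed_levels)})"
                ]
            )
    return entry.total


def _parse_int(value, name: str, errors: list[str]) -> int | None:
    if isinstance(value, bool):
        errors.append(f"{name} must be an integer score, got boolean")
        return None
    if isinstance(value, int):
        return value
    if isinstance(value, float):
        if value.is_integer():
            return int(value)
        errors.append(f"{name} must be an integer score, got {value!r}")
        return None
    try:
        text = str(value).strip()
        if text == "":
            errors.append(f"{name} is missing")
            return None
        as_float = float(text)
    except (TypeError, ValueError):
        errors.append(f"{name} must be an integer score, got {value!r}")
        return None
    if not as_float.is_integer():
        errors.append(f"{name} must be an integer score, got {value!r}")
        return None
    return int(as_float)


def _parse_flag(value, name: str, errors: list[str]) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"", "0", "false", "no"}:
        return False
    if text in {"1", "true", "yes"}:
        return True
    errors.append(f"{name} must be a 0/1 flag, got {value!r}")
    return False


def _parse_date(value, errors: list[str]) -> dt.date | None:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        errors.append(f"date {value!r} is not an ISO-8601 calendar date")
        return None


def validate_entry(record, *, lenient_coldflu: bool = False) -> DiaryEntry:
    """Validate a raw mapping into a :class:`DiaryEntry`.

    Collects the complete list of violations before raising
    :class:`DiaryValidationError`. With ``lenient_coldflu`` the undefined
    cold/flu levels 3 and 4 are mapped to 2 with a warning instead of being
    rejected.
    """
    errors: list[str] = []
    patient_id = str(record.get("patient_id", "")).strip()
    if not patient_id:
        errors.append("patient_id is missing")
    day = _parse_date(record.get("date", record.get("day", "")), errors)

    scores: dict[str, int] = {}
    for item in ITEMS:
        if item.name not in record or record.get(item.name) in ("", None):
            errors.append(f"{item.name} is missing")
            continue
        value = _parse_int(record[item.name], item.name, errors)
        if value is None:
            continue
        if value not in item.allowed_levels:
            if item.name == "cold_flu" and lenient_coldflu and value in (3, 4):
                warnings.warn(
                    f"cold_flu level {value} is not defined on the card; "
                    "mapping to 2 (lenient mode)",
                    stacklevel=2,
                )
                value = 2
            else:
                errors.append(
                    f"{item.name} level {value} not defined "
                    f"(allowed: {sorted(item.allowed_levels)})"
                )
                continue
        scores[item.name] = value

    reported = _parse_flag(record.get("reported_flag", False), "reported_flag", errors)
    abx = _parse_flag(
        record.get("antibiotic_start", False), "antibiotic_start", errors
    )
    if abx and not reported:
        # Treatment is commenced by the study team after patient contact.
        errors.append("antibiotic_start requires reported_flag on the same day")

    if errors:
        raise DiaryValidationError(errors)
    assert day is not None
    return DiaryEntry(
        patient_id=patient_id,
        day=day,
        reported_flag=reported,
        antibiotic_start=abx,
        **scores,
    )


def ml_to_volume_category(volume_ml: float) -> int:
    """Map a 24-h sputum volume in millilitres to the 0-4 diary category.

    Boundaries are lower-inclusive to the higher category: exactly one
    teaspoon (5 ml) is already "teaspoon to an eggcup".
    """
    if volume_ml < 0:
        raise ValueError(f"sputum volume must be non-negative, got {volume_ml}")
    if volume_ml == 0:
        return 0
    if volume_ml < TEASPOON_ML:
        return 1
    if volume_ml < EGGCUP_ML:
        return 2
    if volume_ml < CUP_ML:
        return 3
    return 4


@dataclass
class PatientDiary:
    """A date-ordered diary for one patient.

    ``gaps`` lists the calendar dates between the first and last entry with
    no record (missed diary days).
    """

    patient_id: str
    entries: list[DiaryEntry]
    gaps: list[dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.day)
        seen: set[dt.date] = set()
        for entry in self.entries:
            if entry.patient_id != self.patient_id:
                raise DiaryValidationError(
                    [f"entry for {entry.patient_id} in diary of {self.patient_id}"]
                )
            if entry.day in seen:
                raise DiaryValidationError(
                    [f"duplicate record for {self.patient_id} on {entry.day}"]
                )
            seen.add(entry.day)
        self.gaps = self._compute_gaps()

    def _compute_gaps(self) -> list[dt.date]:
        if len(self.entries) < 2:
            return []
        observed = {e.day for e in self.entries}
        first, last = self.entries[0].day, self.entries[-1].day
        return [
            first + dt.timedelta(days=i)
            for i in range(1, (last - first).days)
            if first + dt.timedelta(days=i) not in observed
        ]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def start(self) -> dt.date:
        return self.entries[0].day

    @property
    def end(self) -> dt.date:
        return self.entries[-1].day

    @property
    def span_days(self) -> int:
        return (self.end - self.start).days + 1

    def totals(self) -> dict[dt.date, int]:
        """Observed daily totals keyed by calendar date."""
        return {e.day: e.total for e in self.entries}

    def entry_on(self, day: dt.date) -> DiaryEntry | None:
        for e in self.entries:
            if e.day == day:
                return e
        return None

    def treatment_days(self) -> list[dt.date]:
        return [e.day for e in self.entries if e.antibiotic_start]


def read_diary_csv(path, *, lenient_coldflu: bool = False) -> dict[str, PatientDiary]:
    """Read a diary CSV into one :class:`PatientDiary` per patient.

    Raises :class:`DiaryFormatError` on unknown columns, duplicate
    (patient, day) rows or malformed records; messages carry line numbers.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise DiaryFormatError(f"{path}: empty file, header required")
        unknown = set(reader.fieldnames) - set(DIARY_COLUMNS)
        missing = set(DIARY_COLUMNS) - set(reader.fieldnames)
        if unknown:
            raise DiaryFormatError(f"{path}: unknown column(s) {sorted(unknown)}")
        if missing:
            raise DiaryFormatError(f"{path}: missing column(s) {sorted(missing)}")
        per_patient: dict[str, list[DiaryEntry]] = {}
        seen: set[tuple[str, dt.date]] = set()
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                entry = validate_entry(row, lenient_coldflu=lenient_coldflu)
            except DiaryValidationError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            key = (entry.patient_id, entry.day)
            if key in seen:
                raise DiaryFormatError(
                    f"{path}: line {lineno}: duplicate record for "
                    f"{entry.patient_id} on {entry.day}"
                )
            seen.add(key)
            per_patient.setdefault(entry.patient_id, []).append(entry)
    if problems:
        raise DiaryFormatError(f"{path}: " + "; ".join(problems))
    return {
        pid: PatientDiary(pid, entries)
        for pid, entries in sorted(per_patient.items())
    }


def write_diary_csv(diaries, path) -> None:
    """Write diaries to CSV. ``read_diary_csv(write_diary_csv(d)) == d``."""
    if isinstance(diaries, dict):
        diaries = list(diaries.values())
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(DIARY_COLUMNS)
        for diary in diaries:
            for e in diary.entries:
                writer.writerow(
                    [
                        e.patient_id,
                        e.day.isoformat(),
                        e.breathlessness,
                        e.fatigue,
                        e.sputum_volume,
                        e.sputum_colour,
                        e.cough,
                        e.cold_flu,
                        int(e.reported_flag),
                        int(e.antibiotic_start),
                    ]
                )


def read_anchors_csv(path):
    """Read the anchor questionnaire CSV into a pandas DataFrame.

    Columns: patient_id, visit, sgrq_total, sgrq_symptom, cat, lcq,
    six_mwt_m. Missing values are blank in the file, NaN in the frame.
    """
    import pandas as pd

    frame = pd.read_csv(path, dtype={"patient_id": str, "visit": str})
    unknown = set(frame.columns) - set(ANCHOR_COLUMNS)
    missing = set(ANCHOR_COLUMNS) - set(frame.columns)
    if unknown:
        raise DiaryFormatError(f"{path}: unknown column(s) {sorted(unknown)}")
    if missing:
        raise DiaryFormatError(f"{path}: missing column(s) {sorted(missing)}")
    bad = set(frame["visit"]) - ANCHOR_VISITS
    if bad:
        raise DiaryFormatError(f"{path}: unknown visit label(s) {sorted(bad)}")
    return frame


def write_anchors_csv(frame, path) -> None:
    frame.to_csv(path, index=False, columns=ANCHOR_COLUMNS)
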