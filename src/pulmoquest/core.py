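"""Domain types, validation and tabular I/O for questionnaire cohorts.

The data model: one record per patient, 45 questionnaire answers on a
6-level ordinal agreement scale (1 = "does not apply at all" ... 6 =
"applies completely"), plus an optional diagnosis label drawn from seven
groups -- cystic fibrosis (CF), asthma (AS), primary ciliary dyskinesia
(PCD), pneumonia (PM), acute bronchitis (AB), protracted bacterial
bronchitis (PBB) and healthy controls (CTRL).

Cohorts are exchanged as UTF-8 CSV with header
``record_id,diagnosis,q01,...,q45``; missing answers are empty cells.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: Canonical diagnosis codes, in the fixed order used for every probability
#: vector, confusion matrix and deterministic tie-break in the package.
DIAGNOSES: tuple[str, ...] = ("CF", "AS", "PCD", "PM", "AB", "PBB", "CTRL")

#: Number of questionnaire items.
N_QUESTIONS: int = 45

#: Ordinal answer levels.
ANSWER_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

QUESTION_COLUMNS: tuple[str, ...] = tuple(f"q{i:02d}" for i in range(1, N_QUESTIONS + 1))
CSV_COLUMNS: tuple[str, ...] = ("record_id", "diagnosis") + QUESTION_COLUMNS


class CohortFormatError(ValueError):
    """Raised when a cohort table's header or layout is malformed."""


class CohortParseError(ValueError):
    """Raised when a cohort table contains an unparseable or invalid row."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration (unknown kinds, bad references...)."""


def class_index(label: str) -> int:
    """Position of ``label`` in the canonical class order."""
    try:
        return DIAGNOSES.index(label)
    except ValueError:
        raise ConfigurationError(f"unknown diagnosis label {label!r}") from None


@dataclass(frozen=True)
class Question:
    """One questionnaire item. ``text`` is metadata and never enters computation."""

    index: int
    short_label: str
    text: str


def load_questions() -> tuple[Question, ...]:
    """The packaged 45-question registry.

    Texts for the items quoted in the published questionnaire analysis are
    the published wordings; the remainder are synthetic placeholders (the
    full questionnaire is not redistributed).  Indices always form 1..45.
    """
    src = resources.files("pulmoquest.data").joinpath("questions_synthetic.tsv")
    df = pd.read_csv(io.StringIO(src.read_text(encoding="utf-8")), sep="\t", comment="#")
    questions = tuple(
        Question(int(r.index), str(r.short_label), str(r.text)) for r in df.itertuples()
    )
    indices = sorted(q.index for q in questions)
    if indices != list(range(1, N_QUESTIONS + 1)):
        raise CohortFormatError("question registry must cover indices 1..45 exactly")
    return questions


# An AnswerVector is a length-45 tuple of ints in 1..6 or None (missing).
AnswerVector = tuple[Optional[int], ...]


def as_answer_vector(values: Iterable[Optional[Union[int, float]]]) -> AnswerVector:
    """Coerce an iterable (ints, floats, NaN, None) to a canonical AnswerVector."""
    out: list[Optional[int]] = []
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(None)
        else:
            out.append(int(v))
    return tuple(out)


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One answered questionnaire: id, 45 answers, optional diagnosis label."""

    record_id: str
    answers: AnswerVector
    label: Optional[str] = None


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    violations: tuple[str, ...] = ()


def validate_record(record: QuestionnaireRecord) -> ValidationResult:
    """Check one record against the questionnaire contract.

    Collects every violation (never raises): wrong answer-vector length,
    out-of-range answer values, unknown diagnosis label.
    """
    violations: list[str] = []
    n = len(record.answers)
    if n != N_QUESTIONS:
        violations.append(f"length {n} != {N_QUESTIONS}")
    for pos, value in enumerate(record.answers, start=1):
        if value is not None and value not in ANSWER_LEVELS:
            violations.append(f"q{pos:02d}: value {value} outside 1..6")
    if record.label is not None and record.label not in DIAGNOSES:
        violations.append(f"unknown diagnosis label {record.label!r}")
    return ValidationResult(ok=not violations, violations=tuple(violations))


@dataclass
class Cohort:
    """A sequence of questionnaire records sharing one question set."""

    records: list[QuestionnaireRecord]
    questions: tuple[Question, ...] = field(default_factory=load_questions)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise CohortParseError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        """Labelled-record count per canonical class (classes with 0 included)."""
        counts = {d: 0 for d in DIAGNOSES}
        for rec in self.records:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts

    def labelled(self) -> "Cohort":
        return Cohort([r for r in self.records if r.label is not None], self.questions)

    def answer_matrix(self) -> np.ndarray:
        """(n, 45) float matrix; missing answers are NaN."""
        mat = np.full((len(self.records), N_QUESTIONS), np.nan)
        for i, rec in enumerate(self.records):
            for j, v in enumerate(rec.answers):
                if v is not None:
                    mat[i, j] = v
        return mat

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "record_id": rec.record_id,
                "diagnosis": "" if rec.label is None else rec.label,
            }
            for col, v in zip(QUESTION_COLUMNS, rec.answers):
                row[col] = "" if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def cohort_from_dataframe(df: pd.DataFrame) -> Cohort:
    """Build a validated Cohort from a DataFrame with the canonical columns."""
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing_cols)}")
    records: list[QuestionnaireRecord] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        raw_label = row["diagnosis"]
        label: Optional[str]
        if raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)) or str(raw_label).strip() == "":
            label = None
        else:
            token = str(raw_label).strip().upper()
            if token not in DIAGNOSES:
                raise CohortParseError(f"row {pos}: unknown diagnosis token {raw_label!r}")
            label = token
        try:
            answers = as_answer_vector(row[c] for c in QUESTION_COLUMNS)
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"row {pos}: unparseable answer value ({exc})") from exc
        rec = QuestionnaireRecord(str(row["record_id"]), answers, label)
        verdict = validate_record(rec)
        if not verdict.ok:
            raise CohortParseError(f"row {pos}: " + "; ".join(verdict.violations))
        records.append(rec)
    return Cohort(records)


def read_cohort(source: Union[str, IO[str]]) -> Cohort:
    """Read a cohort from CSV (path or text stream).

    The header must name ``record_id``, ``diagnosis`` and ``q01``..``q45``.
    Empty answer cells become missing markers; diagnosis tokens are matched
    case-insensitively against the canonical codes; invalid rows are
    rejected with their row number.
    """
    try:
        df = pd.read_csv(source, dtype={"record_id": str, "diagnosis": str})
    except pd.errors.EmptyDataError:
        raise CohortFormatError("empty input: no header row") from None
    return cohort_from_dataframe(df)


def write_cohort(cohort: Cohort, sink: Union[str, IO[str]]) -> None:
    """Write a cohort as canonical CSV; exact inverse of :func:`read_cohort`."""
    cohort.to_dataframe().to_csv(sink, index=False)


def read_cohort_xlsx(path: str, sheet: Union[int, str] = 0) -> Cohort:
    """Optional spreadsheet import (same column contract as the CSV reader).

    Intended for externally supplied raw-data workbooks; requires openpyxl.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype={"record_id": str, "diagnosis": str})
    return cohort_from_dataframe(df)


def impute_missing(answers: AnswerVector, reference: Sequence[int]) -> AnswerVector:
    """Replace missing answers by the per-question reference value.

    ``reference`` supplies one value in 1..6 per question (typically the
    rounded per-question median of a training partition). Present values
    are never altered.
    """
    if len(reference) != N_QUESTIONS:
        raise ConfigurationError(
            f"imputation reference has length {len(reference)}, expected {N_QUESTIONS}"
        )
    for i, v in enumerate(reference, start=1):
        if int(v) not in ANSWER_LEVELS:
            raise ConfigurationError(f"imputation reference for q{i:02d} is {v}, outside 1..6")
    return tuple(int(reference[i]) if v is None else v for i, v in enumerate(answers))


def imputation_reference(cohort: Cohort) -> tuple[int, ...]:
    """Per-question rounded median of the cohort's non-missing answers.

    Questions with no observed answers fall back to the scale midpoint (3,
    the lower of the two central levels).
    """
    mat = cohort.answer_matrix()
    ref: list[int] = []
    for j in range(N_QUESTIONS):
        col = mat[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            ref.append(3)
        else:
            ref.append(int(np.clip(np.rint(np.median(col)), 1, 6)))
    return tuple(ref)
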