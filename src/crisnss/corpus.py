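"""Data model and I/O for documents, standoff annotations and cohort tables.

Documents are dated free-text units (typically correspondence) belonging to a
patient. Annotations are BRAT-style standoff spans labelling symptom mentions
with a polarity (affirmed / negated / irrelevant). Cohort tables hold the
demographic and clinical covariates used by the epidemiological layer:
age, gender, marital status, employment, four HoNOS subscale scores (0-4),
and inpatient admission intervals.

Conventions: character offsets are 0-based half-open; dates are ISO-8601
strings on disk (lexicographic order equals chronological order); missing
covariates are ``None`` — never imputed at this layer, because downstream
models represent missingness as an explicit category.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: The ten negative-symptom labels, in canonical order.
SYMPTOMS: tuple[str, ...] = (
    "poor_motivation",
    "blunted_affect",
    "poor_eye_contact",
    "emotional_withdrawal",
    "poor_rapport",
    "social_withdrawal",
    "poverty_of_speech",
    "mute",
    "apathy",
    "concrete_thinking",
)

POLARITIES: tuple[str, ...] = ("affirmed", "negated", "irrelevant")
SOURCES: tuple[str, ...] = ("correspondence", "event_note", "other")

MARITAL_LEVELS = ("single", "married_cohabiting", "divorced_separated", "widowed")
EMPLOYMENT_LEVELS = ("unemployed", "employed", "in_education", "retired")
GENDER_LEVELS = ("male", "female")
HONOS_FIELDS = ("honos_adl", "honos_social", "honos_psychotic", "honos_depression")


class CorpusError(ValueError):
    """Malformed or inconsistent corpus input."""


@dataclass(frozen=True)
class Document:
    """One dated clinical text unit for one patient."""

    doc_id: str
    patient_id: str
    date: dt.date
    text: str
    source: str = "correspondence"

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"document {self.doc_id!r}: empty text")
        if self.source not in SOURCES:
            raise CorpusError(
                f"document {self.doc_id!r}: unknown source {self.source!r}"
            )
        if not isinstance(self.date, dt.date):
            raise CorpusError(f"document {self.doc_id!r}: date must be a date")


@dataclass(frozen=True)
class AnnotationSpan:
    """A gold-standard symptom mention: character span + symptom + polarity."""

    doc_id: str
    start: int
    end: int
    symptom: str
    polarity: str
    annotator_id: str = "gold"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"span on {self.doc_id!r}: invalid offsets ({self.start}, {self.end})"
            )
        if self.symptom not in SYMPTOMS:
            raise CorpusError(
                f"span on {self.doc_id!r}: unknown symptom label {self.symptom!r}"
            )
        if self.polarity not in POLARITIES:
            raise CorpusError(
                f"span on {self.doc_id!r}: unknown polarity {self.polarity!r}"
            )


@dataclass
class PatientRecord:
    """Covariates and admission history for one patient.

    HoNOS subscales are integers 0-4 or None; admissions are (admit, discharge)
    date pairs with admit <= discharge.
    """

    patient_id: str
    age_years: int | None = None
    gender: str | None = None
    marital_status: str | None = None
    employment: str | None = None
    honos_adl: int | None = None
    honos_social: int | None = None
    honos_psychotic: int | None = None
    honos_depression: int | None = None
    admissions: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 16:
            raise CorpusError(f"patient {self.patient_id!r}: age {self.age_years} < 16")
        _check_level(self.patient_id, "gender", self.gender, GENDER_LEVELS)
        _check_level(self.patient_id, "marital_status", self.marital_status, MARITAL_LEVELS)
        _check_level(self.patient_id, "employment", self.employment, EMPLOYMENT_LEVELS)
        for name in HONOS_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 4):
                raise CorpusError(
                    f"patient {self.patient_id!r}: {name}={v} outside 0-4"
                )
        for admit, discharge in self.admissions:
            if admit > discharge:
                raise CorpusError(
                    f"patient {self.patient_id!r}: admission {admit} after discharge"
                )


def _check_level(pid: str, name: str, value: str | None, levels: Sequence[str]) -> None:
    if value is not None and value not in levels:
        raise CorpusError(f"patient {pid!r}: {name}={value!r} not in {levels}")


def _parse_date(raw: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw)
    except ValueError as exc:
        raise CorpusError(f"{where}: unparseable date {raw!r}") from exc


# ---------------------------------------------------------------------------
# documents (JSONL)

def read_corpus(path: str | Path, fmt: str = "jsonl") -> list[Document]:
    """Read a document corpus, one JSON object per line.

    Order is preserved; a duplicate ``doc_id`` raises :class:`CorpusError`.
    """
    if fmt != "jsonl":
        raise ValueError(f"unsupported corpus format {fmt!r}")
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from exc
            try:
                doc = Document(
                    doc_id=str(obj["doc_id"]),
                    patient_id=str(obj["patient_id"]),
                    date=_parse_date(str(obj["date"]), f"{path}:{lineno}"),
                    text=obj["text"],
                    source=obj.get("source", "correspondence"),
                )
            except KeyError as exc:
                raise CorpusError(f"{path}:{lineno}: missing field {exc.args[0]!r}") from exc
            if doc.doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_corpus(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "patient_id": d.patient_id,
                        "date": d.date.isoformat(),
                        "text": d.text,
                        "source": d.source,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# annotations (BRAT-style standoff)
#
# line format:  T<k>\t<SYMPTOM>_<POLARITY> <start> <end>\t<surface text>
# polarity suffix is the upper-cased polarity name.

def read_annotations(
    path: str | Path, documents: Sequence[Document]
) -> list[AnnotationSpan]:
    """Read standoff annotations and validate them against *documents*."""
    by_id = {d.doc_id: d for d in documents}
    spans: list[AnnotationSpan] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                _tid, body, _surface = line.split("\t", 2)
                label, start_s, end_s = body.rsplit(" ", 2)
                doc_id, label = label.split(":", 1)
                symptom, polarity = label.rsplit("_", 1)
                span = AnnotationSpan(
                    doc_id=doc_id,
                    start=int(start_s),
                    end=int(end_s),
                    symptom=symptom.lower(),
                    polarity=polarity.lower(),
                )
            except (ValueError, CorpusError) as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            doc = by_id.get(span.doc_id)
            if doc is None:
                raise CorpusError(f"{path}:{lineno}: unknown doc_id {span.doc_id!r}")
            if span.end > len(doc.text):
                raise CorpusError(
                    f"{path}:{lineno}: span end {span.end} beyond document "
                    f"length {len(doc.text)}"
                )
            spans.append(span)
    return spans


def write_annotations(spans: Iterable[AnnotationSpan], documents: Sequence[Document],
                      path: str | Path) -> None:
    by_id = {d.doc_id: d for d in documents}
    with open(path, "w", encoding="utf-8") as fh:
        for k, s in enumerate(spans, start=1):
            surface = by_id[s.doc_id].text[s.start:s.end]
            fh.write(
                f"T{k}\t{s.doc_id}:{s.symptom.upper()}_{s.polarity.upper()} "
                f"{s.start} {s.end}\t{surface}\n"
            )


# ---------------------------------------------------------------------------
# cohort tables (CSV)

_COHORT_HEADER = [
    "patient_id", "age_years", "gender", "marital_status", "employment",
    "honos_adl", "honos_social", "honos_psychotic", "honos_depression",
]


def read_cohort_table(
    path: str | Path, admissions_path: str | Path | None = None
) -> list[PatientRecord]:
    """Read patient covariates from CSV; empty cells are missing values.

    An optional companion CSV ``{patient_id, admit_date, discharge_date}``
    supplies admission intervals.
    """
    admissions: dict[str, list[tuple[dt.date, dt.date]]] = {}
    if admissions_path is not None:
        with open(admissions_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                pid = row["patient_id"]
                admissions.setdefault(pid, []).append(
                    (
                        _parse_date(row["admit_date"], str(admissions_path)),
                        _parse_date(row["discharge_date"], str(admissions_path)),
                    )
                )
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(_COHORT_HEADER) - set(reader.fieldnames or [])
        if missing_cols:
            raise CorpusError(f"{path}: missing columns {sorted(missing_cols)}")
        for row in reader:
            pid = row["patient_id"]

            def opt_int(col: str) -> int | None:
                raw = row[col].strip()
                if not raw:
                    return None
                try:
                    return int(raw)
                except ValueError as exc:
                    raise CorpusError(f"{path}: patient {pid!r}: bad {col}={raw!r}") from exc

            records.append(
                PatientRecord(
                    patient_id=pid,
                    age_years=opt_int("age_years"),
                    gender=row["gender"].strip() or None,
                    marital_status=row["marital_status"].strip() or None,
                    employment=row["employment"].strip() or None,
                    honos_adl=opt_int("honos_adl"),
                    honos_social=opt_int("honos_social"),
                    honos_psychotic=opt_int("honos_psychotic"),
                    honos_depression=opt_int("honos_depression"),
                    admissions=sorted(admissions.get(pid, [])),
                )
            )
    return records


def write_cohort_table(
    records: Iterable[PatientRecord],
    path: str | Path,
    admissions_path: str | Path | None = None,
) -> None:
    records = list(records)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    "" if r.age_years is None else r.age_years,
                    r.gender or "",
                    r.marital_status or "",
                    r.employment or "",
                ]
                + ["" if getattr(r, h) is None else getattr(r, h) for h in HONOS_FIELDS]
            )
    if admissions_path is not None:
        with open(admissions_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "admit_date", "discharge_date"])
            for r in records:
                for admit, discharge in r.admissions:
                    writer.writerow([r.patient_id, admit.isoformat(), discharge.isoformat()])
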