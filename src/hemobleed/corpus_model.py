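"""Canonical data model for patient visits, notes, labs and transfusions.

The corpus interchange format is JSONL (UTF-8, one visit per line); see
``data/visit.schema.json`` for the field-level schema.  All timestamps are
ISO-8601 strings on disk and :class:`datetime.datetime` in memory.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NOTE_TYPES = frozenset({"admission", "progress", "operative", "transfusion", "discharge"})
HB_UNITS = frozenset({"g_per_L", "g_per_dL"})
PRODUCTS = frozenset({"rbc_concentrate", "whole_blood", "other"})
QTY_UNITS = frozenset({"U", "mL"})
LABELS = frozenset({"major_bleeding_present", "major_bleeding_absent"})

POSITIVE_LABEL = "major_bleeding_present"
NEGATIVE_LABEL = "major_bleeding_absent"


class CorpusValidationError(ValueError):
    """A record violates the visit schema or one of its invariants."""


def _parse_ts(value: str | datetime, context: str) -> datetime:
    if isinstance(value, datetime):
        return value
    try:
        return datetime.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise CorpusValidationError(f"{context}: unparseable timestamp {value!r}") from exc


@dataclass
class CourseNote:
    note_id: str
    visit_id: str
    note_type: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        self.timestamp = _parse_ts(self.timestamp, f"note {self.note_id}")
        if self.note_type not in NOTE_TYPES:
            raise CorpusValidationError(
                f"note {self.note_id}: note_type {self.note_type!r} not in {sorted(NOTE_TYPES)}"
            )
        if not self.text:
            raise CorpusValidationError(f"note {self.note_id}: text must be non-empty")

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "visit_id": self.visit_id,
            "note_type": self.note_type,
            "timestamp": self.timestamp.isoformat(),
            "text": self.text,
        }


@dataclass
class HemoglobinMeasurement:
    timestamp: datetime
    value: float
    unit: str

    def __post_init__(self) -> None:
        self.timestamp = _parse_ts(self.timestamp, "hb measurement")
        if self.unit not in HB_UNITS:
            raise CorpusValidationError(f"hb measurement: unit {self.unit!r} not in {sorted(HB_UNITS)}")
        if not self.value > 0:
            raise CorpusValidationError(f"hb measurement: value {self.value} must be > 0")
        g_per_l = self.value if self.unit == "g_per_L" else self.value * 10.0
        if not (30.0 <= g_per_l <= 250.0):
            raise CorpusValidationError(
                f"hb measurement: value {self.value} {self.unit} outside plausible range 30-250 g/L"
            )

    def to_dict(self) -> dict:
        return {"timestamp": self.timestamp.isoformat(), "value": self.value, "unit": self.unit}


@dataclass
class TransfusionEvent:
    timestamp: datetime
    product: str
    quantity: float
    unit: str

    def __post_init__(self) -> None:
        self.timestamp = _parse_ts(self.timestamp, "transfusion")
        if self.product not in PRODUCTS:
            raise CorpusValidationError(f"transfusion: product {self.product!r} not in {sorted(PRODUCTS)}")
        if self.unit not in QTY_UNITS:
            raise CorpusValidationError(f"transfusion: unit {self.unit!r} not in {sorted(QTY_UNITS)}")
        if not self.quantity > 0:
            raise CorpusValidationError(f"transfusion: quantity {self.quantity} must be > 0")

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp.isoformat(),
            "product": self.product,
            "quantity": self.quantity,
            "unit": self.unit,
        }


@dataclass
class PatientVisit:
    visit_id: str
    age: int
    sex: str
    surgery_time: datetime
    notes: list[CourseNote] = field(default_factory=list)
    hb_series: list[HemoglobinMeasurement] = field(default_factory=list)
    transfusions: list[TransfusionEvent] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        self.surgery_time = _parse_ts(self.surgery_time, f"visit {self.visit_id}")
        if self.age < 18:
            raise CorpusValidationError(
                f"visit {self.visit_id}: age {self.age} violates inclusion criterion (>= 18)"
            )
        if self.sex not in ("female", "male"):
            raise CorpusValidationError(f"visit {self.visit_id}: sex {self.sex!r} not in ('female', 'male')")
        if not self.notes:
            raise CorpusValidationError(f"visit {self.visit_id}: at least one note required")
        if self.label is not None and self.label not in LABELS:
            raise CorpusValidationError(f"visit {self.visit_id}: label {self.label!r} not in {sorted(LABELS)}")
        timestamps = [n.timestamp for n in self.notes]
        if timestamps != sorted(timestamps):
            raise CorpusValidationError(f"visit {self.visit_id}: notes must be sorted by timestamp")

    def to_dict(self) -> dict:
        return {
            "visit_id": self.visit_id,
            "age": self.age,
            "sex": self.sex,
            "surgery_time": self.surgery_time.isoformat(),
            "notes": [n.to_dict() for n in self.notes],
            "hb_series": [m.to_dict() for m in self.hb_series],
            "transfusions": [t.to_dict() for t in self.transfusions],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, record: dict) -> "PatientVisit":
        try:
            return cls(
                visit_id=record["visit_id"],
                age=record["age"],
                sex=record["sex"],
                surgery_time=record["surgery_time"],
                notes=[CourseNote(**n) for n in record.get("notes", [])],
                hb_series=[HemoglobinMeasurement(**m) for m in record.get("hb_series", [])],
                transfusions=[TransfusionEvent(**t) for t in record.get("transfusions", [])],
                label=record.get("label"),
            )
        except KeyError as exc:
            raise CorpusValidationError(
                f"visit {record.get('visit_id', '<missing id>')}: missing field {exc.args[0]!r}"
            ) from exc
        except TypeError as exc:
            raise CorpusValidationError(
                f"visit {record.get('visit_id', '<missing id>')}: malformed record ({exc})"
            ) from exc


def read_corpus(path: str | Path) -> list[PatientVisit]:
    """Read and validate a JSONL corpus; order is preserved.

    Raises :class:`CorpusValidationError` naming the offending line number
    (malformed JSON) or the visit_id and field (schema violations).
    """
    visits: list[PatientVisit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            visits.append(PatientVisit.from_dict(record))
    return visits


def write_corpus(visits: Iterable[PatientVisit], path: str | Path) -> None:
    """Serialize visits as UTF-8 JSONL; round-trips through :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for visit in visits:
            fh.write(json.dumps(visit.to_dict(), ensure_ascii=False) + "\n")


def split_corpus(
    visits: Sequence[PatientVisit],
    train_fraction: float,
    seed: int,
    stratified: bool = True,
) -> tuple[list[PatientVisit], list[PatientVisit]]:
    """Deterministic train/test partition at the visit level.

    The split is disjoint and exhaustive; with ``stratified=True`` the label
    proportion in each part matches the corpus to within one visit per
    stratum.  Splitting at visit level keeps all notes of a patient stay on
    one side (no leakage).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    n = len(visits)
    n_train = round(train_fraction * n)
    if not stratified:
        order = rng.permutation(n)
        train_idx = set(order[:n_train].tolist())
    else:
        unlabeled = [v.visit_id for v in visits if v.label is None]
        if unlabeled:
            raise ValueError(
                f"stratified split requires labels; {len(unlabeled)} unlabeled visits "
                f"(first: {unlabeled[0]})"
            )
        strata: dict[str, list[int]] = {}
        for i, v in enumerate(visits):
            strata.setdefault(v.label, []).append(i)
        # floor per stratum, then hand out the remainder by largest fractional part
        train_idx = set()
        floors, remainders = {}, []
        for lab, idx in sorted(strata.items()):
            exact = train_fraction * len(idx)
            floors[lab] = int(math.floor(exact))
            remainders.append((exact - floors[lab], lab))
        leftover = n_train - sum(floors.values())
        for _, lab in sorted(remainders, reverse=True)[: max(leftover, 0)]:
            floors[lab] += 1
        for lab, idx in sorted(strata.items()):
            order = rng.permutation(len(idx))
            take = floors[lab]
            train_idx.update(idx[j] for j in order[:take].tolist())
    train = [v for i, v in enumerate(visits) if i in train_idx]
    test = [v for i, v in enumerate(visits) if i not in train_idx]
    return train, test


@dataclass
class CorpusSummary:
    n_visits: int
    n_notes: int
    mean_notes_per_visit: float
    mean_age: float
    sd_age: float
    percent_female: float
    n_labeled: int
    n_positive: int

    @property
    def prevalence_percent(self) -> float | None:
        """Major-bleeding prevalence among labeled visits, in percent."""
        if self.n_labeled == 0:
            return None
        return 100.0 * self.n_positive / self.n_labeled

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["prevalence_percent"] = self.prevalence_percent
        return d


def summarize_corpus(visits: Sequence[PatientVisit]) -> CorpusSummary:
    if not visits:
        raise ValueError("cannot summarize an empty corpus")
    ages = np.array([v.age for v in visits], dtype=float)
    n_notes = sum(len(v.notes) for v in visits)
    labeled = [v for v in visits if v.label is not None]
    return CorpusSummary(
        n_visits=len(visits),
        n_notes=n_notes,
        mean_notes_per_visit=n_notes / len(visits),
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if len(visits) > 1 else 0.0,
        percent_female=100.0 * sum(v.sex == "female" for v in visits) / len(visits),
        n_labeled=len(labeled),
        n_positive=sum(v.label == POSITIVE_LABEL for v in labeled),
    )
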