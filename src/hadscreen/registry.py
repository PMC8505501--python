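"""Canonical data model and I/O for prescription tables and the high-alert-drug registry.

One prescription table row carries one visit identifier (TXN), the patient's
gender and age, one ICD10 diagnosis code and one prescribed drug.  A visit with
several diagnoses repeats them across its rows.  Rows are aggregated by TXN into
:class:`VisitRecord` instances, which every downstream stage consumes.

The :class:`HADRegistry` maps drug codes to high-alert-drug (HAD) membership,
one of four administrative HAD groups and one of six pharmacological HAD types
(ANS, BIG, CVS, CNS, END, Tumor).  A packaged default registry covering the
standard hospital HAD list ships with the package.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

HAD_GROUPS = ("general", "narcotic_psychotropic", "iv_cytotoxic", "oral_cytotoxic")
HAD_TYPES = ("ANS", "BIG", "CVS", "CNS", "END", "Tumor")
NON_HAD = "non-HAD"
HAD = "HAD"
SETTINGS = ("OPD", "IPD")

#: default column names of a prescription CSV; overridable via ``column_map``
DEFAULT_COLUMNS = {
    "txn": "txn",
    "gender": "gender",
    "age": "age",
    "icd10": "icd10",
    "drug_code": "drug_code",
    "drug_name": "drug_name",
}


@dataclass(frozen=True)
class PrescriptionRow:
    """One prescription: a single drug dispensed in a single hospital visit."""

    txn: str
    gender: str  # "male" | "female"
    age: int
    icd10: str
    drug_code: str
    drug_name: str = ""

    def __post_init__(self) -> None:
        if not str(self.txn):
            raise ValueError("txn must be non-empty")
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be 'male' or 'female', got {self.gender!r}")
        if int(self.age) < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not self.drug_code:
            raise ValueError("drug_code must be non-empty")


@dataclass
class VisitRecord:
    """One hospital visit: demographics, deduplicated diagnoses, drug multiset."""

    txn: str
    gender: str
    age: int
    icd10_set: frozenset
    drugs: tuple  # multiset of drug codes, insertion order preserved

    @property
    def total_drugs(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True)
class RegistryEntry:
    is_had: bool
    had_group: Optional[str] = None
    had_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_had:
            if self.had_group not in HAD_GROUPS:
                raise ValueError(f"HAD entry requires a group from {HAD_GROUPS}")
            if self.had_type not in HAD_TYPES:
                raise ValueError(f"HAD entry requires a type from {HAD_TYPES}")
        else:
            if self.had_group is not None or self.had_type is not None:
                raise ValueError("non-HAD entry must not carry group/type")


class HADRegistry:
    """Drug code -> HAD membership, group and type.

    Drugs absent from the registry default to non-HAD.  Each drug code maps to
    exactly one entry; duplicate codes are a fatal error at load time.
    """

    def __init__(self, entries: Mapping[str, RegistryEntry]):
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, drug_code: str) -> bool:
        return drug_code in self._entries

    def entry(self, drug_code: str) -> RegistryEntry:
        return self._entries.get(drug_code, RegistryEntry(is_had=False))

    def is_had(self, drug_code: str) -> bool:
        return self.entry(drug_code).is_had

    def had_group(self, drug_code: str) -> Optional[str]:
        return self.entry(drug_code).had_group

    def had_type(self, drug_code: str) -> Optional[str]:
        return self.entry(drug_code).had_type

    def had_codes(self) -> list:
        return [c for c, e in self._entries.items() if e.is_had]

    def codes_of_type(self, had_type: str) -> list:
        return [c for c, e in self._entries.items() if e.had_type == had_type]

    def visit_types(self, visit: VisitRecord) -> set:
        """Distinct HAD types prescribed in a visit (empty set when none)."""
        return {t for t in (self.had_type(d) for d in visit.drugs) if t is not None}

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, str]]) -> "HADRegistry":
        entries: dict = {}
        for row in rows:
            code = str(row["drug_code"]).strip()
            if not code:
                raise ValueError("registry row with empty drug_code")
            if code in entries:
                raise ValueError(f"duplicate drug_code in registry: {code!r}")
            group = (row.get("had_group") or "").strip() or None
            had_type = (row.get("had_type") or "").strip() or None
            if group is not None and had_type is None:
                raise ValueError(f"HAD drug {code!r} missing had_type")
            entries[code] = RegistryEntry(
                is_had=group is not None, had_group=group, had_type=had_type
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "HADRegistry":
        """The packaged hospital HAD list (four groups, six types)."""
        ref = resources.files("hadscreen.data").joinpath("default_registry.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return cls.from_rows(csv.DictReader(fh))


def read_registry(path) -> HADRegistry:
    """Read a HAD registry from CSV (drug_code, had_group, had_type) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        return HADRegistry.from_rows(payload)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "drug_code" not in reader.fieldnames:
            raise ValueError(f"registry file {path} missing 'drug_code' column")
        return HADRegistry.from_rows(reader)


@dataclass
class ReadReport:
    """Result of reading a prescription table: accepted rows plus reject count."""

    rows: list = field(default_factory=list)
    n_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)


def _normalise_gender(raw: str) -> str:
    g = str(raw).strip().lower()
    if g in ("male", "m", "1"):
        return "male"
    if g in ("female", "f", "0"):
        return "female"
    raise ValueError(f"unrecognised gender {raw!r}")


def read_prescriptions(
    path,
    delimiter: str = ",",
    column_map: Optional[Mapping[str, str]] = None,
) -> ReadReport:
    """Read a delimited prescription table into validated :class:`PrescriptionRow`s.

    ``column_map`` maps the six canonical field names to the file's header
    names.  A missing mandatory column is fatal; malformed rows (negative or
    unparseable age, empty txn/drug code, bad gender) are rejected, counted and
    logged, never silently dropped.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    report = ReadReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for canonical, name in colmap.items():
            if canonical != "drug_name" and name not in header:
                raise ValueError(f"missing mandatory column {name!r} in {path}")
        for i, raw in enumerate(reader):
            try:
                row = PrescriptionRow(
                    txn=str(raw[colmap["txn"]]).strip(),
                    gender=_normalise_gender(raw[colmap["gender"]]),
                    age=int(str(raw[colmap["age"]]).strip()),
                    icd10=str(raw[colmap["icd10"]] or "").strip(),
                    drug_code=str(raw[colmap["drug_code"]]).strip(),
                    drug_name=str(raw.get(colmap["drug_name"], "") or "").strip(),
                )
            except (ValueError, TypeError) as exc:
                report.n_rejected += 1
                report.reject_reasons[str(exc)] += 1
                logger.warning("rejected prescription row %d: %s", i + 1, exc)
                continue
            report.rows.append(row)
    return report


def write_prescriptions(rows: Sequence[PrescriptionRow], path, delimiter: str = ",") -> None:
    """Write prescription rows in the same CSV dialect ``read_prescriptions`` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["txn", "gender", "age", "icd10", "drug_code", "drug_name"])
        for r in rows:
            writer.writerow([r.txn, r.gender, r.age, r.icd10, r.drug_code, r.drug_name])


def aggregate_visits(rows: Sequence[PrescriptionRow]) -> list:
    """Aggregate prescription rows by TXN into one :class:`VisitRecord` each.

    ``total_drugs`` equals the number of input rows of that TXN; the ICD10 set
    is the union of its rows' codes (empty codes are dropped but the visit is
    retained).  Conflicting gender/age within one TXN keeps the first
    occurrence and logs a warning.
    """
    if not rows:
        raise ValueError("aggregate_visits requires at least one row")
    order: list = []
    by_txn: dict = {}
    for r in rows:
        if r.txn not in by_txn:
            by_txn[r.txn] = {"gender": r.gender, "age": r.age, "icd10": set(), "drugs": []}
            order.append(r.txn)
        rec = by_txn[r.txn]
        if (r.gender, r.age) != (rec["gender"], rec["age"]):
            logger.warning("conflicting demographics within txn %s; keeping first", r.txn)
        if r.icd10:
            rec["icd10"].add(r.icd10)
        rec["drugs"].append(r.drug_code)
    visits = []
    for txn in order:
        rec = by_txn[txn]
        if not rec["icd10"]:
            logger.warning("visit %s has no ICD10 codes", txn)
        visits.append(
            VisitRecord(
                txn=txn,
                gender=rec["gender"],
                age=rec["age"],
                icd10_set=frozenset(rec["icd10"]),
                drugs=tuple(rec["drugs"]),
            )
        )
    return visits
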