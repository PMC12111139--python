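"""Canonical dispensing-claim schema, drug formulary, and claims-file IO.

Every downstream stage (cohort gates, monthly plotting, PDC segmentation,
statistics) consumes the :class:`DispensingClaim` / :class:`PatientRecord`
containers defined here.  Claims arrive as flat CSV tables — one row per
pharmacy dispensing event — and are classified against a formulary mapping
drug identifiers onto the analysis drug classes (methylphenidate,
atomoxetine, antidepressant subclasses, flumazenil, other).
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

__all__ = [
    "DrugClass",
    "CNS_OTHER_CLASSES",
    "ANTIDEPRESSANT_CLASSES",
    "DispensingClaim",
    "FormularyEntry",
    "Formulary",
    "PatientRecord",
    "RejectedRow",
    "ReadResult",
    "SchemaError",
    "CLAIMS_COLUMNS",
    "read_claims",
    "write_claims",
    "write_rejects",
    "classify_drug",
    "patient_age",
]

#: Canonical claims CSV header, in order.
CLAIMS_COLUMNS = (
    "patient_id",
    "gender",
    "birth_date",
    "dispense_date",
    "drug_code",
    "drug_name",
    "strength_mg",
    "quantity_units",
    "days_supply",
    "icd10_codes",
)

DEFAULT_STUDY_START = dt.date(2012, 1, 1)
DEFAULT_STUDY_END = dt.date(2016, 12, 31)


class DrugClass(str, enum.Enum):
    """Analysis drug class derived from the formulary."""

    MPH = "MPH"
    ATX = "ATX"
    AD_SSRI = "AD_SSRI"
    AD_TCA = "AD_TCA"
    AD_OTHER = "AD_OTHER"
    FLUMAZENIL = "FLUMAZENIL"
    OTHER = "OTHER"


#: MIMS "1.1.3 Central nervous system other": the index drug classification.
CNS_OTHER_CLASSES = frozenset({DrugClass.MPH, DrugClass.ATX, DrugClass.FLUMAZENIL})

#: Antidepressant subclasses pooled as "AD" therapy downstream.
ANTIDEPRESSANT_CLASSES = frozenset(
    {DrugClass.AD_SSRI, DrugClass.AD_TCA, DrugClass.AD_OTHER}
)


class SchemaError(ValueError):
    """Raised when the claims file header does not match the canonical schema."""


@dataclass(frozen=True)
class DispensingClaim:
    """One pharmacy dispensing event.

    ``days_supply`` is carried through from the source table but is never used
    for coverage arithmetic (supply duration is always derived from quantity
    and the estimated daily dose, for consistency across years).
    """

    patient_id: str
    dispense_date: dt.date
    drug_code: str
    drug_name: str
    strength_mg: float
    quantity_units: int
    drug_class: DrugClass = DrugClass.OTHER
    days_supply: Optional[int] = None
    icd10_codes: tuple[str, ...] = ()

    def has_code_prefix(self, prefixes: Iterable[str]) -> bool:
        ups = tuple(p.upper() for p in prefixes)
        return any(c.upper().startswith(ups) for c in self.icd10_codes)

    @property
    def total_mg(self) -> float:
        return self.strength_mg * self.quantity_units


@dataclass(frozen=True)
class FormularyEntry:
    drug_code: str
    drug_name: str
    drug_class: DrugClass
    default_units_per_day: float = 1.0
    min_antidepressant_dose_mg: Optional[float] = None
    ddd_mg: Optional[float] = None


class Formulary:
    """Drug identifier → class/dosing lookup table.

    Shipped as a packaged CSV (``adhere/data/formulary.csv``); an alternative
    table can be supplied with :meth:`from_csv`.  Lookup is by ``drug_code``
    first, falling back to a case-insensitive ``drug_name`` match; unknown
    drugs classify as :attr:`DrugClass.OTHER`.
    """

    def __init__(self, entries: Iterable[FormularyEntry]):
        self._by_code: dict[str, FormularyEntry] = {}
        self._by_name: dict[str, FormularyEntry] = {}
        for e in entries:
            self._by_code[e.drug_code.upper()] = e
            self._by_name.setdefault(e.drug_name.strip().lower(), e)

    def lookup(self, drug_code: str, drug_name: str = "") -> Optional[FormularyEntry]:
        e = self._by_code.get(drug_code.upper())
        if e is None:
            e = self._by_name.get(drug_name.strip().lower())
        return e

    def classify(self, drug_code: str, drug_name: str = "") -> DrugClass:
        e = self.lookup(drug_code, drug_name)
        return e.drug_class if e is not None else DrugClass.OTHER

    def entries(self) -> Sequence[FormularyEntry]:
        return tuple(self._by_code.values())

    @classmethod
    def from_csv(cls, path) -> "Formulary":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    FormularyEntry(
                        drug_code=row["drug_code"].strip(),
                        drug_name=row["drug_name"].strip(),
                        drug_class=DrugClass(row["drug_class"].strip()),
                        default_units_per_day=float(row.get("default_units_per_day") or 1.0),
                        min_antidepressant_dose_mg=(
                            float(row["min_antidepressant_dose_mg"])
                            if row.get("min_antidepressant_dose_mg")
                            else None
                        ),
                        ddd_mg=float(row["ddd_mg"]) if row.get("ddd_mg") else None,
                    )
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "Formulary":
        ref = resources.files("adhere.data").joinpath("formulary.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class PatientRecord:
    """Demographics plus the patient's date-ordered claim stream."""

    patient_id: str
    gender: str  # "F" or "M"
    birth_date: dt.date
    claims: list[DispensingClaim] = field(default_factory=list)

    def claims_of_class(self, classes: Iterable[DrugClass]) -> list[DispensingClaim]:
        cs = frozenset(classes)
        return [c for c in self.claims if c.drug_class in cs]


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    reason: str


@dataclass
class ReadResult:
    records: list[PatientRecord]
    rejects: list[RejectedRow]


def classify_drug(claim: DispensingClaim, formulary: Formulary) -> DrugClass:
    """Deterministic drug-class assignment; unknown drugs sink to OTHER."""
    return formulary.classify(claim.drug_code, claim.drug_name)


def patient_age(patient: PatientRecord, on: dt.date) -> float:
    """Fractional age in years on a date: days since birth / 365.25."""
    if on < patient.birth_date:
        raise ValueError(
            f"date {on} precedes birth date {patient.birth_date} "
            f"for patient {patient.patient_id}"
        )
    return (on - patient.birth_date).days / 365.25


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def _parse_codes(text: str) -> tuple[str, ...]:
    if not text or not text.strip():
        return ()
    return tuple(c.strip() for c in text.split(";") if c.strip())


def read_claims(
    path,
    formulary: Formulary,
    *,
    study_start: dt.date = DEFAULT_STUDY_START,
    study_end: dt.date = DEFAULT_STUDY_END,
) -> ReadResult:
    """Read a claims CSV into per-patient records.

    Malformed rows are collected into ``rejects`` (row number + reason), never
    silently dropped; a missing mandatory column raises :class:`SchemaError`.
    Claims are classified against the formulary and sorted by dispense date
    within each patient.
    """
    records: dict[str, PatientRecord] = {}
    rejects: list[RejectedRow] = []
    import contextlib

    cm = (
        contextlib.nullcontext(path)
        if hasattr(path, "read")
        else open(path, newline="")
    )
    with cm as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CLAIMS_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"claims file missing mandatory column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                claim, gender, birth = _parse_row(row, formulary, study_start, study_end)
            except ValueError as err:
                rejects.append(RejectedRow(row_number=i, reason=str(err)))
                continue
            rec = records.get(claim.patient_id)
            if rec is None:
                rec = PatientRecord(claim.patient_id, gender, birth)
                records[claim.patient_id] = rec
            rec.claims.append(claim)
    for rec in records.values():
        rec.claims.sort(key=lambda c: (c.dispense_date, c.drug_code))
    return ReadResult(records=list(records.values()), rejects=rejects)


def _parse_row(row, formulary, study_start, study_end):
    pid = (row.get("patient_id") or "").strip()
    if not pid:
        raise ValueError("blank patient_id")
    gender = (row.get("gender") or "").strip().upper()
    if gender not in ("F", "M"):
        raise ValueError(f"gender must be F or M, got {gender!r}")
    try:
        birth = _parse_date(row["birth_date"])
    except ValueError:
        raise ValueError(f"unparseable birth_date {row.get('birth_date')!r}")
    try:
        when = _parse_date(row["dispense_date"])
    except ValueError:
        raise ValueError(f"unparseable dispense_date {row.get('dispense_date')!r}")
    if not (study_start <= when <= study_end):
        raise ValueError(f"dispense_date {when} outside study window")
    try:
        strength = float(row["strength_mg"])
    except ValueError:
        raise ValueError(f"unparseable strength_mg {row.get('strength_mg')!r}")
    if strength < 0:
        raise ValueError("strength_mg must be non-negative")
    try:
        qty = int(row["quantity_units"])
    except ValueError:
        raise ValueError(f"unparseable quantity_units {row.get('quantity_units')!r}")
    if qty < 1:
        raise ValueError("quantity_units must be >= 1")
    supply_text = (row.get("days_supply") or "").strip()
    days_supply = None
    if supply_text:
        try:
            days_supply = int(supply_text)
        except ValueError:
            raise ValueError(f"unparseable days_supply {supply_text!r}")
        if days_supply < 1:
            raise ValueError("days_supply must be >= 1 when present")
    claim = DispensingClaim(
        patient_id=pid,
        dispense_date=when,
        drug_code=(row.get("drug_code") or "").strip(),
        drug_name=(row.get("drug_name") or "").strip(),
        strength_mg=strength,
        quantity_units=qty,
        days_supply=days_supply,
        icd10_codes=_parse_codes(row.get("icd10_codes") or ""),
    )
    claim = replace(claim, drug_class=classify_drug(claim, formulary))
    return claim, gender, birth


def write_claims(records: Iterable[PatientRecord], path) -> None:
    """Write records back to the canonical CSV layout (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CLAIMS_COLUMNS)
        for rec in records:
            for c in rec.claims:
                w.writerow(
                    [
                        rec.patient_id,
                        rec.gender,
                        rec.birth_date.isoformat(),
                        c.dispense_date.isoformat(),
                        c.drug_code,
                        c.drug_name,
                        _fmt_num(c.strength_mg),
                        c.quantity_units,
                        "" if c.days_supply is None else c.days_supply,
                        ";".join(c.icd10_codes),
                    ]
                )


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_rejects(rejects: Iterable[RejectedRow], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["row_number", "reason"])
        for r in rejects:
            w.writerow([r.row_number, r.reason])
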