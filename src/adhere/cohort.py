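"""Cohort construction: inclusion/exclusion cascade and diagnostic grouping.

Patients enter the study when they were dispensed a MIMS "central nervous
system other" drug (methylphenidate, atomoxetine or flumazenil) during the
index year and were aged 18–40 over the follow-up window.  The cascade is
order-stable: the age gate first, then the index-claim gate, then removal of
patients whose only index-class drug was flumazenil with no ADHD diagnostic
code.  Retained patients split into the F90 group (any claim carrying an
ICD-10 code of the F90 family, any year) versus non-F90.

The tricyclic-misuse filter drops TCA issuances that cannot represent
depression pharmacotherapy — sub-therapeutic daily dose, short-term coverage,
or claims coded only to non-mood diagnoses — from antidepressant analyses,
retaining them for audit.
"""

from __future__ import annotations

import datetime as dt
import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .claims_io import (
    CNS_OTHER_CLASSES,
    DispensingClaim,
    DrugClass,
    Formulary,
    PatientRecord,
    patient_age,
)
from .monthly_plot import estimate_daily_dose

__all__ = [
    "CohortStatus",
    "DiagnosticGroup",
    "CohortAssignment",
    "CohortConfig",
    "GateCounts",
    "assess_eligibility",
    "exclude_flumazenil_only",
    "assign_diagnostic_group",
    "filter_tricyclic_misuse",
    "build_cohort",
]

F90_PREFIX = "F90"
DEFAULT_MOOD_PREFIXES = ("F32", "F33", "F34", "F38", "F39", "F41")


class CohortStatus(str, enum.Enum):
    INCLUDED = "INCLUDED"
    EXCLUDED_AGE = "EXCLUDED_AGE"
    EXCLUDED_FLUMAZENIL_ONLY = "EXCLUDED_FLUMAZENIL_ONLY"
    EXCLUDED_NO_INDEX_CLAIM = "EXCLUDED_NO_INDEX_CLAIM"


class DiagnosticGroup(str, enum.Enum):
    F90 = "F90"
    NON_F90 = "NON_F90"
    NOT_ASSIGNED = "NOT_ASSIGNED"


@dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    status: CohortStatus
    group: DiagnosticGroup
    reasons: tuple[str, ...] = ()


@dataclass
class CohortConfig:
    study_start: dt.date = dt.date(2012, 1, 1)
    study_end: dt.date = dt.date(2016, 12, 31)
    index_year: int = 2015
    min_age: int = 18
    max_age: int = 40
    tca_short_term_days: int = 14
    mood_icd_prefixes: tuple[str, ...] = DEFAULT_MOOD_PREFIXES


@dataclass
class GateCounts:
    total: int = 0
    excluded_age: int = 0
    excluded_no_index_claim: int = 0
    excluded_flumazenil_only: int = 0
    included: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "excluded_age": self.excluded_age,
            "excluded_no_index_claim": self.excluded_no_index_claim,
            "excluded_flumazenil_only": self.excluded_flumazenil_only,
            "included": self.included,
        }


def _has_f90(patient: PatientRecord) -> bool:
    return any(c.has_code_prefix((F90_PREFIX,)) for c in patient.claims)


def assess_eligibility(
    patient: PatientRecord,
    index_year: int = 2015,
    study_start: dt.date = dt.date(2012, 1, 1),
    min_age: int = 18,
    max_age: int = 40,
) -> CohortStatus:
    """Age gate then index-claim gate; flumazenil-only is assessed separately.

    Age eligibility: at least ``min_age`` on the first study day and between
    ``min_age`` and ``max_age`` inclusive at some point during the index year.
    """
    if patient.birth_date > study_start:
        return CohortStatus.EXCLUDED_AGE
    if patient_age(patient, study_start) < min_age:
        return CohortStatus.EXCLUDED_AGE
    if patient_age(patient, dt.date(index_year, 1, 1)) > max_age:
        return CohortStatus.EXCLUDED_AGE
    index_claims = [
        c
        for c in patient.claims
        if c.drug_class in CNS_OTHER_CLASSES and c.dispense_date.year == index_year
    ]
    if not index_claims:
        return CohortStatus.EXCLUDED_NO_INDEX_CLAIM
    return CohortStatus.INCLUDED


def exclude_flumazenil_only(patient: PatientRecord) -> bool:
    """True when the patient's only index-class drug is flumazenil and no
    F90 code appears on any claim (so no ADHD-indicated drug or diagnosis)."""
    cns = patient.claims_of_class(CNS_OTHER_CLASSES)
    if not cns:
        return False
    only_flz = all(c.drug_class is DrugClass.FLUMAZENIL for c in cns)
    return only_flz and not _has_f90(patient)


def assign_diagnostic_group(patient: PatientRecord) -> DiagnosticGroup:
    """F90 iff any claim in the follow-up carries an F90-family code."""
    return DiagnosticGroup.F90 if _has_f90(patient) else DiagnosticGroup.NON_F90


def filter_tricyclic_misuse(
    claims: Sequence[DispensingClaim],
    formulary: Formulary,
    *,
    short_term_days: int = 14,
    mood_icd_prefixes: Iterable[str] = DEFAULT_MOOD_PREFIXES,
) -> tuple[list[DispensingClaim], list[DispensingClaim]]:
    """Split a claim stream into (kept, excluded) for antidepressant analysis.

    A tricyclic claim is excluded when its implied daily dose is below the
    accepted minimum antidepressant dose for the agent, its implied coverage
    is short-term, or its diagnostic codes name no mood disorder.  Non-TCA
    claims always pass through.
    """
    mood_prefixes = tuple(mood_icd_prefixes)
    kept: list[DispensingClaim] = []
    excluded: list[DispensingClaim] = []
    # estimate units/day per TCA agent from that agent's own refill pattern
    tca_by_code: dict[str, list[DispensingClaim]] = {}
    for c in claims:
        if c.drug_class is DrugClass.AD_TCA:
            tca_by_code.setdefault(c.drug_code, []).append(c)
    dose_by_code = {code: estimate_daily_dose(cs) for code, cs in tca_by_code.items()}

    for c in claims:
        if c.drug_class is not DrugClass.AD_TCA:
            kept.append(c)
            continue
        units_per_day = dose_by_code.get(c.drug_code, 1.0)
        entry = formulary.lookup(c.drug_code, c.drug_name)
        min_dose = entry.min_antidepressant_dose_mg if entry else None
        daily_mg = c.strength_mg * units_per_day
        coverage = c.quantity_units / units_per_day
        bad_dose = min_dose is not None and daily_mg < min_dose
        short_term = coverage < short_term_days
        off_label = bool(c.icd10_codes) and not c.has_code_prefix(mood_prefixes)
        if bad_dose or short_term or off_label:
            excluded.append(c)
        else:
            kept.append(c)
    return kept, excluded


def build_cohort(
    records: Sequence[PatientRecord],
    config: CohortConfig | None = None,
) -> tuple[list[CohortAssignment], GateCounts]:
    """Run the full cascade over all patients and report per-gate counts."""
    config = config or CohortConfig()
    assignments: list[CohortAssignment] = []
    counts = GateCounts(total=len(records))
    for p in records:
        status = assess_eligibility(
            p, config.index_year, config.study_start, config.min_age, config.max_age
        )
        reasons: list[str] = []
        if status is CohortStatus.EXCLUDED_AGE:
            reasons.append("outside the 18-40 age window over the follow-up")
        elif status is CohortStatus.EXCLUDED_NO_INDEX_CLAIM:
            reasons.append("no index-class claim during the index year")
        elif exclude_flumazenil_only(p):
            status = CohortStatus.EXCLUDED_FLUMAZENIL_ONLY
            reasons.append("flumazenil was the only index-class drug and no F90 code present")
        group = DiagnosticGroup.NOT_ASSIGNED
        if status is CohortStatus.INCLUDED:
            group = assign_diagnostic_group(p)
            reasons.append(
                "F90-family diagnostic code on record"
                if group is DiagnosticGroup.F90
                else "no F90-family diagnostic code on record"
            )
        assignments.append(CohortAssignment(p.patient_id, status, group, tuple(reasons)))
    tally = Counter(a.status for a in assignments)
    counts.excluded_age = tally[CohortStatus.EXCLUDED_AGE]
    counts.excluded_no_index_claim = tally[CohortStatus.EXCLUDED_NO_INDEX_CLAIM]
    counts.excluded_flumazenil_only = tally[CohortStatus.EXCLUDED_FLUMAZENIL_ONLY]
    counts.included = tally[CohortStatus.INCLUDED]
    return assignments, counts
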