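"""Monthly medicine plotting: consolidated issuance grids and TAG criteria.

Dispensing events are consolidated into a per-patient, per-drug-type grid over
the 60 study months (2012-01 … 2016-12).  Two months occasionally hold two
refills because a patient collected a few days early or late; two
reassignment rules move such a claim into an adjacent empty month when the
surrounding pattern supports it, so the grid reflects monthly usage without
altering the underlying dispensing records.  The treatment-adherent group
(TAG) is then classified from the grid: at least 12 monthly issues of either
drug type over the five years and at least 7 within some 12-month span.
"""

from __future__ import annotations

import datetime as dt
import enum
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .claims_io import (
    ANTIDEPRESSANT_CLASSES,
    DispensingClaim,
    DrugClass,
    PatientRecord,
)

__all__ = [
    "DrugType",
    "MonthCell",
    "MonthlyPlot",
    "ReassignRule",
    "ReassignmentDecision",
    "TagClassification",
    "PlotConfig",
    "days_between",
    "estimate_daily_dose",
    "month_index",
    "drug_type_of",
    "build_monthly_grid",
    "classify_tag",
    "DOSE_SNAP_VALUES",
]


class DrugType(str, enum.Enum):
    """The two plotted therapy types: methylphenidate and antidepressants."""

    MPH = "MPH"
    AD = "AD"


def drug_type_of(drug_class: DrugClass) -> Optional[DrugType]:
    """Map a formulary class to its plotted therapy type.

    Atomoxetine, flumazenil and unclassified drugs are not plotted (ATX use
    was negligible in the source population and is excluded from analysis).
    """
    if drug_class is DrugClass.MPH:
        return DrugType.MPH
    if drug_class in ANTIDEPRESSANT_CLASSES:
        return DrugType.AD
    return None


@dataclass
class PlotConfig:
    study_start: dt.date = dt.date(2012, 1, 1)
    study_end: dt.date = dt.date(2016, 12, 31)
    rule1_min_gap_days: int = 21
    rule2_tolerance: float = 0.20
    short_supply_days: int = 14
    tag_policy: str = "AND"  # "AND" or "OR"
    tag_total_min: int = 12
    tag_window_min: int = 7
    tag_window_months: int = 12

    @property
    def n_months(self) -> int:
        return (
            (self.study_end.year - self.study_start.year) * 12
            + self.study_end.month
            - self.study_start.month
            + 1
        )


def days_between(d1: dt.date, d2: dt.date) -> int:
    """Start-exclusive calendar-day difference ``d2 - d1``."""
    if d1 > d2:
        raise ValueError(f"d1 {d1} is after d2 {d2}")
    return (d2 - d1).days


def month_index(when: dt.date, study_start: dt.date) -> int:
    return (when.year - study_start.year) * 12 + when.month - study_start.month


#: Daily doses (units/day) considered plausible when snapping the
#: quantity/gap ratio; anything else falls back to the one-unit-per-day default.
DOSE_SNAP_VALUES = (0.5, 1.0, 1.5, 2.0, 3.0)


def estimate_daily_dose(claims: Sequence[DispensingClaim]) -> float:
    """Approximate daily dose (units/day) for a same-drug claim stream.

    The default of one unit per day is assumed unless the refill pattern gives
    evidence of a logical alternative: at least two consecutive gaps, a stable
    gap length (at least half the gaps within ±25% of the median gap), and a
    quantity/gap ratio within ±20% of one of the plausible snap values.
    """
    if len(claims) < 3:
        return 1.0
    dates = sorted(c.dispense_date for c in claims)
    gaps = [(b - a).days for a, b in zip(dates, dates[1:]) if (b - a).days > 0]
    if len(gaps) < 2:
        return 1.0
    med_gap = statistics.median(gaps)
    stable = sum(abs(g - med_gap) <= 0.25 * med_gap for g in gaps)
    if stable < len(gaps) / 2:
        return 1.0
    med_qty = statistics.median(c.quantity_units for c in claims)
    ratio = med_qty / med_gap
    candidate = min(DOSE_SNAP_VALUES, key=lambda v: abs(v - ratio))
    if abs(ratio - candidate) <= 0.20 * candidate:
        return candidate
    return 1.0


class ReassignRule(str, enum.Enum):
    RULE1 = "RULE1"
    RULE2 = "RULE2"
    NONE = "NONE"


@dataclass(frozen=True)
class ReassignmentDecision:
    patient_id: str
    drug_type: DrugType
    claim: DispensingClaim
    original_month: int
    assigned_month: int
    rule: ReassignRule
    rationale: str


@dataclass
class MonthCell:
    units_assigned: int = 0
    short_supply_flag: bool = False
    reassigned: bool = False
    n_issues: int = 0  # non-short-supply issues assigned to the month

    @property
    def counts_as_issue(self) -> bool:
        return self.n_issues > 0


@dataclass
class MonthlyPlot:
    patient_id: str
    drug_type: DrugType
    months: list[MonthCell]
    decisions: list[ReassignmentDecision] = field(default_factory=list)

    @property
    def total_units(self) -> int:
        return sum(c.units_assigned for c in self.months)

    def issue_months(self) -> list[bool]:
        return [c.counts_as_issue for c in self.months]


@dataclass(frozen=True)
class TagClassification:
    patient_id: str
    tag: bool
    total_monthly_issues: int
    max_issues_in_any_12_months: int


def _modal_signature(claims: Sequence[DispensingClaim]):
    sigs = [(c.drug_code, c.strength_mg, c.quantity_units) for c in claims]
    return max(set(sigs), key=sigs.count) if sigs else None


def build_monthly_grid(
    patient: PatientRecord,
    drug_type: DrugType,
    config: PlotConfig | None = None,
    *,
    claims: Sequence[DispensingClaim] | None = None,
) -> MonthlyPlot:
    """Consolidate a patient's claims of one therapy type into the month grid.

    ``claims`` overrides the patient's own stream (used for antidepressants
    after the tricyclic-misuse filter).  Claims whose implied coverage is
    below ``short_supply_days`` are flagged so a short supply is never read as
    a month of medicine coverage.
    """
    config = config or PlotConfig()
    if claims is None:
        claims = [c for c in patient.claims if drug_type_of(c.drug_class) is drug_type]
    else:
        claims = [c for c in claims if drug_type_of(c.drug_class) is drug_type]
    claims = sorted(claims, key=lambda c: c.dispense_date)
    n = config.n_months

    dose = estimate_daily_dose(claims) if claims else 1.0
    # original month assignment
    assigned: dict[int, list[DispensingClaim]] = {}
    for c in claims:
        assigned.setdefault(month_index(c.dispense_date, config.study_start), []).append(c)

    decisions: list[ReassignmentDecision] = []
    moved: dict[int, list[DispensingClaim]] = {m: list(cs) for m, cs in assigned.items()}
    reassigned_claims: set[int] = set()  # id() of moved claims

    for m in sorted(assigned):
        month_claims = moved.get(m, [])
        originals = [c for c in month_claims if id(c) not in reassigned_claims]
        if len(originals) != 2:
            continue
        first, second = sorted(originals, key=lambda c: c.dispense_date)
        decision = _try_reassign(
            patient.patient_id, drug_type, first, second, m, moved, claims, dose, config, n
        )
        if decision.rule is not ReassignRule.NONE:
            mover = decision.claim
            moved[decision.original_month].remove(mover)
            moved.setdefault(decision.assigned_month, []).append(mover)
            reassigned_claims.add(id(mover))
            decisions.append(decision)

    cells = [MonthCell() for _ in range(n)]
    for m, cs in moved.items():
        if not cs or not (0 <= m < n):
            continue
        cell = cells[m]
        cell.units_assigned = sum(c.quantity_units for c in cs)
        short = [max(1, int(c.quantity_units // dose)) < config.short_supply_days for c in cs]
        cell.short_supply_flag = all(short)
        cell.n_issues = sum(1 for s in short if not s)
        cell.reassigned = any(id(c) in reassigned_claims for c in cs)
    return MonthlyPlot(patient.patient_id, drug_type, cells, decisions)


def _try_reassign(
    patient_id, drug_type, first, second, m, moved, all_claims, dose, config, n_months
) -> ReassignmentDecision:
    gap = days_between(first.dispense_date, second.dispense_date)
    prev_empty = m - 1 >= 0 and not moved.get(m - 1)
    next_empty = m + 1 < n_months and not moved.get(m + 1)

    # Rule 1: wide-gapped double month next to an empty month, stable pattern.
    if gap >= config.rule1_min_gap_days and (prev_empty or next_empty):
        window = [
            c
            for c in all_claims
            if abs(month_index(c.dispense_date, config.study_start) - m) <= 3
        ]
        modal = _modal_signature(window)
        sig_first = (first.drug_code, first.strength_mg, first.quantity_units)
        sig_second = (second.drug_code, second.strength_mg, second.quantity_units)
        if modal is not None and sig_first == modal and sig_second == modal:
            if next_empty:
                return ReassignmentDecision(
                    patient_id, drug_type, second, m, m + 1, ReassignRule.RULE1,
                    f"gap {gap}d >= {config.rule1_min_gap_days}, following month empty, "
                    "stable drug/strength/quantity pattern",
                )
            return ReassignmentDecision(
                patient_id, drug_type, first, m, m - 1, ReassignRule.RULE1,
                f"gap {gap}d >= {config.rule1_min_gap_days}, preceding month empty, "
                "stable drug/strength/quantity pattern",
            )

    # Rule 2: units-to-days ratio over the window matches the regular dose.
    window = [
        c
        for c in all_claims
        if abs(month_index(c.dispense_date, config.study_start) - m) <= 3
    ]
    if len(window) >= 3 and next_empty:
        dates = [c.dispense_date for c in window]
        span = days_between(min(dates), max(dates))
        if span > 0:
            implied = sum(c.quantity_units for c in window[:-1]) / span
            if abs(implied - dose) <= config.rule2_tolerance * dose:
                return ReassignmentDecision(
                    patient_id, drug_type, second, m, m + 1, ReassignRule.RULE2,
                    f"regular trend: window units/days {implied:.2f} within "
                    f"±{config.rule2_tolerance:.0%} of daily dose {dose}",
                )
    return ReassignmentDecision(
        patient_id, drug_type, second, m, m, ReassignRule.NONE, "no rule applicable"
    )


def classify_tag(
    plots: Iterable[MonthlyPlot],
    config: PlotConfig | None = None,
) -> TagClassification:
    """Classify one patient's treatment-adherent-group membership.

    A month counts as a monthly issue when any drug type has a non-short-supply
    issue in it; a month supplied with both therapy types counts once.  Under
    the default AND policy both criteria (total and rolling-window) must hold.
    """
    config = config or PlotConfig()
    plots = list(plots)
    if not plots:
        raise ValueError("classify_tag requires at least one monthly plot")
    pid = plots[0].patient_id
    n = config.n_months
    joint = [False] * n
    for p in plots:
        for i, is_issue in enumerate(p.issue_months()):
            joint[i] = joint[i] or is_issue
    total = sum(joint)
    w = config.tag_window_months
    window_max = 0
    for i in range(max(1, n - w + 1)):
        window_max = max(window_max, sum(joint[i : i + w]))
    meets_total = total >= config.tag_total_min
    meets_window = window_max >= config.tag_window_min
    if config.tag_policy.upper() == "OR":
        tag = meets_total or meets_window
    else:
        tag = meets_total and meets_window
    return TagClassification(pid, tag, total, window_max)
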