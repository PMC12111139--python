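"""Proportion-of-days-covered engine: assessment periods, PDC and PDD.

Refill streams are segmented left-to-right into assessment periods anchored
on issue dates.  The nominal period is 90 days, adjusted by the observed
filling trend:

* **over 90** — coverage of the in-window issues runs past the nominal end;
  the period extends to the next actual issue date (91–119 days);
* **up to 119** — no further issue exists and the final issue's calculated
  supply end falls between 91 and 119 days after the period start;
* **120–129** — the next issue of a regular pattern lands 120–129 days after
  the start and closes the period there;
* **less than 90** — a calendar month inside the window holds no issue while
  the following period opens slightly before the nominal end with at least 60
  covered days; the period closes early at that issue;
* **database end** — a terminal period is truncated at the day after the last
  study day, since later refills are unobservable.

Refill gaps longer than 129 days (drug holidays, discontinuation) close the
running episode terminal-style and open a fresh period at the next issue, so
an intentional break is not scored as non-adherence.  PDC per period is the
union of supply days clipped to the period; average PDC per patient and drug
type is the unweighted mean over that patient's periods.  The prescribed
daily dose (PDD) is total milligrams dispensed over total days covered.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .claims_io import DispensingClaim
from .monthly_plot import days_between, estimate_daily_dose

__all__ = [
    "CoverageInterval",
    "AssessmentPeriod",
    "PeriodRule",
    "PddResult",
    "PdcConfig",
    "predict_next_supply",
    "coverage_intervals",
    "segment_periods",
    "covered_days",
    "average_pdc",
    "compute_pdd",
    "assess_drug_type",
]


@dataclass(frozen=True)
class CoverageInterval:
    """A dispensing event as a half-open supply interval [start, start+supply)."""

    start: dt.date
    supply_days: int
    drug_code: str = ""
    strength_mg: float = 0.0
    quantity_units: int = 0

    def __post_init__(self):
        if self.supply_days < 1:
            raise ValueError("supply_days must be >= 1")

    @property
    def end(self) -> dt.date:
        return self.start + dt.timedelta(days=self.supply_days)


class PeriodRule(str, enum.Enum):
    STANDARD_90 = "STANDARD_90"
    OVER_90 = "OVER_90"
    UP_TO_119 = "UP_TO_119"
    RULE_120_129 = "RULE_120_129"
    LESS_THAN_90 = "LESS_THAN_90"
    DATABASE_END = "DATABASE_END"


@dataclass(frozen=True)
class AssessmentPeriod:
    start: dt.date
    end: dt.date
    covered: int
    rule: PeriodRule
    rationale: str = ""

    @property
    def duration_days(self) -> int:
        return days_between(self.start, self.end)

    @property
    def pdc(self) -> float:
        return self.covered / self.duration_days


@dataclass(frozen=True)
class PddResult:
    patient_id: str
    drug_type: str
    total_mg: float
    covered_days: int
    pdd_mg_per_day: float
    ratio_to_ddd: Optional[float] = None


@dataclass
class PdcConfig:
    standard_days: int = 90
    extended_max_days: int = 119      # "up to 119" ceiling
    far_issue_max_days: int = 129     # "120-129" ceiling; also the period cap
    lt90_min_next_coverage: int = 60
    lt90_proximity_days: int = 14     # "slightly before" the nominal end
    cap_pdc: bool = False
    database_end: dt.date = dt.date(2017, 1, 1)


def predict_next_supply(issue_date: dt.date, supply_days: int) -> dt.date:
    """Calculated proceeding supply date: issue date plus days of supply."""
    return issue_date + dt.timedelta(days=max(1, supply_days))


def coverage_intervals(
    claims: Sequence[DispensingClaim], units_per_day: float | None = None
) -> list[CoverageInterval]:
    """Convert a same-drug-type claim stream into supply intervals.

    ``units_per_day`` defaults to the dose estimated from the stream itself;
    supply length is quantity over dose, floored, minimum one day.  The
    days-supply field on the claim is deliberately not used.
    """
    claims = sorted(claims, key=lambda c: c.dispense_date)
    if units_per_day is None:
        units_per_day = estimate_daily_dose(claims) if claims else 1.0
    out = []
    for c in claims:
        supply = max(1, int(c.quantity_units // units_per_day))
        out.append(
            CoverageInterval(
                start=c.dispense_date,
                supply_days=supply,
                drug_code=c.drug_code,
                strength_mg=c.strength_mg,
                quantity_units=c.quantity_units,
            )
        )
    return out


def covered_days(start: dt.date, end: dt.date, issues: Sequence[CoverageInterval]) -> int:
    """Size of the union of supply day-sets clipped to [start, end).

    Overlapping supplies never double-count a day.
    """
    if end <= start:
        return 0
    spans = []
    for iv in issues:
        s, e = max(iv.start, start), min(iv.end, end)
        if e > s:
            spans.append((s, e))
    spans.sort()
    total = 0
    cur_s: Optional[dt.date] = None
    cur_e: Optional[dt.date] = None
    for s, e in spans:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += (cur_e - cur_s).days
            cur_s, cur_e = s, e
        elif e > cur_e:
            cur_e = e
    if cur_e is not None:
        total += (cur_e - cur_s).days
    return total


def _months_with_issue(issues: Sequence[CoverageInterval]) -> set[tuple[int, int]]:
    return {(iv.start.year, iv.start.month) for iv in issues}


def _month_span(start: dt.date, end: dt.date):
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        yield (y, m)
        m += 1
        if m == 13:
            y, m = y + 1, 1


def _regular_pattern(issues: Sequence[CoverageInterval]) -> bool:
    sigs = {(iv.drug_code, iv.strength_mg, iv.quantity_units) for iv in issues}
    return len(sigs) == 1


def segment_periods(
    issues: Sequence[CoverageInterval],
    config: PdcConfig | None = None,
) -> list[AssessmentPeriod]:
    """Greedy left-to-right segmentation of a supply stream into periods.

    Every issue belongs to exactly one period; rule precedence is
    database-end > less-than-90 > 120–129 > up-to-119 > over-90 > standard 90.
    """
    config = config or PdcConfig()
    issues = sorted(issues, key=lambda iv: iv.start)
    if not issues:
        return []
    all_months = _months_with_issue(issues)
    periods: list[AssessmentPeriod] = []
    i = 0
    n = len(issues)
    while i < n:
        start = issues[i].start
        nominal_end = start + dt.timedelta(days=config.standard_days)
        j = i
        while j < n and issues[j].start < nominal_end:
            j += 1
        window = issues[i:j]
        cov_end = max(iv.end for iv in window)
        nxt = issues[j] if j < n else None

        period, next_i = _close_period(
            start, nominal_end, cov_end, window, nxt, j, issues, all_months, config
        )
        periods.append(period)
        i = next_i
    return periods


def _close_period(start, nominal_end, cov_end, window, nxt, j, issues, all_months, config):
    """Pick the period end and rule; return (period, index of next period's first issue)."""
    cap_end = start + dt.timedelta(days=config.extended_max_days)

    # Less-than-90: an empty month inside the window, with the next episode
    # opening slightly before the nominal end and at least 60 days covered.
    if len(window) >= 2:
        empty_month = any(
            (y, m) not in all_months for (y, m) in _month_span(start, nominal_end - dt.timedelta(days=1))
        )
        candidate = window[-1]
        near_end = candidate.start >= nominal_end - dt.timedelta(days=config.lt90_proximity_days)
        if empty_month and near_end and candidate.start > start:
            tent_end = candidate.start + dt.timedelta(days=config.standard_days)
            tail = [iv for iv in issues if candidate.start <= iv.start < tent_end]
            if covered_days(candidate.start, tent_end, tail) >= config.lt90_min_next_coverage:
                idx = issues.index(candidate)
                period = _finalise(
                    start, candidate.start, window[:-1] if window[-1] is candidate else window,
                    PeriodRule.LESS_THAN_90,
                    "month without issue inside window; next period opens slightly "
                    "before the nominal end with >= "
                    f"{config.lt90_min_next_coverage} covered days",
                    config,
                )
                return period, idx

    if nxt is not None:
        d_next = days_between(start, nxt.start)
        if d_next <= config.standard_days:
            return _finalise(start, nxt.start, window, PeriodRule.STANDARD_90,
                             "standard duration to next issue", config), j
        if d_next <= config.extended_max_days:
            return _finalise(
                start, nxt.start, window, PeriodRule.OVER_90,
                f"next issue {d_next} days after period start", config), j
        if d_next <= config.far_issue_max_days and _regular_pattern(list(window) + [nxt]):
            return _finalise(
                start, nxt.start, window, PeriodRule.RULE_120_129,
                f"regular pattern; next issue at {d_next} days closes the period",
                config), j

    # Terminal-style close: no next issue, or the next issue is too far away
    # (a refill gap / drug holiday) to belong to this period.
    end = max(nominal_end, min(cov_end, cap_end))
    rule = PeriodRule.UP_TO_119 if end > nominal_end else PeriodRule.STANDARD_90
    why = "calculated supply end sets the duration" if end > nominal_end else "standard 90-day duration"
    if end > config.database_end:
        end, rule = config.database_end, PeriodRule.DATABASE_END
        why = "truncated at the end of observable records"
    elif nxt is not None:
        why += f"; next issue {days_between(start, nxt.start)} days away opens a new episode"
    return _finalise(start, end, window, rule, why, config), j


def _finalise(start, end, window, rule, why, config) -> AssessmentPeriod:
    cov = covered_days(start, end, window)
    if config.cap_pdc:
        cov = min(cov, days_between(start, end))
    return AssessmentPeriod(start=start, end=end, covered=cov, rule=rule, rationale=why)


def average_pdc(periods: Sequence[AssessmentPeriod]) -> Optional[float]:
    """Unweighted mean of per-period PDC values; None when no period exists."""
    if not periods:
        return None
    return sum(p.pdc for p in periods) / len(periods)


def compute_pdd(
    claims: Sequence[DispensingClaim],
    covered_days_total: int,
    *,
    patient_id: str = "",
    drug_type: str = "MPH",
    ddd_mg: Optional[float] = None,
) -> Optional[PddResult]:
    """Prescribed daily dose: total milligrams over total days of cover."""
    if covered_days_total <= 0 or not claims:
        return None
    total_mg = sum(c.total_mg for c in claims)
    pdd = total_mg / covered_days_total
    return PddResult(
        patient_id=patient_id,
        drug_type=drug_type,
        total_mg=total_mg,
        covered_days=covered_days_total,
        pdd_mg_per_day=pdd,
        ratio_to_ddd=(pdd / ddd_mg) if ddd_mg else None,
    )


def assess_drug_type(
    claims: Sequence[DispensingClaim],
    config: PdcConfig | None = None,
) -> tuple[list[AssessmentPeriod], Optional[float], int]:
    """Segment one patient's claims of a single drug type.

    Returns (periods, average PDC, total covered days across periods).
    """
    config = config or PdcConfig()
    intervals = coverage_intervals(claims)
    periods = segment_periods(intervals, config)
    total_cov = sum(p.covered for p in periods)
    return periods, average_pdc(periods), total_cov
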