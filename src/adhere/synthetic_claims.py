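"""Seeded synthetic dispensing-claims generator.

The generator emulates the statistical structure of a five-year (2012–2016)
medical-aid dispensing stream for an adult ADHD population: monthly
methylphenidate refills with jitter, antidepressant co-therapy, drug-holiday
blocks, discontinuation, long-tailed irregular use, ICD-10 F90 coding that is
absent in 2012–2013, a days-supply field present only for 2016 claims, and
decoy patients the cohort gates must remove (under-age, flumazenil-only) or
whose tricyclic issuances the misuse filter must drop.  Every patient carries
ground-truth labels (archetype, diagnostic group, TAG intent, intended mean
PDC, intended PDD) so the whole pipeline is testable without external data.

Determinism: a cohort is a pure function of (spec, seed); per-patient
substreams are keyed on (seed, patient index) so adding patients never
perturbs earlier ones.
"""

from __future__ import annotations

import datetime as dt
import enum
import io
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .claims_io import CLAIMS_COLUMNS, Formulary, ReadResult, read_claims

__all__ = [
    "Archetype",
    "DecoyType",
    "CohortSpec",
    "generate_cohort",
    "worked_example_fixture",
    "frame_to_records",
    "simulate_tag_design",
]

STUDY_START = dt.date(2012, 1, 1)
STUDY_END = dt.date(2016, 12, 31)


class Archetype(str, enum.Enum):
    REGULAR = "REGULAR"
    IRREGULAR = "IRREGULAR"
    HOLIDAY = "HOLIDAY"
    DISCONTINUER = "DISCONTINUER"
    AD_DOMINANT = "AD_DOMINANT"


class DecoyType(str, enum.Enum):
    NONE = "NONE"
    UNDERAGE = "UNDERAGE"
    FLUMAZENIL_ONLY = "FLUMAZENIL_ONLY"
    TCA_SUBTHERAPEUTIC = "TCA_SUBTHERAPEUTIC"


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the source population: 89 analysable patients plus the
    8 under-age and 23 flumazenil-only records removed by the gates, an
    F90 : non-F90 mix of 50 : 39, antidepressant co-therapy in roughly 40%
    of the F90 and a third of the non-F90 group, a TAG fraction near 32/89,
    and a methylphenidate prescribed daily dose of about 30 mg.
    """

    n_patients: int = 89
    seed: int = 0
    group_mix: dict[str, float] = field(
        default_factory=lambda: {"F90": 50 / 89, "NON_F90": 39 / 89}
    )
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "REGULAR": 0.20,
            "HOLIDAY": 0.08,
            "AD_DOMINANT": 0.08,
            "IRREGULAR": 0.40,
            "DISCONTINUER": 0.24,
        }
    )
    ad_cotherapy_prob: dict[str, float] = field(
        default_factory=lambda: {"F90": 0.40, "NON_F90": 0.33}
    )
    refill_jitter_days: int = 3
    missing_icd_years: frozenset[int] = frozenset({2012, 2013})
    n_underage: int = 8
    n_flumazenil_only: int = 23
    n_tca_subtherapeutic: int = 5
    mph_pdd_mg_per_day: float = 30.0  # one extended-release unit per day

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, mix in (("group_mix", self.group_mix), ("archetype_mix", self.archetype_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} proportions must be non-negative")


def _month_date(idx: int, day: int) -> dt.date:
    year = STUDY_START.year + idx // 12
    month = idx % 12 + 1
    # clamp to month length
    for d in (day, 28):
        try:
            return dt.date(year, month, d)
        except ValueError:
            continue
    raise AssertionError("unreachable")


def _claim_row(pid, gender, birth, when, code, name, strength, qty, icd, missing_years):
    year = when.year
    codes = "" if year in missing_years else icd
    # days-supply only recorded for 2016 claims, as in the source database
    days_supply = str(qty) if year == 2016 else ""
    return {
        "patient_id": pid,
        "gender": gender,
        "birth_date": birth.isoformat(),
        "dispense_date": when.isoformat(),
        "drug_code": code,
        "drug_name": name,
        "strength_mg": str(int(strength)) if float(strength).is_integer() else repr(float(strength)),
        "quantity_units": str(qty),
        "days_supply": days_supply,
        "icd10_codes": codes,
    }


def _mph_months(rng, archetype: Archetype) -> list[int]:
    """Month indices (0 = 2012-01) carrying a methylphenidate refill."""
    if archetype is Archetype.REGULAR:
        start = int(rng.integers(0, 6))            # near-continuous refiller
        return list(range(start, 60))
    if archetype is Archetype.HOLIDAY:
        # two one-month treatment interruptions per year (Jan and Jul)
        return [m for m in range(12, 60) if m % 12 not in (0, 6)]
    if archetype is Archetype.DISCONTINUER:
        start = int(rng.integers(36, 39))          # early 2015
        length = int(rng.integers(8, 11))          # stops short of 12 issues
        return list(range(start, start + length))
    if archetype is Archetype.IRREGULAR:
        k = int(rng.integers(4, 9))
        months = set(rng.choice(np.arange(24, 60), size=k, replace=False).tolist())
        months.add(int(rng.integers(36, 48)))      # at least one index-year claim
        return sorted(months)
    if archetype is Archetype.AD_DOMINANT:
        return list(range(30, 60, 3))              # quarterly 90-day scripts
    raise ValueError(archetype)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (claims table, ground-truth labels) for one cohort."""
    spec.validate()
    rows: list[dict] = []
    labels: list[dict] = []
    groups = list(spec.group_mix)
    gprobs = [spec.group_mix[g] for g in groups]
    archetypes = list(spec.archetype_mix)
    aprobs = [spec.archetype_mix[a] for a in archetypes]
    jitter = spec.refill_jitter_days
    # monthly 30-unit scripts taken one unit per day (schedule-6 monthly
    # prescriptions); quarterly 90-unit scripts for the AD-dominant archetype
    mph_strength = spec.mph_pdd_mg_per_day

    decoys = (
        [DecoyType.NONE] * spec.n_patients
        + [DecoyType.UNDERAGE] * spec.n_underage
        + [DecoyType.FLUMAZENIL_ONLY] * spec.n_flumazenil_only
        + [DecoyType.TCA_SUBTHERAPEUTIC] * spec.n_tca_subtherapeutic
    )

    for idx, decoy in enumerate(decoys):
        rng = np.random.default_rng([spec.seed % (2**31), idx])
        pid = f"P{idx:04d}"
        gender = "F" if rng.random() < 0.5 else "M"
        if decoy is DecoyType.UNDERAGE:
            # 17 years old on the first study day
            age_2012 = float(rng.uniform(16.6, 17.9))
        else:
            age_2012 = float(rng.uniform(18.3, 35.5))
        birth = STUDY_START - dt.timedelta(days=int(age_2012 * 365.25) + 1)
        group = groups[int(rng.choice(len(groups), p=gprobs))]
        archetype = Archetype(archetypes[int(rng.choice(len(archetypes), p=aprobs))])
        anchor = int(rng.integers(8, 22))

        if decoy is DecoyType.FLUMAZENIL_ONLY:
            group = "NON_F90"
            n_claims = int(rng.integers(1, 4))
            for _ in range(n_claims):
                when = dt.date(2015, int(rng.integers(1, 13)), int(rng.integers(1, 28)))
                rows.append(
                    _claim_row(pid, gender, birth, when, "FLZ-05", "flumazenil",
                               0.5, 2, "", spec.missing_icd_years)
                )
            labels.append(_label(pid, archetype, decoy, group, False, 0.0, 0.0,
                                 "EXCLUDED_FLUMAZENIL_ONLY"))
            continue

        if decoy is DecoyType.TCA_SUBTHERAPEUTIC:
            archetype = Archetype.DISCONTINUER
        tag_intent = archetype in (Archetype.REGULAR, Archetype.HOLIDAY, Archetype.AD_DOMINANT)
        f90 = group == "F90"

        mph_months = _mph_months(rng, archetype)
        quarterly = archetype is Archetype.AD_DOMINANT
        if archetype is Archetype.REGULAR and jitter == 0:
            # perfect refills: exact 30-day cycles, no coverage gaps at all
            first = _month_date(mph_months[0], anchor)
            mph_dates = []
            d = first
            while d <= STUDY_END:
                mph_dates.append(d)
                d += dt.timedelta(days=30)
        else:
            mph_dates = []
            for m in mph_months:
                day = anchor + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
                mph_dates.append(_month_date(m, max(1, min(27, day))))
        for when in mph_dates:
            qty = 90 if quarterly else 30
            rows.append(
                _claim_row(pid, gender, birth, when, "MPH-LA", "methylphenidate extended-release",
                           mph_strength, qty, "F90.0" if f90 else "",
                           spec.missing_icd_years)
            )

        has_ad = quarterly or (rng.random() < spec.ad_cotherapy_prob.get(group, 0.0))
        if has_ad:
            if quarterly:
                ad_dates = []
                for m in range(30, 54):
                    day = anchor + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
                    ad_dates.append(_month_date(m, max(1, min(27, day))))
            else:
                # co-dispensed at the same visits as methylphenidate
                ad_dates = mph_dates
            for when in ad_dates:
                rows.append(
                    _claim_row(pid, gender, birth, when, "FLX-20", "fluoxetine",
                               20, 30, "F32.1", spec.missing_icd_years)
                )

        if decoy is DecoyType.TCA_SUBTHERAPEUTIC:
            # sub-therapeutic short amitriptyline courses coded to a non-mood
            # diagnosis: the tricyclic-misuse filter must drop these
            for m in sorted(rng.choice(np.arange(36, 48), size=3, replace=False).tolist()):
                when = _month_date(m, max(1, min(27, anchor + 2)))
                rows.append(
                    _claim_row(pid, gender, birth, when, "AMI-25", "amitriptyline",
                               25, 30, "M79.2", spec.missing_icd_years)
                )

        status = "EXCLUDED_AGE" if decoy is DecoyType.UNDERAGE else "INCLUDED"
        if decoy is DecoyType.UNDERAGE:
            tag_intent = False
        pdc_intent = {
            Archetype.REGULAR: 1.0,
            Archetype.HOLIDAY: 0.85,
            Archetype.DISCONTINUER: 1.0,
            Archetype.IRREGULAR: 0.40,
            Archetype.AD_DOMINANT: 1.0,
        }[archetype]
        labels.append(
            _label(pid, archetype, decoy, group, tag_intent, pdc_intent,
                   spec.mph_pdd_mg_per_day, status)
        )

    claims = pd.DataFrame(rows, columns=list(CLAIMS_COLUMNS))
    claims = claims.sort_values(
        ["patient_id", "dispense_date", "drug_code"], kind="mergesort"
    ).reset_index(drop=True)
    labels_df = pd.DataFrame(labels)
    return claims, labels_df


def _label(pid, archetype, decoy, group, tag_intent, pdc_intent, pdd_intent, status):
    return {
        "patient_id": pid,
        "archetype": archetype.value,
        "decoy": decoy.value,
        "group": group,
        "tag_intent": bool(tag_intent),
        "true_mean_pdc": float(pdc_intent),
        "true_pdd_mg": float(pdd_intent),
        "status_intent": status,
    }


def frame_to_records(claims: pd.DataFrame, formulary: Formulary) -> ReadResult:
    """Round-trip a claims frame through the canonical reader."""
    buf = io.StringIO()
    claims.to_csv(buf, index=False)
    buf.seek(0)
    return read_claims(buf, formulary)


# ---------------------------------------------------------------------------
# Worked-example fixture: the six period-segmentation scenarios, as published
# dispensing dates, one patient per scenario.
# ---------------------------------------------------------------------------

_WORKED_STREAMS: dict[str, list[str]] = {
    # over-90: coverage overruns the nominal end; 97-day period
    "WX-A": ["2014-01-16", "2014-02-18", "2014-03-20", "2014-04-23"],
    # up-to-119: delayed refill, no further issue; 118-day period
    "WX-B": ["2014-08-03", "2014-10-30"],
    # 120-129: regular pattern with a late fourth issue; 125-day period
    "WX-C": ["2015-04-28", "2015-06-03", "2015-07-03", "2015-08-31"],
    # less-than-90: an empty month closes the period early at 82 days,
    # the following period covering 60 of 91 days
    "WX-D": ["2013-02-25", "2013-04-13", "2013-05-18", "2013-06-27", "2013-08-17"],
    # database end: 60-day terminal period with 57 covered days
    "WX-E": ["2016-11-02", "2016-12-05"],
}


def worked_example_fixture() -> pd.DataFrame:
    """Deterministic miniature cohort of the worked segmentation examples.

    Each patient dispenses 30 units of 10 mg methylphenidate at one unit per
    day on the listed dates.
    """
    rows = []
    birth = dt.date(1985, 6, 15)
    for i, (pid, dates) in enumerate(sorted(_WORKED_STREAMS.items())):
        gender = "F" if i % 2 == 0 else "M"
        for d in dates:
            rows.append(
                _claim_row(pid, gender, birth, dt.date.fromisoformat(d),
                           "MPH-IR", "methylphenidate", 10, 30, "", frozenset())
            )
    return pd.DataFrame(rows, columns=list(CLAIMS_COLUMNS))


def simulate_tag_design(
    n: int,
    seed: int,
    or_ad: float = 20.0,
    or_null: float = 1.0,
    intercept: float = -1.5,
) -> pd.DataFrame:
    """Simulate a per-patient covariate table with a known adherence model.

    The binary outcome follows logit(p) = intercept + ln(or_ad)*ad +
    ln(or_null)*null_cov; used for parameter-recovery checks of the TAG
    logistic fit.
    """
    rng = np.random.default_rng(seed)
    ad = rng.integers(0, 2, size=n)
    null_cov = rng.integers(0, 2, size=n)
    eta = intercept + np.log(or_ad) * ad + np.log(or_null) * null_cov
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.random(n) < p
    return pd.DataFrame({"ad_cotherapy": ad.astype(bool),
                         "null_cov": null_cov.astype(bool),
                         "tag": y})
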