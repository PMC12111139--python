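import datetime as dt

import pytest

from adhere.claims_io import DispensingClaim, DrugClass, Formulary, PatientRecord
from adhere.synthetic_claims import frame_to_records, worked_example_fixture


@pytest.fixture(scope="session")
def formulary():
    return Formulary.default()


@pytest.fixture(scope="session")
def worked_records(formulary):
    """The worked-example refill streams, one patient per scenario."""
    result = frame_to_records(worked_example_fixture(), formulary)
    assert not result.rejects
    return {r.patient_id: r for r in result.records}


def make_claim(
    pid="P1",
    date=dt.date(2015, 3, 10),
    code="MPH-LA",
    name="methylphenidate extended-release",
    drug_class=DrugClass.MPH,
    strength=30.0,
    qty=30,
    icd=(),
):
    return DispensingClaim(
        patient_id=pid,
        dispense_date=date,
        drug_code=code,
        drug_name=name,
        strength_mg=strength,
        quantity_units=qty,
        drug_class=drug_class,
        icd10_codes=tuple(icd),
    )


def make_patient(pid="P1", gender="F", birth=dt.date(1988, 4, 2), claims=()):
    claims = sorted(claims, key=lambda c: c.dispense_date)
    return PatientRecord(patient_id=pid, gender=gender, birth_date=birth, claims=list(claims))


def monthly_claims(pid, year_month_pairs, day=14, **kw):
    """One claim on the given day of each (year, month)."""
    return [
        make_claim(pid=pid, date=dt.date(y, m, day), **kw) for (y, m) in year_month_pairs
    ]
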