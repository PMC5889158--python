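import numpy as np
import pandas as pd
import pytest

from rheumclaims.io import ClaimsBundle, canonicalize_table, validate_bundle
from rheumclaims.codes import BDMARD_CODES, CSDMARD_CODES, ORAL_GC_CODES
from rheumclaims.pipeline import run_all


class BundleBuilder:
    """Hand-build tiny, valid claims bundles for unit scenarios."""

    def __init__(self):
        self._enr, self._cat, self._med, self._rx = [], [], [], []

    def patient(self, pid, birth="1960-01-01", sex="female",
                coverage=(("2009-01-01", "2013-12-31"),), death=None,
                card="2009-06-01", card_code="7140"):
        for s, e in coverage:
            self._enr.append(dict(
                patient_id=pid, birth_date=pd.Timestamp(birth), sex=sex,
                coverage_start=pd.Timestamp(s), coverage_end=pd.Timestamp(e),
                death_date=pd.Timestamp(death) if death else pd.NaT,
            ))
        if card:
            self._cat.append(dict(patient_id=pid, icd9_code=card_code,
                                  effective_date=pd.Timestamp(card)))
        return self

    def visit(self, pid, date, codes="7140", setting="outpatient", end=None,
              injection=False, med_cents=0, nonmed_cents=0):
        start = pd.Timestamp(date)
        self._med.append(dict(
            patient_id=pid, setting=setting, start_date=start,
            end_date=pd.Timestamp(end) if end else start,
            diagnosis_codes=codes, is_gc_joint_injection=injection,
            medication_cost_cents=med_cents, nonmedication_cost_cents=nonmed_cents,
        ))
        return self

    def dispense(self, pid, date, drug_class="bDMARD", agent="etanercept",
                 code=None, days=28, mg=np.nan, cents=0):
        if code is None:
            if drug_class == "bDMARD":
                code = BDMARD_CODES[agent]
            elif drug_class == "csDMARD":
                code = CSDMARD_CODES["methotrexate"]
            elif drug_class == "oral_GC":
                code = ORAL_GC_CODES["prednisolone"]
            else:
                code = "X000"
        self._rx.append(dict(
            patient_id=pid, dispense_date=pd.Timestamp(date), drug_code=code,
            drug_class=drug_class,
            bdmard_agent=agent if drug_class == "bDMARD" else "",
            days_supplied=days, prednisone_equivalent_mg_total=mg,
            cost_cents=cents,
        ))
        return self

    def build(self, validate=True):
        empty = ClaimsBundle.empty()
        bundle = ClaimsBundle(
            enrollment=canonicalize_table(
                "enrollment", pd.DataFrame(self._enr)) if self._enr else empty.enrollment,
            catastrophic_illness=canonicalize_table(
                "catastrophic_illness", pd.DataFrame(self._cat)) if self._cat else empty.catastrophic_illness,
            medical_claims=canonicalize_table(
                "medical_claims", pd.DataFrame(self._med)) if self._med else empty.medical_claims,
            pharmacy_claims=canonicalize_table(
                "pharmacy_claims", pd.DataFrame(self._rx)) if self._rx else empty.pharmacy_claims,
        )
        if validate:
            validate_bundle(bundle)
        return bundle


@pytest.fixture
def builder():
    return BundleBuilder()


def standard_patient(b, pid="P1", index="2010-03-01", agent="etanercept", **kw):
    """A cohort-eligible patient: full enrollment, RA card + claims, index
    dispense with full-year coverage, background methotrexate."""
    b.patient(pid, **kw)
    b.visit(pid, "2009-09-01")
    b.dispense(pid, index, agent=agent, days=365)
    b.dispense(pid, "2009-09-15", drug_class="csDMARD")
    b.dispense(pid, pd.Timestamp(index) + pd.Timedelta(days=40), drug_class="csDMARD")
    return b


def make_cohort_row(pid="P1", index="2010-03-01", agent="etanercept",
                    birth="1960-01-01", sex="female"):
    return pd.DataFrame([dict(
        patient_id=pid, index_date=pd.Timestamp(index), index_agent=agent,
        age_at_index=50, birth_date=pd.Timestamp(birth), sex=sex,
    )])


@pytest.fixture(scope="session")
def paper_run():
    """One full preset pipeline run shared across the suite."""
    return run_all(seed=1234)
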