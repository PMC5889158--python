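import numpy as np
import pandas as pd

from rheumclaims.codes import default_code_lists
from rheumclaims.cohort import (
    apply_exclusion,
    apply_inclusion,
    build_cohort,
    check_continuous_enrollment,
    find_index_events,
)
from rheumclaims.config import StudyConfig
from rheumclaims.io import ClaimsBundle

from conftest import BundleBuilder, standard_patient

LISTS = default_code_lists()


class TestIndexEvents:
    def test_new_user_indexed_on_first_dispense(self, builder):
        b = standard_patient(builder, index="2010-03-01", agent="etanercept").build()
        events, _ = find_index_events(b)
        assert len(events) == 1
        assert events.loc[0, "index_agent"] == "etanercept"
        assert events.loc[0, "index_date"] == pd.Timestamp("2010-03-01")

    def test_prior_use_disqualifies(self, builder):
        b = standard_patient(builder, index="2010-02-01", agent="adalimumab")
        b.dispense("P1", "2009-11-01", agent="adalimumab")
        events, _ = find_index_events(b.build())
        assert events.empty

    def test_first_dispense_after_index_period(self, builder):
        b = standard_patient(builder, index="2011-01-05").build()
        events, _ = find_index_events(b)
        assert events.empty

    def test_two_agents_on_index_date_excluded_as_ambiguous(self, builder):
        b = standard_patient(builder, index="2010-05-01", agent="etanercept")
        b.dispense("P1", "2010-05-01", agent="adalimumab")
        events, att = find_index_events(b.build())
        assert events.empty
        assert att.loc[att["rule"].str.contains("unambiguous"), "n_excluded"].item() == 1


class TestInclusion:
    def _events(self, bundle):
        events, _ = find_index_events(bundle)
        return events

    def test_ra_code_and_card_retained(self, builder):
        b = standard_patient(builder).build()
        kept, _ = apply_inclusion(self._events(b), b, LISTS)
        assert len(kept) == 1

    def test_only_714_3_code_dropped(self, builder):
        b = standard_patient(BundleBuilder()).build()
        med = b.medical_claims.copy()
        med["diagnosis_codes"] = "7143"
        b = ClaimsBundle(b.enrollment, b.catastrophic_illness, med, b.pharmacy_claims)
        kept, _ = apply_inclusion(self._events(b), b, LISTS)
        assert kept.empty

    def test_missing_card_dropped(self, builder):
        b = standard_patient(builder, card=None).build()
        kept, att = apply_inclusion(self._events(b), b, LISTS)
        assert kept.empty
        assert att["n_remaining"].iloc[-1] == 0

    def test_card_after_index_dropped_by_default_but_configurable(self, builder):
        b = standard_patient(builder, card="2012-01-01").build()
        kept, _ = apply_inclusion(self._events(b), b, LISTS)
        assert kept.empty
        lax = StudyConfig(require_card_before_index=False)
        kept, _ = apply_inclusion(self._events(b), b, LISTS, lax)
        assert len(kept) == 1


class TestExclusion:
    def _included(self, bundle):
        events, _ = find_index_events(bundle)
        events, _ = apply_inclusion(events, bundle, LISTS)
        return events

    def test_age_17_excluded(self, builder):
        b = standard_patient(builder, birth="1992-06-01", index="2010-03-01").build()
        kept, att = apply_exclusion(self._included(b), b, LISTS)
        assert kept.empty
        assert att.loc[0, "rule"].startswith("aged")

    def test_age_18_retained(self, builder):
        b = standard_patient(builder, birth="1992-03-01", index="2010-03-01").build()
        kept, _ = apply_exclusion(self._included(b), b, LISTS)
        assert len(kept) == 1
        assert kept.loc[0, "age_at_index"] == 18

    def test_psoriasis_claim_years_later_excludes(self, builder):
        b = standard_patient(builder)
        b.visit("P1", "2012-07-01", codes="6961")
        kept, _ = apply_exclusion(self._included(b.build()), b.build(), LISTS)
        assert kept.empty

    def test_nonmelanoma_skin_cancer_retained(self, builder):
        b = standard_patient(builder)
        b.visit("P1", "2011-02-01", codes="1732")
        kept, _ = apply_exclusion(self._included(b.build()), b.build(), LISTS)
        assert len(kept) == 1

    def test_enrollment_gap_of_30_days_excludes(self, builder):
        # coverage break 2009-06-01..2009-06-30 inclusive = 30 uncovered days
        b = standard_patient(
            builder,
            coverage=[("2009-01-01", "2009-05-31"), ("2009-07-01", "2013-12-31")],
        ).build()
        kept, _ = apply_exclusion(self._included(b), b, LISTS)
        assert kept.empty


class TestContinuousEnrollment:
    W = (pd.Timestamp("2009-03-01"), pd.Timestamp("2010-03-01"))

    def _iv(self, *pairs):
        return [(pd.Timestamp(s), pd.Timestamp(e)) for s, e in pairs]

    def test_single_full_interval(self):
        assert check_continuous_enrollment(
            self._iv(("2009-01-01", "2013-12-31")), *self.W, 30)

    def test_29_day_gap_tolerated(self):
        iv = self._iv(("2009-01-01", "2009-05-31"), ("2009-06-30", "2013-12-31"))
        assert check_continuous_enrollment(iv, *self.W, 30)

    def test_30_day_gap_fails(self):
        iv = self._iv(("2009-01-01", "2009-05-31"), ("2009-07-01", "2013-12-31"))
        assert not check_continuous_enrollment(iv, *self.W, 30)

    def test_death_truncates_coverage(self):
        iv = self._iv(("2009-01-01", "2013-12-31"))
        assert not check_continuous_enrollment(
            iv, *self.W, 30, death_date=pd.Timestamp("2009-09-01"))


class TestFullSelection:
    def test_paper_preset_cohort_is_exactly_818(self, paper_run):
        assert len(paper_run["cohort"]) == 818

    def test_decoys_are_all_excluded_for_their_reason(self, paper_run):
        truth, cohort = paper_run["truth"], paper_run["cohort"]
        decoys = truth[truth["status"] == "excluded"]
        assert len(decoys) == 9
        assert not set(decoys["patient_id"]) & set(cohort["patient_id"])
        assert set(truth.loc[truth["status"] != "excluded", "patient_id"]) == set(
            cohort["patient_id"]
        )

    def test_attrition_monotone_and_consistent(self, paper_run):
        att = paper_run["attrition"]
        rem = att["n_remaining"].to_numpy()
        assert (np.diff(rem) <= 0).all()
        assert rem[-1] == len(paper_run["cohort"])
        # each step's counts are self-consistent
        assert ((att["n_remaining"] + att["n_excluded"]).to_numpy()[1:] == rem[:-1]).all()

    def test_shuffling_claim_rows_does_not_change_cohort(self, paper_run):
        bundle = paper_run["bundle"]
        shuffled = ClaimsBundle(
            enrollment=bundle.enrollment,
            catastrophic_illness=bundle.catastrophic_illness.sample(
                frac=1, random_state=1).reset_index(drop=True),
            medical_claims=bundle.medical_claims.sample(
                frac=1, random_state=2).reset_index(drop=True),
            pharmacy_claims=bundle.pharmacy_claims.sample(
                frac=1, random_state=3).reset_index(drop=True),
        )
        cohort2, _ = build_cohort(shuffled)
        assert cohort2.equals(paper_run["cohort"])

    def test_rerun_is_idempotent(self, paper_run):
        cohort2, att2 = build_cohort(paper_run["bundle"])
        assert cohort2.equals(paper_run["cohort"])
        assert att2.equals(paper_run["attrition"])
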