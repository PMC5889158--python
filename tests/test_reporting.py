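import numpy as np
import pandas as pd
import pytest

from rheumclaims.reporting import (
    baseline_table,
    build_report,
    convert_currency,
    medication_share_pct,
    nonmedication_subtotal,
    percent,
    round_half_up,
    summarize_years,
    switch_matrix,
    time_to_switch,
)
from rheumclaims.response import classify

from conftest import BundleBuilder, make_cohort_row, standard_patient


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (40.5, 41), (31.54, 32), (16.499, 16), (16.5, 17), (0.0, 0), (90.75, 91),
    ])
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_percent(self):
        assert percent(540, 818) == 66
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestCurrency:
    def test_zero(self):
        assert convert_currency(0, 0.033) == 0

    @pytest.mark.parametrize("ntd,usd", [(445_314, 14_695), (404_950, 13_363)])
    def test_published_conversions(self, ntd, usd):
        assert convert_currency(ntd, 0.033) == usd

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            convert_currency(-1, 0.033)
        with pytest.raises(ValueError):
            convert_currency(1, 0)


class TestSwitchAnalyses:
    def _records(self, counts):
        rows = []
        i = 0
        for (frm, to), k in counts.items():
            for _ in range(k):
                rows.append((f"P{i}", frm, to, 400 + i))
                i += 1
        return pd.DataFrame(rows, columns=["patient_id", "from_agent", "to_agent", "switch_day"])

    def test_published_row_percentages(self):
        rec = self._records({
            ("adalimumab", "etanercept"): 32, ("adalimumab", "tocilizumab"): 31,
            ("adalimumab", "golimumab"): 9, ("adalimumab", "abatacept"): 7,
        })
        counts, pct = switch_matrix(rec)
        row = pct.loc["adalimumab"]
        assert row["etanercept"] == 41 and row["tocilizumab"] == 39
        assert row["golimumab"] == 11 and row["abatacept"] == 9
        assert counts.loc["adalimumab"].sum() == 79

    def test_row_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pairs = {("a", f"d{j}"): int(rng.integers(1, 40)) for j in range(4)}
            _, pct = switch_matrix(self._records(pairs))
            assert abs(pct.loc["a"].sum() - 100) <= 2

    def test_empty_matrix(self):
        counts, pct = switch_matrix(self._records({}))
        assert counts.empty and pct.empty

    def test_time_to_switch_is_plain_mean_of_switchers(self):
        rec = self._records({("a", "b"): 3})
        rec["switch_day"] = [100, 200, 600]
        out = time_to_switch(rec)
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "mean_days"] == pytest.approx(300.0)
        assert out.loc[0, "sd_days"] == pytest.approx(np.std([100, 200, 600], ddof=1))

    def test_no_switchers_reported_as_absent(self):
        out = time_to_switch(self._records({}))
        assert out.empty  # absent, not zero

    def test_single_switcher(self):
        rec = self._records({("a", "b"): 1})
        rec["switch_day"] = [100]
        assert time_to_switch(rec).loc[0, "mean_days"] == 100


class TestAnnualSummary:
    def _one_patient_run(self):
        b = standard_patient(BundleBuilder())
        # one 3-day admission in year 1 (NT$90,000), one ED visit (NT$1,500),
        # outpatient visit with split medication/non-medication lines
        b.visit("P1", "2010-05-01", setting="inpatient", end="2010-05-04",
                nonmed_cents=9_000_000)
        b.visit("P1", "2010-06-10", setting="ED", nonmed_cents=150_000)
        b.visit("P1", "2010-07-01", med_cents=20_000, nonmed_cents=80_000)
        bundle = b.build()
        cohort = make_cohort_row()
        results = classify(cohort, bundle)
        return bundle, cohort, results

    def test_admission_and_day_counting(self):
        bundle, cohort, results = self._one_patient_run()
        s = summarize_years(bundle, cohort, results, years=(1,))
        row = s[s["cohort"] == "all"].iloc[0]
        assert row["n_patients"] == 1
        assert row["mean_admissions"] == 1
        assert row["mean_hospital_days"] == 3
        assert row["mean_ed_visits"] == 1
        assert row["mean_outpatient_visits"] == 1
        assert row["mean_inpatient_ntd"] == 90_000
        assert row["mean_ed_ntd"] == 1_500
        assert row["mean_outpatient_ntd"] == 800
        assert row["mean_medication_ntd"] == 200  # medication line of the visit
        assert row["mean_total_ntd"] == 92_500
        assert row["mean_total_usd"] == pytest.approx(92_500 * 0.033)

    def test_same_day_admission_counts_one_hospital_day(self):
        b = standard_patient(BundleBuilder())
        b.visit("P1", "2010-05-01", setting="inpatient", end="2010-05-01")
        bundle = b.build()
        cohort = make_cohort_row()
        s = summarize_years(bundle, cohort, classify(cohort, bundle), years=(1,))
        assert s[s["cohort"] == "all"].iloc[0]["mean_hospital_days"] == 1

    def test_invalid_year(self):
        bundle, cohort, results = self._one_patient_run()
        with pytest.raises(ValueError):
            summarize_years(bundle, cohort, results, years=(4,))

    def test_cost_conservation_every_row(self, paper_run):
        s = paper_run["summary"]
        for _, r in s.iterrows():
            assert r["mean_total_ntd"] == pytest.approx(
                r["mean_inpatient_ntd"] + r["mean_outpatient_ntd"]
                + r["mean_ed_ntd"] + r["mean_medication_ntd"], rel=1e-12
            )

    def test_yearly_n_non_increasing_within_cohort(self, paper_run):
        s = paper_run["summary"]
        for label, grp in s.groupby("cohort"):
            ns = grp.sort_values("year")["n_patients"].to_numpy()
            assert (np.diff(ns) <= 0).all()


class TestDerivedCells:
    def test_nonmedication_subtotal(self):
        assert nonmedication_subtotal(104, 803, 30) == 937
        assert nonmedication_subtotal(667, 857, 50) == 1574

    def test_medication_share(self):
        assert medication_share_pct(13_427, 14_795) == 91


def test_build_report_emits_all_tables(tmp_path, paper_run):
    paths = build_report(
        tmp_path, paper_run["bundle"], paper_run["cohort"],
        paper_run["attrition"], paper_run["results"],
    )
    for name in ("attrition", "baseline", "annual_summary", "criterion_attribution",
                 "switch_records", "time_to_switch", "switch_matrix_counts",
                 "switch_matrix_pct", "response", "summary"):
        assert paths[name].exists(), name
    text = paths["summary"].read_text()
    assert "stable" in text and "ir" in text


def test_baseline_table_matches_planted_demography(paper_run):
    spec = paper_run["spec"]
    bt = baseline_table(
        paper_run["bundle"], paper_run["cohort"], paper_run["results"]
    ).set_index("cohort")
    assert bt.loc["all", "n"] == 818
    for label in ("stable", "ir", "unknown"):
        demo = spec.demography[label]
        n = bt.loc[label, "n"]
        se_age = bt.loc[label, "sd_age"] / np.sqrt(n)
        assert abs(bt.loc[label, "mean_age"] - demo.age_mean) <= max(3 * se_age, 1.0)
        se_f = np.sqrt(demo.female_fraction * (1 - demo.female_fraction) / n)
        assert abs(bt.loc[label, "n_female"] / n - demo.female_fraction) <= max(3 * se_f, 0.05)
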