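"""New-user cohort selection for biologic DMARD initiators.

A patient enters the cohort on the date of their first-ever biologic
dispense (the index date) when that date falls inside the index period
(calendar 2010 by default) — prior biologic use at any time in the data
disqualifies (new-user / naïveté requirement).  Inclusion then requires an
RA diagnosis claim (714.xx excluding 714.3) and an RA catastrophic-illness
certification; exclusions are applied in a fixed order: age < 18 at index,
broken pre-index enrollment (gaps of >= 30 days), specified comorbid
conditions, and malignancy/HIV, the last two scanned over the entire study
horizon.  Every step appends a row to an attrition table whose remaining-n
column is non-increasing.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .codes import CodeList, default_code_lists
from .config import DEFAULT_CONFIG, StudyConfig
from .io import ClaimsBundle

ATTRITION_COLUMNS = ["rule", "n_excluded", "n_remaining"]


def match_mask(diagnosis_codes: pd.Series, code_list: CodeList) -> pd.Series:
    """Boolean mask: does any ';'-joined code in each row match the list?"""
    if diagnosis_codes.empty:
        return pd.Series(dtype=bool)
    split = diagnosis_codes.str.split(";")
    unique = {c for row in split for c in row}
    hits = {c for c in unique if code_list.matches(c)}
    return split.map(lambda row: any(c in hits for c in row))


def _gaps_in_window(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
) -> list[int]:
    """Uncovered spans (in days) of the half-open window, given closed
    coverage intervals; includes leading and trailing uncovered spans."""
    length = (window_end - window_start).days
    last_day = window_end - pd.Timedelta(days=1)
    clipped = sorted(
        (max(s, window_start), min(e, last_day))
        for s, e in intervals
        if s <= last_day and e >= window_start
    )
    if not clipped:
        return [length]
    gaps = [(clipped[0][0] - window_start).days]
    run_end = clipped[0][1]
    for s, e in clipped[1:]:
        gaps.append((s - run_end).days - 1)
        run_end = max(run_end, e)
    gaps.append((last_day - run_end).days)
    return [g for g in gaps if g > 0]


def check_continuous_enrollment(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    window_start: pd.Timestamp,
    window_end: pd.Timestamp,
    tolerance_days: int,
    death_date: pd.Timestamp | None = None,
) -> bool:
    """True iff coverage spans [window_start, window_end) with every break
    strictly shorter than ``tolerance_days`` (a 30-day break fails the
    default "<30 days" tolerance).  Coverage after death is disregarded."""
    if death_date is not None and not pd.isna(death_date):
        intervals = [
            (s, min(e, death_date)) for s, e in intervals if s <= death_date
        ]
    return all(
        g < tolerance_days for g in _gaps_in_window(intervals, window_start, window_end)
    )


def coverage_by_patient(enrollment: pd.DataFrame) -> dict[str, list[tuple]]:
    cov: dict[str, list[tuple]] = {}
    for pid, s, e in zip(
        enrollment["patient_id"], enrollment["coverage_start"], enrollment["coverage_end"]
    ):
        cov.setdefault(pid, []).append((s, e))
    return cov


def death_by_patient(enrollment: pd.DataFrame) -> dict[str, pd.Timestamp]:
    d = enrollment.dropna(subset=["death_date"])
    return dict(zip(d["patient_id"], d["death_date"]))


def age_at(birth: pd.Timestamp, on: pd.Timestamp) -> int:
    """Completed years (administrative birthday convention)."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# selection steps
# ---------------------------------------------------------------------------


def find_index_events(
    bundle: ClaimsBundle, config: StudyConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate index events plus a log of step-wise drops.

    Returns (events, attrition).  Events carry patient_id, index_date,
    index_agent; patients whose first-ever biologic dispense predates the
    index period are dropped (not naïve), as are the pathological cases
    with two distinct agents dispensed on the index date (ambiguous, no
    principled tie-break).
    """
    rx = bundle.pharmacy_claims
    bio = rx[rx["drug_class"] == "bDMARD"]
    att_rows = []
    n_users = bio["patient_id"].nunique()
    att_rows.append(("patients with any bDMARD dispense", 0, n_users))

    first = bio.groupby("patient_id")["dispense_date"].min()
    start = pd.Timestamp(config.index_period_start)
    end = pd.Timestamp(config.index_period_end)
    in_period = first[(first >= start) & (first <= end)]
    att_rows.append(
        ("first-ever bDMARD dispense inside index period (naïve new users)",
         n_users - len(in_period), len(in_period))
    )

    on_index = bio.merge(
        in_period.rename("index_date").reset_index(),
        left_on=["patient_id", "dispense_date"],
        right_on=["patient_id", "index_date"],
    )
    agents = on_index.groupby("patient_id")["bdmard_agent"].agg(["nunique", "first"])
    ambiguous = agents[agents["nunique"] > 1].index
    agents = agents[agents["nunique"] == 1]
    att_rows.append(
        ("single unambiguous index agent", len(ambiguous), len(agents))
    )

    events = pd.DataFrame(
        {
            "patient_id": agents.index,
            "index_date": in_period.loc[agents.index].to_numpy(),
            "index_agent": agents["first"].to_numpy(),
        }
    ).reset_index(drop=True)
    att = pd.DataFrame(att_rows, columns=ATTRITION_COLUMNS)
    return events, att


def apply_inclusion(
    events: pd.DataFrame,
    bundle: ClaimsBundle,
    code_lists: dict[str, CodeList],
    config: StudyConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Require an RA diagnosis claim and an RA catastrophic-illness card."""
    ra = code_lists["ra_diagnosis"]
    att_rows = []

    med = bundle.medical_claims
    has_ra = set(med.loc[match_mask(med["diagnosis_codes"], ra), "patient_id"])
    kept = events[events["patient_id"].isin(has_ra)]
    att_rows.append(
        ("RA diagnosis code 714.xx (excluding 714.3)",
         len(events) - len(kept), len(kept))
    )
    events = kept

    cat = bundle.catastrophic_illness
    ra_card = cat[cat["icd9_code"].map(ra.matches).astype(bool)]
    if config.require_card_before_index:
        card = events.merge(ra_card, on="patient_id")
        carded = set(card.loc[card["effective_date"] <= card["index_date"], "patient_id"])
    else:
        carded = set(ra_card["patient_id"])
    kept = events[events["patient_id"].isin(carded)]
    att_rows.append(
        ("RA catastrophic illness certification", len(events) - len(kept), len(kept))
    )
    return kept.reset_index(drop=True), pd.DataFrame(att_rows, columns=ATTRITION_COLUMNS)


def apply_exclusion(
    events: pd.DataFrame,
    bundle: ClaimsBundle,
    code_lists: dict[str, CodeList],
    config: StudyConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The four exclusions, in the published order."""
    att_rows = []
    enr = bundle.enrollment
    demo = enr.drop_duplicates("patient_id")[["patient_id", "birth_date", "sex"]]
    events = events.merge(demo, on="patient_id", how="left")

    # 1) age < 18 at index
    ages = [
        age_at(b, ix) if not pd.isna(b) else -1
        for b, ix in zip(events["birth_date"], events["index_date"])
    ]
    events = events.assign(age_at_index=ages)
    kept = events[events["age_at_index"] >= 18]
    att_rows.append(("aged >= 18 years at index", len(events) - len(kept), len(kept)))
    events = kept

    # 2) continuous pre-index enrollment (breaks < tolerance ignored)
    cov = coverage_by_patient(enr)
    ok = []
    for pid, ix in zip(events["patient_id"], events["index_date"]):
        ws = ix - pd.Timedelta(days=config.pre_index_days)
        ok.append(
            check_continuous_enrollment(
                cov.get(pid, []), ws, ix, config.enrollment_gap_tolerance_days
            )
        )
    kept = events[np.array(ok, dtype=bool)] if len(events) else events
    att_rows.append(
        ("continuously enrolled in pre-index period", len(events) - len(kept), len(kept))
    )
    events = kept

    # 3) + 4) diagnosis exclusions over the whole study horizon
    med = bundle.medical_claims
    horizon = med[
        (med["start_date"] >= pd.Timestamp(config.study_start))
        & (med["start_date"] <= pd.Timestamp(config.study_end))
    ]
    for rule, list_name in (
        ("no psoriasis/PsA, AS, IBD or juvenile polyarthritis claim", "exclusion_conditions"),
        ("no malignancy (exc. non-melanoma skin) or HIV/AIDS claim", "exclusion_malignancy_hiv"),
    ):
        bad = set(
            horizon.loc[match_mask(horizon["diagnosis_codes"], code_lists[list_name]),
                        "patient_id"]
        )
        kept = events[~events["patient_id"].isin(bad)]
        att_rows.append((rule, len(events) - len(kept), len(kept)))
        events = kept

    return events.reset_index(drop=True), pd.DataFrame(att_rows, columns=ATTRITION_COLUMNS)


def build_cohort(
    bundle: ClaimsBundle,
    code_lists: dict[str, CodeList] | None = None,
    config: StudyConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full selection; returns (cohort, attrition).

    The cohort frame has one row per retained patient with columns
    patient_id, index_date, index_agent, age_at_index, birth_date, sex.
    """
    if code_lists is None:
        code_lists = default_code_lists()
    events, att1 = find_index_events(bundle, config)
    events, att2 = apply_inclusion(events, bundle, code_lists, config)
    events, att3 = apply_exclusion(events, bundle, code_lists, config)
    attrition = pd.concat([att1, att2, att3], ignore_index=True)
    cols = ["patient_id", "index_date", "index_agent", "age_at_index", "birth_date", "sex"]
    cohort = events[cols].sort_values("patient_id").reset_index(drop=True)
    return cohort, attrition
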