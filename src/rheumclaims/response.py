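"""Five-criterion claims-based response classification.

Each cohort patient is classified over the 1-year follow-up window
(half-open day interval [0, 365); day 0 = index date) as:

* **IR** (inadequate responder) — meets at least one of:

  1. low adherence: proportion of days covered by the index biologic
     strictly below 0.80 (union of dispense coverage intervals / 365);
  2. switch or add of a biologic: any dispense of a non-index biologic
     agent inside the window;
  3. addition of a new csDMARD: a compound dispensed strictly after the
     index date with no dispense in the pre-index window or on the index
     date;
  4. more than one glucocorticoid joint injection (>= 2 by default; the
     threshold is configurable);
  5. an increase in oral glucocorticoid dose: mean daily
     prednisone-equivalent dose over follow-up days [90, 365) strictly
     above the pre-index mean daily dose (the first 90 days are excluded
     as routine bridging steroids; both the margin and the bridging
     window are configurable).

* **Unknown** — lost to follow-up (death, or an enrollment break of >= 30
  days) before the window closes, with no criterion met before the censor
  day.  Criteria 2-4 are event-dated and can still flag a censored
  patient; the two year-summary criteria (adherence and oral
  glucocorticoid dose) require complete follow-up.

* **Stable** — observed for the full year and meeting none of the five
  criteria.

The criterion "increase in the dose of the index biologic" used by the
original US algorithm is intentionally absent: biologic doses cannot be
escalated under Taiwan's reimbursement rules, so the localized algorithm
has exactly five criteria.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import coverage_by_patient, death_by_patient
from .config import DEFAULT_CONFIG, StudyConfig
from .errors import RowValidationError
from .io import ClaimsBundle

CRITERIA = (
    "low_adherence",
    "switch_or_add",
    "new_csdmard",
    "gc_injections",
    "oral_gc_increase",
)

RESULT_COLUMNS = (
    ["patient_id", "status", "pdc"]
    + list(CRITERIA)
    + [f"{c}_day" for c in CRITERIA]
    + ["first_criterion_day", "censor_day"]
)


# ---------------------------------------------------------------------------
# criterion primitives (pure functions over day offsets)
# ---------------------------------------------------------------------------


def covered_days(
    dispenses: Iterable[tuple[int, int]], window: tuple[int, int]
) -> int:
    """Distinct days covered by [day, day + supply) intervals, clipped to
    the half-open window."""
    lo, hi = window
    ivs = []
    for day, supply in dispenses:
        if supply < 1:
            raise ValueError(f"days_supplied must be >= 1, got {supply}")
        s, e = max(day, lo), min(day + supply, hi)
        if s < e:
            ivs.append((s, e))
    ivs.sort()
    total = 0
    run_end = None
    for s, e in ivs:
        if run_end is None or s > run_end:
            total += e - s
            run_end = e
        elif e > run_end:
            total += e - run_end
            run_end = e
    return total


def compute_pdc(
    dispenses: Iterable[tuple[int, int]], window: tuple[int, int] = (0, 365)
) -> float:
    """Proportion of days covered by the index agent over the window."""
    lo, hi = window
    return covered_days(dispenses, window) / (hi - lo)


def detect_switch_or_add(
    bdmard_dispenses: Iterable[tuple[int, str]],
    index_agent: str,
    window: tuple[int, int] = (0, 365),
) -> tuple[bool, int | None]:
    """First dispense of a non-index biologic agent inside the window."""
    days = [
        d for d, agent in bdmard_dispenses
        if agent != index_agent and window[0] <= d < window[1]
    ]
    return (True, min(days)) if days else (False, None)


def detect_new_csdmard(
    csdmard_dispenses: Iterable[tuple[int, str]],
    pre_window: tuple[int, int] = (-365, 0),
    follow_window: tuple[int, int] = (0, 365),
) -> tuple[bool, int | None]:
    """A compound dispensed strictly after index with no pre-index or
    index-date use counts as newly added."""
    dispenses = list(csdmard_dispenses)
    prior = {
        code for d, code in dispenses if pre_window[0] <= d <= 0
    }
    new_days = [
        d for d, code in dispenses
        if code not in prior and 0 < d < follow_window[1]
    ]
    return (True, min(new_days)) if new_days else (False, None)


def count_gc_injections(
    injection_days: Iterable[int],
    window: tuple[int, int] = (0, 365),
    min_count: int = 2,
) -> tuple[int, bool, int | None]:
    """Count joint-injection claims in the window; the criterion is met on
    the day the ``min_count``-th injection occurs."""
    days = sorted(d for d in injection_days if window[0] <= d < window[1])
    flag = len(days) >= min_count
    return len(days), flag, (days[min_count - 1] if flag else None)


def detect_oral_gc_increase(
    oral_gc_dispenses: Iterable[tuple[int, float]],
    pre_window: tuple[int, int] = (-365, 0),
    comparison_window: tuple[int, int] = (90, 365),
    margin_pct: float = 0.0,
) -> tuple[bool, int | None]:
    """Mean daily prednisone-equivalent dose, comparison window vs
    pre-index.  Dose totals are attributed to the dispense date; a patient
    with no pre-index use and any use in the comparison window counts as
    an increase (strict inequality over zero)."""
    dispenses = list(oral_gc_dispenses)
    pre_total = sum(mg for d, mg in dispenses if pre_window[0] <= d < pre_window[1])
    cmp_rows = [(d, mg) for d, mg in dispenses
                if comparison_window[0] <= d < comparison_window[1]]
    if not cmp_rows:
        return False, None
    pre_mean = pre_total / (pre_window[1] - pre_window[0])
    cmp_mean = sum(mg for _, mg in cmp_rows) / (
        comparison_window[1] - comparison_window[0]
    )
    if cmp_mean > pre_mean * (1.0 + margin_pct / 100.0):
        return True, min(d for d, _ in cmp_rows)
    return False, None


# ---------------------------------------------------------------------------
# censoring
# ---------------------------------------------------------------------------


def observed_end_day(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    death: pd.Timestamp | None,
    index_date: pd.Timestamp,
    tolerance_days: int,
) -> int:
    """Last observed day offset (inclusive) of the enrollment spell
    containing the index date, after bridging breaks shorter than the
    tolerance and truncating at death."""
    ivs = sorted(intervals)
    if death is not None and not pd.isna(death):
        ivs = [(s, min(e, death)) for s, e in ivs if s <= death]
    merged: list[list[pd.Timestamp]] = []
    for s, e in ivs:
        if merged and (s - merged[-1][1]).days - 1 < tolerance_days:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for s, e in merged:
        if s <= index_date <= e:
            return (e - index_date).days
    return -1


# ---------------------------------------------------------------------------
# full classification
# ---------------------------------------------------------------------------


def classify(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    config: StudyConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Classify every cohort patient; one row per patient (see
    ``RESULT_COLUMNS``)."""
    fu = config.follow_up_days
    idx = cohort.set_index("patient_id")
    known = set(bundle.enrollment["patient_id"])
    missing = [p for p in idx.index if p not in known]
    if missing:
        raise RowValidationError("enrollment", 0,
                                 f"cohort patient {missing[0]!r} absent from enrollment")

    rx = bundle.pharmacy_claims.merge(
        cohort[["patient_id", "index_date", "index_agent"]], on="patient_id"
    )
    rx["day"] = (rx["dispense_date"] - rx["index_date"]).dt.days
    rx_by_pat = dict(tuple(rx.groupby("patient_id", sort=False)))

    med = bundle.medical_claims.merge(
        cohort[["patient_id", "index_date"]], on="patient_id"
    )
    med["day"] = (med["start_date"] - med["index_date"]).dt.days
    inj = med[med["is_gc_joint_injection"]]
    inj_by_pat = {p: g["day"].tolist() for p, g in inj.groupby("patient_id")}

    cov = coverage_by_patient(bundle.enrollment)
    deaths = death_by_patient(bundle.enrollment)

    rows = []
    empty_rx = rx.iloc[0:0]
    for pid, patient in idx.iterrows():
        prx = rx_by_pat.get(pid, empty_rx)
        agent = patient["index_agent"]

        end_day = observed_end_day(
            cov[pid], deaths.get(pid), patient["index_date"],
            config.enrollment_gap_tolerance_days,
        )
        censored = end_day < fu - 1
        censor_day = (end_day + 1) if censored else None
        event_end = censor_day if censored else fu

        flags: dict[str, bool] = {}
        days: dict[str, float] = {}

        b = prx[prx["drug_class"] == "bDMARD"]
        flags["switch_or_add"], days["switch_or_add"] = detect_switch_or_add(
            zip(b["day"], b["bdmard_agent"]), agent, (0, event_end)
        )
        cs = prx[prx["drug_class"] == "csDMARD"]
        flags["new_csdmard"], days["new_csdmard"] = detect_new_csdmard(
            zip(cs["day"], cs["drug_code"]),
            (-config.pre_index_days, 0), (0, event_end),
        )
        n_inj, flags["gc_injections"], days["gc_injections"] = count_gc_injections(
            inj_by_pat.get(pid, []), (0, event_end), config.gc_injection_min_count
        )

        if censored:
            pdc = float("nan")
            flags["low_adherence"] = False
            days["low_adherence"] = None
            flags["oral_gc_increase"] = False
            days["oral_gc_increase"] = None
        else:
            own = b[b["bdmard_agent"] == agent]
            pdc = compute_pdc(zip(own["day"], own["days_supplied"]), (0, fu))
            flags["low_adherence"] = pdc < config.pdc_threshold
            # adherence is only assessable once the window closes
            days["low_adherence"] = fu - 1 if flags["low_adherence"] else None
            gc = prx[prx["drug_class"] == "oral_GC"]
            flags["oral_gc_increase"], days["oral_gc_increase"] = detect_oral_gc_increase(
                zip(gc["day"], gc["prednisone_equivalent_mg_total"]),
                (-config.pre_index_days, 0),
                (config.gc_bridging_exclusion_days, fu),
                config.gc_increase_margin_pct,
            )

        met = [days[c] for c in CRITERIA if flags[c]]
        if any(flags.values()):
            status = "ir"
        elif censored:
            status = "unknown"
        else:
            status = "stable"
        rows.append(
            [pid, status, pdc]
            + [flags[c] for c in CRITERIA]
            + [np.nan if days[c] is None else float(days[c]) for c in CRITERIA]
            + [min(met) if met else np.nan,
               np.nan if censor_day is None else float(censor_day)]
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def attribute_criteria(results: pd.DataFrame) -> pd.DataFrame:
    """Criterion attribution over the whole cohort, reported two ways:
    overlapping marginals (share of cohort meeting each criterion; a
    patient can count toward several) and first-met attribution (each IR
    patient assigned to the earliest criterion they met, ties broken by
    the fixed criterion order)."""
    n = len(results)
    first_counts = dict.fromkeys(CRITERIA, 0)
    flagged = results[results[list(CRITERIA)].any(axis=1)]
    for _, row in flagged.iterrows():
        best = min(
            (c for c in CRITERIA if row[c]),
            key=lambda c: (row[f"{c}_day"], CRITERIA.index(c)),
        )
        first_counts[best] += 1
    rows = []
    for c in CRITERIA:
        n_flag = int(results[c].sum())
        rows.append(
            {
                "criterion": c,
                "n_flagged": n_flag,
                "marginal_pct": 100.0 * n_flag / n if n else 0.0,
                "n_first_met": first_counts[c],
                "first_met_pct": 100.0 * first_counts[c] / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
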