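"""Annualized resource-use and direct-cost summaries, switching analyses,
and report emission.

Conventions (applied consistently to every reported figure):

* rounding is half-up, to whole dollars and whole percent;
* hospital days per admission = discharge - admission in days, minimum 1
  for same-day stays;
* a patient contributes to follow-up year k only when continuously
  enrolled through the whole year-k window (this is what shrinks the
  per-year n);
* per-patient total cost = inpatient + outpatient + ED + medication, where
  the inpatient/outpatient/ED categories carry the non-medication lines of
  claims in that setting and the medication category carries all pharmacy
  costs plus the medication lines of medical claims;
* time-to-switch means are conditional on switching (non-switchers do not
  contribute; an empty switcher set yields no row rather than a zero).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .charlson import cci_for_cohort
from .cohort import check_continuous_enrollment, coverage_by_patient, death_by_patient
from .config import DEFAULT_CONFIG, StudyConfig
from .io import ClaimsBundle
from .response import attribute_criteria

HCRU_METRICS = ("admissions", "hospital_days", "ed_visits", "outpatient_visits")
COST_CATEGORIES = ("inpatient", "outpatient", "ed", "medication")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> int:
    """Whole-percent share, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator)


def convert_currency(amount_ntd: float, rate: float, rounded: bool = True) -> float:
    """NT$ to USD at the study exchange rate; reported means are rounded
    half-up to the nearest dollar."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    if amount_ntd < 0:
        raise ValueError("negative amount")
    usd = amount_ntd * rate
    return float(round_half_up(usd)) if rounded else usd


# ---------------------------------------------------------------------------
# switching
# ---------------------------------------------------------------------------


def build_switch_records(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    horizon_days: int = 3 * 365,
) -> pd.DataFrame:
    """First dispense of a non-index biologic per patient within the
    horizon -> (patient_id, from_agent, to_agent, switch_day)."""
    rx = bundle.pharmacy_claims
    b = rx[rx["drug_class"] == "bDMARD"].merge(
        cohort[["patient_id", "index_date", "index_agent"]], on="patient_id"
    )
    b["switch_day"] = (b["dispense_date"] - b["index_date"]).dt.days
    b = b[
        (b["bdmard_agent"] != b["index_agent"])
        & (b["switch_day"] >= 0)
        & (b["switch_day"] < horizon_days)
    ]
    if b.empty:
        return pd.DataFrame(
            columns=["patient_id", "from_agent", "to_agent", "switch_day"]
        ).astype({"switch_day": np.int64})
    b = b.sort_values(["switch_day", "bdmard_agent"]).groupby("patient_id", sort=False).first()
    out = pd.DataFrame(
        {
            "patient_id": b.index,
            "from_agent": b["index_agent"].to_numpy(),
            "to_agent": b["bdmard_agent"].to_numpy(),
            "switch_day": b["switch_day"].astype(np.int64).to_numpy(),
        }
    ).sort_values("patient_id").reset_index(drop=True)
    return out


def time_to_switch(
    switch_records: pd.DataFrame, results: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean/SD days to switch among switchers, by index agent (and by
    response status when classification results are supplied)."""
    if switch_records.empty:
        cols = ["from_agent", "n", "mean_days", "sd_days"]
        return pd.DataFrame(columns=cols)
    df = switch_records
    keys = ["from_agent"]
    if results is not None:
        df = df.merge(results[["patient_id", "status"]], on="patient_id", how="left")
        keys = ["from_agent", "status"]
    g = df.groupby(keys)["switch_day"]
    out = g.agg(n="size", mean_days="mean", sd_days="std").reset_index()
    return out


def switch_matrix(switch_records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counts, row percentages) of from-agent -> to-agent switches; row
    percentages are whole percent, half-up, of that row's switchers."""
    if switch_records.empty:
        empty = pd.DataFrame()
        return empty, empty
    counts = (
        switch_records.groupby(["from_agent", "to_agent"]).size().unstack(fill_value=0)
    )
    pct = counts.apply(
        lambda row: pd.Series(
            [percent(v, row.sum()) for v in row], index=row.index, dtype=np.int64
        ),
        axis=1,
    )
    return counts, pct


# ---------------------------------------------------------------------------
# annual summaries
# ---------------------------------------------------------------------------


def _patient_year_metrics(
    bundle: ClaimsBundle, cohort: pd.DataFrame, years: tuple[int, ...]
) -> pd.DataFrame:
    """Per (patient, year) HCRU quantities and NT$ costs; zero-filled for
    patients without claims in a year."""
    max_day = 365 * max(years)

    med = bundle.medical_claims.merge(
        cohort[["patient_id", "index_date"]], on="patient_id"
    )
    med["day"] = (med["start_date"] - med["index_date"]).dt.days
    med = med[(med["day"] >= 0) & (med["day"] < max_day)]
    med["year"] = med["day"] // 365 + 1
    med["los"] = np.maximum((med["end_date"] - med["start_date"]).dt.days, 1)

    def per_setting(setting, col, agg):
        sub = med[med["setting"] == setting]
        return sub.groupby(["patient_id", "year"])[col].agg(agg)

    parts = {
        "admissions": per_setting("inpatient", "day", "size"),
        "hospital_days": per_setting("inpatient", "los", "sum"),
        "ed_visits": per_setting("ED", "day", "size"),
        "outpatient_visits": per_setting("outpatient", "day", "size"),
    }
    for setting, name in (("inpatient", "inpatient"), ("outpatient", "outpatient"), ("ED", "ed")):
        parts[f"{name}_ntd"] = (
            per_setting(setting, "nonmedication_cost_cents", "sum") / 100.0
        )
    med_line = med.groupby(["patient_id", "year"])["medication_cost_cents"].sum() / 100.0

    rx = bundle.pharmacy_claims.merge(
        cohort[["patient_id", "index_date"]], on="patient_id"
    )
    rx["day"] = (rx["dispense_date"] - rx["index_date"]).dt.days
    rx = rx[(rx["day"] >= 0) & (rx["day"] < max_day)]
    rx["year"] = rx["day"] // 365 + 1
    rx_cost = rx.groupby(["patient_id", "year"])["cost_cents"].sum() / 100.0
    parts["medication_ntd"] = med_line.add(rx_cost, fill_value=0.0)

    grid = pd.MultiIndex.from_product(
        [cohort["patient_id"], years], names=["patient_id", "year"]
    )
    df = pd.DataFrame(index=grid)
    for name, s in parts.items():
        df[name] = s.reindex(grid).fillna(0.0)
    df["total_ntd"] = (
        df["inpatient_ntd"] + df["outpatient_ntd"] + df["ed_ntd"] + df["medication_ntd"]
    )
    return df.reset_index()


def _enrolled_mask(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    years: tuple[int, ...],
    config: StudyConfig,
) -> pd.DataFrame:
    cov = coverage_by_patient(bundle.enrollment)
    deaths = death_by_patient(bundle.enrollment)
    rows = []
    for pid, ix in zip(cohort["patient_id"], cohort["index_date"]):
        for k in years:
            ws = ix + pd.Timedelta(days=365 * (k - 1))
            we = ix + pd.Timedelta(days=365 * k)
            ok = check_continuous_enrollment(
                cov.get(pid, []), ws, we,
                config.enrollment_gap_tolerance_days, deaths.get(pid),
            )
            rows.append((pid, k, ok))
    return pd.DataFrame(rows, columns=["patient_id", "year", "enrolled"])


def summarize_years(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    config: StudyConfig = DEFAULT_CONFIG,
    years: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Annual summary per cohort label ('all', 'stable', 'ir') and year.

    Per-patient quantities are summed inside the year window and averaged
    across patients continuously enrolled through that window; costs are
    reported in both NT$ and USD (converted at the configured rate).
    """
    if any(k not in (1, 2, 3) for k in years):
        raise ValueError("years must be within {1, 2, 3}")
    pym = _patient_year_metrics(bundle, cohort, years)
    enrolled = _enrolled_mask(bundle, cohort, years, config)
    pym = pym.merge(enrolled, on=["patient_id", "year"])
    pym = pym.merge(results[["patient_id", "status"]], on="patient_id", how="left")

    rate = config.exchange_rate_usd_per_ntd
    rows = []
    for label in ("all", "stable", "ir"):
        sub = pym if label == "all" else pym[pym["status"] == label]
        for k in years:
            yk = sub[(sub["year"] == k) & sub["enrolled"]]
            row: dict[str, object] = {"cohort": label, "year": k, "n_patients": len(yk)}
            for m in HCRU_METRICS:
                row[f"mean_{m}"] = yk[m].mean() if len(yk) else np.nan
                row[f"sd_{m}"] = yk[m].std(ddof=1) if len(yk) > 1 else np.nan
            for c in COST_CATEGORIES + ("total",):
                ntd = yk[f"{c}_ntd"]
                row[f"mean_{c}_ntd"] = ntd.mean() if len(yk) else np.nan
                row[f"sd_{c}_ntd"] = ntd.std(ddof=1) if len(yk) > 1 else np.nan
                row[f"mean_{c}_usd"] = row[f"mean_{c}_ntd"] * rate
                row[f"sd_{c}_usd"] = row[f"sd_{c}_ntd"] * rate
            rows.append(row)
    return pd.DataFrame(rows)


def baseline_table(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    config: StudyConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Baseline characteristics by response cohort (the Table 1 analogue):
    n, age, sex split, Charlson Comorbidity Index."""
    cci = cci_for_cohort(bundle, cohort, config=config)
    df = cohort.merge(results[["patient_id", "status"]], on="patient_id")
    df["cci"] = df["patient_id"].map(cci)
    rows = []
    for label in ("all", "stable", "ir", "unknown"):
        sub = df if label == "all" else df[df["status"] == label]
        n = len(sub)
        rows.append(
            {
                "cohort": label,
                "n": n,
                "mean_age": sub["age_at_index"].mean() if n else np.nan,
                "sd_age": sub["age_at_index"].std(ddof=1) if n > 1 else np.nan,
                "n_male": int((sub["sex"] == "male").sum()),
                "pct_male": percent((sub["sex"] == "male").sum(), n) if n else np.nan,
                "n_female": int((sub["sex"] == "female").sum()),
                "pct_female": percent((sub["sex"] == "female").sum(), n) if n else np.nan,
                "mean_cci": sub["cci"].mean() if n else np.nan,
                "sd_cci": sub["cci"].std(ddof=1) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derived cells (always computed from components, never re-entered)
# ---------------------------------------------------------------------------


def nonmedication_subtotal(inpatient: float, outpatient: float, ed: float) -> float:
    return inpatient + outpatient + ed


def medication_share_pct(medication: float, total: float) -> int:
    return percent(medication, total)


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------


def build_report(
    outdir: str | Path,
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    attrition: pd.DataFrame,
    results: pd.DataFrame,
    config: StudyConfig = DEFAULT_CONFIG,
) -> dict[str, Path]:
    """Emit all output tables as CSV plus a plain-text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    switches = build_switch_records(bundle, cohort)
    summary = summarize_years(bundle, cohort, results, config)
    base = baseline_table(bundle, cohort, results, config)
    attribution = attribute_criteria(results)
    tts = time_to_switch(switches)
    counts, pct = switch_matrix(switches)

    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=kw.pop("index", False), lineterminator="\n")
        paths[name] = p

    emit("attrition", attrition)
    emit("baseline", base)
    emit("annual_summary", summary)
    emit("criterion_attribution", attribution)
    emit("switch_records", switches)
    emit("time_to_switch", tts)
    emit("switch_matrix_counts", counts, index=True)
    emit("switch_matrix_pct", pct, index=True)
    emit("response", results)

    lines = ["Cohort summary", "=============", ""]
    n = len(results)
    for label in ("stable", "ir", "unknown"):
        c = int((results["status"] == label).sum())
        lines.append(f"{label:>8}: n={c}" + (f" ({percent(c, n)}%)" if n else ""))
    lines.append("")
    for _, r in summary[summary["cohort"].isin(("stable", "ir"))].iterrows():
        lines.append(
            f"{r['cohort']:>8} year {int(r['year'])}: n={int(r['n_patients'])}, "
            f"admissions {r['mean_admissions']:.2f}, "
            f"total ${round_half_up(r['mean_total_usd'])}, "
            f"non-medication ${round_half_up(nonmedication_subtotal(r['mean_inpatient_usd'], r['mean_outpatient_usd'], r['mean_ed_usd']))}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["summary"] = outdir / "summary.txt"
    return paths
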