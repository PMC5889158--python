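"""Synthetic claims generator with planted, per-patient ground truth.

The generator emulates the structure of Taiwan's population-wide claims
data (enrollment spells, a catastrophic-illness registry, medical claims
with ICD-9-CM codes, and pharmacy dispensings) for a cohort of RA patients
initiating their first biologic.  Every patient carries a planted response
label (stable / IR / unknown) and planted criterion flags, each realized by
concrete claims:

* low adherence — index-agent dispenses whose union coverage is strictly
  below the PDC threshold (contiguous coverage from day 0, then
  discontinuation);
* switch/add — a dispense of a different biologic inside follow-up;
* new csDMARD — a first-ever leflunomide dispense after index (every
  background methotrexate user has pre-index dispenses, so background
  therapy never looks new);
* glucocorticoid injections — two injection-flagged outpatient visits;
* oral glucocorticoid increase — comparison-window mean daily
  prednisone-equivalent dose strictly above the pre-index mean (everyone
  may receive bridging steroids in the first 90 days, which the classifier
  must ignore).

A non-interference guarantee holds by construction: patients planted
stable keep coverage at or above the threshold, never receive a non-index
biologic, a new csDMARD compound, more than one injection, or a dose
increase, so the default classifier recovers the planted labels exactly.
Planted counts (status split, index-drug mix, switchers per drug) are
assigned exactly, not in expectation; continuous targets (costs, resource
use, switch timing) are planted as distributional means.

``paper_preset()`` returns the calibration used throughout the test suite:
818 patients split 258/540/20, a 375/443 adalimumab/etanercept mix, 79/56
three-year switchers with 782.4/755.6-day mean switch times, and per
cohort-year cost and utilization means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import BDMARD_CODES, CSDMARD_CODES, ORAL_GC_CODES
from .config import DEFAULT_CONFIG, StudyConfig
from .errors import ConfigError
from .io import ClaimsBundle, canonicalize_table, validate_bundle

CRITERIA = (
    "low_adherence",
    "switch_or_add",
    "new_csdmard",
    "gc_injections",
    "oral_gc_increase",
)

# outpatient diagnosis codes safe to add anywhere: they match no study
# inclusion/exclusion list and no Charlson category
SAFE_NUISANCE_CODES = ("460", "462", "5990", "7295", "V700")

# weight-1 Charlson categories outside every exclusion list, used to plant
# baseline comorbidity
_COMORBIDITY_CODES = ("4280", "496", "5330", "2500", "2900", "5712", "4330", "4439")

_PRE_VISIT_COST_CENTS = 80_000  # NT$800 per pre-index visit


@dataclass(frozen=True)
class Demography:
    age_mean: float
    age_sd: float
    female_fraction: float


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int
    status_proportions: Mapping[str, float]  # stable / ir / unknown
    criterion_marginals: Mapping[str, float]  # among IR patients
    index_drug_mix: Mapping[str, float]
    switch_probability_by_drug: Mapping[str, float]  # 3-year switch prob
    switch_day_mean_by_drug: Mapping[str, float]
    switch_day_sd: float
    switch_destinations: Mapping[str, Mapping[str, float]]
    # fraction of each status cohort still enrolled through years 1..3
    year_retention: Mapping[str, tuple[float, float, float]]
    # per status -> year -> metric means (admissions, hospital_days,
    # ed_visits, outpatient_visits)
    hcru_means: Mapping[str, Mapping[int, Mapping[str, float]]]
    # per status -> year -> category -> (mean USD, sd USD)
    cost_means_usd: Mapping[str, Mapping[int, Mapping[str, tuple[float, float]]]]
    demography: Mapping[str, Demography]
    cci_mean: Mapping[str, float]
    background_visit_rate: float = 38.0
    n_decoys: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, probs in (
            ("status_proportions", self.status_proportions),
            ("index_drug_mix", self.index_drug_mix),
        ):
            if any(not (0.0 <= p <= 1.0) for p in probs.values()):
                raise ConfigError(f"{name} outside [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        if any(not (0.0 <= p <= 1.0) for p in self.criterion_marginals.values()):
            raise ConfigError("criterion_marginals outside [0, 1]")
        if self.status_proportions.get("ir", 0.0) > 0 and not any(
            p > 0 for p in self.criterion_marginals.values()
        ):
            raise ConfigError(
                "infeasible: IR proportion > 0 with all criterion marginals 0"
            )
        if self.criterion_marginals.get("switch_or_add", 0.0) > 0 and self.status_proportions.get("ir", 0.0) > 0:
            for drug in self.index_drug_mix:
                dest = {a: p for a, p in self.switch_destinations.get(drug, {}).items()
                        if a != drug and p > 0}
                if not dest:
                    raise ConfigError(
                        f"infeasible: switch criterion planted but no switch "
                        f"destination defined for index drug {drug!r}"
                    )


def paper_preset() -> ScenarioSpec:
    """The published-study calibration (818-patient cohort)."""
    t2 = {  # mean annual resource use per cohort-year
        "stable": {
            1: dict(admissions=0.10, hospital_days=0.49, ed_visits=0.30, outpatient_visits=37.66),
            2: dict(admissions=0.27, hospital_days=1.54, ed_visits=0.45, outpatient_visits=37.10),
            3: dict(admissions=0.39, hospital_days=1.95, ed_visits=0.42, outpatient_visits=37.79),
        },
        "ir": {
            1: dict(admissions=0.46, hospital_days=3.40, ed_visits=0.51, outpatient_visits=42.50),
            2: dict(admissions=0.58, hospital_days=2.74, ed_visits=0.37, outpatient_visits=39.96),
            3: dict(admissions=0.63, hospital_days=3.36, ed_visits=0.46, outpatient_visits=41.15),
        },
    }
    t3 = {  # mean (sd) annual direct costs in USD per cohort-year
        "stable": {
            1: dict(inpatient=(104, 455), outpatient=(803, 1371), ed=(30, 116), medication=(15198, 1464)),
            2: dict(inpatient=(307, 1027), outpatient=(837, 1392), ed=(32, 124), medication=(11908, 3486)),
            3: dict(inpatient=(394, 1090), outpatient=(834, 1418), ed=(38, 117), medication=(10467, 3987)),
        },
        "ir": {
            1: dict(inpatient=(667, 1651), outpatient=(857, 610), ed=(50, 131), medication=(12580, 3918)),
            2: dict(inpatient=(522, 1759), outpatient=(855, 867), ed=(35, 112), medication=(9263, 4966)),
            3: dict(inpatient=(526, 1516), outpatient=(884, 700), ed=(57, 142), medication=(8276, 4906)),
        },
    }
    return ScenarioSpec(
        n_patients=818,
        status_proportions={"stable": 258 / 818, "ir": 540 / 818, "unknown": 20 / 818},
        # cohort-level shares 36/20/17/8/3 (%) re-expressed among the 66% IR
        criterion_marginals={
            "low_adherence": 0.36 / 0.66,
            "oral_gc_increase": 0.20 / 0.66,
            "gc_injections": 0.17 / 0.66,
            "new_csdmard": 0.08 / 0.66,
            "switch_or_add": 0.03 / 0.66,
        },
        index_drug_mix={"adalimumab": 375 / 818, "etanercept": 443 / 818},
        switch_probability_by_drug={"adalimumab": 79 / 375, "etanercept": 56 / 443},
        switch_day_mean_by_drug={"adalimumab": 782.4, "etanercept": 755.6},
        switch_day_sd=180.0,
        switch_destinations={
            "adalimumab": {"etanercept": 32 / 79, "tocilizumab": 31 / 79,
                           "golimumab": 9 / 79, "abatacept": 7 / 79},
            "etanercept": {"adalimumab": 30 / 56, "tocilizumab": 13 / 56,
                           "golimumab": 8 / 56, "abatacept": 5 / 56},
        },
        year_retention={
            "stable": (1.0, 256 / 258, 243 / 258),
            "ir": (1.0, 529 / 540, 498 / 540),
            "unknown": (0.0, 0.0, 0.0),
        },
        hcru_means=t2,
        cost_means_usd=t3,
        demography={
            "stable": Demography(54.1, 11.6, 0.83),
            "ir": Demography(55.7, 13.4, 0.85),
            "unknown": Demography(69.1, 13.9, 0.70),
        },
        cci_mean={"stable": 1.48, "ir": 1.68, "unknown": 2.75},
        n_decoys=9,
        rng_seed=0,
    )


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------


def _largest_remainder(props: Mapping[str, float], n: int) -> dict[str, int]:
    raw = {k: p * n for k, p in props.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _mean_matched_ints(rng, n: int, target_mean: float, sd: float,
                       lo: int, hi: int) -> np.ndarray:
    """Integer draws in [lo, hi] whose sample mean matches the target
    (normal draw, then iterative clip-and-shift)."""
    target = float(np.clip(target_mean, lo, hi))
    x = rng.normal(target, sd, n)
    for _ in range(100):
        x = np.clip(x, lo, hi)
        err = target - x.mean()
        if abs(err) < 0.05:
            break
        x = x + err
    return np.rint(np.clip(x, lo, hi)).astype(int)


def _lognormal(rng, mean: float, sd: float, size=None):
    """Log-normal draws matching the requested mean and SD."""
    if mean <= 0:
        return np.zeros(size if size is not None else 1)
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _alloc_cents(total_cents: int, weights: Sequence[float]) -> list[int]:
    """Split an integer cent amount across claims proportionally; the last
    claim absorbs the rounding remainder so sums are exact."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(w))
    shares = np.floor(total_cents * w / w.sum()).astype(int)
    shares[-1] += total_cents - shares.sum()
    return shares.tolist()


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


class _Rows:
    """Accumulates table rows during generation."""

    def __init__(self) -> None:
        self.enrollment: list[tuple] = []
        self.cat: list[tuple] = []
        self.med: list[tuple] = []
        self.rx: list[tuple] = []

    def visit(self, pid, date, codes, injection=False, nonmed_cents=0, med_cents=0):
        self.med.append(
            (pid, "outpatient", date, date, ";".join(codes), injection,
             med_cents, nonmed_cents)
        )

    def ed(self, pid, date, nonmed_cents=0):
        self.med.append((pid, "ED", date, date, "7140", False, 0, nonmed_cents))

    def admission(self, pid, start, los_days, nonmed_cents=0):
        self.med.append(
            (pid, "inpatient", start, start + pd.Timedelta(days=int(los_days)),
             "7140", False, 0, nonmed_cents)
        )

    def dispense(self, pid, date, code, drug_class, agent="", days=30,
                 mg=np.nan, cents=0):
        self.rx.append((pid, date, code, drug_class, agent, int(days), mg, int(cents)))


def generate(
    spec: ScenarioSpec, config: StudyConfig = DEFAULT_CONFIG
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle plus the planted ground-truth table.

    Deterministic given ``spec.rng_seed``; the ground truth has one row per
    patient with the planted status, criterion flags, index drug/date,
    switch day/destination and censor day (decoy patients carry status
    ``excluded`` and the rule they are meant to fail).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    fu = config.follow_up_days
    study_end = pd.Timestamp(config.study_end)
    index_start = pd.Timestamp(config.index_period_start)
    n_index_days = (pd.Timestamp(config.index_period_end) - index_start).days + 1

    # ---- planted assignments (exact counts) ---------------------------
    status_counts = _largest_remainder(spec.status_proportions, n)
    statuses = np.array(
        [s for s, c in status_counts.items() for _ in range(c)], dtype=object
    )
    rng.shuffle(statuses)
    drug_counts = _largest_remainder(spec.index_drug_mix, n)
    drugs = np.array(
        [d for d, c in drug_counts.items() for _ in range(c)], dtype=object
    )
    rng.shuffle(drugs)

    ir_idx = np.flatnonzero(statuses == "ir")
    flags = {c: np.zeros(n, dtype=bool) for c in CRITERIA}
    if len(ir_idx):
        quotas = {
            c: int(round(spec.criterion_marginals.get(c, 0.0) * len(ir_idx)))
            for c in CRITERIA
        }
        # phase 1: every IR patient gets one criterion, drawn proportional
        # to the remaining quotas (guarantees >= 1 flag per IR patient)
        order = rng.permutation(ir_idx)
        for i in order:
            remaining = np.array([max(quotas[c], 0) for c in CRITERIA], dtype=float)
            if remaining.sum() <= 0:
                remaining = np.array(
                    [spec.criterion_marginals.get(c, 0.0) for c in CRITERIA]
                )
            pick = CRITERIA[rng.choice(len(CRITERIA), p=remaining / remaining.sum())]
            flags[pick][i] = True
            quotas[pick] -= 1
        # phase 2: distribute leftover quota among patients lacking the flag
        for c in CRITERIA:
            if quotas[c] > 0:
                lacking = np.array([i for i in ir_idx if not flags[c][i]])
                take = min(quotas[c], len(lacking))
                if take:
                    for i in rng.choice(lacking, size=take, replace=False):
                        flags[c][i] = True

    # ---- switchers ----------------------------------------------------
    switch_day = np.full(n, -1, dtype=int)
    switch_to = np.full(n, "", dtype=object)
    for drug, p_sw in spec.switch_probability_by_drug.items():
        drug_idx = np.flatnonzero(drugs == drug)
        n_sw = int(round(p_sw * len(drug_idx)))
        y1 = [i for i in drug_idx if flags["switch_or_add"][i]]
        if y1:
            switch_day[y1] = rng.integers(30, 335, size=len(y1))
        n_more = max(n_sw - len(y1), 0)
        eligible = np.array(
            [i for i in drug_idx
             if not flags["switch_or_add"][i] and statuses[i] != "unknown"]
        )
        more = (
            rng.choice(eligible, size=min(n_more, len(eligible)), replace=False)
            if n_more and len(eligible) else np.array([], dtype=int)
        )
        all_sw = np.concatenate([np.array(y1, dtype=int), more.astype(int)])
        if len(more):
            target = spec.switch_day_mean_by_drug.get(drug, 780.0)
            y1_sum = switch_day[y1].sum() if y1 else 0
            late_mean = (target * len(all_sw) - y1_sum) / len(more)
            switch_day[more] = _mean_matched_ints(
                rng, len(more), late_mean, spec.switch_day_sd, 366, 3 * 365 - 31
            )
        dest = spec.switch_destinations.get(drug, {})
        dest = {a: p for a, p in dest.items() if a != drug and p > 0}
        if len(all_sw) and dest:
            total = sum(dest.values())
            dest_counts = _largest_remainder(
                {a: p / total for a, p in sorted(dest.items())}, len(all_sw)
            )
            pool = np.array(
                [a for a, c in dest_counts.items() for _ in range(c)], dtype=object
            )
            rng.shuffle(pool)
            switch_to[all_sw] = pool

    # ---- censoring plan ----------------------------------------------
    censor_day = np.full(n, -1, dtype=int)  # year-1 censor (unknown only)
    obs_end = np.full(n, 3 * 365, dtype=int)  # last generated day offset
    unk = np.flatnonzero(statuses == "unknown")
    if len(unk):
        censor_day[unk] = rng.integers(30, 335, size=len(unk))
        obs_end[unk] = censor_day[unk] - 1
    for status in ("stable", "ir"):
        s_idx = np.flatnonzero(statuses == status)
        r1, r2, r3 = spec.year_retention.get(status, (1.0, 1.0, 1.0))
        n_y2 = int(round(r2 * len(s_idx)))
        n_y3 = int(round(r3 * len(s_idx)))
        non_sw = np.array([i for i in s_idx if switch_day[i] < 0])
        n_c2 = max(len(s_idx) - n_y2, 0)
        n_c3 = max(n_y2 - n_y3, 0)
        chosen = rng.choice(non_sw, size=min(n_c2 + n_c3, len(non_sw)), replace=False)
        c2, c3 = chosen[:n_c2], chosen[n_c2:]
        if len(c2):
            obs_end[c2] = rng.integers(365 + 31, 2 * 365 - 31, size=len(c2))
        if len(c3):
            obs_end[c3] = rng.integers(2 * 365 + 31, 3 * 365 - 31, size=len(c3))

    # ---- per-patient claim realization --------------------------------
    rows = _Rows()
    rate = config.exchange_rate_usd_per_ntd
    truth_rows = []

    for i in range(n):
        pid = f"P{i:05d}"
        rx_start = len(rows.rx)
        status = statuses[i]
        agent = drugs[i]
        demo = spec.demography.get(status) or next(iter(spec.demography.values()))
        index_date = index_start + pd.Timedelta(days=int(rng.integers(0, n_index_days)))
        age = int(np.clip(round(rng.normal(demo.age_mean, demo.age_sd)), 19, 90))
        birth = (index_date - pd.DateOffset(years=age)
                 - pd.Timedelta(days=int(rng.integers(0, 364))))
        sex = "female" if rng.random() < demo.female_fraction else "male"

        end_cov = min(index_date + pd.Timedelta(days=int(obs_end[i])), study_end)
        death = pd.NaT
        if status == "unknown" and rng.random() < 0.5:
            death = end_cov
        rows.enrollment.append(
            (pid, birth, sex, pd.Timestamp(config.study_start), end_cov, death)
        )
        rows.cat.append(
            (pid, "7140", index_date - pd.Timedelta(days=int(rng.integers(180, 360))))
        )

        # pre-index outpatient visits with RA code + planted comorbidity
        n_pre = max(int(rng.poisson(spec.background_visit_rate)), 1)
        pre_days = rng.integers(-config.pre_index_days, 0, size=n_pre)
        extra = min(int(rng.poisson(max(spec.cci_mean.get(status, 1.0) - 1.0, 0.0))),
                    len(_COMORBIDITY_CODES))
        comorb = list(rng.choice(_COMORBIDITY_CODES, size=extra, replace=False))
        for j, d in enumerate(sorted(pre_days)):
            codes = ["7140"] + ([comorb.pop()] if comorb and j < extra else [])
            rows.visit(pid, index_date + pd.Timedelta(days=int(d)), codes,
                       nonmed_cents=_PRE_VISIT_COST_CENTS)

        # background csDMARD (methotrexate, pre-index AND follow-up) and
        # background oral glucocorticoids
        has_mtx = rng.random() < 0.85
        if has_mtx:
            for d in (-300, -200, -100):
                rows.dispense(pid, index_date + pd.Timedelta(days=d),
                              CSDMARD_CODES["methotrexate"], "csDMARD")
            for d in (30, 120, 210, 300, 395, 485, 575, 665, 760, 850, 940, 1030):
                if d <= obs_end[i]:
                    rows.dispense(pid, index_date + pd.Timedelta(days=d),
                                  CSDMARD_CODES["methotrexate"], "csDMARD")
        gc_code = ORAL_GC_CODES["prednisolone"]
        if rng.random() < 0.8:  # bridging steroids at biologic start
            for d in (0, 30, 60):
                if d <= obs_end[i]:
                    rows.dispense(pid, index_date + pd.Timedelta(days=d), gc_code,
                                  "oral_GC", days=30, mg=300.0)
        if flags["oral_gc_increase"][i]:
            d0 = float(rng.choice([0.0, 2.5, 5.0]))
            d1 = d0 + 2.5 + float(rng.uniform(0.0, 2.5))
            if d0 > 0:
                for d in range(-360, 0, 30):
                    rows.dispense(pid, index_date + pd.Timedelta(days=d), gc_code,
                                  "oral_GC", days=30, mg=d0 * 365 / 12)
            cmp_days = list(range(90, 365, 30))
            for d in cmp_days:
                rows.dispense(pid, index_date + pd.Timedelta(days=d), gc_code,
                              "oral_GC", days=30, mg=d1 * 275 / len(cmp_days))
        elif rng.random() < 0.5:  # chronic user tapering (never an increase)
            for d in range(-360, 0, 30):
                rows.dispense(pid, index_date + pd.Timedelta(days=d), gc_code,
                              "oral_GC", days=30, mg=5.0 * 365 / 12)
            if status != "unknown":
                cmp_days = list(range(90, 365, 30))
                for d in cmp_days:
                    rows.dispense(pid, index_date + pd.Timedelta(days=d), gc_code,
                                  "oral_GC", days=30, mg=4.0 * 275 / len(cmp_days))

        # new csDMARD criterion: first-ever leflunomide after index
        if flags["new_csdmard"][i]:
            d = int(rng.integers(1, 365))
            rows.dispense(pid, index_date + pd.Timedelta(days=d),
                          CSDMARD_CODES["leflunomide"], "csDMARD")

        # index-agent coverage in year 1 (PDC construction)
        if status == "unknown":
            covered = int(obs_end[i]) + 1
        elif flags["low_adherence"][i]:
            covered = int(rng.integers(73, 292))  # PDC in [0.2, 0.8)
        else:
            covered = int(rng.integers(292, 366))  # PDC in [0.8, 1.0]
        d = 0
        while d < covered:
            chunk = min(28, covered - d)
            rows.dispense(pid, index_date + pd.Timedelta(days=d),
                          BDMARD_CODES[agent], "bDMARD", agent=agent, days=chunk)
            d += 28

        # the switch dispense and years 2-3 maintenance
        sday = int(switch_day[i])
        to_agent = str(switch_to[i])
        if sday >= 0 and to_agent:
            rows.dispense(pid, index_date + pd.Timedelta(days=sday),
                          BDMARD_CODES[to_agent], "bDMARD", agent=to_agent, days=28)
        if status != "unknown":
            for d in range(365, 3 * 365, 91):
                if d > obs_end[i]:
                    break
                cur = to_agent if (sday >= 0 and to_agent and d >= sday) else agent
                rows.dispense(pid, index_date + pd.Timedelta(days=d),
                              BDMARD_CODES[cur], "bDMARD", agent=cur, days=90)

        # follow-up utilization and costs, year by year
        hcru_all = spec.hcru_means.get(status) or spec.hcru_means["ir"]
        cost_all = spec.cost_means_usd.get(status) or spec.cost_means_usd["ir"]
        for k in (1, 2, 3):
            ws, we = 365 * (k - 1), 365 * k
            if ws > obs_end[i]:
                break
            frac = (min(we - 1, obs_end[i]) - ws + 1) / 365.0
            hcru = hcru_all[k]
            cost = cost_all[k]
            hi_day = min(we, obs_end[i] + 1)

            n_out = int(rng.poisson(hcru["outpatient_visits"] * frac))
            if k == 1 and flags["gc_injections"][i]:
                n_out = max(n_out, 2)
            out_days = sorted(rng.integers(ws, hi_day, size=n_out))
            out_total = int(round(_lognormal(
                rng, cost["outpatient"][0] / rate, cost["outpatient"][1] / rate
            ) * 100 * frac))
            out_cents = _alloc_cents(out_total, [1.0] * n_out) if n_out else []
            n_inj = 2 if (k == 1 and flags["gc_injections"][i]) else 0
            for j, d in enumerate(out_days):
                rows.visit(pid, index_date + pd.Timedelta(days=int(d)), ["7140"],
                           injection=j < n_inj, nonmed_cents=out_cents[j])

            lam_adm = hcru["admissions"] * frac
            n_adm = int(rng.poisson(lam_adm))
            if n_adm:
                los_mean = max(hcru["hospital_days"] / max(hcru["admissions"], 1e-9) - 1, 0.0)
                p_pos = -math.expm1(-max(lam_adm, 1e-9))
                adm_total = int(round(float(_lognormal(
                    rng, cost["inpatient"][0] / rate / p_pos,
                    0.95 * cost["inpatient"][0] / rate / p_pos,
                )) * 100))
                adm_cents = _alloc_cents(adm_total, [1.0] * n_adm)
                for j in range(n_adm):
                    los = 1 + int(rng.poisson(los_mean))
                    start = int(rng.integers(ws, max(hi_day - los, ws + 1)))
                    rows.admission(pid, index_date + pd.Timedelta(days=start), los,
                                   nonmed_cents=adm_cents[j])

            lam_ed = hcru["ed_visits"] * frac
            n_ed = int(rng.poisson(lam_ed))
            if n_ed:
                p_pos = -math.expm1(-max(lam_ed, 1e-9))
                ed_total = int(round(float(_lognormal(
                    rng, cost["ed"][0] / rate / p_pos,
                    0.95 * cost["ed"][0] / rate / p_pos,
                )) * 100))
                ed_cents = _alloc_cents(ed_total, [1.0] * n_ed)
                for j in range(n_ed):
                    d = int(rng.integers(ws, hi_day))
                    rows.ed(pid, index_date + pd.Timedelta(days=d), ed_cents[j])

            med_total = int(round(_lognormal(
                rng, cost["medication"][0] / rate, cost["medication"][1] / rate
            ) * 100 * frac))
            year_rx = [idx for idx in range(rx_start, len(rows.rx))
                       if ws <= (rows.rx[idx][1] - index_date).days < hi_day]
            if year_rx:
                weights = [rows.rx[idx][5] for idx in year_rx]
                for idx, cents in zip(year_rx, _alloc_cents(med_total, weights)):
                    r = rows.rx[idx]
                    rows.rx[idx] = r[:7] + (cents,)

        truth_rows.append(
            [pid, status, agent, index_date]
            + [bool(flags[c][i]) for c in CRITERIA]
            + [sday if sday >= 0 else np.nan, to_agent,
               censor_day[i] if censor_day[i] >= 0 else np.nan, age, sex, ""]
        )

    _add_decoys(rows, truth_rows, spec, config, rng)

    bundle = ClaimsBundle(
        enrollment=canonicalize_table("enrollment", pd.DataFrame(
            rows.enrollment,
            columns=["patient_id", "birth_date", "sex", "coverage_start",
                     "coverage_end", "death_date"],
        )),
        catastrophic_illness=canonicalize_table("catastrophic_illness", pd.DataFrame(
            rows.cat, columns=["patient_id", "icd9_code", "effective_date"]
        )),
        medical_claims=canonicalize_table("medical_claims", pd.DataFrame(
            rows.med,
            columns=["patient_id", "setting", "start_date", "end_date",
                     "diagnosis_codes", "is_gc_joint_injection",
                     "medication_cost_cents", "nonmedication_cost_cents"],
        )),
        pharmacy_claims=canonicalize_table("pharmacy_claims", pd.DataFrame(
            rows.rx,
            columns=["patient_id", "dispense_date", "drug_code", "drug_class",
                     "bdmard_agent", "days_supplied",
                     "prednisone_equivalent_mg_total", "cost_cents"],
        )),
    )
    validate_bundle(bundle)
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "status", "index_agent", "index_date"]
        + list(CRITERIA)
        + ["switch_day", "switch_to", "censor_day", "age", "sex", "exclusion_reason"],
    )
    return bundle, truth


DECOY_REASONS = (
    "prior_bdmard", "index_outside_period", "ambiguous_index", "no_ra_code",
    "no_card", "underage", "enrollment_gap", "excluded_condition", "malignancy",
)


def _add_decoys(rows: _Rows, truth_rows: list, spec: ScenarioSpec,
                config: StudyConfig, rng) -> None:
    """Patients engineered to fail exactly one selection rule each, so the
    attrition table is exercised; they never reach the final cohort."""
    for j in range(spec.n_decoys):
        reason = DECOY_REASONS[j % len(DECOY_REASONS)]
        pid = f"D{j:03d}"
        index_date = pd.Timestamp("2010-06-01") + pd.Timedelta(days=j)
        birth = index_date - pd.DateOffset(years=16 if reason == "underage" else 50)
        cov = [(pd.Timestamp(config.study_start), pd.Timestamp(config.study_end))]
        if reason == "enrollment_gap":
            cov = [
                (pd.Timestamp(config.study_start), pd.Timestamp("2009-08-01")),
                (pd.Timestamp("2009-10-01"), pd.Timestamp(config.study_end)),
            ]
        for s, e in cov:
            rows.enrollment.append((pid, birth, "female", s, e, pd.NaT))
        if reason != "no_card":
            rows.cat.append((pid, "7140", pd.Timestamp("2009-03-01")))
        ra_code = "7193" if reason == "no_ra_code" else "7140"
        for d in (-200, -50):
            rows.visit(pid, index_date + pd.Timedelta(days=d), [ra_code],
                       nonmed_cents=_PRE_VISIT_COST_CENTS)
        if reason == "excluded_condition":
            rows.visit(pid, index_date + pd.Timedelta(days=400), ["6961"])
        if reason == "malignancy":
            rows.visit(pid, index_date + pd.Timedelta(days=400), ["1530"])
        if reason == "prior_bdmard":
            rows.dispense(pid, pd.Timestamp("2009-05-15"),
                          BDMARD_CODES["etanercept"], "bDMARD",
                          agent="etanercept", days=28)
        if reason == "index_outside_period":
            rows.dispense(pid, pd.Timestamp("2011-02-15"),
                          BDMARD_CODES["adalimumab"], "bDMARD",
                          agent="adalimumab", days=28)
        else:
            rows.dispense(pid, index_date, BDMARD_CODES["adalimumab"], "bDMARD",
                          agent="adalimumab", days=28)
            if reason == "ambiguous_index":
                rows.dispense(pid, index_date, BDMARD_CODES["etanercept"],
                              "bDMARD", agent="etanercept", days=28)
        truth_rows.append(
            [pid, "excluded", "", index_date]
            + [False] * len(CRITERIA)
            + [np.nan, "", np.nan, 16 if reason == "underage" else 50,
               "female", reason]
        )


def add_nuisance_claims(
    bundle: ClaimsBundle, intensity: float, rng_seed: int
) -> ClaimsBundle:
    """Add outpatient visits whose diagnosis codes match no study code list
    (mean ``intensity`` extra claims per covered patient-year); the planted
    ground truth, and hence downstream classification, is unchanged."""
    if intensity < 0:
        raise ConfigError("intensity must be >= 0")
    if intensity == 0:
        return bundle
    rng = np.random.default_rng(rng_seed)
    new_rows = []
    enr = bundle.enrollment
    spans = enr.groupby("patient_id").agg(
        start=("coverage_start", "min"), end=("coverage_end", "max")
    )
    for pid, row in spans.iterrows():
        span_days = (row["end"] - row["start"]).days + 1
        n_extra = int(rng.poisson(intensity * span_days / 365.0))
        for _ in range(n_extra):
            d = row["start"] + pd.Timedelta(days=int(rng.integers(0, span_days)))
            code = str(rng.choice(SAFE_NUISANCE_CODES))
            new_rows.append((pid, "outpatient", d, d, code, False, 0, 0))
    extra = pd.DataFrame(new_rows, columns=bundle.medical_claims.columns)
    med = canonicalize_table(
        "medical_claims", pd.concat([bundle.medical_claims, extra], ignore_index=True)
    )
    return ClaimsBundle(
        enrollment=bundle.enrollment,
        catastrophic_illness=bundle.catastrophic_illness,
        medical_claims=med,
        pharmacy_claims=bundle.pharmacy_claims,
    )
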