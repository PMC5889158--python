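"""Charlson Comorbidity Index from ICD-9-CM claims (Deyo adaptation).

Seventeen diagnosis-defined categories with the original weights
(1, 2, 3 or 6).  Within a hierarchy group (diabetes, liver disease,
malignancy) the more severe category suppresses the milder one, so
a patient with both uncomplicated and complicated diabetes scores 2,
not 3.  Every RA cohort patient triggers the rheumatic-disease category
through the 714.x diagnosis itself, so cohort CCI means are >= 1; a
config switch excludes that category for sensitivity analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .codes import normalize_code
from .config import DEFAULT_CONFIG, StudyConfig


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    prefixes: tuple[str, ...]
    hierarchy_group: str | None = None
    severity_rank: int = 0  # higher rank suppresses lower within a group


@dataclass(frozen=True)
class CharlsonMap:
    categories: tuple[CharlsonCategory, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(names) != len(set(names)):
            raise ValueError("duplicate Charlson category names")

    def score(self, codes: Iterable[str], include: set[str] | None = None) -> tuple[int, dict[str, bool]]:
        """Return (CCI, per-category trigger flags after hierarchy suppression).

        ``include``, when given, restricts scoring to the named categories
        (used to drop the rheumatic-disease category on request); the raw
        trigger flags are reported for all categories regardless.
        """
        normed = {normalize_code(c) for c in codes}
        raw: dict[str, bool] = {}
        for cat in self.categories:
            raw[cat.name] = any(
                n.startswith(p) for n in normed for p in cat.prefixes
            )
        # hierarchy suppression: keep only the highest triggered rank per group
        flags = dict(raw)
        by_group: dict[str, list[CharlsonCategory]] = {}
        for cat in self.categories:
            if cat.hierarchy_group:
                by_group.setdefault(cat.hierarchy_group, []).append(cat)
        for group_cats in by_group.values():
            triggered = [c for c in group_cats if raw[c.name]]
            if len(triggered) > 1:
                top = max(triggered, key=lambda c: c.severity_rank)
                for c in triggered:
                    if c.name != top.name:
                        flags[c.name] = False
        score = sum(
            cat.weight
            for cat in self.categories
            if flags[cat.name] and (include is None or cat.name in include)
        )
        return score, flags


DEFAULT_CHARLSON_MAP = CharlsonMap(
    (
        CharlsonCategory("myocardial_infarction", 1, ("410", "412")),
        CharlsonCategory("congestive_heart_failure", 1, ("428",)),
        CharlsonCategory("peripheral_vascular_disease", 1, ("4439", "441", "7854", "V434")),
        CharlsonCategory("cerebrovascular_disease", 1, tuple(f"{i}" for i in range(430, 439))),
        CharlsonCategory("dementia", 1, ("290",)),
        CharlsonCategory(
            "chronic_pulmonary_disease", 1,
            tuple(f"{i}" for i in range(490, 506)) + ("5064",),
        ),
        CharlsonCategory(
            "rheumatic_disease", 1,
            ("7100", "7101", "7104", "7140", "7141", "7142", "71481", "725"),
        ),
        CharlsonCategory("peptic_ulcer_disease", 1, ("531", "532", "533", "534")),
        CharlsonCategory(
            "mild_liver_disease", 1, ("5712", "5714", "5715", "5716"),
            "liver", 1,
        ),
        CharlsonCategory(
            "diabetes_uncomplicated", 1, ("2500", "2501", "2502", "2503", "2507"),
            "diabetes", 1,
        ),
        CharlsonCategory(
            "diabetes_with_complications", 2, ("2504", "2505", "2506"),
            "diabetes", 2,
        ),
        CharlsonCategory("hemiplegia_paraplegia", 2, ("342", "3441")),
        CharlsonCategory(
            "renal_disease", 2,
            ("582", "5830", "5831", "5832", "5834", "5836", "5837",
             "585", "586", "5880"),
        ),
        CharlsonCategory(
            "any_malignancy", 2,
            tuple(f"{i}" for i in range(140, 173))
            + tuple(f"{i}" for i in range(174, 196))
            + tuple(f"{i}" for i in range(200, 209)),
            "cancer", 1,
        ),
        CharlsonCategory(
            "moderate_severe_liver_disease", 3,
            ("4560", "4561", "4562", "5722", "5723", "5724", "5728"),
            "liver", 2,
        ),
        CharlsonCategory(
            "metastatic_solid_tumor", 6, ("196", "197", "198", "199"),
            "cancer", 2,
        ),
        CharlsonCategory("aids_hiv", 6, ("042", "043", "044")),
    )
)


def compute_cci(
    codes: Iterable[str],
    cmap: CharlsonMap = DEFAULT_CHARLSON_MAP,
    count_ra: bool = True,
) -> tuple[int, dict[str, bool]]:
    """CCI for one patient's lookback diagnosis codes."""
    include = None
    if not count_ra:
        include = {c.name for c in cmap.categories} - {"rheumatic_disease"}
    return cmap.score(codes, include)


def cci_for_cohort(
    bundle,
    cohort: pd.DataFrame,
    cmap: CharlsonMap = DEFAULT_CHARLSON_MAP,
    config: StudyConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Baseline CCI per cohort patient.

    Lookback = the pre-index window plus the index date itself; a single
    claim in any setting triggers a category.
    """
    med = bundle.medical_claims.merge(
        cohort[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    day = (med["start_date"] - med["index_date"]).dt.days
    med = med[(day >= -config.pre_index_days) & (day <= 0)]
    codes_by_pat = (
        med.groupby("patient_id")["diagnosis_codes"]
        .apply(lambda s: [c for row in s for c in row.split(";")])
        .to_dict()
    )
    out = {}
    for pid in cohort["patient_id"]:
        score, _ = compute_cci(codes_by_pat.get(pid, []), cmap, config.cci_count_ra)
        out[pid] = score
    return pd.Series(out, name="cci").rename_axis("patient_id")


def write_charlson_csv(path: str | Path, cmap: CharlsonMap = DEFAULT_CHARLSON_MAP) -> None:
    """Export the mapping as an editable code-list file."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "icd9_prefix", "weight", "hierarchy_group", "severity_rank"])
        for cat in cmap.categories:
            for p in cat.prefixes:
                w.writerow([cat.name, p, cat.weight, cat.hierarchy_group or "", cat.severity_rank])
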