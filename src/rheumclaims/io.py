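"""Claim-table schemas, validation, and delimited-file round trip.

Five tables make up a :class:`ClaimsBundle`:

* ``enrollment`` — one row per coverage interval (closed date interval),
  with patient demographics repeated per row.
* ``catastrophic_illness`` — registry certifications (patient, ICD-9-CM
  code, effective date).
* ``medical_claims`` — encounters with setting (outpatient / inpatient /
  ED), dates, ';'-joined ICD-9-CM diagnosis codes, a glucocorticoid
  joint-injection procedure flag, and the claim's NT$ cost split into
  medication and non-medication lines.
* ``pharmacy_claims`` — drug dispensings with class, days supplied,
  prednisone-equivalent milligrams (oral glucocorticoids only) and NT$ cost.
* files are comma-delimited UTF-8 with a header row and ISO-8601 dates;
  costs are integer NT$ cents so sums are exact.

Every read validates all row-level invariants and raises a typed error
naming the table and row; writes are deterministic (byte-identical for
equal bundles).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codes import BDMARD_AGENTS, DRUG_CLASSES
from .errors import RowValidationError, SchemaError

SETTINGS = ("outpatient", "inpatient", "ED")
SEXES = ("male", "female")

TABLE_COLUMNS: Mapping[str, list[str]] = {
    "enrollment": [
        "patient_id", "birth_date", "sex",
        "coverage_start", "coverage_end", "death_date",
    ],
    "catastrophic_illness": ["patient_id", "icd9_code", "effective_date"],
    "medical_claims": [
        "patient_id", "setting", "start_date", "end_date", "diagnosis_codes",
        "is_gc_joint_injection", "medication_cost_cents", "nonmedication_cost_cents",
    ],
    "pharmacy_claims": [
        "patient_id", "dispense_date", "drug_code", "drug_class", "bdmard_agent",
        "days_supplied", "prednisone_equivalent_mg_total", "cost_cents",
    ],
}

_DATE_COLS = {
    "enrollment": ["birth_date", "coverage_start", "coverage_end", "death_date"],
    "catastrophic_illness": ["effective_date"],
    "medical_claims": ["start_date", "end_date"],
    "pharmacy_claims": ["dispense_date"],
}
_INT_COLS = {
    "medical_claims": ["medication_cost_cents", "nonmedication_cost_cents"],
    "pharmacy_claims": ["days_supplied", "cost_cents"],
}
_FLOAT_COLS = {"pharmacy_claims": ["prednisone_equivalent_mg_total"]}
_BOOL_COLS = {"medical_claims": ["is_gc_joint_injection"]}


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    return canonicalize_table(name, df)


def canonicalize_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a table to the package's canonical dtypes and column order."""
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    df = df[TABLE_COLUMNS[name]].copy()
    for c in _DATE_COLS.get(name, []):
        df[c] = pd.to_datetime(df[c], errors="raise")
    for c in _INT_COLS.get(name, []):
        df[c] = df[c].astype(np.int64) if len(df) else pd.Series(dtype=np.int64)
    for c in _FLOAT_COLS.get(name, []):
        df[c] = df[c].astype(np.float64) if len(df) else pd.Series(dtype=np.float64)
    for c in _BOOL_COLS.get(name, []):
        df[c] = df[c].astype(bool) if len(df) else pd.Series(dtype=bool)
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].fillna("").astype(str) if len(df) else df[c].astype(object)
    return df.reset_index(drop=True)


@dataclass
class ClaimsBundle:
    enrollment: pd.DataFrame
    catastrophic_illness: pd.DataFrame
    medical_claims: pd.DataFrame
    pharmacy_claims: pd.DataFrame

    @classmethod
    def empty(cls) -> "ClaimsBundle":
        return cls(**{f.name: _empty_table(f.name) for f in fields(cls)})

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(
            t.reset_index(drop=True).equals(o.reset_index(drop=True))
            for t, o in zip(self.tables().values(), other.tables().values())
        )

    def validate(self) -> None:
        validate_bundle(self)


# ---------------------------------------------------------------------------
# invariant validation
# ---------------------------------------------------------------------------


def _fail_first(name: str, bad: pd.Series, message: str) -> None:
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise RowValidationError(name, row, message)


_REQUIRED_DATES = {
    "enrollment": ["birth_date", "coverage_start", "coverage_end"],
    "catastrophic_illness": ["effective_date"],
    "medical_claims": ["start_date", "end_date"],
    "pharmacy_claims": ["dispense_date"],
}


def validate_bundle(bundle: ClaimsBundle) -> None:
    """Check every row-level invariant; raises :class:`RowValidationError`."""
    for name, df in bundle.tables().items():
        if len(df):
            for c in _REQUIRED_DATES[name]:
                _fail_first(name, df[c].isna(), f"missing required date {c!r}")
    enr = bundle.enrollment
    if len(enr):
        _fail_first("enrollment", ~enr["sex"].isin(SEXES),
                    f"sex must be one of {SEXES}")
        _fail_first("enrollment", enr["coverage_end"] < enr["coverage_start"],
                    "coverage_end precedes coverage_start")
        has_death = enr["death_date"].notna()
        _fail_first("enrollment", has_death & (enr["death_date"] < enr["birth_date"]),
                    "death_date precedes birth_date")
        # per-patient demographic consistency and sorted, non-overlapping intervals
        g = enr.groupby("patient_id", sort=False)
        for col in ("birth_date", "sex"):
            _fail_first("enrollment", g[col].transform("nunique") > 1,
                        f"{col} inconsistent across a patient's rows")
        prev_end = g["coverage_end"].shift(1)
        prev_start = g["coverage_start"].shift(1)
        _fail_first("enrollment",
                    prev_end.notna() & (enr["coverage_start"] <= prev_end),
                    "coverage intervals must be sorted and non-overlapping")
        _fail_first("enrollment",
                    prev_start.notna() & (enr["coverage_start"] < prev_start),
                    "coverage intervals must be sorted")

    cat = bundle.catastrophic_illness
    if len(cat):
        _fail_first("catastrophic_illness",
                    cat["icd9_code"].str.strip() == "", "empty icd9_code")

    med = bundle.medical_claims
    if len(med):
        _fail_first("medical_claims", ~med["setting"].isin(SETTINGS),
                    f"setting must be one of {SETTINGS}")
        same_day = med["setting"] != "inpatient"
        _fail_first("medical_claims", same_day & (med["end_date"] != med["start_date"]),
                    "outpatient/ED claims must have end_date == start_date")
        _fail_first("medical_claims", med["end_date"] < med["start_date"],
                    "end_date precedes start_date")
        _fail_first("medical_claims", med["diagnosis_codes"].str.strip() == "",
                    "at least one diagnosis code is required")
        for c in ("medication_cost_cents", "nonmedication_cost_cents"):
            _fail_first("medical_claims", med[c] < 0, f"{c} must be >= 0")

    rx = bundle.pharmacy_claims
    if len(rx):
        _fail_first("pharmacy_claims", ~rx["drug_class"].isin(DRUG_CLASSES),
                    f"drug_class must be one of {DRUG_CLASSES}")
        is_b = rx["drug_class"] == "bDMARD"
        _fail_first("pharmacy_claims", is_b & ~rx["bdmard_agent"].isin(BDMARD_AGENTS),
                    f"bDMARD rows need bdmard_agent in {BDMARD_AGENTS}")
        _fail_first("pharmacy_claims", ~is_b & (rx["bdmard_agent"] != ""),
                    "bdmard_agent only allowed when drug_class=bDMARD")
        is_gc = rx["drug_class"] == "oral_GC"
        mg = rx["prednisone_equivalent_mg_total"]
        _fail_first("pharmacy_claims", is_gc & (mg.isna() | (mg < 0)),
                    "oral_GC rows need non-negative prednisone_equivalent_mg_total")
        _fail_first("pharmacy_claims", ~is_gc & mg.notna(),
                    "prednisone_equivalent_mg_total only allowed for oral_GC")
        _fail_first("pharmacy_claims", rx["days_supplied"] < 1,
                    "days_supplied must be >= 1")
        _fail_first("pharmacy_claims", rx["cost_cents"] < 0, "cost_cents must be >= 0")


# ---------------------------------------------------------------------------
# delimited-file round trip
# ---------------------------------------------------------------------------


def table_paths(directory: str | Path) -> dict[str, Path]:
    d = Path(directory)
    return {name: d / f"{name}.csv" for name in TABLE_COLUMNS}


def write_tables(bundle: ClaimsBundle, directory: str | Path) -> dict[str, Path]:
    """Write the five CSVs; byte-identical for equal bundles."""
    validate_bundle(bundle)
    paths = table_paths(directory)
    Path(directory).mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        out = df.copy()
        for c in _DATE_COLS.get(name, []):
            out[c] = out[c].dt.strftime("%Y-%m-%d").fillna("") if len(out) else ""
        for c in _BOOL_COLS.get(name, []):
            out[c] = out[c].map({True: "true", False: "false"}) if len(out) else ""
        for c in _FLOAT_COLS.get(name, []):
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(float(v))) if len(out) else ""
        out.to_csv(paths[name], index=False, lineterminator="\n")
    return paths


def _parse_col(name: str, col: str, raw: pd.Series, kind: str) -> pd.Series:
    present = raw.str.strip() != ""
    if kind == "date":
        parsed = pd.to_datetime(raw.where(present), format="%Y-%m-%d", errors="coerce")
        bad = present & parsed.isna()
    elif kind == "int":
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round())
    elif kind == "float":
        def _f(s: str):
            try:  # correctly-rounded conversion (round-trips repr exactly)
                return float(s)
            except ValueError:
                return None
        vals = raw.str.strip().map(lambda s: _f(s) if s else np.nan)
        bad = vals.map(lambda v: v is None)
        parsed = vals.map(lambda v: np.nan if v is None else v).astype(np.float64)
    elif kind == "bool":
        parsed = raw.map({"true": True, "false": False})
        bad = parsed.isna()
    else:  # pragma: no cover
        raise ValueError(kind)
    _fail_first(name, bad, f"unparseable {kind} in column {col!r}")
    if kind == "int":
        parsed = parsed.astype(np.int64)
    if kind == "bool":
        parsed = parsed.astype(bool)
    return parsed


def read_tables(directory: str | Path) -> ClaimsBundle:
    """Read and fully validate a bundle from a directory of CSVs."""
    paths = table_paths(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        if not Path(path).exists():
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing column(s) {missing}")
        df = df[TABLE_COLUMNS[name]]
        if len(df):
            for c in _DATE_COLS.get(name, []):
                df[c] = _parse_col(name, c, df[c], "date")
            for c in _INT_COLS.get(name, []):
                df[c] = _parse_col(name, c, df[c], "int")
            for c in _FLOAT_COLS.get(name, []):
                df[c] = _parse_col(name, c, df[c], "float")
            for c in _BOOL_COLS.get(name, []):
                df[c] = _parse_col(name, c, df[c], "bool")
            frames[name] = df
        else:
            frames[name] = _empty_table(name)
    bundle = ClaimsBundle(**frames)
    validate_bundle(bundle)
    return bundle
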