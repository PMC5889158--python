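"""Study configuration: windows, thresholds and conversion rates.

All analysis windows are half-open day intervals relative to the index date
(day 0 = index date).  The defaults reproduce the published decision rules:
a 2010 index period with 365-day pre-index and follow-up windows, a PDC
threshold of 0.80 (strictly below flags low adherence), "more than one"
glucocorticoid joint injection, a 90-day bridging exclusion at the start of
follow-up for the oral-glucocorticoid dose comparison, a <30-day tolerance
for enrollment breaks, and 1 NT$ = 0.033 USD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date
from pathlib import Path

from .errors import ConfigError


@dataclass(frozen=True)
class StudyConfig:
    index_period_start: date = date(2010, 1, 1)
    index_period_end: date = date(2010, 12, 31)  # inclusive
    study_start: date = date(2009, 1, 1)
    study_end: date = date(2013, 12, 31)
    pre_index_days: int = 365
    follow_up_days: int = 365
    pdc_threshold: float = 0.80
    gc_injection_min_count: int = 2
    gc_increase_margin_pct: float = 0.0
    gc_bridging_exclusion_days: int = 90
    enrollment_gap_tolerance_days: int = 30  # exclusive bound: a 30-day gap fails
    exchange_rate_usd_per_ntd: float = 0.033
    # Whether the RA catastrophic-illness certification must predate (or equal)
    # the index date for cohort inclusion.
    require_card_before_index: bool = True
    # Whether the rheumatic-disease Charlson category (which every cohort
    # patient triggers through the RA diagnosis) counts toward the CCI.
    cci_count_ra: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.index_period_end < self.index_period_start:
            raise ConfigError("index period end precedes start")
        for name in ("pre_index_days", "follow_up_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.pdc_threshold <= 1.0):
            raise ConfigError("pdc_threshold must lie in (0, 1]")
        if self.gc_injection_min_count < 1:
            raise ConfigError("gc_injection_min_count must be >= 1")
        if self.gc_increase_margin_pct < 0:
            raise ConfigError("gc_increase_margin_pct must be >= 0")
        if not (0 <= self.gc_bridging_exclusion_days < self.follow_up_days):
            raise ConfigError("gc_bridging_exclusion_days out of range")
        if self.exchange_rate_usd_per_ntd <= 0:
            raise ConfigError("exchange rate must be positive")

    # -- flat key=value persistence -------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}={v.isoformat() if isinstance(v, date) else v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            raw[k.strip()] = v.strip()
        kwargs = {}
        by_name = {f.name: f for f in fields(cls)}
        for k, v in raw.items():
            if k not in by_name:
                raise ConfigError(f"unknown config key {k!r}")
            typ = by_name[k].type
            try:
                if typ == "date":
                    kwargs[k] = date.fromisoformat(v)
                elif typ == "int":
                    kwargs[k] = int(v)
                elif typ == "float":
                    kwargs[k] = float(v)
                elif typ == "bool":
                    kwargs[k] = v.lower() in ("1", "true", "yes")
                else:
                    kwargs[k] = v
            except ValueError as e:
                raise ConfigError(f"bad value for {k}: {v!r}") from e
        return cls(**kwargs)


DEFAULT_CONFIG = StudyConfig()
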