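"""ICD-9-CM / drug code lists and prefix matching.

NHIRD claims record ICD-9-CM codes at varying precision (three, four or five
digits, with or without the decimal point), so diagnosis code lists match on
the dot-stripped prefix: list entry ``714`` matches ``714.0``, ``7140`` and
``71481`` alike.  Published "xx" wildcards become prefixes ("714.3x" ->
prefix ``7143``); numeric ranges such as 140-208 are expanded to explicit
three-digit prefixes at build time.  Drug code lists match exactly on the
(ATC-style) dispensing code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CodeListError

# ---------------------------------------------------------------------------
# normalization and the CodeList primitive
# ---------------------------------------------------------------------------


def normalize_code(code: str) -> str:
    """Uppercase, strip the decimal point and any trailing wildcard x's."""
    c = str(code).strip().upper().replace(".", "")
    return c.rstrip("X")


@dataclass(frozen=True)
class CodeList:
    """A named set of code prefixes (or exact codes) with optional carve-outs.

    A code matches when it matches at least one include entry and no exclude
    entry; the malignancy list, for example, includes prefixes 140-208 but
    excludes 173 (non-melanoma skin cancer).
    """

    name: str
    entries: frozenset[str]
    match_rule: str = "prefix"  # "prefix" | "exact"
    exclude_entries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.match_rule not in ("prefix", "exact"):
            raise CodeListError(f"{self.name}: unknown match_rule {self.match_rule!r}")
        if not self.entries:
            raise CodeListError(f"{self.name}: empty code list")

    def matches(self, code: str) -> bool:
        c = normalize_code(code)
        if not c:
            return False
        if self.match_rule == "exact":
            hit = c in self.entries
        else:
            hit = any(c.startswith(e) for e in self.entries)
        if hit and self.exclude_entries:
            if self.match_rule == "exact":
                return c not in self.exclude_entries
            return not any(c.startswith(e) for e in self.exclude_entries)
        return hit

    def matches_any(self, codes: Iterable[str]) -> bool:
        return any(self.matches(c) for c in codes)


def expand_numeric_range(start: int, stop: int) -> list[str]:
    """Expand an inclusive three-digit ICD-9 chapter range to prefixes."""
    if not (0 < start <= stop <= 999):
        raise CodeListError(f"bad numeric range {start}-{stop}")
    return [f"{i:03d}" for i in range(start, stop + 1)]


# ---------------------------------------------------------------------------
# drug vocabulary (ATC-style dispensing codes used throughout the package)
# ---------------------------------------------------------------------------

BDMARD_AGENTS = ("abatacept", "adalimumab", "etanercept", "golimumab", "tocilizumab")

BDMARD_CODES: Mapping[str, str] = {
    "abatacept": "L04AA24",
    "adalimumab": "L04AB04",
    "etanercept": "L04AB01",
    "golimumab": "L04AB06",
    "tocilizumab": "L04AC07",
}

CSDMARD_CODES: Mapping[str, str] = {
    "methotrexate": "L04AX03",
    "leflunomide": "L04AA13",
    "hydroxychloroquine": "P01BA02",
    "sulfasalazine": "A07EC01",
    "azathioprine": "L04AX01",
}

ORAL_GC_CODES: Mapping[str, str] = {
    "prednisolone": "H02AB06",
    "methylprednisolone": "H02AB04",
    "prednisone": "H02AB07",
}

# mg prednisone-equivalent per mg of drug (anti-inflammatory potency;
# 5 mg prednisone == 5 mg prednisolone == 4 mg methylprednisolone ==
# 0.75 mg dexamethasone == 20 mg hydrocortisone)
GC_PREDNISONE_EQUIVALENCE: Mapping[str, float] = {
    "prednisone": 1.0,
    "prednisolone": 1.0,
    "methylprednisolone": 1.25,
    "dexamethasone": 20 / 3,
    "hydrocortisone": 0.25,
}

DRUG_CLASSES = ("bDMARD", "csDMARD", "oral_GC", "injectable_GC", "NSAID", "other")


# ---------------------------------------------------------------------------
# built-in study code lists
# ---------------------------------------------------------------------------


def default_code_lists() -> dict[str, CodeList]:
    """The study's diagnosis and drug code lists.

    * ``ra_diagnosis`` — 714.xx excluding 714.3x.
    * ``exclusion_conditions`` — psoriasis/psoriatic arthritis 696.xx,
      ankylosing spondylitis 720.0x, Crohn's 555.xx, ulcerative colitis
      556.xx, juvenile chronic polyarthritis 714.3x.
    * ``exclusion_malignancy_hiv`` — solid/hematologic malignancy 140-208.xx
      except non-melanoma skin cancer 173.xx, plus HIV/AIDS 042-044.xx.
    * drug lists for the five in-scope biologics, csDMARD compounds and
      oral glucocorticoids (exact match on dispensing code).
    * ``charlson:<category>`` — one diagnosis list per Charlson category.
    """
    from .charlson import DEFAULT_CHARLSON_MAP  # avoids a module cycle

    lists: dict[str, CodeList] = {
        "ra_diagnosis": CodeList(
            "ra_diagnosis", frozenset({"714"}), "prefix", frozenset({"7143"})
        ),
        "exclusion_conditions": CodeList(
            "exclusion_conditions",
            frozenset({"696", "7200", "555", "556", "7143"}),
            "prefix",
        ),
        "exclusion_malignancy_hiv": CodeList(
            "exclusion_malignancy_hiv",
            frozenset(expand_numeric_range(140, 208)) | {"042", "043", "044"},
            "prefix",
            frozenset({"173"}),
        ),
        "bdmard_agents": CodeList(
            "bdmard_agents", frozenset(BDMARD_CODES.values()), "exact"
        ),
        "csdmard_agents": CodeList(
            "csdmard_agents", frozenset(CSDMARD_CODES.values()), "exact"
        ),
        "oral_glucocorticoids": CodeList(
            "oral_glucocorticoids", frozenset(ORAL_GC_CODES.values()), "exact"
        ),
    }
    for cat in DEFAULT_CHARLSON_MAP.categories:
        lists[f"charlson:{cat.name}"] = CodeList(
            f"charlson:{cat.name}", frozenset(cat.prefixes), "prefix"
        )
    return lists


# ---------------------------------------------------------------------------
# CSV persistence: (list_name, entry, match_rule, polarity)
# ---------------------------------------------------------------------------

_CODELIST_HEADER = ["list_name", "entry", "match_rule", "polarity"]


def write_code_lists(lists: Mapping[str, CodeList], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CODELIST_HEADER)
        for name in sorted(lists):
            cl = lists[name]
            for e in sorted(cl.entries):
                w.writerow([name, e, cl.match_rule, "include"])
            for e in sorted(cl.exclude_entries):
                w.writerow([name, e, cl.match_rule, "exclude"])


def load_code_lists(path: str | Path) -> dict[str, CodeList]:
    """Read named code lists from a (list_name, entry, match_rule, polarity) CSV."""
    inc: dict[str, set[str]] = {}
    exc: dict[str, set[str]] = {}
    rule: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames is None or [c.strip() for c in r.fieldnames] != _CODELIST_HEADER:
            raise CodeListError(
                f"expected header {_CODELIST_HEADER}, got {r.fieldnames}"
            )
        for i, row in enumerate(r, 1):
            name = row["list_name"].strip()
            if not name:
                raise CodeListError(f"row {i}: empty list name")
            entry = normalize_code(row["entry"])
            if not entry:
                raise CodeListError(f"row {i}: empty entry in list {name!r}")
            mr = row["match_rule"].strip()
            if name in rule and rule[name] != mr:
                raise CodeListError(f"row {i}: conflicting match_rule for {name!r}")
            rule[name] = mr
            pol = row["polarity"].strip()
            if pol == "include":
                inc.setdefault(name, set()).add(entry)
            elif pol == "exclude":
                exc.setdefault(name, set()).add(entry)
            else:
                raise CodeListError(f"row {i}: polarity must be include|exclude")
    out: dict[str, CodeList] = {}
    for name in rule:
        if name not in inc:
            raise CodeListError(f"list {name!r} has no include entries")
        out[name] = CodeList(
            name, frozenset(inc[name]), rule[name], frozenset(exc.get(name, set()))
        )
    return out
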