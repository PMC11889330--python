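"""ACMG/AMP evidence combination.

Implements the published 2015 combining rules in full: coded evidence items
(PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1, BS1-4, BP1-7 on the
benign side) are combined into one of five classes.  BA1 is stand-alone
benign.  When a pathogenic-side rule and a benign-side rule are satisfied
simultaneously the evidence is contradictory and the variant is a VUS, as
is any evidence set meeting no rule.

The engine classifies from supplied codes only; it never derives codes from
data.  The one bridge from the trio layer — a segregation observation that
may support PP1 — is surfaced as a *suggestion*, never auto-applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "VALID_CODES",
    "CLASSES",
    "AcmgEvidence",
    "combine",
    "classify_table",
    "read_evidence_table",
]

_PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
_BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
VALID_CODES = frozenset(_PATHOGENIC_CODES + _BENIGN_CODES)

CLASSES = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of ACMG criterion codes; unknown codes are rejected."""

    codes: frozenset[str]

    def __init__(self, codes: Iterable[str]):
        codes = frozenset(c.strip().upper() for c in codes if c.strip())
        unknown = codes - VALID_CODES
        if unknown:
            raise ValueError(
                f"unknown ACMG code(s) {sorted(unknown)}; valid codes: "
                f"{sorted(VALID_CODES)}"
            )
        object.__setattr__(self, "codes", codes)

    @classmethod
    def from_string(cls, s: str) -> "AcmgEvidence":
        """Parse a comma-separated code list, e.g. ``"PM1, PM2, PP2, PP3"``."""
        return cls(s.split(",")) if s.strip() else cls([])

    def counts(self) -> dict[str, int]:
        c = self.codes
        return {
            "pvs": sum(1 for x in c if x == "PVS1"),
            "ps": sum(1 for x in c if x.startswith("PS")),
            "pm": sum(1 for x in c if x.startswith("PM")),
            "pp": sum(1 for x in c if x.startswith("PP")),
            "ba": sum(1 for x in c if x == "BA1"),
            "bs": sum(1 for x in c if x.startswith("BS")),
            "bp": sum(1 for x in c if x.startswith("BP")),
        }


def _pathogenic(n: dict[str, int]) -> bool:
    return (
        (n["pvs"] >= 1 and n["ps"] >= 1)
        or (n["pvs"] >= 1 and n["pm"] >= 2)
        or (n["pvs"] >= 1 and n["pm"] >= 1 and n["pp"] >= 1)
        or (n["pvs"] >= 1 and n["pp"] >= 2)
        or n["ps"] >= 2
        or (n["ps"] >= 1 and n["pm"] >= 3)
        or (n["ps"] >= 1 and n["pm"] >= 2 and n["pp"] >= 2)
        or (n["ps"] >= 1 and n["pm"] >= 1 and n["pp"] >= 4)
    )


def _likely_pathogenic(n: dict[str, int]) -> bool:
    return (
        (n["pvs"] >= 1 and n["pm"] >= 1)
        or (n["ps"] >= 1 and n["pm"] >= 1)
        or (n["ps"] >= 1 and n["pp"] >= 2)
        or n["pm"] >= 3
        or (n["pm"] >= 2 and n["pp"] >= 2)
        or (n["pm"] >= 1 and n["pp"] >= 4)
    )


def _benign(n: dict[str, int]) -> bool:
    return n["ba"] >= 1 or n["bs"] >= 2


def _likely_benign(n: dict[str, int]) -> bool:
    return (n["bs"] >= 1 and n["bp"] >= 1) or n["bp"] >= 2


def combine(ev: AcmgEvidence) -> str:
    """Combine an evidence set into one of the five classes."""
    n = ev.counts()
    path_side = _pathogenic(n) or _likely_pathogenic(n)
    benign_side = _benign(n) or _likely_benign(n)
    if path_side and benign_side:
        return "vus"  # contradictory evidence
    if _pathogenic(n):
        return "pathogenic"
    if _likely_pathogenic(n):
        return "likely_pathogenic"
    if _benign(n):
        return "benign"
    if _likely_benign(n):
        return "likely_benign"
    return "vus"


def classify_table(
    rows: Sequence[tuple[str, AcmgEvidence]],
) -> list[tuple[str, str]]:
    """Apply :func:`combine` row-wise to (variant_id, evidence) pairs."""
    return [(vid, combine(ev)) for vid, ev in rows]


def class_counts(classified: Sequence[tuple[str, str]]) -> dict[str, int]:
    out = {c: 0 for c in CLASSES}
    for _, cls in classified:
        out[cls] += 1
    return out


def read_evidence_table(path: str) -> list[tuple[str, AcmgEvidence]]:
    """Read a TSV of variant_id and comma-separated ACMG codes."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant_id" not in df.columns or "acmg_codes" not in df.columns:
        raise ValueError(f"{path}: evidence table needs columns variant_id, acmg_codes")
    return [
        (row["variant_id"], AcmgEvidence.from_string(row["acmg_codes"]))
        for _, row in df.iterrows()
    ]
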