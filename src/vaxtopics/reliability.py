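"""Coding-scheme data structures and inter-rater reliability.

Qualitative content analysis of the prominent topics proceeds in two
phases — inductive topic identification, then deductive assignment of the
four message-framing dimensions (problem definition, causal
interpretation, moral evaluation, remedy recommendation).  This module
holds the machine-readable coding records and computes two-coder
agreement: the contingency table and the unweighted Cohen kappa
chance-corrected agreement statistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_CATEGORIES",
    "EntmanFrame",
    "CodingRecord",
    "agreement_table",
    "cohen_kappa",
    "KappaResult",
    "read_coding_records",
    "write_coding_records",
    "codes_by_item",
]

#: The four message-framing dimensions.
FRAME_CATEGORIES = (
    "problem_definition",
    "causal_interpretation",
    "moral_evaluation",
    "remedy_recommendation",
)

PHASES = ("topic", "frame")


@dataclass(frozen=True)
class EntmanFrame:
    """One of the four message-frame categories, with an optional note."""

    category: str
    note: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FRAME_CATEGORIES:
            raise ValueError(f"category must be one of {FRAME_CATEGORIES}")


@dataclass(frozen=True)
class CodingRecord:
    """One coder's code for one item in one phase."""

    item_id: str
    coder_id: str
    phase: str
    code: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if not self.item_id or not self.coder_id:
            raise ValueError("item_id and coder_id must be non-empty")


def agreement_table(
    a: Mapping[str, str],
    b: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Square contingency table of two coders over the same item set.

    Entry (i, j) counts items coded category i by coder A and j by coder
    B.  Category order is shared between rows and columns: sorted union of
    observed codes unless given explicitly.
    """
    if not a or not b:
        raise ValueError("codings must be non-empty")
    if set(a) != set(b):
        raise ValueError("both coders must code the same item set")
    if categories is None:
        categories = sorted(set(a.values()) | set(b.values()))
    else:
        categories = list(categories)
        unknown = (set(a.values()) | set(b.values())) - set(categories)
        if unknown:
            raise ValueError(f"codes outside the category list: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(categories)}
    M = np.zeros((len(categories), len(categories)), dtype=int)
    for item in a:
        M[idx[a[item]], idx[b[item]]] += 1
    return pd.DataFrame(M, index=categories, columns=categories)


@dataclass(frozen=True)
class KappaResult:
    """Observed/expected agreement and the kappa statistic."""

    p_o: float
    p_e: float
    kappa: float
    n_items: int


def cohen_kappa(table: pd.DataFrame | np.ndarray) -> KappaResult:
    """Unweighted Cohen kappa from a square contingency table.

    p_o = trace / n; p_e = sum of row-margin x column-margin products over
    n^2; kappa = (p_o - p_e) / (1 - p_e), defined as 1 when both coders
    agree perfectly on a single category (p_e = 1).
    """
    M = np.asarray(table, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(M < 0):
        raise ValueError("contingency table entries must be nonnegative")
    n = M.sum()
    if n < 1:
        raise ValueError("contingency table must count at least one item")
    p_o = float(np.trace(M) / n)
    p_e = float((M.sum(axis=1) * M.sum(axis=0)).sum() / n**2)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(p_o=p_o, p_e=p_e, kappa=float(kappa), n_items=int(n))


def write_coding_records(records: Sequence[CodingRecord], path: str | Path) -> None:
    """Write coding records as CSV (item_id, coder_id, phase, code)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_id", "coder_id", "phase", "code"])
        for r in records:
            w.writerow([r.item_id, r.coder_id, r.phase, r.code])


def read_coding_records(path: str | Path) -> list[CodingRecord]:
    """Read coding records from CSV."""
    out = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CodingRecord(
                    item_id=row["item_id"],
                    coder_id=row["coder_id"],
                    phase=row["phase"],
                    code=row["code"],
                )
            )
    return out


def codes_by_item(
    records: Sequence[CodingRecord], coder_id: str, phase: str
) -> dict[str, str]:
    """Extract one coder's item -> code map for a phase (uniqueness enforced)."""
    out: dict[str, str] = {}
    for r in records:
        if r.coder_id == coder_id and r.phase == phase:
            if r.item_id in out:
                raise ValueError(
                    f"duplicate coding for item {r.item_id!r} by {coder_id!r} in phase {phase!r}"
                )
            out[r.item_id] = r.code
    return out
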