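"""Beneficiary/diagnosis table I/O and the four-way cohort split.

The interchange format is two comma-separated UTF-8 tables with header rows:

* a beneficiary table with columns ``id, age, sex, observed_cost`` plus any
  number of extra subgroup columns (race, geography, ...), one row per
  beneficiary;
* a long-format diagnosis table with columns ``id, code``, one row per
  recorded (beneficiary, diagnosis-code) pair.

Diagnosis codes are treated as an unordered, deduplicated set per
beneficiary-year.  Sex is a two-level category written as ``F``/``M`` on
disk; costs are non-negative USD written with two fractional digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPLIT_LABELS",
    "DEFAULT_SPLIT_FRACTIONS",
    "Beneficiary",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]

#: Cohort roles, in the order the split fractions refer to them.
SPLIT_LABELS: tuple[str, ...] = ("embeddings", "training", "validation", "test")

#: Default split fractions: embeddings 20%, training 40%, validation 20%, test 20%.
DEFAULT_SPLIT_FRACTIONS: tuple[float, ...] = (0.2, 0.4, 0.2, 0.2)

_REQUIRED_BENEFICIARY_COLUMNS = ("id", "age", "sex", "observed_cost")
_SEX_LEVELS = ("F", "M")


@dataclass(frozen=True)
class Beneficiary:
    """One person-year record: demographics, cost outcome and diagnosis set."""

    id: str
    age: int
    sex: str  # "F" or "M"
    observed_cost: float
    dx_codes: frozenset[str] = frozenset()
    subgroups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in _SEX_LEVELS:
            raise ValueError(f"sex must be one of {_SEX_LEVELS}, got {self.sex!r}")
        if self.observed_cost < 0:
            raise ValueError(f"observed_cost must be >= 0, got {self.observed_cost}")


class Cohort:
    """A collection of beneficiaries with optional train/test split labels.

    Internally a pandas DataFrame (one row per beneficiary, ``id`` column
    unique) plus a parallel list of frozen diagnosis-code sets.  Extra
    DataFrame columns beyond ``id, age, sex, observed_cost, split`` are
    treated as subgroup attributes.
    """

    def __init__(self, table: pd.DataFrame, dx: Sequence[frozenset[str]]):
        table = table.reset_index(drop=True)
        missing = [c for c in _REQUIRED_BENEFICIARY_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"beneficiary table missing required column(s): {missing}")
        if len(dx) != len(table):
            raise ValueError("dx list length must equal table length")
        if table["id"].duplicated().any():
            dups = table.loc[table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate beneficiary ids: {dups[:5]}")
        if (table["observed_cost"] < 0).any():
            raise ValueError("observed_cost must be >= 0 for all beneficiaries")
        bad_sex = set(table["sex"]) - set(_SEX_LEVELS)
        if bad_sex:
            raise ValueError(f"unknown sex level(s): {sorted(bad_sex)}")
        self.table = table
        self.dx = [frozenset(s) for s in dx]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def subgroup_columns(self) -> list[str]:
        skip = set(_REQUIRED_BENEFICIARY_COLUMNS) | {"split"}
        return [c for c in self.table.columns if c not in skip]

    def beneficiary(self, i: int) -> Beneficiary:
        row = self.table.iloc[i]
        subgroups = {c: row[c] for c in self.subgroup_columns}
        return Beneficiary(
            id=str(row["id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            observed_cost=float(row["observed_cost"]),
            dx_codes=self.dx[i],
            subgroups=subgroups,
        )

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        table = self.table.loc[mask].reset_index(drop=True)
        dx = [s for s, m in zip(self.dx, mask) if m]
        return Cohort(table, dx)

    def split(self, label: str) -> "Cohort":
        """Return the sub-cohort carrying the given split label."""
        if "split" not in self.table.columns:
            raise ValueError("cohort has no split labels; call split_cohort first")
        if label not in SPLIT_LABELS:
            raise ValueError(f"unknown split label {label!r}; expected one of {SPLIT_LABELS}")
        return self.subset((self.table["split"] == label).to_numpy())

    def equals(self, other: "Cohort") -> bool:
        return self.table.equals(other.table) and self.dx == other.dx


def read_cohort(beneficiary_table: str | Path, diagnosis_table: str | Path) -> Cohort:
    """Load a cohort from the two delimited tables.

    Beneficiaries absent from the diagnosis table get empty code sets;
    duplicate (id, code) rows collapse to one.  Diagnosis rows whose id does
    not appear in the beneficiary table are an error.
    """
    bene = pd.read_csv(beneficiary_table, dtype={"id": str, "sex": str})
    missing = [c for c in _REQUIRED_BENEFICIARY_COLUMNS if c not in bene.columns]
    if missing:
        raise ValueError(f"beneficiary table missing required column(s): {missing}")
    bene["age"] = bene["age"].astype(int)
    bene["observed_cost"] = bene["observed_cost"].astype(float)

    dx_long = pd.read_csv(diagnosis_table, dtype={"id": str, "code": str})
    missing_dx = [c for c in ("id", "code") if c not in dx_long.columns]
    if missing_dx:
        raise ValueError(f"diagnosis table missing required column(s): {missing_dx}")

    known = set(bene["id"])
    unknown = sorted(set(dx_long["id"]) - known)
    if unknown:
        raise ValueError(f"diagnosis table references unknown beneficiary id(s): {unknown[:10]}")

    codes_by_id: dict[str, set[str]] = {}
    for bid, code in zip(dx_long["id"], dx_long["code"]):
        codes_by_id.setdefault(bid, set()).add(code)
    dx = [frozenset(codes_by_id.get(bid, ())) for bid in bene["id"]]
    return Cohort(bene, dx)


def write_cohort(
    cohort: Cohort, beneficiary_table: str | Path, diagnosis_table: str | Path
) -> None:
    """Write the two delimited tables (costs with 2 fractional digits)."""
    out = cohort.table.copy()
    out["observed_cost"] = out["observed_cost"].map(lambda v: f"{v:.2f}")
    out.to_csv(beneficiary_table, index=False)

    rows: list[tuple[str, str]] = []
    for bid, codes in zip(cohort.table["id"], cohort.dx):
        rows.extend((bid, code) for code in sorted(codes))
    pd.DataFrame(rows, columns=["id", "code"]).to_csv(diagnosis_table, index=False)


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer group sizes summing to n, each within 1 of n*fraction."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def split_cohort(
    cohort: Cohort,
    fractions: Sequence[float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
) -> Cohort:
    """Label each beneficiary with one of the four cohort roles.

    A seeded permutation is cut into contiguous blocks sized by
    largest-remainder rounding, so realized counts are within +/-1 of the
    exact proportions and the split is reproducible for a fixed seed.
    """
    fractions = list(fractions)
    if len(fractions) != len(SPLIT_LABELS):
        raise ValueError(f"need {len(SPLIT_LABELS)} fractions, got {len(fractions)}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    n = len(cohort)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    counts = _largest_remainder_counts(n, fractions)
    labels = np.empty(n, dtype=object)
    start = 0
    for label, count in zip(SPLIT_LABELS, counts):
        labels[order[start : start + count]] = label
        start += count
    table = cohort.table.copy()
    table["split"] = labels
    return Cohort(table, cohort.dx)
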