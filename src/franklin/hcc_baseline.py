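"""HCC-style baseline scorer: categories, hierarchy suppression, linear weights.

This reproduces the *structure* of hierarchical-condition-category risk
scoring — diagnosis codes map to disease categories, a severity hierarchy
suppresses subordinate categories when a dominant one is present, and the
risk score is a demographic cell weight plus a sum of non-negative category
weights, converted to dollars by a base cost (the published 2024 figure,
$12,963 per unit score, is the default).  The category/weight tables
themselves are configurable toy maps: the production tables are proprietary
and out of scope, and the baseline only needs to be structurally faithful
to serve as a comparison model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_io import Beneficiary, Cohort

__all__ = [
    "DEFAULT_BASE_COST",
    "CategoryMap",
    "HccScore",
    "load_category_map",
    "save_category_map",
    "assign_categories",
    "hcc_score",
    "score_cohort",
    "normalize_scores",
    "toy_category_map",
    "category_map_from_ground_truth",
]

#: Dollars of predicted annual cost per unit of (normalized) risk score.
DEFAULT_BASE_COST = 12_963.0


@dataclass(frozen=True)
class CategoryMap:
    """Category definitions: weights, code mappings, hierarchy, demographics.

    ``hierarchy`` edges run dominant -> subordinate; suppression is
    transitive, so only the most dominant present category in a chain
    contributes.  ``interactions`` optionally adds extra weight when both
    categories of a pair survive suppression.
    """

    weights: Mapping[str, float]
    icd_to_category: Mapping[str, str]
    hierarchy: tuple[tuple[str, str], ...]
    demographic_cells: tuple[tuple[int, int, str, float], ...]  # (age_min, age_max, sex, weight)
    base_cost: float = DEFAULT_BASE_COST
    interactions: Mapping[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, w in self.weights.items():
            if w < 0:
                raise ValueError(f"category {cat!r} has negative weight {w}")
        known = set(self.weights)
        for dom, sub in self.hierarchy:
            if dom not in known or sub not in known:
                raise ValueError(f"hierarchy edge ({dom!r}, {sub!r}) references unknown category")
        unknown_targets = set(self.icd_to_category.values()) - known
        if unknown_targets:
            raise ValueError(f"icd mapping references unknown categories: {sorted(unknown_targets)}")
        cycle = _find_cycle(known, self.hierarchy)
        if cycle:
            raise ValueError(f"hierarchy contains a cycle: {' -> '.join(cycle)}")
        if self.base_cost <= 0:
            raise ValueError("base_cost must be positive")

    def descendants(self, category: str) -> frozenset[str]:
        """All categories suppressed (transitively) by ``category``."""
        children: dict[str, list[str]] = {}
        for dom, sub in self.hierarchy:
            children.setdefault(dom, []).append(sub)
        seen: set[str] = set()
        stack = list(children.get(category, ()))
        while stack:
            c = stack.pop()
            if c not in seen:
                seen.add(c)
                stack.extend(children.get(c, ()))
        return frozenset(seen)

    def demographic_weight(self, age: int, sex: str) -> float:
        for age_min, age_max, cell_sex, w in self.demographic_cells:
            if cell_sex == sex and age_min <= age <= age_max:
                return w
        raise ValueError(f"no demographic cell covers (age={age}, sex={sex!r})")


def _find_cycle(nodes: Iterable[str], edges: Sequence[tuple[str, str]]) -> list[str] | None:
    """Return one directed cycle as a node path, or None (iterative DFS)."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in adj}
    parent: dict[str, str] = {}
    for start in adj:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GRAY
        while stack:
            node, i = stack[-1]
            if i < len(adj[node]):
                stack[-1] = (node, i + 1)
                nxt = adj[node][i]
                if color[nxt] == GRAY:
                    path = [nxt]
                    cur = node
                    while cur != nxt:
                        path.append(cur)
                        cur = parent[cur]
                    path.append(nxt)
                    path = path[::-1]
                    return path
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    parent[nxt] = node
                    stack.append((nxt, 0))
            else:
                color[node] = BLACK
                stack.pop()
    return None


@dataclass(frozen=True)
class HccScore:
    """A scored beneficiary: surviving categories, score, dollar prediction."""

    beneficiary_id: str
    categories: frozenset[str]
    score: float
    predicted_cost: float


def load_category_map(path: str | Path) -> CategoryMap:
    """Load a category map from a directory of CSVs plus ``meta.json``.

    Expected files: ``categories.csv`` (category,weight), ``mappings.csv``
    (code,category), ``hierarchy.csv`` (dominant,subordinate),
    ``cells.csv`` (age_min,age_max,sex,weight), ``meta.json``
    ({"base_cost": ...}).  ``mappings.csv``/``hierarchy.csv`` may be
    header-only.
    """
    path = Path(path)
    cats = pd.read_csv(path / "categories.csv", dtype={"category": str})
    weights = dict(zip(cats["category"], cats["weight"].astype(float)))

    mappings = pd.read_csv(path / "mappings.csv", dtype=str)
    icd_to_category = dict(zip(mappings["code"], mappings["category"]))

    hier = pd.read_csv(path / "hierarchy.csv", dtype=str)
    hierarchy = tuple(zip(hier["dominant"], hier["subordinate"]))

    cells = pd.read_csv(path / "cells.csv", dtype={"sex": str})
    demographic_cells = tuple(
        (int(r.age_min), int(r.age_max), str(r.sex), float(r.weight))
        for r in cells.itertuples()
    )
    meta = json.loads((path / "meta.json").read_text())
    return CategoryMap(
        weights=weights,
        icd_to_category=icd_to_category,
        hierarchy=hierarchy,
        demographic_cells=demographic_cells,
        base_cost=float(meta.get("base_cost", DEFAULT_BASE_COST)),
    )


def save_category_map(cmap: CategoryMap, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(cmap.weights.items()), columns=["category", "weight"]
    ).to_csv(path / "categories.csv", index=False)
    pd.DataFrame(
        sorted(cmap.icd_to_category.items()), columns=["code", "category"]
    ).to_csv(path / "mappings.csv", index=False)
    pd.DataFrame(list(cmap.hierarchy), columns=["dominant", "subordinate"]).to_csv(
        path / "hierarchy.csv", index=False
    )
    pd.DataFrame(
        list(cmap.demographic_cells), columns=["age_min", "age_max", "sex", "weight"]
    ).to_csv(path / "cells.csv", index=False)
    (path / "meta.json").write_text(json.dumps({"base_cost": cmap.base_cost}))


def assign_categories(dx_codes: Iterable[str], cmap: CategoryMap) -> frozenset[str]:
    """Map codes to categories and apply transitive hierarchy suppression.

    Unmapped codes are silently ignored; a category is dropped when any
    present category dominates it (directly or through a chain).
    """
    present = {cmap.icd_to_category[c] for c in dx_codes if c in cmap.icd_to_category}
    suppressed: set[str] = set()
    for cat in present:
        suppressed |= cmap.descendants(cat) & present
    return frozenset(present - suppressed)


def hcc_score(beneficiary: Beneficiary, cmap: CategoryMap) -> HccScore:
    """Score one beneficiary: demographic cell + surviving category weights."""
    cell = cmap.demographic_weight(beneficiary.age, beneficiary.sex)
    cats = assign_categories(beneficiary.dx_codes, cmap)
    score = cell + sum(cmap.weights[c] for c in cats)
    for pair, extra in cmap.interactions.items():
        if pair <= cats:
            score += extra
    return HccScore(
        beneficiary_id=beneficiary.id,
        categories=cats,
        score=score,
        predicted_cost=score * cmap.base_cost,
    )


def score_cohort(cohort: Cohort, cmap: CategoryMap) -> np.ndarray:
    """Raw (unnormalized) scores for every beneficiary in a cohort."""
    ages = cohort.table["age"].to_numpy()
    sexes = cohort.table["sex"].to_numpy()
    scores = np.empty(len(cohort))
    for i in range(len(cohort)):
        cell = cmap.demographic_weight(int(ages[i]), str(sexes[i]))
        cats = assign_categories(cohort.dx[i], cmap)
        s = cell + sum(cmap.weights[c] for c in cats)
        for pair, extra in cmap.interactions.items():
            if pair <= cats:
                s += extra
        scores[i] = s
    return scores


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Scale scores so the cohort mean is exactly 1.0."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    mean = scores.mean()
    if mean == 0:
        raise ValueError("mean score is 0; cannot normalize")
    return scores / mean


def toy_category_map() -> CategoryMap:
    """Small bundled category map (10 categories) used in tests and demos."""
    from importlib.resources import files

    return load_category_map(files("franklin").joinpath("data/toy_map"))


def category_map_from_ground_truth(
    truth,
    conditions: Sequence[int],
    base_cost: float = DEFAULT_BASE_COST,
) -> CategoryMap:
    """Build a category map covering a subset of the generator's conditions.

    Each covered condition becomes one category containing all its codes,
    weighted by the (floored-at-zero, since category weights must be
    non-negative) relative cost multiplier exp(effect) - 1.  Demographic
    cells follow the generator's age/sex effects.  This yields a baseline
    that is well-specified for the covered conditions and blind to the rest
    — the partial-coverage regime the baseline is meant to represent.
    """
    effects = truth.config.resolved_effects()
    weights: dict[str, float] = {}
    icd_to_category: dict[str, str] = {}
    for c in conditions:
        cat = f"CAT{c:02d}"
        weights[cat] = max(0.0, float(np.exp(effects[c]) - 1.0))
        for code in truth.condition_codes(c):
            icd_to_category[code] = cat
    cfg = truth.config
    cells = []
    for age_min, age_max in ((65, 74), (75, 84), (85, 120)):
        mid = (age_min + min(age_max, 99)) / 2
        for sex in ("F", "M"):
            w = float(
                np.exp(
                    cfg.intercept
                    + cfg.age_log_cost_effect * (mid - 65)
                    + cfg.female_log_cost_effect * (sex == "F")
                )
                / base_cost
            )
            cells.append((age_min, age_max, sex, w))
    return CategoryMap(
        weights=weights,
        icd_to_category=icd_to_category,
        hierarchy=(),
        demographic_cells=tuple(cells),
        base_cost=base_cost,
    )
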