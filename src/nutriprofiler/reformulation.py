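"""Reformulation scenario engine: reduce sodium and/or saturated fat,
rescore, and account class transitions.

A scenario is a pair of multiplicative factors in (0, 1] applied to the
sodium (equivalently salt) and saturated-fat declarations.  The scenarios of
interest are a 30 % sodium reduction (the WHO salt-intake target), a 10 %
SFA reduction, and both combined.  Energy is deliberately left unchanged
when SFA is reduced: the replacing ingredient is unknown, so no defensible
energy correction exists — scenario totals may be optimistic if substitutes
add energy.

Because the factors never increase a nutrient and the score is monotone in
sodium and SFA, a scenario can only lower (improve) the total, so a
product's class never moves toward E.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    Category,
    NutrientProfile,
    ProductRecord,
    assign_analysis_group,
)
from .scoring import (
    CLASS_LETTERS,
    AlgorithmVariant,
    ScoreTableSet,
    nutriscore,
)

__all__ = [
    "Scenario",
    "TransitionMatrix",
    "BASELINE",
    "SODIUM_MINUS_30",
    "SFA_MINUS_10",
    "COMBINED",
    "STUDY_SCENARIOS",
    "apply_scenario",
    "apply_scenario_record",
    "transition_matrix",
    "count_class_changes",
    "scenario_report",
]


@dataclass(frozen=True)
class Scenario:
    """A reformulation scenario: multiplicative nutrient reductions."""

    name: str
    sodium_factor: float = 1.0
    sfa_factor: float = 1.0

    def __post_init__(self) -> None:
        for label, f in (("sodium_factor", self.sodium_factor), ("sfa_factor", self.sfa_factor)):
            if not 0 < f <= 1:
                raise ValueError(f"{label} must be in (0, 1], got {f!r}")

    @property
    def is_baseline(self) -> bool:
        return self.sodium_factor == 1.0 and self.sfa_factor == 1.0


BASELINE = Scenario("baseline", 1.0, 1.0)
SODIUM_MINUS_30 = Scenario("minus 30% sodium", 0.7, 1.0)
SFA_MINUS_10 = Scenario("minus 10% SFA", 1.0, 0.9)
COMBINED = Scenario("minus 30% sodium and 10% SFA", 0.7, 0.9)

#: The three scenarios studied alongside the baseline.
STUDY_SCENARIOS: tuple[Scenario, ...] = (SODIUM_MINUS_30, SFA_MINUS_10, COMBINED)


def apply_scenario(profile: NutrientProfile, scenario: Scenario) -> NutrientProfile:
    """Return a new profile with the scenario's reductions applied.

    Sodium and salt are scaled together (the conversion is linear, so the
    pair stays consistent); SFA is scaled by its factor; every other field —
    energy included — is untouched.  The input profile is not modified.
    """
    changes: dict[str, float] = {}
    if profile.sodium_mg is not None:
        changes["sodium_mg"] = profile.sodium_mg * scenario.sodium_factor
    if profile.salt_g is not None:
        changes["salt_g"] = profile.salt_g * scenario.sodium_factor
    if profile.sfa_g is not None:
        changes["sfa_g"] = profile.sfa_g * scenario.sfa_factor
    if not changes:
        return profile
    return replace(profile, **changes)


def apply_scenario_record(record: ProductRecord, scenario: Scenario) -> ProductRecord:
    """Scenario application lifted to a whole record."""
    return replace(record, profile=apply_scenario(record.profile, scenario))


_CLASS_INDEX = {letter: i for i, letter in enumerate(CLASS_LETTERS)}


@dataclass(frozen=True)
class TransitionMatrix:
    """5x5 class-change counts, rows = baseline class, columns = scenario class."""

    counts: np.ndarray
    n_products: int
    scenario: Scenario
    variant: AlgorithmVariant

    def __post_init__(self) -> None:
        if self.counts.shape != (5, 5):
            raise ValueError(f"counts must be 5x5, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n_products:
            raise ValueError("counts must sum to n_products")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(CLASS_LETTERS), columns=list(CLASS_LETTERS)
        )

    @property
    def baseline_distribution(self) -> np.ndarray:
        """Row sums: the class counts before reformulation."""
        return self.counts.sum(axis=1)

    @property
    def scenario_distribution(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def transition_matrix(
    products: Sequence[ProductRecord],
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    scenario: Scenario = BASELINE,
    tables: ScoreTableSet | None = None,
) -> TransitionMatrix:
    """Score each product at baseline and under the scenario; count moves."""
    counts = np.zeros((5, 5), dtype=int)
    for record in products:
        before = nutriscore(record, variant, tables).letter
        after = nutriscore(apply_scenario_record(record, scenario), variant, tables).letter
        counts[_CLASS_INDEX[before], _CLASS_INDEX[after]] += 1
    return TransitionMatrix(
        counts=counts, n_products=len(products), scenario=scenario, variant=variant
    )


def count_class_changes(matrix: TransitionMatrix) -> int:
    """Number of products whose class changed: the off-diagonal total."""
    return int(matrix.counts.sum() - np.trace(matrix.counts))


def _hierarchy_keys(record: ProductRecord) -> list[tuple[str, str]]:
    """(level, label) rows a record contributes to, mirroring the report
    hierarchy: category, technological group within meat products, and the
    analysis subgroup split by meat class."""
    keys: list[tuple[str, str]] = []
    if record.category is Category.MEAT_PREPARATION:
        keys.append(("category", "meat preparations"))
        return keys
    keys.append(("category", "meat products"))
    group_labels = {
        "smoked": "smoked meats",
        "sausage": "sausages",
        "offal": "offal meats",
        "other": "other meat products",
    }
    keys.append(("group", group_labels[record.group.value]))
    keys.append(("subgroup", assign_analysis_group(record).label))
    return keys


def scenario_report(
    products: Sequence[ProductRecord],
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    scenarios: Sequence[Scenario] = STUDY_SCENARIOS,
    tables: ScoreTableSet | None = None,
) -> pd.DataFrame:
    """Class-distribution table for the baseline and each scenario.

    Long format with one row per (scenario, hierarchy level, group, class):
    columns ``scenario, level, group, class, count, pct``.  Percentages use
    the group's own product count as denominator, so they sum to 100 within
    each (scenario, group) cell.
    """
    all_scenarios = [BASELINE, *scenarios]
    rows: list[dict[str, object]] = []
    # Pre-compute hierarchy membership once per product.
    memberships = [_hierarchy_keys(r) for r in products]
    for scenario in all_scenarios:
        letters = [
            nutriscore(apply_scenario_record(r, scenario), variant, tables).letter
            for r in products
        ]
        cells: dict[tuple[str, str], np.ndarray] = {}
        for member, letter in zip(memberships, letters):
            for key in member:
                cells.setdefault(key, np.zeros(5, dtype=int))[_CLASS_INDEX[letter]] += 1
        for (level, group), counts in sorted(cells.items()):
            n = counts.sum()
            for i, letter in enumerate(CLASS_LETTERS):
                rows.append(
                    {
                        "scenario": scenario.name,
                        "level": level,
                        "group": group,
                        "class": letter,
                        "count": int(counts[i]),
                        "pct": 100.0 * counts[i] / n if n else 0.0,
                    }
                )
    return pd.DataFrame(rows)
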