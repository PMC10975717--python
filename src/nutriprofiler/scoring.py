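"""The Nutri-Score scoring engine for processed meat products.

The score is built from per-100 g nutrient content.  Four unfavourable
N-components (energy density, sugars, saturated fatty acids, sodium) each
earn 0-10 points from a threshold table; three favourable P-components
(fruit/vegetable/pulse/nut/oil percentage, fibre, protein) earn points that
are subtracted under a conditional rule:

* if the N total is below 11, all P points are subtracted;
* if the N total is 11 or more but the FVL component scored its maximal
  5 points, all P points are still subtracted;
* otherwise only FVL and fibre points are subtracted — protein is excluded.

The total maps to the five letter classes: A for -1 and below, B for 0-2,
C for 3-10, D for 11-18, E for 19 and above.

Two algorithm variants are supported.  They differ ONLY in the protein
table applied to red meat and its products: the original algorithm scores
all meat on the 0-5 point protein scale, while the refined algorithm (the
2022 Scientific Committee change for meat) caps red-meat protein at 2
points.  White meat is scored identically under both.

Threshold semantics are strict: a value earns the points of the highest
bound it strictly exceeds, so a value sitting exactly on a bound takes the
lower score (335 kJ earns 0 energy points, 336 kJ earns 1).
"""

from __future__ import annotations

import enum
from bisect import bisect_left
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .catalog import MeatClass, NutrientProfile, ProductRecord

__all__ = [
    "AlgorithmVariant",
    "ScoreTable",
    "ScoreTableSet",
    "ComponentScores",
    "ClassBands",
    "NutriScoreResult",
    "ScoringError",
    "TableError",
    "sodium_from_salt",
    "component_points",
    "score_components",
    "combine_score",
    "assign_class",
    "nutriscore",
    "load_score_tables",
    "default_tables",
    "DEFAULT_BANDS",
    "CLASS_LETTERS",
]

CLASS_LETTERS = ("A", "B", "C", "D", "E")

#: Protein-exclusion cut-off: P points are subtracted in full only when the
#: N total is below this, or when FVL scored its 5-point maximum.
N_TOTAL_PROTEIN_CUTOFF = 11


class ScoringError(ValueError):
    """A product cannot be scored (missing nutrient, bad input)."""


class TableError(ValueError):
    """A threshold table violates its structural invariants."""


class AlgorithmVariant(enum.Enum):
    ORIGINAL = "original"
    REFINED = "refined"


def sodium_from_salt(salt_g: float) -> float:
    """Sodium (mg/100 g) from the labelled salt content (g/100 g).

    Labels declare salt, not sodium; sodium is obtained by dividing the salt
    content by 2.5 and multiplying by 1000.
    """
    if salt_g < 0:
        raise ScoringError(f"salt content must be >= 0, got {salt_g!r}")
    return salt_g / 2.5 * 1000.0


@dataclass(frozen=True)
class ScoreTable:
    """One component's point table: ordered (strict lower bound, points) rows."""

    component: str
    thresholds: tuple[tuple[float, int], ...]
    max_points: int
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise TableError(f"{self.component}: empty threshold table")
        bounds = [b for b, _ in self.thresholds]
        points = [p for _, p in self.thresholds]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise TableError(f"{self.component}: bounds not strictly increasing")
        if any(p2 < p1 for p1, p2 in zip(points, points[1:])):
            raise TableError(f"{self.component}: points decreasing")
        if points[-1] != self.max_points or any(p > self.max_points for p in points):
            raise TableError(
                f"{self.component}: points inconsistent with max_points="
                f"{self.max_points}"
            )
        if any(p <= 0 for p in points):
            raise TableError(f"{self.component}: threshold points must be positive")

    @property
    def bounds(self) -> tuple[float, ...]:
        return tuple(b for b, _ in self.thresholds)


def component_points(value: float, table: ScoreTable) -> int:
    """Points for one component: the points of the highest bound strictly
    exceeded by ``value``; 0 when the value is at or below the first bound."""
    if value < 0:
        raise ScoringError(f"{table.component}: value must be >= 0, got {value!r}")
    idx = bisect_left(table.bounds, value)
    # idx counts bounds < value, except when value equals a bound, where
    # bisect_left also excludes it — exactly the strict-greater rule.
    if idx == 0:
        return 0
    return table.thresholds[idx - 1][1]


@dataclass(frozen=True)
class ScoreTableSet:
    """The full table set for one algorithm run (all seven components)."""

    energy: ScoreTable
    sugars: ScoreTable
    sfa: ScoreTable
    sodium: ScoreTable
    fvl: ScoreTable
    fibre: ScoreTable
    protein_white: ScoreTable
    protein_red: ScoreTable
    version: int = 1

    def protein_table(self, meat_class: MeatClass, variant: AlgorithmVariant) -> ScoreTable:
        """Protein table selection — the single point where variants differ."""
        if variant is AlgorithmVariant.REFINED and meat_class is MeatClass.RED:
            return self.protein_red
        return self.protein_white


def load_score_tables(path: str | Path | None = None) -> ScoreTableSet:
    """Load the component tables from a YAML file (default: bundled tables).

    The file is human-readable so the thresholds can be audited row by row;
    structurally invalid tables are refused.
    """
    if path is None:
        text = (
            resources.files("nutriprofiler")
            .joinpath("nutriscore_tables.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    tables = {}
    for name, spec in raw["tables"].items():
        tables[name] = ScoreTable(
            component=name,
            thresholds=tuple(
                (float(row["above"]), int(row["points"])) for row in spec["thresholds"]
            ),
            max_points=int(spec["max_points"]),
            unit=str(spec.get("unit", "")),
        )
    expected = {
        "energy",
        "sugars",
        "sfa",
        "sodium",
        "fvl",
        "fibre",
        "protein_white",
        "protein_red",
    }
    missing = expected - tables.keys()
    if missing:
        raise TableError(f"table file missing components: {sorted(missing)}")
    return ScoreTableSet(version=int(raw.get("version", 1)), **tables)


_DEFAULT_TABLES: ScoreTableSet | None = None


def default_tables() -> ScoreTableSet:
    """The bundled table set, loaded once."""
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_score_tables()
    return _DEFAULT_TABLES


@dataclass(frozen=True)
class ComponentScores:
    """Per-component points and the N / P totals."""

    energy_pts: int
    sugars_pts: int
    sfa_pts: int
    sodium_pts: int
    fvl_pts: int
    fibre_pts: int
    protein_pts: int

    @property
    def n_total(self) -> int:
        return self.energy_pts + self.sugars_pts + self.sfa_pts + self.sodium_pts

    @property
    def p_total(self) -> int:
        return self.fvl_pts + self.fibre_pts + self.protein_pts


def score_components(
    profile: NutrientProfile,
    meat_class: MeatClass,
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    tables: ScoreTableSet | None = None,
) -> ComponentScores:
    """Score every component of a profile.

    Sodium comes from the declared value or the salt conversion; a missing
    FVL percentage is scored as 0 % (processed meats essentially never reach
    the 40 % threshold).  Fibre must be present (observed or imputed).
    """
    t = tables or default_tables()
    sodium = profile.sodium_resolved_mg
    if sodium is None:
        raise ScoringError("sodium unresolvable: neither sodium_mg nor salt_g present")
    required = {
        "energy_kj": profile.energy_kj,
        "sugars_g": profile.sugars_g,
        "sfa_g": profile.sfa_g,
        "protein_g": profile.protein_g,
        "fibre_g": profile.fibre_g,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ScoringError(f"profile incomplete for scoring: missing {missing}")
    return ComponentScores(
        energy_pts=component_points(profile.energy_kj, t.energy),
        sugars_pts=component_points(profile.sugars_g, t.sugars),
        sfa_pts=component_points(profile.sfa_g, t.sfa),
        sodium_pts=component_points(sodium, t.sodium),
        fvl_pts=component_points(profile.fvl_pct or 0.0, t.fvl),
        fibre_pts=component_points(profile.fibre_g, t.fibre),
        protein_pts=component_points(
            profile.protein_g, t.protein_table(meat_class, variant)
        ),
    )


def combine_score(components: ComponentScores) -> tuple[int, bool]:
    """Combine N and P totals under the conditional protein rule.

    Returns ``(total, protein_counted)``: protein enters the subtraction when
    the N total is below 11, or when FVL scored its maximal 5 points;
    otherwise only FVL and fibre are subtracted.
    """
    n = components.n_total
    if n < N_TOTAL_PROTEIN_CUTOFF or components.fvl_pts == 5:
        return n - components.p_total, True
    return n - (components.fvl_pts + components.fibre_pts), False


@dataclass(frozen=True)
class ClassBands:
    """Total-score intervals mapped to the five letter classes."""

    bands: tuple[tuple[float, float, str], ...]  # (low, high, letter), inclusive

    def __post_init__(self) -> None:
        letters = [b[2] for b in self.bands]
        if tuple(letters) != CLASS_LETTERS:
            raise TableError(f"bands must be A..E in order, got {letters}")
        for (_, hi1, _), (lo2, _, _) in zip(self.bands, self.bands[1:]):
            if lo2 != hi1 + 1:
                raise TableError("bands must tile the integers without gap or overlap")

    def letter(self, total: int) -> str:
        for lo, hi, letter in self.bands:
            if lo <= total <= hi:
                return letter
        raise ScoringError(f"total {total} outside all bands")


DEFAULT_BANDS = ClassBands(
    bands=(
        (float("-inf"), -1, "A"),
        (0, 2, "B"),
        (3, 10, "C"),
        (11, 18, "D"),
        (19, float("inf"), "E"),
    )
)


def assign_class(total: int, bands: ClassBands = DEFAULT_BANDS) -> str:
    """Letter class for an integer total score."""
    if total != int(total):
        raise ScoringError(f"total score must be an integer, got {total!r}")
    return bands.letter(int(total))


@dataclass(frozen=True)
class NutriScoreResult:
    """Full scoring outcome for one product."""

    total: int
    letter: str
    variant: AlgorithmVariant
    components: ComponentScores
    protein_counted: bool
    product_id: str | None = None


def nutriscore(
    record: ProductRecord,
    variant: AlgorithmVariant = AlgorithmVariant.REFINED,
    tables: ScoreTableSet | None = None,
    bands: ClassBands = DEFAULT_BANDS,
) -> NutriScoreResult:
    """Score one product: components -> conditional combination -> class."""
    try:
        components = score_components(record.profile, record.meat_class, variant, tables)
    except ScoringError as exc:
        raise ScoringError(f"product {record.product_id}: {exc}") from exc
    total, protein_counted = combine_score(components)
    return NutriScoreResult(
        total=total,
        letter=assign_class(total, bands),
        variant=variant,
        components=components,
        protein_counted=protein_counted,
        product_id=record.product_id,
    )
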