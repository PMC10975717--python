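"""Product taxonomy, label-table I/O, completeness filtering and fibre imputation.

Processed meat is split into two regulatory categories (meat preparations,
i.e. minimally processed meat, versus meat products) and the meat products
further into four technological groups (smoked meats, sausages, offal meats,
other meats), each subdivided by meat species into red meat (domestic
ungulates) and white meat (poultry and lagomorphs).  That yields the nine
analysis groups used for grouping, fibre imputation and all reporting.

Nutrient declarations are per 100 g of product, as printed on the label.
Sodium is rarely declared directly; when absent it is derived from the salt
declaration (sodium mg = salt g / 2.5 x 1000).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MeatClass",
    "Category",
    "TechGroup",
    "AnalysisGroup",
    "NutrientProfile",
    "ProductRecord",
    "ReadReport",
    "CatalogError",
    "DialectError",
    "ImputationError",
    "CANONICAL_COLUMNS",
    "read_products",
    "write_products",
    "records_to_frame",
    "assign_analysis_group",
    "filter_complete",
    "impute_fibre",
    "meat_class_from_species",
]

#: Conversion factor: sodium (mg/100 g) = salt (g/100 g) / 2.5 * 1000.
SALT_TO_SODIUM_MG = 400.0


class CatalogError(ValueError):
    """Invalid product data or configuration."""


class DialectError(CatalogError):
    """A required column cannot be resolved in the input table."""


class ImputationError(CatalogError):
    """Fibre imputation impossible: a group has no observed fibre values."""


class MeatClass(enum.Enum):
    """Red meat (domestic ungulates) vs white meat (poultry, lagomorphs)."""

    RED = "red"
    WHITE = "white"


class Category(enum.Enum):
    MEAT_PREPARATION = "meat_preparation"
    MEAT_PRODUCT = "meat_product"


class TechGroup(enum.Enum):
    SMOKED = "smoked"
    SAUSAGE = "sausage"
    OFFAL = "offal"
    OTHER = "other"
    PREPARATION = "preparation"


class AnalysisGroup(enum.Enum):
    """The nine analysis groups; preparations are not split by species."""

    MEAT_PREPARATIONS = "meat preparations"
    SMOKED_POULTRY = "smoked poultry meats"
    SMOKED_RED = "smoked red meats"
    POULTRY_SAUSAGES = "poultry meat sausages"
    RED_SAUSAGES = "red meat sausages"
    OFFAL_POULTRY = "offal poultry meat products"
    OFFAL_RED = "offal red meat products"
    OTHER_POULTRY = "other poultry meat products"
    OTHER_RED = "other red meat products"

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient declaration of one product.

    Any field may be missing (``None``); completeness is enforced by
    :func:`filter_complete`, not at construction.  Present values must be
    non-negative and ``fvl_pct`` (fruits / vegetables / pulses / nuts /
    permitted oils percentage) at most 100.
    """

    energy_kj: float | None = None
    sugars_g: float | None = None
    sfa_g: float | None = None
    salt_g: float | None = None
    sodium_mg: float | None = None
    protein_g: float | None = None
    fibre_g: float | None = None
    fvl_pct: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "energy_kj",
            "sugars_g",
            "sfa_g",
            "salt_g",
            "sodium_mg",
            "protein_g",
            "fibre_g",
            "fvl_pct",
        ):
            value = getattr(self, name)
            if value is None:
                continue
            if not math.isfinite(value):
                raise CatalogError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise CatalogError(f"{name} must be >= 0, got {value!r}")
        if self.fvl_pct is not None and self.fvl_pct > 100:
            raise CatalogError(f"fvl_pct must be <= 100, got {self.fvl_pct!r}")

    @property
    def sodium_resolved_mg(self) -> float | None:
        """Sodium in mg/100 g, derived from salt when not declared directly.

        A declared sodium value takes precedence; the salt conversion exists
        only because labels usually omit sodium.
        """
        if self.sodium_mg is not None:
            return self.sodium_mg
        if self.salt_g is not None:
            return self.salt_g * SALT_TO_SODIUM_MG
        return None


@dataclass(frozen=True)
class ProductRecord:
    """One labelled product: taxonomy, nutrient profile and additive flag."""

    product_id: str
    name: str
    category: Category
    group: TechGroup
    meat_class: MeatClass
    profile: NutrientProfile
    has_flavour_enhancer: bool | None = None
    fibre_imputed: bool = False
    meat_class_mixed: bool = False

    def __post_init__(self) -> None:
        prep_cat = self.category is Category.MEAT_PREPARATION
        prep_grp = self.group is TechGroup.PREPARATION
        if prep_cat != prep_grp:
            raise CatalogError(
                f"{self.product_id}: category {self.category.value!r} inconsistent "
                f"with group {self.group.value!r}"
            )
        if self.fibre_imputed and self.profile.fibre_g is None:
            raise CatalogError(
                f"{self.product_id}: fibre_imputed set but fibre_g missing"
            )


_GROUP_MAP: dict[tuple[TechGroup, MeatClass], AnalysisGroup] = {
    (TechGroup.SMOKED, MeatClass.WHITE): AnalysisGroup.SMOKED_POULTRY,
    (TechGroup.SMOKED, MeatClass.RED): AnalysisGroup.SMOKED_RED,
    (TechGroup.SAUSAGE, MeatClass.WHITE): AnalysisGroup.POULTRY_SAUSAGES,
    (TechGroup.SAUSAGE, MeatClass.RED): AnalysisGroup.RED_SAUSAGES,
    (TechGroup.OFFAL, MeatClass.WHITE): AnalysisGroup.OFFAL_POULTRY,
    (TechGroup.OFFAL, MeatClass.RED): AnalysisGroup.OFFAL_RED,
    (TechGroup.OTHER, MeatClass.WHITE): AnalysisGroup.OTHER_POULTRY,
    (TechGroup.OTHER, MeatClass.RED): AnalysisGroup.OTHER_RED,
}


def assign_analysis_group(record: ProductRecord) -> AnalysisGroup:
    """Map a record to its analysis group.

    Total and deterministic: meat preparations map to the single
    "meat preparations" group regardless of species; meat products map to
    (technological group x meat class).
    """
    if record.category is Category.MEAT_PREPARATION:
        return AnalysisGroup.MEAT_PREPARATIONS
    return _GROUP_MAP[(record.group, record.meat_class)]


# Species keyword table for the meat-class split.  Red = domestic ungulates;
# white = poultry and lagomorphs.  Polish and English label vocabulary.
_RED_SPECIES = {
    "red",
    "pork",
    "beef",
    "veal",
    "lamb",
    "mutton",
    "horse",
    "boar",
    "wieprzowina",
    "wieprzowe",
    "wolowina",
    "wołowina",
    "wolowe",
    "cielecina",
    "cielęcina",
    "jagniecina",
    "jagnięcina",
    "baranina",
    "konina",
    "dzik",
}
_WHITE_SPECIES = {
    "white",
    "poultry",
    "chicken",
    "turkey",
    "duck",
    "goose",
    "rabbit",
    "drob",
    "drób",
    "kurczak",
    "kura",
    "indyk",
    "kaczka",
    "ges",
    "gęś",
    "krolik",
    "królik",
}


def meat_class_from_species(species: str) -> tuple[MeatClass, bool]:
    """Resolve a species declaration to (meat class, mixed flag).

    The declaration may list several species ("pork; chicken").  Any red-meat
    ingredient makes the product red meat — the stricter assignment, since red
    meat is scored less favourably under the refined protein cap.  The mixed
    flag records that both classes were present, so the assignment rule is
    visible downstream rather than silently applied.
    """
    tokens = [
        t.strip().lower()
        for t in species.replace(";", ",").replace("/", ",").split(",")
        if t.strip()
    ]
    if not tokens:
        raise CatalogError("empty species declaration")
    has_red = any(t in _RED_SPECIES for t in tokens)
    has_white = any(t in _WHITE_SPECIES for t in tokens)
    unknown = [t for t in tokens if t not in _RED_SPECIES and t not in _WHITE_SPECIES]
    if unknown:
        raise CatalogError(f"unrecognised species token(s): {unknown}")
    if has_red:
        return MeatClass.RED, has_white
    return MeatClass.WHITE, False


CANONICAL_COLUMNS: tuple[str, ...] = (
    "product_id",
    "name",
    "category",
    "group",
    "species",
    "energy_kj",
    "sugars_g",
    "sfa_g",
    "salt_g",
    "sodium_mg",
    "protein_g",
    "fibre_g",
    "fvl_pct",
    "flavour_enhancer",
)

_REQUIRED_COLUMNS = ("product_id", "category", "group", "species")
_NUMERIC_COLUMNS = (
    "energy_kj",
    "sugars_g",
    "sfa_g",
    "salt_g",
    "sodium_mg",
    "protein_g",
    "fibre_g",
    "fvl_pct",
)

_TRUE_TOKENS = {"1", "true", "yes", "y", "tak", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "nie", "f"}


def _parse_number(raw: object) -> float | None:
    """Parse a label number; comma decimal separators are normalised."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip()
    if not text or text.lower() in {"na", "nan", "none", "-"}:
        return None
    return float(text.replace(",", "."))


def _parse_flag(raw: object) -> bool | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, bool):
        return raw
    text = str(raw).strip().lower()
    if not text:
        return None
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise CatalogError(f"unparseable boolean flag: {raw!r}")


@dataclass
class ReadReport:
    """Outcome of reading a label table: accepted records plus a rejects report.

    Malformed rows are never silently dropped — each lands in ``rejects``
    with the offending row index, product id and a reason.
    """

    records: list[ProductRecord]
    rejects: pd.DataFrame

    @property
    def n_read(self) -> int:
        return len(self.records) + len(self.rejects)


def read_products(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ReadReport:
    """Read a product label table (CSV, UTF-8, header row).

    Parameters
    ----------
    path
        CSV file with one row per product.
    dialect
        Optional mapping from canonical column names (see
        ``CANONICAL_COLUMNS``) to the names actually used in the file.

    Sodium is filled from salt when absent via the standard conversion.
    Rows with malformed or negative numerics, unknown taxonomy values or
    unresolvable species go to the rejects report with a reason.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    dialect = dict(dialect or {})
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon in _REQUIRED_COLUMNS:
        if colmap[canon] not in frame.columns:
            raise DialectError(
                f"required column {colmap[canon]!r} (canonical {canon!r}) "
                f"not found in {path}"
            )

    def cell(row: pd.Series, canon: str) -> object:
        col = colmap[canon]
        return row[col] if col in frame.columns else None

    records: list[ProductRecord] = []
    rejected: list[dict[str, object]] = []
    for idx, row in frame.iterrows():
        pid = str(cell(row, "product_id") or f"row{idx}")
        try:
            records.append(_row_to_record(row, cell, pid))
        except (CatalogError, ValueError) as exc:
            rejected.append({"row": idx, "product_id": pid, "reason": str(exc)})
    rejects = pd.DataFrame(rejected, columns=["row", "product_id", "reason"])
    return ReadReport(records=records, rejects=rejects)


def _row_to_record(row: pd.Series, cell: Callable, pid: str) -> ProductRecord:
    category = Category(str(cell(row, "category")).strip().lower())
    group = TechGroup(str(cell(row, "group")).strip().lower())
    meat_class, mixed = meat_class_from_species(str(cell(row, "species")))
    numbers = {name: _parse_number(cell(row, name)) for name in _NUMERIC_COLUMNS}
    if numbers["sodium_mg"] is None and numbers["salt_g"] is not None:
        numbers["sodium_mg"] = numbers["salt_g"] * SALT_TO_SODIUM_MG
    profile = NutrientProfile(**numbers)
    return ProductRecord(
        product_id=pid,
        name=str(cell(row, "name") or pid),
        category=category,
        group=group,
        meat_class=meat_class,
        profile=profile,
        has_flavour_enhancer=_parse_flag(cell(row, "flavour_enhancer")),
        meat_class_mixed=mixed,
    )


def records_to_frame(records: Sequence[ProductRecord]) -> pd.DataFrame:
    """Flatten records into the canonical tabular layout."""
    rows = []
    for r in records:
        p = r.profile
        rows.append(
            {
                "product_id": r.product_id,
                "name": r.name,
                "category": r.category.value,
                "group": r.group.value,
                "species": r.meat_class.value,
                "energy_kj": p.energy_kj,
                "sugars_g": p.sugars_g,
                "sfa_g": p.sfa_g,
                "salt_g": p.salt_g,
                "sodium_mg": p.sodium_mg,
                "protein_g": p.protein_g,
                "fibre_g": p.fibre_g,
                "fvl_pct": p.fvl_pct,
                "flavour_enhancer": (
                    "" if r.has_flavour_enhancer is None else int(r.has_flavour_enhancer)
                ),
                "fibre_imputed": int(r.fibre_imputed),
                "meat_class_mixed": int(r.meat_class_mixed),
                "analysis_group": assign_analysis_group(r).label,
            }
        )
    return pd.DataFrame(rows)


def write_products(records: Sequence[ProductRecord], path: str | Path) -> None:
    """Write records as a canonical CSV readable by :func:`read_products`."""
    records_to_frame(records).to_csv(path, index=False)


_SCORING_FIELDS = ("energy_kj", "sugars_g", "sfa_g", "protein_g")


def filter_complete(
    products: Iterable[ProductRecord],
) -> tuple[list[ProductRecord], list[ProductRecord]]:
    """Partition records into (scoreable, incomplete).

    A record is scoreable when energy, sugars, saturated fat and protein are
    declared and sodium is resolvable (declared directly or via salt).  Fibre
    may be missing — imputation fills it — and a missing FVL percentage is
    scored as 0 %.  The partition is exhaustive and disjoint.
    """
    complete: list[ProductRecord] = []
    incomplete: list[ProductRecord] = []
    for record in products:
        p = record.profile
        ok = all(getattr(p, f) is not None for f in _SCORING_FIELDS)
        ok = ok and p.sodium_resolved_mg is not None
        (complete if ok else incomplete).append(record)
    return complete, incomplete


def impute_fibre(
    products: Sequence[ProductRecord],
    level: str | Callable[[ProductRecord], object] = "analysis_group",
) -> list[ProductRecord]:
    """Fill missing fibre with the group mean of observed fibre values.

    ``level`` selects the grouping: the default ``"analysis_group"`` uses the
    nine analysis groups; any callable mapping a record to a hashable key
    gives finer control (e.g. the technological subgroups).

    Observed values and all non-fibre fields are untouched; imputed records
    carry ``fibre_imputed=True``.  The result is independent of input order.
    A group that needs imputation but has no observed fibre raises
    :class:`ImputationError` naming the group.
    """
    if callable(level):
        keyfn = level
    elif level == "analysis_group":
        keyfn = lambda r: assign_analysis_group(r).label  # noqa: E731
    else:
        raise CatalogError(f"unknown imputation level {level!r}")

    sums: dict[object, float] = {}
    counts: dict[object, int] = {}
    for record in products:
        if record.profile.fibre_g is not None:
            key = keyfn(record)
            sums[key] = sums.get(key, 0.0) + record.profile.fibre_g
            counts[key] = counts.get(key, 0) + 1

    out: list[ProductRecord] = []
    for record in products:
        if record.profile.fibre_g is not None:
            out.append(record)
            continue
        key = keyfn(record)
        if counts.get(key, 0) == 0:
            raise ImputationError(
                f"group {key!r} has no observed fibre values; cannot impute "
                f"(product {record.product_id})"
            )
        mean = sums[key] / counts[key]
        out.append(
            replace(
                record,
                profile=replace(record.profile, fibre_g=mean),
                fibre_imputed=True,
            )
        )
    return out
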