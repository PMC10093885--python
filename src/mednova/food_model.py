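"""Branded-food data model: records, validation, unit conversions and I/O.

A branded food is one packaged supermarket product described by its on-pack
information: a food subcategory from a controlled vocabulary, whether it is
scored as a solid or a beverage, a free-text ingredient list, and the
nutrition declaration per 100 g (solids) or 100 mL (beverages).

Missing nutrient values are a first-class state, distinct from zero: a blank
sugars cell on a label is *unknown* sugars, and downstream scoring treats the
two very differently (missing "negative" nutrients exclude the product from
nutrient-profile scoring, missing "positive" nutrients are imputed to zero).
CSV encodes missing as an empty cell, JSON as ``null``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "NutrientPanel",
    "BrandedFood",
    "ValidationProblem",
    "ValidationReport",
    "NEGATIVE_NUTRIENTS",
    "POSITIVE_NUTRIENTS",
    "CSV_COLUMNS",
    "KJ_PER_KCAL",
    "SODIUM_MG_PER_G_SALT",
    "kcal_to_kj",
    "salt_to_sodium_mg",
    "validate_food",
    "validate_table",
    "read_food_table",
    "write_food_table",
    "default_vocabulary",
]

#: Nutrients whose absence makes a nutrient-profile score uncomputable.
NEGATIVE_NUTRIENTS = ("energy_kcal", "sugars_g", "sfa_g", "salt_g")

#: Nutrients imputed to zero when absent.
POSITIVE_NUTRIENTS = ("protein_g", "fiber_g", "fv_percent")

#: Energy conversion used throughout (labels declare kcal, scoring uses kJ).
KJ_PER_KCAL = 4.184

#: EU labelling convention: salt (g) = sodium (g) x 2.5, so 1 g salt = 400 mg Na.
SODIUM_MG_PER_G_SALT = 400.0

CSV_COLUMNS = [
    "id",
    "name",
    "subcategory",
    "basis",
    "is_water",
    "is_composite_dish",
    "is_plant_based_imitation",
    "ingredient_text",
    "energy_kcal",
    "protein_g",
    "total_fat_g",
    "sfa_g",
    "sugars_g",
    "salt_g",
    "fiber_g",
    "fv_percent",
]

_OPTIONAL_CSV_COLUMNS = ["tier_hint"]

_PANEL_FIELDS = [
    "energy_kcal",
    "protein_g",
    "total_fat_g",
    "sfa_g",
    "sugars_g",
    "salt_g",
    "fiber_g",
    "fv_percent",
]

_BASES = ("solid", "beverage")


@dataclass(frozen=True)
class NutrientPanel:
    """Nutrition declaration per 100 g/mL. ``None`` means *not declared*."""

    energy_kcal: Optional[float] = None
    protein_g: Optional[float] = None
    total_fat_g: Optional[float] = None
    sfa_g: Optional[float] = None
    sugars_g: Optional[float] = None
    salt_g: Optional[float] = None
    fiber_g: Optional[float] = None
    fv_percent: Optional[float] = None

    def get(self, name: str) -> Optional[float]:
        if name not in _PANEL_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def missing(self, names: Iterable[str]) -> list[str]:
        """Return the subset of ``names`` that are not declared."""
        return [n for n in names if self.get(n) is None]


@dataclass(frozen=True)
class BrandedFood:
    """One packaged product: identity, category, flags, ingredients, panel."""

    id: str
    name: str
    subcategory: str
    basis: str  # "solid" | "beverage"
    is_water: bool = False
    is_composite_dish: bool = False
    is_plant_based_imitation: bool = False
    ingredient_text: Optional[str] = None
    panel: NutrientPanel = field(default_factory=NutrientPanel)
    #: Optional disambiguation for subcategories that occur in several
    #: pyramid tiers; names the tier the product belongs to.
    tier_hint: Optional[str] = None


@dataclass(frozen=True)
class ValidationProblem:
    field: str
    problem: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    """All invariant violations found on one food. Empty report == valid."""

    food_id: str
    problems: list[ValidationProblem] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(p.severity == "error" for p in self.problems)

    def add(self, field_name: str, problem: str, severity: str = "error") -> None:
        self.problems.append(ValidationProblem(field_name, problem, severity))


def kcal_to_kj(e: float) -> float:
    """Convert energy from kilocalories to kilojoules (1 kcal = 4.184 kJ)."""
    if e < 0:
        raise ValueError(f"energy must be >= 0, got {e}")
    return e * KJ_PER_KCAL


def salt_to_sodium_mg(salt: float) -> float:
    """Convert salt (g) to sodium (mg) with the EU factor salt = 2.5 x sodium."""
    if salt < 0:
        raise ValueError(f"salt must be >= 0, got {salt}")
    return salt * SODIUM_MG_PER_G_SALT


def default_vocabulary() -> frozenset[str]:
    """The controlled subcategory vocabulary shipped with the package."""
    from .pyramid import load_pyramid_config

    return frozenset(load_pyramid_config()["vocabulary"])


def validate_food(
    food: BrandedFood, vocabulary: Optional[Iterable[str]] = None
) -> ValidationReport:
    """Check every data-model invariant on one food; never raises.

    ``vocabulary`` defaults to the packaged subcategory vocabulary; pass an
    explicit collection to validate against a custom one, or ``()`` to skip
    the vocabulary check entirely.
    """
    report = ValidationReport(food.id)
    if not food.id:
        report.add("id", "id must be non-empty")
    if food.basis not in _BASES:
        report.add("basis", f"basis must be one of {_BASES}, got {food.basis!r}")
    if food.is_water and food.basis != "beverage":
        report.add("is_water", "a water product must have basis 'beverage'")

    p = food.panel
    for name in _PANEL_FIELDS:
        v = p.get(name)
        if v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            report.add(name, "NaN is not a valid declared value (use missing)")
        elif v < 0:
            report.add(name, f"{name} must be >= 0, got {v}")
    if p.sfa_g is not None and p.total_fat_g is not None and p.sfa_g > p.total_fat_g:
        report.add("sfa_g", f"saturated fat ({p.sfa_g}) exceeds total fat ({p.total_fat_g})")
    if p.sugars_g is not None and p.sugars_g > 100:
        report.add("sugars_g", f"sugars per 100 g cannot exceed 100, got {p.sugars_g}")
    if p.fv_percent is not None and p.fv_percent > 100:
        report.add("fv_percent", f"fv_percent cannot exceed 100, got {p.fv_percent}")

    if vocabulary is None:
        vocabulary = default_vocabulary()
    vocab = frozenset(vocabulary)
    if vocab and food.subcategory not in vocab:
        report.add("subcategory", f"unknown subcategory {food.subcategory!r}")
    return report


def validate_table(
    foods: Sequence[BrandedFood], vocabulary: Optional[Iterable[str]] = None
) -> list[ValidationReport]:
    """Per-food reports plus table-level duplicate-id detection."""
    if vocabulary is None:
        vocabulary = default_vocabulary()
    reports = [validate_food(f, vocabulary) for f in foods]
    seen: dict[str, int] = {}
    for i, f in enumerate(foods):
        if f.id in seen:
            reports[i].add("id", f"duplicate id {f.id!r} (first at record {seen[f.id]})")
        else:
            seen[f.id] = i
    return reports


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw: str, record: int, col: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"record {record}: cannot parse boolean {col}={raw!r}")


def _parse_float(raw: str, record: int, col: str) -> Optional[float]:
    s = str(raw).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"record {record}: cannot parse number {col}={raw!r}") from None


def _infer_format(source: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    if isinstance(source, (str, Path)):
        suffix = Path(source).suffix.lower()
        if suffix == ".csv":
            return "csv"
        if suffix == ".json":
            return "json"
    raise ParseError("format could not be inferred; pass format='csv' or 'json'")


def _panel_value(raw, record: int, col: str) -> Optional[float]:
    if raw is None:
        return None
    if isinstance(raw, bool):
        raise ParseError(f"record {record}: {col} must be a number, got {raw!r}")
    if isinstance(raw, (int, float)):
        return float(raw)
    return _parse_float(raw, record, col)


def _food_from_record(rec: dict, i: int) -> BrandedFood:
    panel = NutrientPanel(**{n: _panel_value(rec.get(n), i, n) for n in _PANEL_FIELDS})
    flags = {}
    for col in ("is_water", "is_composite_dish", "is_plant_based_imitation"):
        v = rec.get(col, False)
        flags[col] = v if isinstance(v, bool) else _parse_bool(v, i, col)
    text = rec.get("ingredient_text")
    if text is not None:
        text = str(text).strip() or None
    hint = rec.get("tier_hint")
    if hint is not None:
        hint = str(hint).strip() or None
    return BrandedFood(
        id=str(rec.get("id", "")).strip(),
        name=str(rec.get("name", "")).strip(),
        subcategory=str(rec.get("subcategory", "")).strip(),
        basis=str(rec.get("basis", "")).strip(),
        ingredient_text=text,
        panel=panel,
        tier_hint=hint,
        **flags,
    )


def read_food_table(
    source,
    format: Optional[str] = None,
    vocabulary: Optional[Iterable[str]] = None,
    permissive: bool = False,
) -> list[BrandedFood]:
    """Read a branded-food table from CSV or JSON.

    Returns one :class:`BrandedFood` per record, in file order. Empty cells
    (CSV) and ``null`` values (JSON) become missing panel values, never zero.
    Unless ``permissive`` is set, any invariant violation (including an
    unknown subcategory) raises :class:`ValidationError`.
    """
    fmt = _infer_format(source, format)
    if fmt == "csv":
        try:
            df = pd.read_csv(source, dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot parse CSV: {exc}") from exc
        missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ParseError(f"CSV header missing columns: {missing_cols}")
        records = df.to_dict(orient="records")
    elif fmt == "json":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        else:
            data = json.load(source)
        if not isinstance(data, list):
            raise ParseError("JSON food table must be an array of objects")
        records = data
    else:
        raise ParseError(f"unknown format {fmt!r}")

    foods = [_food_from_record(rec, i) for i, rec in enumerate(records)]
    reports = validate_table(foods, vocabulary)
    bad = [r for r in reports if not r.ok]
    if bad and not permissive:
        lines = [
            f"{r.food_id or '<record ' + str(i) + '>'}: "
            + "; ".join(f"{p.field}: {p.problem}" for p in r.problems if p.severity == "error")
            for i, r in enumerate(reports)
            if not r.ok
        ]
        raise ValidationError("invalid food records:\n" + "\n".join(lines))
    return foods


def _food_to_record(food: BrandedFood, json_mode: bool) -> dict:
    rec: dict = {
        "id": food.id,
        "name": food.name,
        "subcategory": food.subcategory,
        "basis": food.basis,
        "is_water": food.is_water,
        "is_composite_dish": food.is_composite_dish,
        "is_plant_based_imitation": food.is_plant_based_imitation,
        "ingredient_text": food.ingredient_text,
    }
    for n in _PANEL_FIELDS:
        rec[n] = food.panel.get(n)
    if food.tier_hint is not None:
        rec["tier_hint"] = food.tier_hint
    if not json_mode:
        rec = {
            k: ("" if v is None else (str(v).lower() if isinstance(v, bool) else v))
            for k, v in rec.items()
        }
    return rec


def write_food_table(foods: Sequence[BrandedFood], sink, format: Optional[str] = None) -> None:
    """Write a table so that :func:`read_food_table` reproduces it exactly."""
    fmt = _infer_format(sink, format)
    any_hint = any(f.tier_hint is not None for f in foods)
    if fmt == "csv":
        cols = CSV_COLUMNS + (["tier_hint"] if any_hint else [])
        records = [_food_to_record(f, json_mode=False) for f in foods]
        for rec in records:
            rec.setdefault("tier_hint", "")
        df = pd.DataFrame.from_records(records, columns=cols) if records else pd.DataFrame(columns=cols)
        df.to_csv(sink, index=False)
    elif fmt == "json":
        data = [_food_to_record(f, json_mode=True) for f in foods]
        if isinstance(sink, (str, Path)):
            with open(sink, "w", encoding="utf-8") as fh:
                json.dump(data, fh, indent=1, ensure_ascii=False)
        else:
            json.dump(data, sink, indent=1, ensure_ascii=False)
    else:
        raise ParseError(f"unknown format {fmt!r}")
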