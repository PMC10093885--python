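"""FSAm-NPS nutrient-profile scoring and five-letter Nutri-Score grading.

The FSAm-NPS score of a product is computed per 100 g/mL from its nutrition
declaration:

* "negative" components -- energy (kJ), total sugars (g), saturated fatty
  acids (g) and sodium (mg) -- each score 0-10 points for increasing
  content (N in 0..40);
* "positive" components -- protein (g), fiber (g) and the fruit/vegetable/
  pulse/nut/specific-oil fraction FV% -- each score 0-5 points (P in 0..15);
* the score is ``S = N - P``, an integer in [-15, +40]; lower is better.

Labels declare energy in kcal and salt in grams, so both are converted
(4.184 kJ/kcal; sodium mg = salt g x 400) before threshold lookup.

Missing-data policy: a product missing any negative nutrient cannot be
scored and is excluded (``status = "excluded_missing_negative"``); missing
positive nutrients are imputed to zero and recorded in ``imputed_fields``.

Grades: waters are always A. Solids map A/B/C/D/E to scores <= -1 / 0-2 /
3-10 / 11-18 / >= 19; non-water beverages to B/C/D/E at <= 1 / 2-5 / 6-9 /
>= 10 (no beverage other than water can be graded A).

Two scoring modes exist. ``paper_subtraction`` (default) is the plain
``N - P`` rule. ``full_rule`` additionally applies the official restriction
that protein points are not counted when ``N >= 11`` unless the FV points
are maximal or the product is cheese.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import ConfigurationError
from .food_model import (
    BrandedFood,
    NEGATIVE_NUTRIENTS,
    POSITIVE_NUTRIENTS,
    NutrientPanel,
    kcal_to_kj,
    salt_to_sodium_mg,
)

__all__ = [
    "ComponentTable",
    "ScoreTables",
    "FSAmNPSResult",
    "MissingNegativeNutrient",
    "NEGATIVE_COMPONENTS",
    "POSITIVE_COMPONENTS",
    "default_score_tables",
    "load_score_tables",
    "component_points",
    "negative_points",
    "positive_points",
    "fsam_nps",
    "grade",
    "score_all",
]

NEGATIVE_COMPONENTS = ("energy_kj", "sugars_g", "sfa_g", "sodium_mg")
POSITIVE_COMPONENTS = ("protein_g", "fiber_g", "fv_percent")

SCORE_MIN, SCORE_MAX = -15, 40

#: subcategory treated as cheese by the full_rule protein restriction
CHEESE_SUBCATEGORY = "Cheese"


class MissingNegativeNutrient(ConfigurationError):
    """Raised when a negative component is requested for an undeclared value."""


@dataclass(frozen=True)
class ComponentTable:
    """Ordered thresholds and the points awarded per band exceeded."""

    thresholds: tuple[float, ...]
    points: tuple[int, ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ConfigurationError(
                f"thresholds must be strictly increasing, got {self.thresholds}"
            )
        if len(self.points) != len(self.thresholds) + 1:
            raise ConfigurationError(
                "points list must have len(thresholds) + 1 entries"
            )
        if any(b < a for a, b in zip(self.points, self.points[1:])):
            raise ConfigurationError("points must be non-decreasing")

    @classmethod
    def from_config(cls, cfg: dict) -> "ComponentTable":
        thresholds = tuple(float(t) for t in cfg["thresholds"])
        points = cfg.get("points")
        if points is None:
            points = tuple(range(len(thresholds) + 1))
        return cls(thresholds, tuple(int(p) for p in points))


@dataclass(frozen=True)
class ScoreTables:
    """Per-basis component tables plus the scoring mode."""

    solid: dict[str, ComponentTable]
    beverage: dict[str, ComponentTable]
    mode: str = "paper_subtraction"  # or "full_rule"

    def __post_init__(self):
        if self.mode not in ("paper_subtraction", "full_rule"):
            raise ConfigurationError(f"unknown scoring mode {self.mode!r}")
        for basis_tables in (self.solid, self.beverage):
            missing = set(NEGATIVE_COMPONENTS + POSITIVE_COMPONENTS) - set(basis_tables)
            if missing:
                raise ConfigurationError(f"score tables missing components: {sorted(missing)}")

    def for_basis(self, basis: str) -> dict[str, ComponentTable]:
        if basis == "solid":
            return self.solid
        if basis == "beverage":
            return self.beverage
        raise ConfigurationError(f"unknown basis {basis!r}")


def load_score_tables(source: Union[str, Path, dict], mode: Optional[str] = None) -> ScoreTables:
    """Load threshold tables from a YAML/JSON config file or parsed mapping."""
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    try:
        solid = {k: ComponentTable.from_config(v) for k, v in cfg["solid"].items()}
        beverage = {k: ComponentTable.from_config(v) for k, v in cfg["beverage"].items()}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed score-table config: {exc}") from exc
    return ScoreTables(solid, beverage, mode or cfg.get("mode", "paper_subtraction"))


def default_score_tables(mode: Optional[str] = None) -> ScoreTables:
    """The 2017 FSA/FSAm-NPS threshold tables shipped with the package."""
    text = resources.files("mednova.data").joinpath("score_tables.yaml").read_text("utf-8")
    return load_score_tables(yaml.safe_load(text), mode=mode)


@dataclass(frozen=True)
class FSAmNPSResult:
    food_id: str
    status: str  # "scored" | "excluded_missing_negative"
    negative_points: Optional[int] = None
    negative_breakdown: dict[str, int] = field(default_factory=dict)
    positive_points: Optional[int] = None
    positive_breakdown: dict[str, int] = field(default_factory=dict)
    score: Optional[int] = None
    grade: Optional[str] = None
    imputed_fields: tuple[str, ...] = ()
    missing_negative: tuple[str, ...] = ()


def component_points(value: float, table: ComponentTable) -> int:
    """Points for one component: the band of the largest threshold exceeded.

    Strict comparison -- a value exactly on a threshold takes the lower
    band. Monotone non-decreasing in ``value``.
    """
    if value < 0:
        raise ValueError(f"component value must be >= 0, got {value}")
    # bisect_left counts thresholds strictly below value
    return table.points[bisect_left(table.thresholds, value)]


def negative_points(
    panel: NutrientPanel, basis: str, tables: ScoreTables
) -> tuple[int, dict[str, int]]:
    """Total negative points N (0..40) with a per-component breakdown.

    Requires all four negative nutrients declared; energy is converted
    kcal -> kJ and salt g -> sodium mg before lookup.
    """
    missing = panel.missing(NEGATIVE_NUTRIENTS)
    if missing:
        raise MissingNegativeNutrient(f"missing negative nutrients: {missing}")
    t = tables.for_basis(basis)
    breakdown = {
        "energy_kj": component_points(kcal_to_kj(panel.energy_kcal), t["energy_kj"]),
        "sugars_g": component_points(panel.sugars_g, t["sugars_g"]),
        "sfa_g": component_points(panel.sfa_g, t["sfa_g"]),
        "sodium_mg": component_points(salt_to_sodium_mg(panel.salt_g), t["sodium_mg"]),
    }
    return sum(breakdown.values()), breakdown


def positive_points(
    panel: NutrientPanel, basis: str, tables: ScoreTables
) -> tuple[int, dict[str, int]]:
    """Total positive points P (0..15); missing values count as zero."""
    t = tables.for_basis(basis)
    breakdown = {
        "protein_g": component_points(panel.protein_g or 0.0, t["protein_g"]),
        "fiber_g": component_points(panel.fiber_g or 0.0, t["fiber_g"]),
        "fv_percent": component_points(panel.fv_percent or 0.0, t["fv_percent"]),
    }
    return sum(breakdown.values()), breakdown


def grade(score: int, basis: str, is_water: bool = False) -> str:
    """Five-scale Nutri-Score letter for an FSAm-NPS score.

    Waters are graded A regardless of score; other beverages can never be A.
    """
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValueError(f"score must be in [{SCORE_MIN}, {SCORE_MAX}], got {score}")
    if is_water:
        return "A"
    if basis == "solid":
        if score <= -1:
            return "A"
        if score <= 2:
            return "B"
        if score <= 10:
            return "C"
        if score <= 18:
            return "D"
        return "E"
    if basis == "beverage":
        if score <= 1:
            return "B"
        if score <= 5:
            return "C"
        if score <= 9:
            return "D"
        return "E"
    raise ConfigurationError(f"unknown basis {basis!r}")


def fsam_nps(food: BrandedFood, tables: Optional[ScoreTables] = None) -> FSAmNPSResult:
    """Score one food, applying the exclusion and imputation rules.

    A food missing any negative nutrient is returned with status
    ``excluded_missing_negative`` and no score or grade. Missing positive
    nutrients are imputed to zero and listed in ``imputed_fields``.
    """
    if tables is None:
        tables = default_score_tables()
    missing_neg = food.panel.missing(NEGATIVE_NUTRIENTS)
    if missing_neg:
        return FSAmNPSResult(
            food.id,
            status="excluded_missing_negative",
            missing_negative=tuple(missing_neg),
        )
    imputed = tuple(food.panel.missing(POSITIVE_NUTRIENTS))
    n, n_breakdown = negative_points(food.panel, food.basis, tables)
    p, p_breakdown = positive_points(food.panel, food.basis, tables)
    if tables.mode == "full_rule":
        t = tables.for_basis(food.basis)
        fv_max = t["fv_percent"].points[-1]
        is_cheese = food.subcategory == CHEESE_SUBCATEGORY
        if n >= 11 and p_breakdown["fv_percent"] < fv_max and not is_cheese:
            p = p - p_breakdown["protein_g"]
            p_breakdown = dict(p_breakdown, protein_g=0)
    score = n - p
    return FSAmNPSResult(
        food.id,
        status="scored",
        negative_points=n,
        negative_breakdown=n_breakdown,
        positive_points=p,
        positive_breakdown=p_breakdown,
        score=score,
        grade=grade(score, food.basis, food.is_water),
        imputed_fields=imputed,
    )


def score_all(
    foods: Sequence[BrandedFood], tables: Optional[ScoreTables] = None
) -> list[FSAmNPSResult]:
    """Score every food independently, preserving input order."""
    if tables is None:
        tables = default_score_tables()
    return [fsam_nps(f, tables) for f in foods]
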