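"""Synthetic branded-food databases with known ground truth.

Real branded-food composition databases cannot be redistributed, so every
pipeline stage here is exercised on generated data that emulates their
structure: per-subcategory blocks of products with right-skewed (log-normal)
nutrient distributions, ingredient texts assembled so that the default
marker lexicon reproduces a chosen NOVA mix, label-style missing-value
patterns (independent per-nutrient missingness), and composite-dish /
plant-based-imitation flags.

Ingredient texts are built constructively from the intended group:

* NOVA4 -> base ingredients plus at least one ultra-processing marker;
* NOVA3 -> base ingredients plus a culinary term, no markers;
* NOVA2 -> a single culinary term;
* NOVA1 -> base ingredients plus optional distractor tokens that are
  disjoint from the lexicon.

The generator never writes its labels into the food records: the ground
truth (intended NOVA group, intended tier per pyramid, and the nutrient
values before missingness masking) travels in a separate table.

Determinism: each block draws from its own pseudo-random stream derived
from ``(seed, subcategory)``, so adding or reordering blocks never changes
another block's output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .food_model import (
    NEGATIVE_NUTRIENTS,
    POSITIVE_NUTRIENTS,
    BrandedFood,
    NutrientPanel,
)
from .pyramid import default_mappings

__all__ = [
    "NutrientSpec",
    "BlockConfig",
    "SyntheticConfig",
    "GroundTruth",
    "DEFAULT_DISTRACTORS",
    "generate_db",
    "default_config",
]

#: tokens guaranteed to be absent from the default lexicon
DEFAULT_DISTRACTORS = (
    "oregano",
    "thyme",
    "basil",
    "rosemary",
    "paprika",
    "cumin",
    "garlic",
    "onion",
    "lemon juice",
    "black pepper",
)

#: UPF marker phrases injected into NOVA4 ingredient texts; all hit the
#: default lexicon.
_UPF_SNIPPETS = (
    "emulsifier: soy lecithin",
    "xanthan gum",
    "natural flavouring",
    "preservative: sodium benzoate",
    "glucose syrup",
    "maltodextrin",
    "stabiliser: carrageenan",
    "acidity regulator",
    "monosodium glutamate",
    "soy protein isolate",
)

_GENERATED_NUTRIENTS = ("energy_kcal", "protein_g", "total_fat_g", "sugars_g", "salt_g", "fiber_g")


@dataclass(frozen=True)
class NutrientSpec:
    """Log-normal generator for one nutrient: exp(log median + sigma Z).

    ``dispersion`` is the standard deviation of the log; zero gives a
    fixed-value fixture.
    """

    median: float
    dispersion: float = 0.3

    def __post_init__(self):
        if self.median < 0 or self.dispersion < 0:
            raise ConfigurationError("NutrientSpec median and dispersion must be >= 0")


@dataclass(frozen=True)
class BlockConfig:
    """One per-subcategory block of generated products."""

    subcategory: str
    n_products: int
    nova_mix: dict[int, float]  # probability per NOVA group 1-4
    nutrients: dict[str, NutrientSpec] = field(default_factory=dict)
    basis: str = "solid"
    base_ingredients: tuple[str, ...] = ()
    culinary_ingredient: str = "salt"
    fv_percent: Optional[float] = None
    sfa_fraction: tuple[float, float] = (0.2, 0.5)
    p_missing_neg: Union[float, dict[str, float]] = 0.0
    p_missing_pos: Union[float, dict[str, float]] = 0.0
    composite_rate: float = 0.0
    imitation_rate: float = 0.0
    is_water: bool = False
    distractor_rate: float = 0.0

    def missing_rate(self, nutrient: str) -> float:
        table = self.p_missing_neg if nutrient in NEGATIVE_NUTRIENTS else self.p_missing_pos
        if isinstance(table, dict):
            return float(table.get(nutrient, 0.0))
        return float(table)

    def validate(self) -> None:
        if self.n_products < 0:
            raise ConfigurationError(f"{self.subcategory}: n_products must be >= 0")
        if not self.nova_mix:
            raise ConfigurationError(f"{self.subcategory}: nova_mix is empty")
        if set(self.nova_mix) - {1, 2, 3, 4}:
            raise ConfigurationError(f"{self.subcategory}: nova_mix keys must be 1..4")
        probs = list(self.nova_mix.values())
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.subcategory}: nova_mix must sum to 1")
        for rate_name in ("composite_rate", "imitation_rate", "distractor_rate"):
            r = getattr(self, rate_name)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{self.subcategory}: {rate_name} not in [0, 1]")
        for nutrient in NEGATIVE_NUTRIENTS + POSITIVE_NUTRIENTS:
            r = self.missing_rate(nutrient)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"{self.subcategory}: missing rate for {nutrient} not in [0, 1]"
                )


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    blocks: tuple[BlockConfig, ...]
    distractor_pool: tuple[str, ...] = DEFAULT_DISTRACTORS

    def validate(self) -> None:
        seen = set()
        for block in self.blocks:
            block.validate()
            if block.subcategory in seen:
                raise ConfigurationError(
                    f"duplicate block for subcategory {block.subcategory!r}"
                )
            seen.add(block.subcategory)


#: ground truth is a tidy table: one row per generated food
GroundTruth = pd.DataFrame


def _block_rng(seed: int, subcategory: str) -> np.random.Generator:
    digest = hashlib.sha256(subcategory.encode("utf-8")).digest()
    sub_key = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed, sub_key])


def _slug(subcategory: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in subcategory.lower()).strip("-")


def _ingredient_text(
    group: int,
    block: BlockConfig,
    rng: np.random.Generator,
    distractors: Sequence[str],
) -> str:
    base = list(block.base_ingredients) or [block.subcategory.lower()]
    if group == 2:
        return block.culinary_ingredient
    parts = list(base)
    if group == 1 and block.distractor_rate and distractors:
        if rng.random() < block.distractor_rate:
            k = int(rng.integers(1, 3))
            picks = rng.choice(len(distractors), size=min(k, len(distractors)), replace=False)
            parts.extend(distractors[i] for i in sorted(picks))
    if group == 3:
        parts.append(block.culinary_ingredient)
    if group == 4:
        if rng.random() < 0.5:
            parts.append(block.culinary_ingredient)
        k = int(rng.integers(1, 3))
        picks = rng.choice(len(_UPF_SNIPPETS), size=k, replace=False)
        parts.extend(_UPF_SNIPPETS[i] for i in sorted(picks))
    return ", ".join(parts)


def _draw_nutrients(
    block: BlockConfig, rng: np.random.Generator
) -> dict[str, Optional[float]]:
    values: dict[str, Optional[float]] = {}
    for nutrient in _GENERATED_NUTRIENTS:
        spec = block.nutrients.get(nutrient)
        if spec is None:
            values[nutrient] = 0.0
            continue
        if spec.dispersion == 0:
            v = spec.median
        else:
            v = spec.median * float(np.exp(rng.normal(0.0, spec.dispersion)))
        values[nutrient] = round(v, 2)
    # saturated fat as a sub-fraction of total fat keeps the panel invariant
    lo, hi = block.sfa_fraction
    frac = float(rng.uniform(lo, hi))
    values["sfa_g"] = round((values["total_fat_g"] or 0.0) * frac, 2)
    if values["sugars_g"] is not None:
        values["sugars_g"] = min(values["sugars_g"], 100.0)
    values["fv_percent"] = block.fv_percent
    return values


def generate_db(config: SyntheticConfig) -> tuple[list[BrandedFood], GroundTruth]:
    """Generate a branded-food table plus its ground-truth table.

    Fully deterministic given ``config.seed``. Returns the foods (file
    order: blocks in config order, products in index order) and a tidy
    ground-truth frame with the intended NOVA group, the intended tier (or
    exclusion status) per pyramid, and every nutrient value before the
    missingness mask was applied.
    """
    config.validate()
    mappings = default_mappings()
    foods: list[BrandedFood] = []
    truth_rows: list[dict] = []

    for block in config.blocks:
        rng = _block_rng(config.seed, block.subcategory)
        slug = _slug(block.subcategory)
        groups = sorted(block.nova_mix)
        probs = [block.nova_mix[g] for g in groups]
        drawn_groups = rng.choice(groups, size=block.n_products, p=probs)
        for i in range(block.n_products):
            group = int(drawn_groups[i])
            fid = f"{slug}-{i:04d}"
            is_composite = bool(rng.random() < block.composite_rate)
            is_imitation = bool(rng.random() < block.imitation_rate)
            text = _ingredient_text(group, block, rng, config.distractor_pool)
            full = _draw_nutrients(block, rng)
            masked: dict[str, Optional[float]] = {}
            for nutrient, value in full.items():
                rate = block.missing_rate(nutrient)
                drop = rate > 0 and rng.random() < rate
                masked[nutrient] = None if drop else value
            food = BrandedFood(
                id=fid,
                name=f"{block.subcategory} product {i}",
                subcategory=block.subcategory,
                basis=block.basis,
                is_water=block.is_water,
                is_composite_dish=is_composite,
                is_plant_based_imitation=is_imitation,
                ingredient_text=text,
                panel=NutrientPanel(**masked),
            )
            foods.append(food)
            truth: dict = {
                "food_id": fid,
                "subcategory": block.subcategory,
                "nova": f"NOVA{group}",
            }
            for pyramid, mapping in mappings.items():
                if is_imitation:
                    status = "excluded_imitation"
                elif is_composite:
                    status = "excluded_composite"
                elif block.subcategory in mapping.subcategory_to_tier:
                    status = mapping.subcategory_to_tier[block.subcategory]
                else:
                    status = "ineligible_modern"
                truth[f"tier_{pyramid}"] = status
            for nutrient, value in full.items():
                truth[f"true_{nutrient}"] = value
            truth_rows.append(truth)

    return foods, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------


def _spec(median, dispersion=0.3):
    return NutrientSpec(median, dispersion)


def default_config(seed: int = 0) -> SyntheticConfig:
    """A database emulating a national branded-food repository.

    Every subcategory of both default pyramid mappings is covered, with
    NOVA mixes qualitatively echoing a modern supermarket (pulses all
    minimally processed, industrial bakery all ultra-processed, cheese
    split between processed and ultra-processed, a large modern segment
    outside both pyramids). Nutrient medians are typical per-100 g label
    values for each subcategory. Missing-value rates default to 4% per
    negative nutrient and 8% per positive nutrient.
    """
    neg, pos = 0.04, 0.08

    def blk(subcategory, n, mix, *, energy, protein, fat, sugars, salt, fiber=0.0,
            base=(), basis="solid", culinary="salt", fv=None, water=False,
            composite=0.0, imitation=0.0, p_neg=neg, p_pos=pos, distractors=0.3):
        nutrients = {
            "energy_kcal": _spec(energy),
            "protein_g": _spec(protein),
            "total_fat_g": _spec(fat),
            "sugars_g": _spec(sugars),
            "salt_g": _spec(salt),
            "fiber_g": _spec(fiber),
        }
        return BlockConfig(
            subcategory=subcategory,
            n_products=n,
            nova_mix={g: p for g, p in mix.items() if p > 0},
            nutrients=nutrients,
            basis=basis,
            base_ingredients=tuple(base),
            culinary_ingredient=culinary,
            fv_percent=fv,
            p_missing_neg=p_neg,
            p_missing_pos=p_pos,
            composite_rate=composite,
            imitation_rate=imitation,
            is_water=water,
            distractor_rate=distractors,
        )

    blocks = (
        # --- pyramid base: cereals, fruit & vegetables --------------------
        blk("Pulses", 160, {1: 1.0}, energy=330, protein=22, fat=1.7, sugars=2.4,
            salt=0.02, fiber=15, base=["chickpeas"], fv=100),
        blk("Nuts", 40, {1: 0.3, 3: 0.2, 4: 0.5}, energy=600, protein=20, fat=50,
            sugars=4, salt=0.5, fiber=7, base=["almonds"], fv=100),
        blk("Seeds or Kernel", 30, {3: 0.5, 4: 0.5}, energy=560, protein=20, fat=45,
            sugars=1, salt=1.5, fiber=8, base=["sunflower seeds"], fv=100),
        blk("Nut or Seed Product", 15, {1: 0.4, 4: 0.6}, energy=580, protein=21,
            fat=50, sugars=5, salt=0.4, fiber=6, base=["peanuts"], fv=90),
        blk("Vegetable", 120, {1: 0.38, 3: 0.17, 4: 0.45}, energy=35, protein=2.5,
            fat=0.3, sugars=3, salt=0.2, fiber=3, base=["tomatoes"], fv=100),
        blk("Processed fruit", 25, {1: 0.05, 3: 0.10, 4: 0.85}, energy=80,
            protein=0.6, fat=0.2, sugars=16, salt=0.02, fiber=2,
            base=["peaches"], culinary="sugar", fv=60),
        blk("Starchy Root or Potato", 12, {1: 0.1, 3: 0.1, 4: 0.8}, energy=130,
            protein=2.3, fat=3.5, sugars=0.9, salt=0.2, fiber=2, base=["potatoes"]),
        blk("Rice or Similar Product", 50, {1: 0.8, 4: 0.2}, energy=350, protein=7.5,
            fat=1, sugars=0.4, salt=0.01, fiber=2, base=["parboiled rice"]),
        blk("Pasta or Similar product", 120, {1: 0.85, 3: 0.03, 4: 0.12}, energy=355,
            protein=12, fat=1.6, sugars=3.3, salt=0.03, fiber=3,
            base=["durum wheat semolina"]),
        blk("Bread or similar product", 120, {4: 1.0}, energy=400, protein=11,
            fat=6, sugars=4.5, salt=1.1, fiber=4, base=["wheat flour", "yeast"],
            culinary="salt"),
        # --- dairy ---------------------------------------------------------
        blk("Milk", 90, {1: 0.55, 3: 0.05, 4: 0.4}, energy=55, protein=3.4, fat=2.2,
            sugars=4.8, salt=0.11, base=["pasteurised cow milk"]),
        blk("Yogurt", 70, {1: 0.3, 4: 0.7}, energy=85, protein=5, fat=4, sugars=6,
            salt=0.13, base=["milk", "yogurt cultures"]),
        blk("Cheese", 100, {3: 0.6, 4: 0.4}, energy=300, protein=22, fat=24,
            sugars=0.6, salt=1.75, base=["pasteurised milk", "rennet", "lactic cultures"]),
        # --- meat, fish, eggs ----------------------------------------------
        blk("Fresh or Processed Egg", 25, {1: 0.95, 4: 0.05}, energy=140,
            protein=13, fat=11, sugars=0.2, salt=0.3, base=["eggs"]),
        blk("Seafood Product", 40, {3: 0.7, 4: 0.3}, energy=190, protein=20,
            fat=10, sugars=0.1, salt=1.1, base=["tuna", "water"]),
        blk("Preserved Meat", 25, {4: 1.0}, energy=220, protein=14, fat=16,
            sugars=1, salt=2.4, base=["pork"]),
        blk("Sausage or similar meat product", 20, {4: 1.0}, energy=280, protein=13,
            fat=24, sugars=1, salt=2.2, base=["pork", "beef"]),
        blk("Meat dish", 5, {4: 1.0}, energy=210, protein=14, fat=14, sugars=1,
            salt=1.8, base=["chicken"]),
        # --- sweets and modern sMDP categories -----------------------------
        blk("Fine Bakery Ware", 120, {4: 1.0}, energy=460, protein=6, fat=20,
            sugars=30, salt=0.5, fiber=2, base=["wheat flour", "sugar"]),
        blk("Sugar, Honey or Syrup", 30, {2: 0.95, 3: 0.05}, energy=320, protein=0.2,
            fat=0, sugars=78, salt=0.01, base=["grape must"], culinary="honey",
            p_pos=0.3),
        blk("Jam or Marmalade", 40, {4: 1.0}, energy=240, protein=0.4, fat=0.1,
            sugars=55, salt=0.02, fiber=1, base=["strawberries", "sugar"], fv=40),
        blk("Non-chocolate confectionary or other sugar product", 40,
            {3: 0.3, 4: 0.7}, energy=380, protein=2, fat=5, sugars=65, salt=0.1,
            base=["sesame", "sugar"], culinary="sugar"),
        blk("Prepared Food Product", 40, {4: 1.0}, energy=330, protein=6, fat=14,
            sugars=22, salt=0.6, base=["wheat flour", "milk"], composite=0.10),
        blk("Frozen dairy dessert", 30, {4: 1.0}, energy=230, protein=3.5, fat=11,
            sugars=24, salt=0.15, base=["milk", "cream", "sugar"]),
        blk("Cereal or cereal milling product", 15, {4: 1.0}, energy=380, protein=8,
            fat=3, sugars=20, salt=0.5, fiber=6, base=["oat flakes"]),
        blk("Chocolate", 90, {4: 1.0}, energy=540, protein=7, fat=32, sugars=50,
            salt=0.1, fiber=3, base=["cocoa mass", "sugar", "cocoa butter"]),
        blk("Juice or Nectar", 80, {1: 0.3, 4: 0.7}, energy=45, protein=0.5,
            fat=0.1, sugars=10, salt=0.01, basis="beverage",
            base=["orange juice"], culinary="sugar", fv=100),
        blk("Non-alcoholic beverages", 90, {4: 1.0}, energy=40, protein=0,
            fat=0, sugars=10, salt=0.02, basis="beverage",
            base=["carbonated water", "sugar"]),
        blk("Water", 30, {1: 1.0}, energy=0, protein=0, fat=0, sugars=0, salt=0.0,
            basis="beverage", base=["natural mineral water"], water=True,
            p_neg=0.0, p_pos=0.0, distractors=0.0),
        # --- modern categories outside both pyramids -----------------------
        blk("Savoury Snack", 80, {4: 1.0}, energy=520, protein=6, fat=30, sugars=3,
            salt=1.5, fiber=3, base=["potatoes", "sunflower oil"]),
        blk("Instant Noodles or Asian Dish", 30, {4: 1.0}, energy=450, protein=9,
            fat=18, sugars=4, salt=4.0, base=["wheat flour", "palm oil"]),
        blk("Energy Drink", 25, {4: 1.0}, energy=45, protein=0, fat=0, sugars=11,
            salt=0.1, basis="beverage", base=["carbonated water", "sugar", "taurine"]),
        blk("Sauce or Condiment", 60, {3: 0.2, 4: 0.8}, energy=120, protein=1.5,
            fat=8, sugars=10, salt=2.0, base=["tomatoes", "water"]),
        blk("Plant-Based Meat Imitation", 60, {1: 0.1, 4: 0.9}, energy=210,
            protein=17, fat=12, sugars=1.5, salt=1.6, fiber=4,
            base=["soybeans", "water"], imitation=1.0),
        blk("Plant-Based Dairy Imitation", 60, {1: 0.2, 4: 0.8}, energy=55,
            protein=1.2, fat=2.5, sugars=4, salt=0.1, fiber=0.5,
            base=["oats", "water"], basis="beverage", imitation=1.0),
        blk("Composite Dish", 40, {3: 0.4, 4: 0.6}, energy=160, protein=7, fat=9,
            sugars=3, salt=1.0, fiber=2, base=["eggplant", "minced beef", "milk"],
            composite=1.0),
    )
    return SyntheticConfig(seed=seed, blocks=blocks)
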