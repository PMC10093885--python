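"""Eligibility and tier assignment for the Mediterranean-diet pyramids.

Two pictorial dietary guidelines are modelled: the traditional pyramid
(tMDP), which reflects the 1960s Cretan pattern and admits only traditional
food categories, and the sustainable pyramid (sMDP), its modern revision
that also admits categories such as chocolate, juices and soft drinks in
its top tier. Each pyramid is an ordered list of tiers (base to top, tagged
with a daily/weekly/monthly consumption frequency) and a mapping from food
subcategories to tiers.

Assignment is keyed on the subcategory and the product flags only; nutrient
content and NOVA group never affect eligibility. Precedence:

1. plant-based meat/dairy imitations -> ``excluded_imitation``
   (described in neither pyramid's tier specifications);
2. composite traditional dishes      -> ``excluded_composite``
   (cannot be mapped to a single tier);
3. unmapped subcategory              -> ``ineligible_modern``;
4. otherwise                         -> ``assigned`` to the mapped tier.

A few subcategories genuinely occur in more than one tier; they default to
their majority tier, and a per-food ``tier_hint`` naming one of the allowed
alternatives overrides the default (a warning is logged when the default is
used silently).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import ConfigurationError
from .food_model import BrandedFood

__all__ = [
    "PyramidMapping",
    "TierAssignment",
    "load_pyramid_config",
    "load_mappings",
    "default_mappings",
    "assign_tier",
    "assign_all",
]

log = logging.getLogger(__name__)

# ambiguous-subcategory warnings are emitted once per (pyramid, subcategory)
_warned_ambiguous: set[tuple[str, str]] = set()

STATUSES = ("assigned", "ineligible_modern", "excluded_composite", "excluded_imitation")


@dataclass(frozen=True)
class PyramidMapping:
    pyramid: str  # "tMDP" | "sMDP"
    tiers: tuple[str, ...]  # base to top
    subcategory_to_tier: dict[str, str]
    tier_frequency: dict[str, str] = field(default_factory=dict)
    #: subcategories occurring in several tiers -> allowed alternatives
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        tier_set = set(self.tiers)
        bad = {t for t in self.subcategory_to_tier.values() if t not in tier_set}
        if bad:
            raise ConfigurationError(
                f"{self.pyramid}: mapped tiers not in tier list: {sorted(bad)}"
            )
        for sub, alts in self.ambiguous.items():
            if sub not in self.subcategory_to_tier:
                raise ConfigurationError(
                    f"{self.pyramid}: ambiguous subcategory {sub!r} is not mapped"
                )
            if not set(alts) <= tier_set:
                raise ConfigurationError(
                    f"{self.pyramid}: ambiguous tiers for {sub!r} not in tier list"
                )


@dataclass(frozen=True)
class TierAssignment:
    food_id: str
    pyramid: str
    status: str
    tier: Optional[str] = None  # present iff status == "assigned"


def load_pyramid_config(source: Union[str, Path, None] = None) -> dict:
    """Parsed pyramid config (vocabulary + both pyramid mappings)."""
    if source is None:
        text = resources.files("mednova.data").joinpath("pyramids.yaml").read_text("utf-8")
        return yaml.safe_load(text)
    with open(source, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _mapping_from_config(name: str, cfg: dict) -> PyramidMapping:
    try:
        tiers = tuple(str(t["name"]) for t in cfg["tiers"])
        freq = {str(t["name"]): str(t.get("frequency", "")) for t in cfg["tiers"]}
        sub2tier = {str(k): str(v) for k, v in cfg["subcategories"].items()}
        ambiguous = {
            str(k): tuple(str(t) for t in v) for k, v in cfg.get("ambiguous", {}).items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed pyramid config for {name}: {exc}") from exc
    return PyramidMapping(name, tiers, sub2tier, freq, ambiguous)


def load_mappings(source: Union[str, Path, None] = None) -> dict[str, PyramidMapping]:
    """Load all pyramid mappings from a config file (default: packaged)."""
    cfg = load_pyramid_config(source)
    mappings = {
        name: _mapping_from_config(name, sub) for name, sub in cfg["pyramids"].items()
    }
    # tMDP-eligible subcategories must stay eligible under the sMDP
    if "tMDP" in mappings and "sMDP" in mappings:
        missing = set(mappings["tMDP"].subcategory_to_tier) - set(
            mappings["sMDP"].subcategory_to_tier
        )
        if missing:
            raise ConfigurationError(
                f"subcategories mapped in tMDP but not sMDP: {sorted(missing)}"
            )
    return mappings


def default_mappings() -> dict[str, PyramidMapping]:
    return load_mappings(None)


def assign_tier(food: BrandedFood, mapping: PyramidMapping) -> TierAssignment:
    """Screen one food for pyramid eligibility and map it to a tier."""
    if food.is_plant_based_imitation:
        return TierAssignment(food.id, mapping.pyramid, "excluded_imitation")
    if food.is_composite_dish:
        return TierAssignment(food.id, mapping.pyramid, "excluded_composite")
    tier = mapping.subcategory_to_tier.get(food.subcategory)
    if tier is None:
        return TierAssignment(food.id, mapping.pyramid, "ineligible_modern")
    alts = mapping.ambiguous.get(food.subcategory)
    if alts:
        if food.tier_hint is not None and food.tier_hint in alts:
            tier = food.tier_hint
        elif food.tier_hint is None:
            key = (mapping.pyramid, food.subcategory)
            if key not in _warned_ambiguous:
                _warned_ambiguous.add(key)
                log.warning(
                    "subcategory %r occurs in several %s tiers; "
                    "defaulting to %r (set tier_hint to override)",
                    food.subcategory,
                    mapping.pyramid,
                    tier,
                )
    return TierAssignment(food.id, mapping.pyramid, "assigned", tier)


def assign_all(
    foods: Sequence[BrandedFood], mapping: PyramidMapping
) -> list[TierAssignment]:
    """Assign every food independently, preserving input order."""
    return [assign_tier(f, mapping) for f in foods]
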