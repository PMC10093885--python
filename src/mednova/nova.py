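"""NOVA group assignment from ingredient lists.

The NOVA system sorts foods into four groups by the extent and purpose of
their processing:

1. unprocessed or minimally processed foods,
2. processed culinary ingredients (salt, sugar, honey, oils, flours, starches),
3. processed foods (a minimally processed food plus culinary ingredients,
   e.g. canned vegetables in brine, cheese, cured fish),
4. ultra-processed foods (UPFs): industrial formulations carrying additives
   or food-derived substances rarely used in home kitchens.

On a branded-food database the only scalable evidence is the ingredient
list, so classification here is purely lexical: the free text is normalised
into ingredient tokens and matched against a configurable marker lexicon.
Any hit on an ultra-processing marker (emulsifier, industrial sweetener,
protein isolate, flavouring, ...) puts the product in group 4; otherwise the
presence and arrangement of culinary terms separates groups 1-3.

Decision precedence (``rule_fired`` on each assignment records the branch):

0. no/empty ingredient text          -> ``UNCLASSIFIABLE``
1. >=1 UPF-marker hit                -> ``NOVA4``
2. every token is a culinary term
   (water carriers ignored)          -> ``NOVA2``
3. >=1 culinary hit next to >=1
   non-culinary ingredient           -> ``NOVA3``
4. otherwise                         -> ``NOVA1``

Rule 2 covers single culinary substances ("honey") as well as blends of
culinary substances ("salt, vinegar"): a mixture of group-2 ingredients is
still a culinary ingredient, not a processed food.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import ConfigurationError
from .food_model import BrandedFood

__all__ = [
    "MatchingPolicy",
    "MarkerTerm",
    "MarkerLexicon",
    "MarkerHit",
    "NovaAssignment",
    "UPF_CATEGORIES",
    "default_lexicon",
    "load_lexicon",
    "normalize_ingredient_text",
    "detect_markers",
    "classify_nova",
    "classify_all",
]

UPF_CATEGORIES = frozenset(
    {
        "sweetener",
        "added_sodium",
        "added_oil",
        "protein_isolate",
        "flavor",
        "emulsifier",
        "thickener_bulking",
        "antioxidant_preservative",
        "fortificant",
        "other_industrial",
    }
)

#: category tag used for culinary-term evidence attached to an assignment
CULINARY_CATEGORY = "culinary"

GROUPS = ("NOVA1", "NOVA2", "NOVA3", "NOVA4")
UNCLASSIFIABLE = "UNCLASSIFIABLE"


@dataclass(frozen=True)
class MatchingPolicy:
    case_fold: bool = True
    word_boundary: bool = True


@dataclass(frozen=True)
class MarkerTerm:
    term: str
    category: str


@dataclass(frozen=True)
class MarkerHit:
    """One piece of evidence: ``term`` (tagged ``category``) found in ``token``."""

    term: str
    category: str
    token: str


@dataclass(frozen=True)
class NovaAssignment:
    food_id: str
    group: str  # NOVA1..NOVA4 or UNCLASSIFIABLE
    hits: tuple[MarkerHit, ...] = ()
    rule_fired: str = ""

    @property
    def upf_hits(self) -> tuple[MarkerHit, ...]:
        return tuple(h for h in self.hits if h.category in UPF_CATEGORIES)


class MarkerLexicon:
    """Marker terms for UPF detection plus culinary terms, with match policy.

    Matching is case-folded substring-at-word-boundary by default, so the
    term ``soy lecithin`` matches inside the token
    ``emulsifier: soy lecithin``. Set ``word_boundary=False`` for plain
    substring matching or build terms for exact-token semantics.
    """

    def __init__(
        self,
        upf_markers: Sequence[MarkerTerm],
        culinary_terms: Sequence[str],
        matching_policy: MatchingPolicy = MatchingPolicy(),
    ):
        self.upf_markers = tuple(upf_markers)
        self.culinary_terms = tuple(culinary_terms)
        self.matching_policy = matching_policy
        self._validate()
        self._upf_patterns = [
            (m, self._compile(m.term)) for m in sorted(self.upf_markers, key=lambda m: m.term)
        ]
        self._culinary_patterns = [
            (t, self._compile(t)) for t in sorted(self.culinary_terms)
        ]

    def _validate(self) -> None:
        if not self.upf_markers:
            raise ConfigurationError("lexicon has no upf_markers")
        if not self.culinary_terms:
            raise ConfigurationError("lexicon has no culinary_terms")
        bad = {m.category for m in self.upf_markers} - UPF_CATEGORIES
        if bad:
            raise ConfigurationError(f"unknown upf_marker categories: {sorted(bad)}")
        fold = (lambda s: s.casefold()) if self.matching_policy.case_fold else (lambda s: s)
        overlap = {fold(m.term) for m in self.upf_markers} & {
            fold(t) for t in self.culinary_terms
        }
        if overlap:
            raise ConfigurationError(
                f"terms in both upf_markers and culinary_terms: {sorted(overlap)}"
            )

    def _compile(self, term: str) -> re.Pattern:
        flags = re.IGNORECASE if self.matching_policy.case_fold else 0
        pat = re.escape(term.strip())
        if self.matching_policy.word_boundary:
            pat = rf"(?<!\w){pat}(?!\w)"
        return re.compile(pat, flags)

    # -- queries -----------------------------------------------------------
    def upf_hits(self, token: str) -> list[MarkerHit]:
        return [
            MarkerHit(m.term, m.category, token)
            for m, pat in self._upf_patterns
            if pat.search(token)
        ]

    def culinary_hits(self, token: str) -> list[MarkerHit]:
        return [
            MarkerHit(t, CULINARY_CATEGORY, token)
            for t, pat in self._culinary_patterns
            if pat.search(token)
        ]

    def is_culinary(self, token: str) -> bool:
        return any(pat.search(token) for _, pat in self._culinary_patterns)


def load_lexicon(path: Union[str, Path, dict]) -> MarkerLexicon:
    """Load a lexicon from a YAML/JSON config file or a parsed mapping."""
    if isinstance(path, dict):
        cfg = path
    else:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    try:
        markers = [MarkerTerm(str(e["term"]), str(e["category"])) for e in cfg["upf_markers"]]
        culinary = [str(t) for t in cfg["culinary_terms"]]
        pol = cfg.get("matching_policy", {})
        policy = MatchingPolicy(
            case_fold=bool(pol.get("case_fold", True)),
            word_boundary=bool(pol.get("word_boundary", True)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed lexicon config: {exc}") from exc
    return MarkerLexicon(markers, culinary, policy)


def default_lexicon() -> MarkerLexicon:
    """The English lexicon shipped with the package."""
    text = resources.files("mednova.data").joinpath("lexicon.yaml").read_text("utf-8")
    return load_lexicon(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

# parenthetical that is purely a quantity or percentage, e.g. "(5%)", "(30 g)"
_QUANTITY_PAREN = re.compile(
    r"[\(\[]\s*[<>~≈]?\s*\d[\d.,\s]*\s*(?:%|g|mg|kg|ml|l)?\s*[\)\]]"
)
# bare trailing percentage, e.g. "sugar 5%"
_BARE_PERCENT = re.compile(r"\s\d+(?:[.,]\d+)?\s*%")


def normalize_ingredient_text(text: Optional[str]) -> list[str]:
    """Turn a free-text ingredient list into a list of ingredient tokens.

    Case-folds, strips percentage annotations and bracketed quantities, and
    splits on commas/semicolons at the top level only: sub-ingredient lists
    inside parentheses stay attached to their parent token.

    >>> normalize_ingredient_text("Sugar (5%), cocoa mass, emulsifier: soy lecithin")
    ['sugar', 'cocoa mass', 'emulsifier: soy lecithin']
    """
    if text is None:
        return []
    s = text.casefold()
    s = _QUANTITY_PAREN.sub(" ", s)
    s = _BARE_PERCENT.sub(" ", s)

    tokens: list[str] = []
    depth = 0
    buf: list[str] = []
    for ch in s:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth = max(0, depth - 1)
        if ch in ",;" and depth == 0:
            tokens.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    tokens.append("".join(buf))

    out = []
    for tok in tokens:
        tok = re.sub(r"\s+", " ", tok).strip(" .\t\n")
        if tok:
            out.append(tok)
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def detect_markers(tokens: Sequence[str], lexicon: MarkerLexicon) -> list[MarkerHit]:
    """Every UPF-marker (term, category, token) triple found in ``tokens``.

    Deterministic: hits come out ordered by token position then term.
    """
    hits: list[MarkerHit] = []
    for token in tokens:
        hits.extend(lexicon.upf_hits(token))
    return hits


def _is_water(token: str) -> bool:
    return token.strip() == "water"


def classify_nova(food: BrandedFood, lexicon: Optional[MarkerLexicon] = None) -> NovaAssignment:
    """Assign one food to a NOVA group with auditable marker evidence."""
    if lexicon is None:
        lexicon = default_lexicon()
    tokens = normalize_ingredient_text(food.ingredient_text)
    if not tokens:
        return NovaAssignment(food.id, UNCLASSIFIABLE, (), "no_ingredient_text")

    upf = detect_markers(tokens, lexicon)
    culinary: list[MarkerHit] = []
    for token in tokens:
        culinary.extend(lexicon.culinary_hits(token))
    evidence = tuple(upf + culinary)

    if upf:
        return NovaAssignment(food.id, "NOVA4", evidence, "upf_marker")

    non_water = [t for t in tokens if not _is_water(t)]
    if non_water and all(lexicon.is_culinary(t) for t in non_water):
        return NovaAssignment(food.id, "NOVA2", evidence, "all_culinary")

    has_culinary = bool(culinary)
    has_non_culinary = any(
        not lexicon.is_culinary(t) and not _is_water(t) for t in tokens
    )
    if has_culinary and has_non_culinary:
        return NovaAssignment(food.id, "NOVA3", evidence, "culinary_plus_food")

    return NovaAssignment(food.id, "NOVA1", evidence, "no_markers")


def classify_all(
    foods: Sequence[BrandedFood], lexicon: Optional[MarkerLexicon] = None
) -> list[NovaAssignment]:
    """Classify every food independently, preserving input order."""
    if lexicon is None:
        lexicon = default_lexicon()
    return [classify_nova(f, lexicon) for f in foods]
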