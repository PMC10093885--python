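# Methods

mednova implements a food-level analysis pipeline for branded-food
composition databases (BFCDs): per-product label data — ingredient list and
nutrition declaration per 100 g/mL — are turned into a NOVA processing
group, an FSAm-NPS/Nutri-Score nutritional-quality grade, and a position in
(or exclusion from) the traditional and sustainable Mediterranean-diet
pyramids, and those per-product results are aggregated into distribution
and comparison tables. This note records the models, the defaults and the
design choices behind each stage, and what the synthetic test data does and
does not establish.

## Data model

A product record carries identity, a subcategory from a controlled
vocabulary, a solid/beverage basis, three flags (water, composite
traditional dish, plant-based imitation), the free-text ingredient list and
a per-100 g/mL nutrient panel. Missingness is first-class: an undeclared
nutrient is `None` (CSV: empty cell, JSON: `null`), never zero, because the
scoring rules treat the two differently — a missing "negative" nutrient
makes the score uncomputable, a missing "positive" nutrient is imputed to
zero. Unit conversions are fixed constants: 1 kcal = 4.184 kJ and
sodium (mg) = salt (g) × 400 (the EU labelling convention salt = 2.5 ×
sodium). Labels declare kcal and salt; scoring consumes kJ and sodium, and
no published factor accompanies the table set we reproduce, so these two
standard constants are adopted as package defaults.

## NOVA classification

Classification is purely lexical and per-food. The ingredient text is
case-folded, percentage annotations and bracketed quantities are stripped,
and the text is split into tokens on top-level commas/semicolons
(parenthesised sub-ingredient lists stay attached to their parent token).
Tokens are matched against a configurable lexicon with two term sets:

* **UPF markers** — additives and food-derived industrial substances
  (sweeteners, added sodium forms, industrially modified oils, protein
  isolates, flavourings, emulsifiers, thickeners/bulking agents,
  antioxidants/preservatives, fortificants, other industrial agents). Any
  hit assigns NOVA 4.
* **Culinary terms** — group-2 substances (salts, sugars, honey, syrups,
  oils, butter/lard, flours, starches, vinegar).

Matching is case-folded substring-at-word-boundary by default, so
`soy lecithin` matches inside `emulsifier: soy lecithin` but `aroma` does
not fire inside `aromatic`. Exact-token and case-sensitive modes are
config switches. The default lexicon is English and deliberately compact;
it is a YAML file, not code, so extended or non-English lexicons can be
swapped in.

Decision precedence: no/empty text → unclassifiable (such products are
excluded from all denominators); any UPF-marker hit → NOVA 4; all non-water
tokens culinary → NOVA 2; a culinary hit alongside at least one other
ingredient → NOVA 3; otherwise NOVA 1. Two deliberate choices here:

* *Water is ignored* when deciding whether a product is a pure culinary
  substance, so brine/syrup carriers do not demote plain salt-in-water
  products out of group 2.
* *Blends of culinary substances are NOVA 2*, not only single-substance
  products. Group 2 is defined by what the substances are, not by their
  count; this reading also makes classification stable under appending
  non-lexicon tokens (the only possible transition is NOVA 2 → NOVA 3 when
  a non-culinary ingredient joins a culinary product), which the test
  suite enforces as an invariant.

There are no subcategory-level overrides (e.g. cheese is not forced to
NOVA 3): real databases show genuine NOVA 3/NOVA 4 splits within a
subcategory, and the split must come from the ingredient evidence.

## FSAm-NPS score and Nutri-Score grade

Negative components (energy kJ, total sugars g, SFA g, sodium mg) score
0–10 points each against ten strictly increasing thresholds; positive
components (protein g, fiber g, FV% — the fruit/vegetable/pulse/nut/
specific-oil fraction) score 0–5. A value exactly on a threshold takes the
lower band, and declared values are used unrounded. The default tables are
the 2017 FSA/FSAm-NPS publication: energy 335…3350 kJ in steps of 335;
sugars 4.5…45 g; SFA 1…10 g; sodium 90…900 mg; protein 1.6…8.0 g; fiber
0.9…4.7 g; FV bands at 40/60/80 % awarding 0/1/2/5 points. Beverages use
the beverage energy (0…270 kJ) and sugars (0…13.5 g) scales; beverage FV
points (0/2/4 at the same bands) are capped at 5 so that every score stays
within the −15…+40 scale of the subtraction rule — this cap is the one
deliberate departure from the official beverage FV scale (0/2/4/10), made
so both bases share a single score range. Tables ship as editable YAML.

The default mode computes the score as the plain subtraction
`S = N − P ∈ [−15, 40]`. A `full_rule` mode also implements the official
restriction that protein is not counted when `N ≥ 11` unless FV points are
maximal or the product is cheese (subcategory `Cheese`); it is an option,
not the default, because the analysis this package reproduces describes
plain subtraction and its one self-contained worked example (the egg
product below) cannot distinguish the two.

Grades: waters → A always. Solids: A ≤ −1, B 0–2, C 3–10, D 11–18,
E ≥ 19; non-water beverages: B ≤ 1, C 2–5, D 6–9, E ≥ 10. Solid A covers
every score ≤ −1 (not only −5…−1, the nominal display floor of the scale):
leaving scores below −5 ungraded would make valid products ungradable, and
every published grade map uses ≤ −1 → A.

Products missing any negative nutrient get status
`excluded_missing_negative` and no score or grade; missing positive
nutrients are imputed to zero and recorded per product.

## Pyramid tier mapping

Each pyramid is an ordered tier list (base → top, tagged daily/weekly/
monthly) plus a subcategory → tier map reconstructed from the published
tier × subcategory enumerations. Screening precedence: plant-based
meat/dairy imitations are excluded from both pyramids (described in
neither), composite traditional dishes are excluded (no single tier),
subcategories outside the map are modern foods ineligible for that
pyramid, everything else is assigned its mapped tier. Eligibility depends
only on subcategory and flags — never on nutrients or NOVA group, since
the NOVA distribution within tiers is the analysis *output*.

A few subcategories legitimately appear under more than one tier
(`Vegetable`, `Prepared Food Product`). The config keeps the majority tier
as the default, records the allowed alternatives, and a per-food
`tier_hint` overrides the default; without a hint a warning is logged once
per subcategory. The exact product-level screening rules used on the real
database are not public, so this subcategory-driven reconstruction is a
documented approximation. Every subcategory mapped in the traditional
pyramid is also mapped in the sustainable one, which makes the traditional
assigned set a subset of the sustainable assigned set — enforced at config
load and verified as a property test.

## Statistics and tables

Label data are strongly right-skewed, so descriptives are median (Q1, Q3)
using the weighted-average (n+1)p quantile definition (type 6), matching
the default of the commercial package commonly used for such analyses.
Group comparisons are rank-based: Mann–Whitney U for pairs (exact by full
enumeration when the combined n ≤ 12 with no ties, otherwise the normal
approximation with tie-corrected variance and continuity correction;
scipy provides both branches) and tie-corrected Kruskal–Wallis with the
χ² tail for three or more groups. Any comparison touching a group with
fewer than two observations is reported "n.a.", never as a p-value.
Pairwise tests are NOVA 1 vs NOVA 4 and NOVA 3 vs NOVA 4; Bonferroni
adjustment multiplies each raw p by the number of pairs actually testable
within one tier × variable family (capped at 1). The default significance
level is α = 0.01 (a config parameter); score summaries additionally print
mean ± SD, which is how the reference tables present the score even though
the declared summary statistic is median (IQR) — both are emitted.

Distribution tables report counts and percentages per scope (whole
database and per-pyramid eligible sets), with unclassifiable foods removed
from every denominator; tier × subcategory crosstabs omit empty rows.

## Synthetic data

No real BFCD is redistributable, so the generator builds databases with
known ground truth. Each subcategory block draws from its own random
stream derived from `(seed, subcategory)` (adding a block never perturbs
another block's output). Ingredient texts are assembled constructively
from the intended NOVA group — markers injected for NOVA 4, a culinary
term added for NOVA 3, a single culinary term for NOVA 2, and base tokens
plus optional distractor tokens (disjoint from the lexicon) for NOVA 1 —
so the default lexicon recovers the intended label exactly. Nutrients are
log-normal around per-subcategory medians typical of label data
(dispersion 0.3 on the log scale; dispersion 0 gives fixed-value
fixtures); SFA is drawn as a 20–50 % fraction of total fat to respect the
panel invariant. Missingness is masked independently per nutrient, by
default 4 % per negative nutrient (≈ 15 % of products excluded from
scoring, the same order as real label data) and 8 % per positive nutrient
(below the ~10 % imputation ceiling typical of the real database).

The default configuration covers every subcategory of both pyramid
mappings plus a modern segment outside both (snacks, instant dishes,
energy drinks, imitations, composite dishes), ~2 000 products in total,
with NOVA mixes qualitatively echoing a modern supermarket (pulses all
NOVA 1, industrial bakery and chocolate all NOVA 4, cheese split
NOVA 3/NOVA 4). Ground truth (intended group, intended tier per pyramid,
pre-masking nutrient values) travels in a separate table that the pipeline
never sees.

What passing tests on this data shows: the pipeline's rules are applied
exactly and the statistics behave (type-I error controlled on null data,
shifted distributions detected). What it does not show: performance on
real ingredient texts — real labels carry multilingual text, typos,
E-numbers and marker vocabulary far beyond the compact default lexicon, so
market-level percentages from real databases are not reproduced here and
classification quality on real data is bounded by the lexicon supplied.

## Numerical and edge-case conventions

* Threshold lookup is strict (`value > threshold` advances a band); ties
  on the boundary take the lower band.
* Percentages in tables are rounded to one decimal; row counts always sum
  to the row n and percentages to 100 ± 0.1.
* Degenerate Kruskal–Wallis input (all values identical in all groups)
  returns H = 0, p = 1 by definition rather than an error.
* Scores are integers by construction; the score mean ± SD uses the
  sample SD (ddof = 1) and is NaN for singleton cells.
* Files are UTF-8; numbers use the period decimal separator only.

## Known limitations

* The default lexicon makes no completeness claim over E-numbers or
  non-English ingredient vocabulary; it is a seed list, intended to be
  replaced for production use.
* FV% is consumed as a declared input field and never inferred from the
  ingredient list.
* Tier mapping cannot resolve genuinely ambiguous subcategories without a
  per-food hint.
* The 2023+ revised Nutri-Score algorithm, per-portion scoring and diet
  adherence indices are out of scope.
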