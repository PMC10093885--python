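# mednova

Food-level analysis of branded-food composition databases: NOVA
ultra-processing classification from ingredient lists, FSAm-NPS/Nutri-Score
nutritional-quality grading, Mediterranean-diet pyramid tier mapping, and
the distribution/comparison tables that tie the three together.

## Who this is for

Nutrition and public-health researchers working with branded-food
composition databases (BFCDs) — per-product label data for packaged foods —
who want to ask questions like: *how many supermarket products eligible
under a Mediterranean-diet pyramid are ultra-processed, and does their
nutritional quality differ from less processed products in the same tier?*
The pipeline runs end-to-end on any table in the documented CSV/JSON
schema, and ships a synthetic-database generator with known ground truth so
every stage is testable without access to proprietary data.

## What it computes

**NOVA group (1–4).** Foods are sorted by extent and purpose of processing:
1 unprocessed/minimally processed, 2 processed culinary ingredients,
3 processed foods, 4 ultra-processed foods (UPFs). Classification is
lexical: the ingredient text is tokenised and matched against a
configurable marker lexicon; any hit on an ultra-processing marker
(emulsifier, industrial sweetener, protein isolate, flavouring, …) assigns
NOVA 4, and the arrangement of culinary terms (salt, sugar, oils, flours,
…) separates groups 1–3. Every assignment carries its matching evidence.

**FSAm-NPS score and Nutri-Score grade.** Per 100 g/mL, "negative"
components (energy kJ, sugars g, SFA g, sodium mg) score 0–10 points each
and "positive" components (protein g, fiber g, fruit/vegetable/pulse/nut
fraction FV %) score 0–5; the score is

    S = (p_energy + p_sugars + p_SFA + p_sodium) − (p_protein + p_fiber + p_FV)  ∈ [−15, 40]

with kcal→kJ (×4.184) and salt→sodium (g→mg, ×400) conversion before
lookup. Grades: waters → A; solids A/B/C/D/E at S ≤ −1 / 0–2 / 3–10 /
11–18 / ≥ 19; non-water beverages B/C/D/E at S ≤ 1 / 2–5 / 6–9 / ≥ 10.
Products missing a negative nutrient are excluded; missing positive
nutrients are imputed to zero.

**Pyramid tiers.** Subcategory-driven mapping into the traditional (tMDP)
and sustainable (sMDP) Mediterranean-diet pyramids, with explicit statuses
for modern-food ineligibility and for excluded composite dishes and
plant-based imitations.

**Tables.** NOVA distributions per scope, tier × subcategory crosstabs,
per-tier nutrient comparisons (median (Q1, Q3), Kruskal–Wallis /
Mann–Whitney, Bonferroni-adjusted pairwise tests vs NOVA 4) and
Nutri-Score grade distributions with mean ± SD scores.

See `docs/methods.md` for the full model description, defaults and design
choices.

## Worked example

```python
from mednova import (BrandedFood, NutrientPanel, classify_nova, fsam_nps,
                     assign_tier, default_mappings)

egg = BrandedFood(
    id="egg-1", name="pasteurised egg white",
    subcategory="Fresh or Processed Egg", basis="solid",
    ingredient_text="pasteurised egg white, preservative: sodium benzoate",
    panel=NutrientPanel(energy_kcal=46, protein_g=11.0, total_fat_g=0.3,
                        sfa_g=0.0, sugars_g=0.3, salt_g=0.44),
)

nova = classify_nova(egg)
print(nova.group, nova.rule_fired, [h.term for h in nova.upf_hits])
# NOVA4 upf_marker ['preservative', 'sodium benzoate']

score = fsam_nps(egg)
print(score.negative_points, score.positive_points, score.score, score.grade,
      score.imputed_fields)
# 1 5 -4 A ('fiber_g', 'fv_percent')

tier = assign_tier(egg, default_mappings()["tMDP"])
print(tier.status, tier.tier)
# assigned Eggs
```

Reading the output: the preservative in the ingredient list is an
ultra-processing marker, so the product is NOVA 4. Its declaration earns
1 negative point (176 mg sodium from 0.44 g salt; energy, sugars and SFA
all score 0) against 5 positive points (11 g protein saturates the protein
scale; undeclared fiber and FV% are imputed to zero), giving
S = 1 − 5 = −4 — grade A for a solid food. Under the traditional pyramid
it sits in the Eggs tier.

For a full synthetic run:

```bash
mednova simulate --seed 17 --out foods.csv --truth truth.csv
mednova analyze  --foods foods.csv --out-dir results/
```

which writes `table1.csv` … `table7.csv` (distributions, nutrient and
score comparisons per pyramid) and `figure1.csv` (tier-level NOVA
percentages). `mednova classify / score / map` expose the individual
stages.

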