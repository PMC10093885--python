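# Default English ingredient-marker lexicon.
#
# upf_markers: terms whose presence in an ingredient list marks a product as
#   ultra-processed (NOVA group 4). Each carries a category tag so that the
#   evidence behind a classification can be audited.
# culinary_terms: processed culinary ingredients (NOVA group 2 substances --
#   salts, sugars, oils, starches, flours) used to separate groups 2/3 from 1.
#
# This file is configuration, not code: swap in a Greek or extended lexicon
# by pointing the classifier at another file with the same structure.

matching_policy:
  case_fold: true
  word_boundary: true

upf_markers:
  # industrial sweeteners, caloric and non-caloric
  - {term: glucose syrup, category: sweetener}
  - {term: glucose-fructose syrup, category: sweetener}
  - {term: fructose syrup, category: sweetener}
  - {term: high fructose corn syrup, category: sweetener}
  - {term: invert sugar syrup, category: sweetener}
  - {term: maltodextrin, category: sweetener}
  - {term: dextrose, category: sweetener}
  - {term: aspartame, category: sweetener}
  - {term: acesulfame k, category: sweetener}
  - {term: sucralose, category: sweetener}
  - {term: saccharin, category: sweetener}
  - {term: steviol glycosides, category: sweetener}
  - {term: sorbitol, category: sweetener}
  - {term: xylitol, category: sweetener}
  - {term: maltitol, category: sweetener}
  - {term: isomalt, category: sweetener}
  # added sodium in its industrial forms
  - {term: monosodium glutamate, category: added_sodium}
  - {term: disodium phosphate, category: added_sodium}
  - {term: sodium citrate, category: added_sodium}
  - {term: sodium bicarbonate, category: added_sodium}
  - {term: sodium nitrite, category: added_sodium}
  - {term: sodium nitrate, category: added_sodium}
  # industrially modified added oils and fats
  - {term: hydrogenated vegetable oil, category: added_oil}
  - {term: hydrogenated palm oil, category: added_oil}
  - {term: partially hydrogenated oil, category: added_oil}
  - {term: hydrogenated fat, category: added_oil}
  - {term: interesterified fat, category: added_oil}
  # protein isolates and concentrates
  - {term: protein isolate, category: protein_isolate}
  - {term: protein concentrate, category: protein_isolate}
  - {term: whey protein, category: protein_isolate}
  - {term: sodium caseinate, category: protein_isolate}
  - {term: hydrolysed protein, category: protein_isolate}
  # added flavours and flavour enhancers
  - {term: flavouring, category: flavor}
  - {term: flavoring, category: flavor}
  - {term: natural flavour, category: flavor}
  - {term: natural flavor, category: flavor}
  - {term: flavour enhancer, category: flavor}
  - {term: flavor enhancer, category: flavor}
  - {term: aroma, category: flavor}
  # emulsifiers
  - {term: emulsifier, category: emulsifier}
  - {term: lecithin, category: emulsifier}
  - {term: monoglycerides, category: emulsifier}
  - {term: diglycerides, category: emulsifier}
  - {term: polysorbate, category: emulsifier}
  # bulking agents and thickeners
  - {term: thickener, category: thickener_bulking}
  - {term: bulking agent, category: thickener_bulking}
  - {term: carboxymethyl cellulose, category: thickener_bulking}
  - {term: cellulose gel, category: thickener_bulking}
  - {term: guar gum, category: thickener_bulking}
  - {term: xanthan gum, category: thickener_bulking}
  - {term: carrageenan, category: thickener_bulking}
  - {term: locust bean gum, category: thickener_bulking}
  - {term: modified starch, category: thickener_bulking}
  - {term: pectin, category: thickener_bulking}
  # antioxidants and preservatives
  - {term: preservative, category: antioxidant_preservative}
  - {term: antioxidant, category: antioxidant_preservative}
  - {term: sodium benzoate, category: antioxidant_preservative}
  - {term: potassium sorbate, category: antioxidant_preservative}
  - {term: sulfur dioxide, category: antioxidant_preservative}
  - {term: sulphur dioxide, category: antioxidant_preservative}
  - {term: sodium metabisulfite, category: antioxidant_preservative}
  - {term: ascorbyl palmitate, category: antioxidant_preservative}
  - {term: bha, category: antioxidant_preservative}
  - {term: bht, category: antioxidant_preservative}
  # fortificants rarely used in kitchens
  - {term: vitamin a palmitate, category: fortificant}
  - {term: vitamin d2, category: fortificant}
  - {term: vitamin d3, category: fortificant}
  - {term: zinc sulfate, category: fortificant}
  - {term: ferrous sulfate, category: fortificant}
  - {term: folic acid, category: fortificant}
  - {term: cyanocobalamin, category: fortificant}
  # other industrial agents
  - {term: stabiliser, category: other_industrial}
  - {term: stabilizer, category: other_industrial}
  - {term: acidity regulator, category: other_industrial}
  - {term: anti-caking agent, category: other_industrial}
  - {term: humectant, category: other_industrial}
  - {term: glazing agent, category: other_industrial}
  - {term: firming agent, category: other_industrial}
  - {term: colouring, category: other_industrial}
  - {term: coloring, category: other_industrial}
  - {term: caramel colour, category: other_industrial}

culinary_terms:
  - salt
  - sugar
  - honey
  - syrup
  - molasses
  - olive oil
  - sunflower oil
  - corn oil
  - soybean oil
  - rapeseed oil
  - canola oil
  - palm oil
  - coconut oil
  - sesame oil
  - vegetable oil
  - butter
  - lard
  - flour
  - starch
  - cornstarch
  - vinegar
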