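# Mediterranean-diet pyramid tier mappings and the controlled subcategory
# vocabulary.
#
# tMDP: the traditional pyramid (1960s Crete pattern) -- fresh/minimally
#   processed local foods only; modern categories (chocolate, soft drinks,
#   savoury snacks, ...) are ineligible.
# sMDP: the sustainable revision -- admits modern foods (sweets, juices and
#   soft drinks in the top tier) while keeping the traditional base.
#
# Each pyramid lists its tiers base-to-top with a consumption-frequency tag
# and a subcategory -> tier map. Subcategories that genuinely occur in more
# than one tier keep their majority tier here and list the alternatives
# under `ambiguous`; a per-food `tier_hint` naming one of those alternatives
# overrides the default.

vocabulary:
  - Preserved Meat
  - Sausage or similar meat product
  - Meat dish
  - Fine Bakery Ware
  - Sugar, Honey or Syrup
  - Jam or Marmalade
  - Non-chocolate confectionary or other sugar product
  - Prepared Food Product
  - Frozen dairy dessert
  - Cereal or cereal milling product
  - Chocolate
  - Juice or Nectar
  - Non-alcoholic beverages
  - Fresh or Processed Egg
  - Starchy Root or Potato
  - Pulses
  - Nut or Seed Product
  - Seeds or Kernel
  - Nuts
  - Vegetable
  - Processed fruit
  - Seafood Product
  - Milk
  - Yogurt
  - Cheese
  - Rice or Similar Product
  - Pasta or Similar product
  - Bread or similar product
  # modern categories outside both pyramids
  - Savoury Snack
  - Instant Noodles or Asian Dish
  - Energy Drink
  - Sauce or Condiment
  - Plant-Based Meat Imitation
  - Plant-Based Dairy Imitation
  - Composite Dish
  - Water

pyramids:
  tMDP:
    tiers:
      - {name: Non refined cereals, frequency: daily}
      - {name: Fruits and Vegetables, frequency: daily}
      - {name: "Olives, Pulses, Nuts", frequency: daily}
      - {name: Dairy, frequency: daily}
      - {name: Fish, frequency: weekly}
      - {name: Potatoes, frequency: weekly}
      - {name: Eggs, frequency: weekly}
      - {name: Sweets, frequency: weekly}
      - {name: Red Meat, frequency: monthly}
    subcategories:
      Preserved Meat: Red Meat
      Sausage or similar meat product: Red Meat
      Meat dish: Red Meat
      Fine Bakery Ware: Sweets
      Sugar, Honey or Syrup: Sweets
      Jam or Marmalade: Sweets
      Non-chocolate confectionary or other sugar product: Sweets
      Prepared Food Product: Sweets
      Fresh or Processed Egg: Eggs
      Starchy Root or Potato: Potatoes
      Pulses: "Olives, Pulses, Nuts"
      Nut or Seed Product: "Olives, Pulses, Nuts"
      Seeds or Kernel: "Olives, Pulses, Nuts"
      Nuts: "Olives, Pulses, Nuts"
      Seafood Product: Fish
      Milk: Dairy
      Yogurt: Dairy
      Cheese: Dairy
      Vegetable: Fruits and Vegetables
      Processed fruit: Fruits and Vegetables
      Rice or Similar Product: Non refined cereals
      Pasta or Similar product: Non refined cereals
      Bread or similar product: Non refined cereals
    ambiguous:
      Vegetable: ["Fruits and Vegetables", "Olives, Pulses, Nuts"]
      Prepared Food Product: ["Sweets", "Olives, Pulses, Nuts"]

  sMDP:
    tiers:
      - {name: "Fruits, Vegetables, Cereals", frequency: daily}
      - {name: "Olives, Pulses, Nuts", frequency: daily}
      - {name: Dairy, frequency: daily}
      - {name: "White meat, fish, eggs", frequency: weekly}
      - {name: Red and processed Meat, frequency: monthly}
      - {name: Sweets, frequency: monthly}
    subcategories:
      Fine Bakery Ware: Sweets
      Sugar, Honey or Syrup: Sweets
      Jam or Marmalade: Sweets
      Non-chocolate confectionary or other sugar product: Sweets
      Prepared Food Product: Sweets
      Frozen dairy dessert: Sweets
      Cereal or cereal milling product: Sweets
      Chocolate: Sweets
      Juice or Nectar: Sweets
      Non-alcoholic beverages: Sweets
      Preserved Meat: Red and processed Meat
      Sausage or similar meat product: Red and processed Meat
      Meat dish: Red and processed Meat
      Fresh or Processed Egg: "White meat, fish, eggs"
      Seafood Product: "White meat, fish, eggs"
      Milk: Dairy
      Yogurt: Dairy
      Cheese: Dairy
      Pulses: "Olives, Pulses, Nuts"
      Nut or Seed Product: "Olives, Pulses, Nuts"
      Seeds or Kernel: "Olives, Pulses, Nuts"
      Nuts: "Olives, Pulses, Nuts"
      Processed fruit: "Fruits, Vegetables, Cereals"
      Vegetable: "Fruits, Vegetables, Cereals"
      Starchy Root or Potato: "Fruits, Vegetables, Cereals"
      Rice or Similar Product: "Fruits, Vegetables, Cereals"
      Pasta or Similar product: "Fruits, Vegetables, Cereals"
      Bread or similar product: "Fruits, Vegetables, Cereals"
    ambiguous:
      Vegetable: ["Fruits, Vegetables, Cereals", "Olives, Pulses, Nuts"]
      Prepared Food Product: ["Sweets", "White meat, fish, eggs", "Olives, Pulses, Nuts"]
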