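# Default survey configuration: ten raw eating-occasion labels collapsing onto
# four occasion groups, the seven replaceable sweetened categories, and the
# serving-rule knobs.  Other surveys can ship their own copy of this file.
occasion_map:
  "Before breakfast": breakfast
  "Breakfast": breakfast
  "In the morning": breakfast
  "Aperitif before lunch": lunch
  "Lunch": lunch
  "Snack": snack
  "In the afternoon (excluding snacks)": snack
  "Aperitif before dinner": dinner
  "Dinner": dinner
  "In the evening/night": dinner
replaceable_categories:
  - soft_drink
  - fruit_juice
  - pastry
  - biscuit
  - dairy_dessert
  - ice_cream
  - chocolate_confectionery
serving_overrides: []
# fallback servings for a category x age group with no observed events at all
default_servings:
  fruit_puree: 100.0
  soft_drink: 250.0
  fruit_juice: 150.0
  pastry: 60.0
  biscuit: 40.0
  dairy_dessert: 110.0
  ice_cream: 70.0
  chocolate_confectionery: 30.0
# minimum events for a cell median to be trusted before falling back
robustness_threshold: 10
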