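"""Nutrient vocabulary shared across the pipeline.

A daily intake is a vector over :data:`NUTRIENTS` (energy plus 18
nutrients); throughout the package these live as columns of a pandas
DataFrame, one row per child-day.
"""

from __future__ import annotations

# Canonical column order: energy first, then macronutrients (g),
# minerals (mg), vitamins.  Units are fixed per component.
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "calcium_mg",
    "phosphorus_mg",
    "iron_mg",
    "zinc_mg",
    "vitamin_a_ug_rae",
    "vitamin_d_ug",
    "vitamin_c_mg",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vitamin_b6_mg",
    "folate_ug_dfe",
)

#: Nutrients other than energy.
NUTRIENT_COLUMNS: tuple[str, ...] = NUTRIENTS[1:]

#: General Atwater factors, kcal per gram.
ATWATER: dict[str, float] = {
    "protein_g": 4.0,
    "carbohydrate_g": 4.0,
    "fat_g": 9.0,
}

#: Macronutrients classified against an AMDR as % of energy.
AMDR_MACROS: tuple[str, ...] = ("protein_g", "carbohydrate_g", "fat_g")

#: Dairy subtype tags recognised in recall tables.  ``tea_milk`` is the
#: milk component of tea served with milk; it counts as milk.
DAIRY_TAGS: tuple[str, ...] = (
    "milk_buffalo",
    "milk_cow",
    "milk_goat",
    "milk_fortified",
    "tea_milk",
    "yogurt",
    "ice_cream",
    "dairy_dessert",
    "milkshake",
)

#: Tags whose grams count as *milk* (substitution scenario operates on these).
MILK_TAGS: tuple[str, ...] = (
    "milk_buffalo",
    "milk_cow",
    "milk_goat",
    "milk_fortified",
    "tea_milk",
)

#: Map milk-type tags to the milk kind in the composition config.
MILK_KIND_OF_TAG: dict[str, str] = {
    "milk_buffalo": "buffalo",
    "milk_cow": "cow",
    "milk_goat": "goat",
    "milk_fortified": "fortified",
    # tea-with-milk is buffalo milk by default in Pakistani diets; the
    # recall's food code decides the actual composition, this mapping is
    # used only when a scenario needs to know which milk a tag carries.
    "tea_milk": "buffalo",
}
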