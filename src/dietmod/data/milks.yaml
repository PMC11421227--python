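# Default per-100 g milk compositions used by the modeling scenarios.
#
# SYNTHETIC DEFAULTS: these are typical values assembled from standard
# food-composition references (whole buffalo, cow and goat milk; a
# reconstituted fortified "filled" milk beverage with vegetable oil and
# added Ca/Fe/Zn and vitamins A, C, D and B-group).  They are NOT tied to
# any particular survey's composition database and are intended to be
# overridden with a study-specific file (``--milks my_milks.yaml``).
#
# ``retinol_fraction``: share of vitamin A (RAE) present as preformed
# retinol (relevant to the vitamin A UL).  ``folic_acid_fraction``: share
# of folate (DFE) present as synthetic folic acid (relevant to the folate
# UL).  Natural milk folate is food folate, hence 0.0.
buffalo:
  energy_kcal: 97.9
  protein_g: 3.75
  carbohydrate_g: 5.2
  fat_g: 6.9
  sfa_g: 4.6
  mufa_g: 1.8
  pufa_g: 0.15
  calcium_mg: 169.0
  phosphorus_mg: 117.0
  iron_mg: 0.12
  zinc_mg: 0.22
  vitamin_a_ug_rae: 53.0
  vitamin_d_ug: 0.1
  vitamin_c_mg: 2.3
  thiamin_mg: 0.052
  riboflavin_mg: 0.135
  niacin_mg: 0.091
  vitamin_b6_mg: 0.023
  folate_ug_dfe: 6.0
  retinol_fraction: 1.0
  folic_acid_fraction: 0.0
cow:
  energy_kcal: 61.7
  protein_g: 3.2
  carbohydrate_g: 4.8
  fat_g: 3.3
  sfa_g: 1.9
  mufa_g: 0.8
  pufa_g: 0.2
  calcium_mg: 113.0
  phosphorus_mg: 91.0
  iron_mg: 0.03
  zinc_mg: 0.37
  vitamin_a_ug_rae: 46.0
  vitamin_d_ug: 0.05
  vitamin_c_mg: 0.0
  thiamin_mg: 0.046
  riboflavin_mg: 0.169
  niacin_mg: 0.089
  vitamin_b6_mg: 0.036
  folate_ug_dfe: 5.0
  retinol_fraction: 1.0
  folic_acid_fraction: 0.0
goat:
  energy_kcal: 69.3
  protein_g: 3.6
  carbohydrate_g: 4.5
  fat_g: 4.1
  sfa_g: 2.7
  mufa_g: 1.1
  pufa_g: 0.15
  calcium_mg: 134.0
  phosphorus_mg: 111.0
  iron_mg: 0.05
  zinc_mg: 0.3
  vitamin_a_ug_rae: 57.0
  vitamin_d_ug: 0.06
  vitamin_c_mg: 1.3
  thiamin_mg: 0.048
  riboflavin_mg: 0.138
  niacin_mg: 0.277
  vitamin_b6_mg: 0.046
  folate_ug_dfe: 1.0
  retinol_fraction: 1.0
  folic_acid_fraction: 0.0
fortified:
  energy_kcal: 64.6
  protein_g: 2.9
  carbohydrate_g: 6.5
  fat_g: 3.0
  sfa_g: 0.6
  mufa_g: 1.0
  pufa_g: 1.2
  calcium_mg: 170.0
  phosphorus_mg: 90.0
  iron_mg: 1.5
  zinc_mg: 0.6
  vitamin_a_ug_rae: 60.0
  vitamin_d_ug: 1.0
  vitamin_c_mg: 9.0
  thiamin_mg: 0.1
  riboflavin_mg: 0.2
  niacin_mg: 0.8
  vitamin_b6_mg: 0.1
  folate_ug_dfe: 10.0
  retinol_fraction: 1.0
  folic_acid_fraction: 1.0
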