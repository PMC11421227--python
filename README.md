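# dietmod

A diet-modeling pipeline for single-day dietary surveys of school-age
children: from 24-h recall records to per-child nutrient intakes, dairy
serving classification, counterfactual milk interventions, usual-intake
estimation, and population prevalence of nutrient inadequacy.

The package is aimed at nutrition epidemiologists who want to ask: *if
children who fall short of dairy recommendations were given more (or
better-fortified) milk, which nutrient gaps would close?* It was built
around the situation of 5–9 year-old Pakistani children — buffalo milk
as the dominant dairy, 250 g = 1 serving, a 2–3 servings/d
recommendation — but every reference value, milk composition and
scenario is configuration.

## What it computes

**Intakes.** Recall items (grams of a food code) are converted with a
per-100 g composition table and summed per child per day over energy and
18 nutrients. Implausible energy intakes (beyond 3 SD of the mean within
each 1-y age stratum, single pass) are excluded. Dairy grams are
accumulated by subtype (milk by kind, the milk in tea, yogurt, ice
cream, desserts, milkshakes) and converted to servings.

**Scenarios.** Two interventions, applied with no compensation elsewhere
in the diet:

* *substitution* — current milk is replaced volume-by-volume with a
  fortified milk beverage, among milk consumers not already drinking it;
* *addition* — children below 2 servings/d are topped up by a tiered
  rule (current servings s → added servings a):
  s ∈ [0, 0.5) → 2; [0.5, 1) → 1.5; [1, 1.5) → 1; [1.5, 2) → 0.5,
  optionally capped at 1 added serving/d.

**Usual intakes.** With one recall day per child, observed
between-person variance over-states true between-person variance. Given
an external within:between variance ratio *r* on the log scale
(default 0.73, sensitivity sweep 0.2–0.9), transformed deviations from
the mean are shrunk by 1/√(1+r) and back-transformed with an exact
mean-matching correction.

**Adequacy.** Per nutrient: % of usual intakes below the EAR (cut-point
method); for iron, the full probability method
p = (1/n) Σᵢ P(Rᵢ > yᵢ) with a log-normal requirement distribution
anchored so its 97.5th percentile equals the WHO RNI; macronutrients are
classified against the AMDR as % of energy (Atwater 4/4/9); UL
exceedance uses preformed retinol for vitamin A and folic acid for
folate. Zinc and iron references are derived from WHO RNIs at low
bioavailability (zinc EAR = RNI / 1.2: 8.0 mg/d for 5–6 y, 9.3 mg/d for
7–9 y).

**Synthetic surveys.** Because comparable survey microdata are
request-only, a generator produces recall/composition/truth tables with
exactly log-normal usual intakes, controlled within:between variance
ratio, and a dairy-consumption pattern with known ground truth — the
test bed for every estimator.

## Worked example

```python
import dietmod as dm

spec = dm.PopulationSpec(n_children=2000, seed=42)
recall, foods, truth = dm.generate_survey(spec)
childday = dm.compute_intakes(recall, foods)
childday, n_out = dm.flag_energy_outliers(childday)
childday = childday[~childday["energy_outlier"]]
print(f"{len(childday)} children analysed ({n_out} energy outliers excluded)")
print(f"dairy consumers: {100*childday['dairy_consumer'].mean():.1f}%")

refs, milks = dm.load_references(), dm.load_milks()
cfg = dm.UsualIntakeConfig(variance_ratio=0.73)
scen = dm.ScenarioSpec(kind="addition", milk="fortified", cap_servings=2.0)
modified, mask = dm.apply_scenario(childday, scen, milks)
before = dm.summarize_adequacy(childday[mask], refs, cfg)
after = dm.summarize_adequacy(modified, refs, cfg)
cmp_df = dm.compare_scenarios(before[before.basis == "amount"],
                              after[after.basis == "amount"])
print(cmp_df.loc[["calcium_mg", "iron_mg", "vitamin_c_mg"]].round(1))
```

prints

```
1976 children analysed (24 energy outliers excluded)
dairy consumers: 89.3%
              baseline_pct  scenario_pct  absolute_reduction_pp  relative_reduction_pct
nutrient
calcium_mg            97.5          12.0                   85.5                    87.7
iron_mg               81.0          23.9                   57.1                    70.5
vitamin_c_mg          18.4           0.0                   18.4                  100.0
```

i.e. topping this synthetic population up to 2 dairy servings/d with
fortified milk would cut calcium inadequacy from 97.5% to 12.0% of
children (an 87.7% relative reduction) and essentially eliminate
vitamin C and riboflavin inadequacy; iron inadequacy (full probability
method) falls by 70% because the beverage is iron-fortified.

The same pipeline runs end-to-end from the shell:

```
dietmod report --seed 1 --outdir out/        # full synthetic run
dietmod simulate | validate | intakes | scenario | usual | adequacy | compare
```

writing dairy-consumption and adequacy tables, before/after reduction
tables, sensitivity-sweep CSVs, prevalence figures and a run manifest.

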