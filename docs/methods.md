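# Methods

This note documents the models and procedures implemented in `dietmod`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real survey data.

## 1. From recall items to child-days

A 24-h recall is a table of (child, food code, grams) rows; a
composition table gives each food's energy and 18 nutrients per 100 g
edible portion, plus two fractions used only for UL analyses: the
preformed-retinol share of vitamin A (µg RAE) and the folic-acid share
of folate (µg DFE). Intakes are the exact linear aggregation
Σ grams/100 × composition per child per day; the operation is linear in
grams and additive over disjoint children, and both properties are
enforced by tests.

Dairy is the sum of milk (buffalo, cow, goat, fortified, and the milk
component of tea-with-milk), milkshakes, dairy desserts, yogurt and ice
cream. One serving is 250 g; the 250 g denominator is applied uniformly
to all dairy subtypes, since the guideline defines the serving only for
milk. Servings are kept at full precision internally — the addition
tiers are defined on exact servings — and rounded to one decimal only in
reports.

**Energy-outlier screen.** Within each 1-y age stratum, a child is
excluded when |energy − stratum mean| > 3 sample SDs, computed once over
the full stratum (not re-estimated after exclusions). A consequence of
the single-pass rule worth knowing: in a stratum of n children no point
can lie more than (n−1)/√n sample SDs from the mean, so strata of ten or
fewer children can never trip the 3-SD rule; the screen is meaningful
only at survey scale. Strata with fewer than two children are skipped
with a warning.

## 2. Intervention scenarios

Both scenarios are best-case counterfactuals: full compliance, no
compensation elsewhere in the diet.

*Substitution* replaces every gram of non-fortified milk (tea-milk
included) volume-by-volume with fortified milk among milk consumers,
excluding children already drinking fortified milk. Nutrient totals move
by grams/100 × (fortified − original) per-100 g composition; total dairy
grams are invariant. Replacing the milk inside tea as well as plain milk
is a deliberate reading ("milk including tea with milk" is dairy); users
who want plain-milk-only substitution can re-tag tea-milk rows.

*Addition* tops up children below 2 servings/d with buffalo or fortified
milk by the tiered rule [0, 0.5) → +2, [0.5, 1) → +1.5, [1, 1.5) → +1,
[1.5, 2) → +0.5 servings. Tier bounds are half-open on exact servings —
the display bands "0.5–0.9" etc. are read as one-decimal decades — which
guarantees every treated child reaches at least 2 servings/d (and at
most 2.5, by enumeration). The restricted variant clips the tier at 1
added serving/d, under which children starting below 1 serving remain
short of the recommendation by design. Applying the uncapped rule twice
adds nothing the second time (idempotence), and children already
consuming fortified milk remain eligible for addition — the exclusion
applies to substitution only.

## 3. Usual intakes from one recall day

One day of intake per child confounds between-person variance with
day-to-day variance. Let y be intake transformed by log(x + ε) (ε =
half the smallest positive observed value per nutrient; Box-Cox with
fixed λ is available). Under the external-ratio model the observed
transformed variance is s² = σ_b²(1 + r), where r is the within:between
variance ratio on the transformed scale. Each value is mapped to
m + (y − m)/√(1+r), then back-transformed and rescaled multiplicatively
so the population mean on the original scale is preserved exactly (a
stronger form of the usual half-variance bias correction). Shrinkage is
strictly monotone, so individual ranks are never reordered; r = 0 is the
identity, and as r → ∞ the distribution collapses to a point.

Defaults: r = 0.73 for all nutrients, chosen from published
variance-ratio compilations for comparable school-age South-Asian
populations; a sensitivity sweep over r ∈ {0.2, …, 0.9} is part of the
standard pipeline because prevalence estimates for nutrients whose mean
sits near the EAR can swing substantially with r. The direction is
predictable: shrinkage concentrates mass at the mean, so prevalence
moves toward 0% or 100% according to whether the mean clears the EAR.

Zeros are handled through the ε offset rather than a two-part
(probability × amount) model; the in-scope nutrients are consumed
near-universally, where the two-part machinery adds nothing. A column
that is entirely zero (e.g. folic acid in a population with no fortified
foods) is returned unchanged. The identity (r = 0) path accepts any
sample size; the estimating path requires n ≥ 10.

## 4. Adequacy estimators

**EAR cut-point.** Prevalence of inadequacy = % of usual intakes below
the age-band/sex-resolved EAR. Age bands split at 5–8 vs 9 y, except
iron and zinc whose WHO references split at 5–6 vs 7–9 y. The protein
EAR is per kg body weight (0.76 g/kg/d) and is multiplied by the child's
weight. Nutrients without any reference (SFA, MUFA, PUFA) yield an
explicit not-applicable result, never a silent 0.

**Iron: full probability method.** Individual iron requirements are
right-skewed in growing children, so the cut-point method is biased for
iron. Requirements are modeled log-normal with the 97.5th percentile
anchored at the WHO RNI for 5% bioavailability (12.6 mg/d for 5–6 y,
17.8 mg/d for 7–9 y) — the RNI is defined to cover ~97.5% of
individuals, and the anchor uses the only quantity the guideline
states. The log-scale SD defaults to 0.25 (configurable); prevalence is
the mean over children of P(R > y), evaluated analytically and
cross-checked against a 10⁵-draw Monte-Carlo oracle in the tests. With
vanishing spread the method reduces to a cut-point at the anchor.

**AMDR.** %E = grams × Atwater factor (4/4/9 kcal/g) / energy × 100,
classified against inclusive bounds (protein 10–30, carbohydrate 45–65,
fat 25–35 %E). Children with zero energy are excluded with a warning.

**UL.** Vitamin A's UL applies to preformed retinol and folate's to
folic acid; the child-level preformed-retinol and folic-acid totals are
accumulated from the composition-table fractions during intake
aggregation. Other nutrients compare total intake to the UL.

**Comparisons.** Scenario effects are reported as absolute (percentage
point) and relative (% of baseline) reductions in prevalence, computed
on the scenario-eligible population only; relative reduction is
not-applicable (NaN) when baseline prevalence is 0. Means and SEs
(SD/√n, unweighted — no survey design is modeled) describe observed
single-day intakes; prevalences are computed after adjustment
(adjust-then-classify order throughout).

## 5. The synthetic survey generator

The generator emulates the statistical structure the estimators assume,
with known ground truth:

* usual intake per nutrient is **exactly log-normal** (default
  arithmetic means echo a low-income South-Asian school-age baseline:
  energy ≈ 1283 kcal/d, calcium 371 mg/d, iron 6.6 mg/d, …; default
  GSD 1.6), so closed-form CDF values are exact oracles for prevalence
  and SD-recovery tests;
* the observed day is usual × exp(N(−σ_w²/2, σ_w²)) with σ_w² = r σ_b²
  (default r = 0.73), mean-unbiased on the original scale;
* energy is the Atwater sum of the drawn macronutrients at both the
  usual and observed level, so %E quantities behave like real diets;
* dairy-rich nutrients are coupled to the child's dairy volume by a
  Gaussian copula (calcium ρ = 0.8 down to carbohydrate ρ = 0.2), which
  leaves marginals log-normal while making heavy milk-drinkers
  calcium-rich, as in real data;
* dairy items are Bernoulli(consumption) × gamma(grams) per subtype,
  scaled so the overall consumer fraction is exactly the specified
  p_dairy (default 0.895, with ~1.5% fortified-milk consumers);
* each child's dairy nutrients are carved out of the day's totals and
  the remainder is emitted as per-nutrient composite "residual diet"
  items, so item sums reproduce the day's totals exactly.

When a child's dairy draw would exceed the day's total for some nutrient
(most often vitamin D for fortified-milk consumers), dairy grams are
scaled down to keep residuals non-negative; the latent truth is
untouched but the upper tail of the dairy-gram distribution is thinner
than the consumption parameters alone imply (≈0.3% of children reach 2
servings/d under the defaults, versus a few percent in real surveys).

What the generator does **not** emulate: real food-item granularity (the
non-dairy diet is a set of single-nutrient composites), day-of-week or
seasonal effects, household clustering, survey weights, correlated
nutrient-to-nutrient structure beyond the shared dairy items, and
reporting error. Passing tests therefore establish that the estimators
are correct under the stated measurement model — not that the model
captures every feature of field data.

The hand-checkable toy fixture contains one child per addition tier, a
fortified-milk consumer, a dairy non-consumer, and an energy outlier
placed in a 12-member age stratum (the minimum size at which a 3-SD
outlier is arithmetically possible, see §1).

## 6. Reference data and compositions

Reference values (EARs, ULs, AMDRs, FAO moderate-activity EERs by age
and sex, WHO RNIs and conversion factors for iron/zinc) ship as a
versioned CSV and can be replaced wholesale. Derived zinc EARs
(RNI/1.2 → 8.0 and 9.3 mg/d) are stored and revalidated against the
derivation at load time. The vitamin A EAR at age 9 is sex-specific
(420 F / 445 M µg RAE).

Milk compositions (buffalo, cow, goat, fortified filled milk) are
typical literature values, explicitly **not** tied to any survey's
database, validated for Atwater consistency (±15%) at load, and meant to
be overridden with study-specific values. The fortified-milk defaults
carry the fortification profile that defines the product: iron
1.5 mg/100 g, vitamin C 9 mg, vitamin D 1 µg, folate as folic acid.

## 7. Problem sizes and runtime

The test suite runs synthetic populations of 150–20 000 children
(estimator-recovery checks at n = 5 000; the variance-ratio convergence
check at n = 20 000) and completes in well under a minute; the
acceptance script runs the full n = 5 842 pipeline plus a 10⁵-draw
Monte-Carlo cross-check in a few seconds. All randomness flows through
explicit seeds; identical spec + seed reproduces byte-identical tables.

## 8. Known limitations

* The external variance ratio is a modeling input, not estimable from
  one recall day; conclusions about prevalence inherit its uncertainty
  (hence the mandatory sweep).
* The iron requirement distribution's spread (log-SD 0.25) is a
  convention, anchored only at the RNI; different spreads move iron
  prevalence by a few points.
* Back-calculating EARs from RNIs via a single conversion factor is a
  guideline approximation.
* The substitution scenario assumes the composition table used for the
  recall matches the milk compositions used for the delta; feeding
  mismatched tables will silently bias deltas.
* No survey weights, clustering or measurement-error deconvolution
  beyond the shrinkage model.
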