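"""Synthetic 24-h recall survey generator with known ground truth.

The generator emulates the structure of a single-day school-age dietary
survey: one recall day per child (5-9 y), a food-composition table, and a
latent table of *usual* (long-run average) intakes that downstream
estimators try to recover.

Generative model
----------------
For child *i* and nutrient *n*:

* usual intake ``U[i, n]`` is log-normal with stated arithmetic mean and
  geometric SD (so the closed-form log-normal CDF is the exact truth for
  prevalence-of-inadequacy checks);
* the observed recall-day total is ``T = U * exp(W)`` with
  ``W ~ N(-sw^2/2, sw^2)`` and ``sw^2 = r * sb^2`` — ``r`` is the
  within:between variance ratio on the log scale and the noise is
  mean-unbiased on the original scale;
* dairy items (milk by kind, the milk component of tea, yogurt, ice
  cream, dairy desserts, milkshakes) are drawn from Bernoulli consumption
  indicators and gamma gram amounts, and their nutrients are carved out
  of the day's total; the remainder is emitted as per-nutrient composite
  "residual diet" items.  Item-level nutrient sums therefore reproduce
  the day total exactly;
* energy is the Atwater sum (4/4/9 kcal/g) of the drawn protein,
  carbohydrate and fat, at both the usual and the observed level, so
  percent-of-energy quantities behave like real diets;
* dairy-rich nutrients (calcium, phosphorus, riboflavin, protein, fat,
  ...) are coupled to the child's dairy volume through a Gaussian
  copula — heavier milk drinkers draw higher usual intakes — which
  leaves every marginal exactly log-normal.

When a child's dairy items would still exceed the day's total for some
nutrient (e.g. a fortified-milk consumer on a low vitamin-D day), the
dairy grams are scaled down so every residual stays non-negative; the
latent truth is untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, PositiveInt, model_validator
from scipy import stats

from .errors import InputValidationError
from .nutrients import ATWATER, DAIRY_TAGS, NUTRIENTS
from .reference_data import load_milks

__all__ = ["DairyPattern", "PopulationSpec", "generate_survey", "make_toy_fixture"]

#: Arithmetic means of usual intake per day used as generator defaults.
#: They echo the baseline intake levels of a rural/peri-urban South-Asian
#: school-age population (energy ~1280 kcal/d, calcium ~370 mg/d, ...).
DEFAULT_USUAL_MEAN: dict[str, float] = {
    "energy_kcal": 1283.0,
    "protein_g": 31.8,
    "carbohydrate_g": 181.0,
    "fat_g": 50.0,
    "sfa_g": 20.0,
    "mufa_g": 13.9,
    "pufa_g": 7.1,
    "calcium_mg": 371.0,
    "phosphorus_mg": 649.0,
    "iron_mg": 6.6,
    "zinc_mg": 4.8,
    "vitamin_a_ug_rae": 222.0,
    "vitamin_d_ug": 1.0,
    "vitamin_c_mg": 43.0,
    "thiamin_mg": 0.8,
    "riboflavin_mg": 0.98,
    "niacin_mg": 10.0,
    "vitamin_b6_mg": 1.0,
    "folate_ug_dfe": 137.0,
}

#: Mean body weight (kg) by age in years, with ~3 kg SD.
_WEIGHT_BY_AGE = {5: 17.4, 6: 19.7, 7: 21.8, 8: 24.0, 9: 26.9}

#: Preformed-retinol / folic-acid fractions of the non-dairy residual diet.
_RESIDUAL_RETINOL_FRACTION = 0.3
_RESIDUAL_FOLIC_FRACTION = 0.0

#: Gaussian-copula correlation between a child's dairy volume and their
#: usual intake of dairy-rich nutrients.  Marginals stay exactly
#: log-normal; the coupling reflects that heavy milk drinkers obtain
#: higher calcium/phosphorus/riboflavin intakes, and it keeps the dairy
#: carve-out from truncating large dairy portions.
DAIRY_COPULA_RHO: dict[str, float] = {
    "calcium_mg": 0.8,
    "phosphorus_mg": 0.7,
    "riboflavin_mg": 0.5,
    "protein_g": 0.4,
    "fat_g": 0.4,
    "sfa_g": 0.4,
    "vitamin_a_ug_rae": 0.3,
    "zinc_mg": 0.3,
    "vitamin_d_ug": 0.3,
    "carbohydrate_g": 0.2,
}


class DairyPattern(BaseModel):
    """Marginal consumption pattern for one dairy subtype."""

    p: float = Field(ge=0.0, le=1.0)  # marginal probability of consuming
    mean_g: float = Field(gt=0.0)     # mean grams among consumers
    shape: float = Field(gt=0.0)      # gamma shape (mean/SD ratio squared)


def _default_dairy() -> dict[str, DairyPattern]:
    # Marginal consumer fractions and among-consumer gram distributions
    # patterned on observed dairy consumption in Pakistani children
    # (buffalo milk dominant, ~1.5% fortified-milk consumers).
    return {
        "milk_buffalo": DairyPattern(p=0.58, mean_g=135.0, shape=1.27),
        "milk_cow": DairyPattern(p=0.226, mean_g=140.0, shape=1.68),
        "milk_goat": DairyPattern(p=0.029, mean_g=93.0, shape=5.7),
        "milk_fortified": DairyPattern(p=0.015, mean_g=206.0, shape=0.92),
        "tea_milk": DairyPattern(p=0.30, mean_g=60.0, shape=2.0),
        "yogurt": DairyPattern(p=0.169, mean_g=120.0, shape=1.5),
        "ice_cream": DairyPattern(p=0.037, mean_g=65.0, shape=2.0),
        "dairy_dessert": DairyPattern(p=0.02, mean_g=130.0, shape=1.5),
        "milkshake": DairyPattern(p=0.015, mean_g=220.0, shape=1.5),
    }


class PopulationSpec(BaseModel):
    """Parameters of the synthetic survey population."""

    n_children: PositiveInt = 5842
    age_probs: dict[int, float] = Field(
        default_factory=lambda: {a: 0.2 for a in range(5, 10)}
    )
    p_female: float = Field(default=0.5, ge=0.0, le=1.0)
    usual_mean: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_USUAL_MEAN))
    usual_gsd: float | dict[str, float] = 1.6
    variance_ratio: float = Field(default=0.73, ge=0.0)
    p_dairy: float = Field(default=0.895, ge=0.0, le=1.0)
    dairy: dict[str, DairyPattern] = Field(default_factory=_default_dairy)
    seed: int = 20240501

    @model_validator(mode="after")
    def _check(self) -> "PopulationSpec":
        if set(self.age_probs) - set(range(5, 10)):
            raise InputValidationError("age_probs keys must lie in 5..9")
        tot = sum(self.age_probs.values())
        if not np.isclose(tot, 1.0):
            self.age_probs = {a: p / tot for a, p in self.age_probs.items()}
        missing = [n for n in NUTRIENTS if n not in self.usual_mean]
        if missing:
            raise InputValidationError(f"usual_mean missing nutrients: {missing}")
        if any(v <= 0 for v in self.usual_mean.values()):
            raise InputValidationError("usual_mean values must be positive")
        bad = set(self.dairy) - set(DAIRY_TAGS)
        if bad:
            raise InputValidationError(f"unknown dairy tags: {sorted(bad)}")
        return self

    def gsd_of(self, nutrient: str) -> float:
        if isinstance(self.usual_gsd, dict):
            g = self.usual_gsd.get(nutrient, 1.6)
        else:
            g = self.usual_gsd
        if g < 1.0:
            raise InputValidationError("geometric SD must be >= 1")
        return float(g)


# --------------------------------------------------------------------------
# default dairy-food compositions for the synthetic composition table
# --------------------------------------------------------------------------

def _dairy_compositions() -> pd.DataFrame:
    """Per-100 g compositions for the dairy food codes the generator emits."""
    milks = load_milks()
    rows: dict[str, dict[str, float]] = {}

    def put(code: str, comp: dict[str, float], retinol: float, folic: float,
            tag: str) -> None:
        rows[code] = {**comp, "retinol_fraction": retinol,
                      "folic_acid_fraction": folic, "dairy_tag": tag}

    for tag, kind in [("milk_buffalo", "buffalo"), ("milk_cow", "cow"),
                      ("milk_goat", "goat"), ("milk_fortified", "fortified")]:
        m = milks[kind]
        put(tag.upper(), dict(m.per_100g), m.retinol_fraction,
            m.folic_acid_fraction, tag)
    # the milk component of tea-with-milk is buffalo milk
    b = milks["buffalo"]
    put("TEA_MILK", dict(b.per_100g), b.retinol_fraction,
        b.folic_acid_fraction, "tea_milk")
    # plain whole-milk yogurt tracks cow milk closely
    put("YOGURT", dict(milks["cow"].per_100g), 1.0, 0.0, "yogurt")
    put("ICE_CREAM", {
        "energy_kcal": 207.4, "protein_g": 3.5, "carbohydrate_g": 23.6,
        "fat_g": 11.0, "sfa_g": 6.8, "mufa_g": 3.0, "pufa_g": 0.5,
        "calcium_mg": 128.0, "phosphorus_mg": 105.0, "iron_mg": 0.09,
        "zinc_mg": 0.69, "vitamin_a_ug_rae": 118.0, "vitamin_d_ug": 0.2,
        "vitamin_c_mg": 0.6, "thiamin_mg": 0.041, "riboflavin_mg": 0.24,
        "niacin_mg": 0.116, "vitamin_b6_mg": 0.048, "folate_ug_dfe": 5.0,
    }, 1.0, 0.0, "ice_cream")
    put("DAIRY_DESSERT", {
        "energy_kcal": 120.0, "protein_g": 3.0, "carbohydrate_g": 18.0,
        "fat_g": 4.0, "sfa_g": 2.4, "mufa_g": 1.1, "pufa_g": 0.2,
        "calcium_mg": 100.0, "phosphorus_mg": 85.0, "iron_mg": 0.2,
        "zinc_mg": 0.4, "vitamin_a_ug_rae": 40.0, "vitamin_d_ug": 0.05,
        "vitamin_c_mg": 0.5, "thiamin_mg": 0.04, "riboflavin_mg": 0.15,
        "niacin_mg": 0.2, "vitamin_b6_mg": 0.04, "folate_ug_dfe": 5.0,
    }, 1.0, 0.0, "dairy_dessert")
    put("MILKSHAKE", {
        "energy_kcal": 95.5, "protein_g": 3.0, "carbohydrate_g": 13.0,
        "fat_g": 3.5, "sfa_g": 2.0, "mufa_g": 0.9, "pufa_g": 0.2,
        "calcium_mg": 105.0, "phosphorus_mg": 88.0, "iron_mg": 0.1,
        "zinc_mg": 0.35, "vitamin_a_ug_rae": 45.0, "vitamin_d_ug": 0.05,
        "vitamin_c_mg": 1.0, "thiamin_mg": 0.04, "riboflavin_mg": 0.16,
        "niacin_mg": 0.1, "vitamin_b6_mg": 0.04, "folate_ug_dfe": 5.0,
    }, 1.0, 0.0, "milkshake")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "food_code"
    return df.reset_index()


def _residual_compositions(spec: PopulationSpec) -> pd.DataFrame:
    """One composite 'residual diet' food per nutrient.

    Each row carries a single nutrient at a density of a quarter of the
    population-mean usual intake per 100 g, so typical residual portions
    land in a food-like 100-600 g range.  These composites stand in for
    the non-dairy diet; they are synthetic by construction.
    """
    rows = []
    for n in NUTRIENTS:
        if n == "energy_kcal":
            continue  # energy rides on the macronutrient residual items
        comp = {k: 0.0 for k in NUTRIENTS}
        comp[n] = spec.usual_mean[n] / 4.0
        if n in ATWATER:
            comp["energy_kcal"] = comp[n] * ATWATER[n]
        rows.append({
            "food_code": f"RES_{n.upper()}", **comp,
            "retinol_fraction": _RESIDUAL_RETINOL_FRACTION if n == "vitamin_a_ug_rae" else 0.0,
            "folic_acid_fraction": _RESIDUAL_FOLIC_FRACTION if n == "folate_ug_dfe" else 0.0,
            "dairy_tag": "",
        })
    return pd.DataFrame(rows)


def generate_survey(
    spec: PopulationSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one survey: ``(recall, foods, truth)`` tables.

    ``recall`` has one row per child x food item (child_id, age, sex,
    weight_kg, food_code, grams, dairy_tag); ``foods`` is the matching
    per-100 g composition table; ``truth`` holds each child's latent usual
    intake per nutrient.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_children
    nn = len(NUTRIENTS)

    ages_support = sorted(spec.age_probs)
    ages = rng.choice(ages_support, size=n,
                      p=[spec.age_probs[a] for a in ages_support])
    sexes = np.where(rng.random(n) < spec.p_female, "F", "M")
    weights = np.maximum(
        rng.normal([_WEIGHT_BY_AGE[a] for a in ages], 3.0), 10.0
    ).round(1)

    # dairy items first: their volume drives the copula below
    dairy_foods = _dairy_compositions()
    comp_mat = dairy_foods.set_index("dairy_tag")[list(NUTRIENTS)]
    tags = [t for t in DAIRY_TAGS if t in spec.dairy]
    is_dairy = rng.random(n) < spec.p_dairy
    grams = np.zeros((n, len(tags)))
    for j, tag in enumerate(tags):
        pat = spec.dairy[tag]
        p_cond = min(pat.p / spec.p_dairy, 1.0) if spec.p_dairy > 0 else 0.0
        has = is_dairy & (rng.random(n) < p_cond)
        g = rng.gamma(pat.shape, pat.mean_g / pat.shape, size=n)
        grams[:, j] = np.where(has, g, 0.0)
    # a dairy consumer with no subtype drawn gets buffalo milk
    if "milk_buffalo" in tags and spec.p_dairy > 0:
        jb = tags.index("milk_buffalo")
        none = is_dairy & (grams.sum(axis=1) == 0)
        pat = spec.dairy["milk_buffalo"]
        grams[none, jb] = rng.gamma(pat.shape, pat.mean_g / pat.shape,
                                    size=int(none.sum()))
    comp = comp_mat.loc[tags].to_numpy()      # (tags, nutrients)
    dairy_nutr = grams @ comp / 100.0

    # latent usual intakes: exactly log-normal per nutrient, coupled to
    # dairy volume via a Gaussian copula on the normal scores
    sb = np.array([np.log(spec.gsd_of(nu)) for nu in NUTRIENTS])
    mean = np.array([spec.usual_mean[nu] for nu in NUTRIENTS])
    mu = np.log(mean) - 0.5 * sb**2
    total_dairy = grams.sum(axis=1)
    ranks = pd.Series(total_dairy).rank(method="average").to_numpy()
    z_dairy = stats.norm.ppf((ranks - 0.5) / n)
    z = rng.normal(size=(n, nn))
    for k, nu in enumerate(NUTRIENTS):
        rho = DAIRY_COPULA_RHO.get(nu, 0.0)
        if rho:
            z[:, k] = rho * z_dairy + np.sqrt(1.0 - rho**2) * z[:, k]
    usual = np.exp(mu + sb * z)
    sw = np.sqrt(spec.variance_ratio) * sb
    day_noise = rng.normal(-0.5 * sw**2, sw, size=(n, nn))
    observed = usual * np.exp(day_noise)
    # energy is the Atwater sum of the macronutrients at both levels
    k_e = NUTRIENTS.index("energy_kcal")
    for arr in (usual, observed):
        arr[:, k_e] = sum(
            ATWATER[m] * arr[:, NUTRIENTS.index(m)] for m in ATWATER)

    # carve dairy out of the day's totals; scale dairy down where it
    # would exceed the total for any nutrient
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dairy_nutr > 0, observed / dairy_nutr, np.inf)
    scale = np.clip(0.999 * ratio.min(axis=1), None, 1.0)
    grams *= scale[:, None]
    dairy_nutr *= scale[:, None]
    residual = np.clip(observed - dairy_nutr, 0.0, None)

    child_ids = np.array([f"C{i:05d}" for i in range(1, n + 1)])
    res_density = mean / 4.0
    rows_child, rows_code, rows_grams, rows_tag = [], [], [], []
    tag_codes = dairy_foods.set_index("dairy_tag")["food_code"]
    for j, tag in enumerate(tags):
        sel = grams[:, j] > 0
        rows_child.append(np.flatnonzero(sel))
        rows_code.append(np.full(int(sel.sum()), tag_codes[tag]))
        rows_grams.append(grams[sel, j])
        rows_tag.append(np.full(int(sel.sum()), tag))
    for k, nu in enumerate(NUTRIENTS):
        if nu == "energy_kcal":
            continue  # carried by the macronutrient residual items
        sel = residual[:, k] > 0
        rows_child.append(np.flatnonzero(sel))
        rows_code.append(np.full(int(sel.sum()), f"RES_{nu.upper()}"))
        rows_grams.append(residual[sel, k] / res_density[k] * 100.0)
        rows_tag.append(np.full(int(sel.sum()), ""))
    idx = np.concatenate(rows_child)
    recall = pd.DataFrame({
        "child_id": child_ids[idx],
        "age": ages[idx],
        "sex": sexes[idx],
        "weight_kg": weights[idx],
        "food_code": np.concatenate(rows_code),
        "grams": np.concatenate(rows_grams),
        "dairy_tag": np.concatenate(rows_tag),
    }).sort_values(["child_id", "food_code"], kind="stable").reset_index(drop=True)

    foods = pd.concat([dairy_foods, _residual_compositions(spec)],
                      ignore_index=True)
    truth = pd.DataFrame(usual, columns=list(NUTRIENTS))
    truth.insert(0, "child_id", child_ids)
    truth.insert(1, "age", ages)
    truth.insert(2, "sex", sexes)
    truth.insert(3, "weight_kg", weights)
    return recall, foods, truth


def make_toy_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic hand-checkable fixture: ``(recall, foods)``.

    Contains one child per milk-addition tier (<0.5, 0.5-0.9, 1-1.4,
    1.5-1.9 and >=2 servings/d), a fortified-milk consumer, a dairy
    non-consumer, and one energy outlier.  The outlier sits in a
    12-member age stratum: in a stratum of size n no point can exceed
    (n-1)/sqrt(n) sample SDs from the stratum mean, so strata of ten or
    fewer children can never trip a 3-SD rule.
    """
    foods = pd.concat(
        [_dairy_compositions(),
         pd.DataFrame([
             {"food_code": "ROTI", "energy_kcal": 264.0, "protein_g": 8.9,
              "carbohydrate_g": 55.8, "fat_g": 1.2, "sfa_g": 0.3,
              "mufa_g": 0.2, "pufa_g": 0.5, "calcium_mg": 25.0,
              "phosphorus_mg": 120.0, "iron_mg": 2.5, "zinc_mg": 1.5,
              "vitamin_a_ug_rae": 0.0, "vitamin_d_ug": 0.0,
              "vitamin_c_mg": 0.0, "thiamin_mg": 0.3, "riboflavin_mg": 0.1,
              "niacin_mg": 4.0, "vitamin_b6_mg": 0.2, "folate_ug_dfe": 30.0,
              "retinol_fraction": 0.0, "folic_acid_fraction": 0.0,
              "dairy_tag": ""},
             {"food_code": "DAL", "energy_kcal": 116.0, "protein_g": 7.0,
              "carbohydrate_g": 20.0, "fat_g": 0.4, "sfa_g": 0.1,
              "mufa_g": 0.1, "pufa_g": 0.2, "calcium_mg": 27.0,
              "phosphorus_mg": 100.0, "iron_mg": 2.1, "zinc_mg": 1.0,
              "vitamin_a_ug_rae": 1.0, "vitamin_d_ug": 0.0,
              "vitamin_c_mg": 1.0, "thiamin_mg": 0.2, "riboflavin_mg": 0.1,
              "niacin_mg": 1.0, "vitamin_b6_mg": 0.2, "folate_ug_dfe": 90.0,
              "retinol_fraction": 0.0, "folic_acid_fraction": 0.0,
              "dairy_tag": ""},
         ])],
        ignore_index=True,
    )

    def rows(cid, age, sex, wt, items):
        return [{"child_id": cid, "age": age, "sex": sex, "weight_kg": wt,
                 "food_code": code, "grams": g,
                 "dairy_tag": foods.set_index("food_code")["dairy_tag"][code]}
                for code, g in items]

    recall_rows = []
    # one child per addition tier (servings = dairy grams / 250)
    recall_rows += rows("T01", 5, "M", 17.5,
                        [("MILK_BUFFALO", 100.0), ("ROTI", 300.0)])   # 0.4
    recall_rows += rows("T02", 5, "F", 17.0,
                        [("MILK_COW", 150.0), ("ROTI", 280.0)])       # 0.6
    recall_rows += rows("T03", 6, "M", 20.0,
                        [("MILK_BUFFALO", 300.0), ("DAL", 200.0)])    # 1.2
    recall_rows += rows("T04", 6, "F", 19.5,
                        [("MILK_COW", 250.0), ("YOGURT", 150.0),
                         ("ROTI", 250.0)])                            # 1.6
    recall_rows += rows("T05", 7, "M", 22.0,
                        [("MILK_BUFFALO", 400.0), ("TEA_MILK", 150.0),
                         ("ROTI", 200.0)])                            # 2.2
    # fortified-milk consumer and dairy non-consumer
    recall_rows += rows("T06", 7, "F", 21.5,
                        [("MILK_FORTIFIED", 200.0), ("ROTI", 250.0)])
    recall_rows += rows("T07", 8, "M", 24.0,
                        [("ROTI", 350.0), ("DAL", 250.0)])
    # 12-member age-9 stratum hosting the single energy outlier
    base = [1150.0, 1170.0, 1185.0, 1195.0, 1200.0, 1205.0,
            1210.0, 1220.0, 1235.0, 1250.0, 1260.0]
    for k, kcal in enumerate(base, start=8):
        recall_rows += rows(f"T{k:02d}", 9, "M" if k % 2 else "F", 27.0,
                            [("ROTI", round(kcal / 2.64, 2))])
    recall_rows += rows("T19", 9, "M", 27.0, [("ROTI", round(8000.0 / 2.64, 2))])
    recall = pd.DataFrame(recall_rows)
    return recall, foods
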