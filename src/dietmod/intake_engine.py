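"""From recall items to per-child daily intakes, dairy servings and flags.

The central container is the *ChildDay* table: one row per child with the
summed nutrient vector, dairy grams by subtype, dairy servings (250 g = 1
serving), consumer flags and the energy-outlier flag.  Servings are kept
at full precision internally; one-decimal rounding is a reporting
concern only, because the addition-scenario tiers are defined on exact
servings.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputValidationError, UnknownFoodError
from .nutrients import DAIRY_TAGS, MILK_TAGS, NUTRIENTS
from .reference_data import ServingRule

__all__ = [
    "classify_dairy_adherence",
    "compute_intakes",
    "flag_energy_outliers",
    "grams_to_servings",
]

log = logging.getLogger(__name__)

RECALL_COLUMNS = ("child_id", "age", "sex", "weight_kg", "food_code",
                  "grams", "dairy_tag")

#: ChildDay columns holding dairy grams per subtype.
DAIRY_GRAM_COLUMNS = tuple(f"g_{t}" for t in DAIRY_TAGS)


def compute_intakes(
    recall: pd.DataFrame,
    foods: pd.DataFrame,
    children: pd.DataFrame | None = None,
    serving_rule: ServingRule | None = None,
) -> pd.DataFrame:
    """Sum item-level nutrients to one ChildDay row per child.

    Parameters
    ----------
    recall
        One row per consumed item; columns ``child_id, age, sex,
        weight_kg, food_code, grams, dairy_tag``.
    foods
        Per-100 g composition, one row per ``food_code`` with all
        nutrient columns plus ``retinol_fraction`` and
        ``folic_acid_fraction``.
    children
        Optional roster (``child_id, age, sex, weight_kg``); children
        with no recall rows get zero vectors and non-consumer flags.

    Returns
    -------
    DataFrame with one row per child: nutrient totals, preformed-retinol
    and folic-acid totals, ``g_<subtype>`` dairy grams, ``dairy_g``,
    ``dairy_servings`` and consumer flags.
    """
    serving_rule = serving_rule or ServingRule()
    if (recall["grams"] < 0).any():
        bad = recall.loc[recall["grams"] < 0, "child_id"].unique()
        raise InputValidationError(f"negative gram amounts for children: {list(bad)[:5]}")
    unknown = set(recall["food_code"]) - set(foods["food_code"])
    if unknown:
        raise UnknownFoodError(
            f"recall references food codes absent from the composition table: "
            f"{sorted(unknown)}"
        )

    merged = recall.merge(foods, on="food_code", how="left",
                          suffixes=("", "_comp"))
    factor = merged["grams"].to_numpy() / 100.0
    for n in NUTRIENTS:
        merged[n] = factor * merged[n].to_numpy()
    merged["preformed_retinol_ug"] = (
        merged["vitamin_a_ug_rae"] * merged["retinol_fraction"].to_numpy()
    )
    merged["folic_acid_ug"] = (
        merged["folate_ug_dfe"] * merged["folic_acid_fraction"].to_numpy()
    )
    tag = merged["dairy_tag"].fillna("")
    for t in DAIRY_TAGS:
        merged[f"g_{t}"] = np.where(tag == t, merged["grams"], 0.0)

    value_cols = (list(NUTRIENTS) + ["preformed_retinol_ug", "folic_acid_ug"]
                  + list(DAIRY_GRAM_COLUMNS))
    totals = merged.groupby("child_id", sort=True)[value_cols].sum()
    meta = recall.drop_duplicates("child_id").set_index("child_id")[
        ["age", "sex", "weight_kg"]]
    childday = meta.join(totals)

    if children is not None:
        roster = children.drop_duplicates("child_id").set_index("child_id")[
            ["age", "sex", "weight_kg"]]
        childday = roster.join(totals)
        childday[value_cols] = childday[value_cols].fillna(0.0)

    childday["dairy_g"] = childday[list(DAIRY_GRAM_COLUMNS)].sum(axis=1)
    childday["dairy_servings"] = grams_to_servings(
        childday["dairy_g"], serving_rule)
    milk_g = childday[[f"g_{t}" for t in MILK_TAGS]].sum(axis=1)
    childday["dairy_consumer"] = childday["dairy_g"] > 0
    childday["milk_consumer"] = milk_g > 0
    childday["fortified_consumer"] = childday["g_milk_fortified"] > 0
    childday["energy_outlier"] = False
    return childday.reset_index()


def grams_to_servings(
    dairy_grams: float | pd.Series | np.ndarray,
    serving_rule: ServingRule | None = None,
):
    """Convert dairy grams/day to servings/day (250 g = 1 serving).

    Full precision is preserved; round to one decimal only for display.
    """
    serving_rule = serving_rule or ServingRule()
    arr = np.asarray(dairy_grams, dtype=float)
    if (arr < 0).any():
        raise InputValidationError("dairy grams must be non-negative")
    out = arr / serving_rule.grams_per_serving
    if isinstance(dairy_grams, pd.Series):
        return pd.Series(out, index=dairy_grams.index, name="dairy_servings")
    return float(out) if np.isscalar(dairy_grams) else out


def flag_energy_outliers(
    childday: pd.DataFrame, n_sd: float = 3.0
) -> tuple[pd.DataFrame, int]:
    """Flag implausible energy intakes per 1-y age stratum, single pass.

    A child is flagged iff its energy lies more than ``n_sd`` sample
    standard deviations from its stratum's mean, with mean and SD
    computed once over the full stratum (not re-estimated after
    exclusions).  Strata with fewer than two children cannot be screened
    and are left unflagged with a warning.

    Returns the table with the ``energy_outlier`` column set, and the
    number flagged.  Downstream analyses should drop flagged rows.
    """
    out = childday.copy()
    flags = pd.Series(False, index=out.index)
    for age, grp in out.groupby("age"):
        if len(grp) < 2:
            log.warning("age stratum %s has <2 children; outlier screen skipped", age)
            continue
        mean, sd = grp["energy_kcal"].mean(), grp["energy_kcal"].std(ddof=1)
        if sd == 0:
            continue
        flags.loc[grp.index] = (grp["energy_kcal"] - mean).abs() > n_sd * sd
    out["energy_outlier"] = flags
    return out, int(flags.sum())


def classify_dairy_adherence(servings):
    """Categorise servings/d: ``none``, ``<1``, ``1-1.9`` or ``>=2``.

    Meeting the dairy recommendation means >= 2 servings/d (boundary
    inclusive); non-consumers and anyone below 2 servings do not meet it.
    """
    arr = np.asarray(servings, dtype=float)
    if (arr < 0).any():
        raise InputValidationError("servings must be non-negative")
    cat = np.select(
        [arr == 0, arr < 1.0, arr < 2.0],
        ["none", "<1", "1-1.9"],
        default=">=2",
    )
    if isinstance(servings, pd.Series):
        return pd.Series(cat, index=servings.index, name="dairy_category")
    return str(cat) if np.isscalar(servings) else cat


def meets_recommendation(servings) -> bool | np.ndarray | pd.Series:
    """True iff servings/d >= 2 (the guideline's lower bound)."""
    arr = np.asarray(servings, dtype=float)
    out = arr >= 2.0
    if isinstance(servings, pd.Series):
        return pd.Series(out, index=servings.index)
    return bool(out) if np.isscalar(servings) else out
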