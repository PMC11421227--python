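"""Counterfactual milk interventions on ChildDay records.

Two interventions are modelled, with no compensation elsewhere in the
diet (a deliberate best-case assumption):

* **substitution** — every gram of currently consumed non-fortified milk
  (buffalo, cow, goat, and the milk in tea) is replaced volume-by-volume
  with fortified milk, among milk consumers who do not already consume
  fortified milk;
* **addition** — children below 2 dairy servings/d are topped up with
  buffalo or fortified milk following a tiered rule that brings everyone
  to at least 2 servings/d, optionally capped at 1 added serving/d.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import CompositionError, InputValidationError
from .nutrients import MILK_KIND_OF_TAG, MILK_TAGS, NUTRIENTS
from .reference_data import MilkComposition, ServingRule
from .intake_engine import grams_to_servings

__all__ = [
    "ScenarioSpec",
    "apply_addition",
    "apply_scenario",
    "select_eligible",
    "substitute_milk",
    "tier_addition",
]

#: Tiered top-up (servings added) on half-open current-serving bands.
#: Bands are the exact-serving reading of one-decimal display bands
#: (e.g. "0.5-0.9" means [0.5, 1.0)), which guarantees every treated
#: child reaches >= 2 servings/d under the uncapped rule.
_TIER_EDGES = (0.0, 0.5, 1.0, 1.5, 2.0)
_TIER_ADD = (2.0, 1.5, 1.0, 0.5, 0.0)


class ScenarioSpec(BaseModel):
    """Declarative description of one intervention."""

    kind: Literal["substitution", "addition"]
    milk: str = "fortified"
    target_servings: float = Field(default=2.0, gt=0)
    cap_servings: float = Field(default=2.0, gt=0)
    name: str = ""

    def model_post_init(self, __context) -> None:
        if not self.name:
            cap = "" if self.cap_servings >= 2.0 else f"_cap{self.cap_servings:g}"
            self.name = (f"{self.kind}_{self.milk}{cap}"
                         if self.kind == "addition" else self.kind)


def select_eligible(childday: pd.DataFrame, spec: ScenarioSpec) -> pd.Series:
    """Boolean eligibility mask for the scenario.

    Substitution: current milk consumers, excluding children already
    consuming fortified milk.  Addition: everyone below 2 dairy
    servings/d, including dairy non-consumers.
    """
    if spec.kind == "substitution":
        return childday["milk_consumer"] & ~childday["fortified_consumer"]
    return childday["dairy_servings"] < spec.target_servings


def _require(milks: dict[str, MilkComposition], kind: str) -> MilkComposition:
    if kind not in milks:
        raise CompositionError(f"no composition available for milk kind '{kind}'")
    return milks[kind]


def substitute_milk(
    childday: pd.DataFrame,
    milks: dict[str, MilkComposition],
    tag_kind: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Replace all non-fortified milk grams with fortified milk.

    Volume is preserved: each subtype's grams move to the fortified
    column unchanged, and the nutrient totals shift by
    ``grams/100 x (fortified - original)`` per-100 g composition.
    Non-milk dairy (yogurt, ice cream, desserts, milkshakes) and the
    rest of the diet are untouched.  Apply only to eligible rows.
    """
    tag_kind = tag_kind or MILK_KIND_OF_TAG
    out = childday.copy()
    fort = _require(milks, "fortified")
    fvec = fort.vector().to_numpy()
    for t in MILK_TAGS:
        if t == "milk_fortified":
            continue
        g = out[f"g_{t}"].to_numpy(dtype=float)
        if not (g > 0).any():
            continue
        m = _require(milks, tag_kind[t])
        delta = np.outer(g / 100.0, fvec - m.vector().to_numpy())
        out[list(NUTRIENTS)] = out[list(NUTRIENTS)].to_numpy() + delta
        out["preformed_retinol_ug"] += g / 100.0 * (
            fort.per_100g["vitamin_a_ug_rae"] * fort.retinol_fraction
            - m.per_100g["vitamin_a_ug_rae"] * m.retinol_fraction)
        out["folic_acid_ug"] += g / 100.0 * (
            fort.per_100g["folate_ug_dfe"] * fort.folic_acid_fraction
            - m.per_100g["folate_ug_dfe"] * m.folic_acid_fraction)
        out["g_milk_fortified"] += g
        out[f"g_{t}"] = 0.0
    out["fortified_consumer"] = out["g_milk_fortified"] > 0
    out["milk_consumer"] = out[[f"g_{t}" for t in MILK_TAGS]].sum(axis=1) > 0
    return out


def tier_addition(current_servings, cap: float = 2.0):
    """Servings of milk to add given current dairy servings/d.

    Piecewise on half-open bands of exact servings: [0, 0.5) -> 2.0,
    [0.5, 1.0) -> 1.5, [1.0, 1.5) -> 1.0, [1.5, 2.0) -> 0.5, and 0 at or
    above 2 servings/d; the result is then clipped to ``cap`` (the
    restricted variant uses cap = 1 added serving/d).
    """
    arr = np.asarray(current_servings, dtype=float)
    if (arr < 0).any():
        raise InputValidationError("servings must be non-negative")
    if cap <= 0:
        raise InputValidationError("cap must be positive")
    added = np.select(
        [arr < e for e in _TIER_EDGES[1:]], _TIER_ADD[:-1], default=0.0
    )
    added = np.minimum(added, cap)
    if isinstance(current_servings, pd.Series):
        return pd.Series(added, index=current_servings.index)
    return float(added) if np.isscalar(current_servings) else added


def apply_addition(
    childday: pd.DataFrame,
    milks: dict[str, MilkComposition],
    spec: ScenarioSpec,
    serving_rule: ServingRule | None = None,
) -> pd.DataFrame:
    """Top up each row's dairy with ``spec.milk`` per the tier rule.

    Added grams = tier(servings, cap) x 250; nutrient totals, subtype
    grams, servings and flags are updated.  Rows at or above the target
    are unchanged.  Apply only to eligible rows (callers typically pass
    the eligible subset; ineligible rows are a no-op anyway).
    """
    serving_rule = serving_rule or ServingRule()
    milk = _require(milks, spec.milk)
    out = childday.copy()
    added_serv = tier_addition(out["dairy_servings"], cap=spec.cap_servings)
    added_g = added_serv * serving_rule.grams_per_serving
    delta = np.outer(added_g.to_numpy() / 100.0, milk.vector().to_numpy())
    out[list(NUTRIENTS)] = out[list(NUTRIENTS)].to_numpy() + delta
    out["preformed_retinol_ug"] += (added_g / 100.0) * (
        milk.per_100g["vitamin_a_ug_rae"] * milk.retinol_fraction)
    out["folic_acid_ug"] += (added_g / 100.0) * (
        milk.per_100g["folate_ug_dfe"] * milk.folic_acid_fraction)
    col = f"g_milk_{spec.milk}"
    if col not in out.columns:
        raise CompositionError(f"unknown milk kind '{spec.milk}'")
    out[col] += added_g
    out["dairy_g"] += added_g
    out["dairy_servings"] = grams_to_servings(out["dairy_g"], serving_rule)
    out["dairy_consumer"] = out["dairy_g"] > 0
    out["milk_consumer"] = out[[f"g_{t}" for t in MILK_TAGS]].sum(axis=1) > 0
    out["fortified_consumer"] = out["g_milk_fortified"] > 0
    return out


def apply_scenario(
    childday: pd.DataFrame,
    spec: ScenarioSpec,
    milks: dict[str, MilkComposition],
    serving_rule: ServingRule | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Run one scenario end-to-end on a ChildDay table.

    Returns ``(modified eligible subset, eligibility mask)``: the
    scenario population is the eligible children only, matching how
    before/after comparisons are reported.
    """
    mask = select_eligible(childday, spec)
    subset = childday.loc[mask]
    if spec.kind == "substitution":
        return substitute_milk(subset, milks), mask
    return apply_addition(subset, milks, spec, serving_rule), mask
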