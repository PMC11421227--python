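"""Population nutrient-adequacy estimators.

Implements the EAR cut-point method (fraction of usual intakes below the
estimated average requirement), the full probability method for iron
(average probability that a randomly drawn requirement exceeds the
child's usual intake — appropriate when requirements are right-skewed,
as absorbed-iron requirements are in growing children), AMDR percent-of-
energy classification for macronutrients, and UL exceedance with the
preformed-retinol (vitamin A) and folic-acid (folate) conventions.
Prevalences are computed on usual (variance-adjusted) intakes: adjust
first, then classify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .errors import (InputValidationError, InvalidReferenceError,
                     ReferenceLookupError)
from .nutrients import AMDR_MACROS, ATWATER, NUTRIENTS
from .reference_data import load_references, lookup_reference
from .usual_intake import UsualIntakeConfig, shrink_to_usual

__all__ = [
    "RequirementDistribution",
    "amdr_classify",
    "compare_scenarios",
    "ear_cutpoint_prevalence",
    "full_probability_prevalence",
    "per_child_reference",
    "summarize_adequacy",
    "ul_exceedance",
]

_Z975 = float(stats.norm.ppf(0.975))


class RequirementDistribution(BaseModel):
    """Individual-requirement distribution for the full probability method.

    Log-normal, anchored so that its 97.5th percentile equals the WHO
    RNI for the child's age band (the RNI is defined to cover ~97.5% of
    individual requirements).  ``log_sd`` controls the spread on the log
    scale; 0.25 is a conventional right-skewed choice for absorbed-iron
    requirements and is configurable.
    """

    nutrient: str = "iron_mg"
    log_sd: float = Field(default=0.25, gt=0.0)

    def mu(self, rni) -> np.ndarray:
        """Log-scale location such that P(R <= rni) = 0.975."""
        rni = np.asarray(rni, dtype=float)
        if (rni <= 0).any():
            raise InvalidReferenceError("RNI anchor must be positive")
        return np.log(rni) - _Z975 * self.log_sd

    def prob_requirement_exceeds(self, intake, rni) -> np.ndarray:
        """P(R > intake) per child; an intake of 0 is inadequate w.p. 1."""
        y = np.asarray(intake, dtype=float)
        mu = self.mu(rni)
        out = np.ones_like(y, dtype=float)
        pos = y > 0
        out[pos] = stats.norm.sf((np.log(y[pos]) - np.broadcast_to(mu, y.shape)[pos])
                                 / self.log_sd)
        return out


def per_child_reference(
    childday: pd.DataFrame,
    nutrient: str,
    field: str,
    refs: pd.DataFrame | None = None,
) -> pd.Series:
    """Age-band/sex-resolved reference value (``ear``, ``ul``, ``rni``...)
    aligned to the ChildDay rows.  Protein's per-kg EAR is multiplied by
    body weight.  Missing references yield NaN.
    """
    if refs is None:
        refs = load_references()
    out = pd.Series(np.nan, index=childday.index, dtype=float)
    basis = pd.Series("", index=childday.index)
    for (age, sex), grp in childday.groupby([childday["age"].astype(int),
                                             "sex"]):
        try:
            rec = lookup_reference(nutrient, float(age), str(sex), refs)
        except ReferenceLookupError:
            continue  # nutrient without a reference entry -> NaN
        out.loc[grp.index] = rec[field]
        basis.loc[grp.index] = rec.get("ear_basis", "") or ""
    if field == "ear" and (basis == "per_kg").any():
        per_kg = basis == "per_kg"
        out.loc[per_kg] = out.loc[per_kg] * childday.loc[per_kg, "weight_kg"]
    return out


def ear_cutpoint_prevalence(intakes, ear) -> float:
    """Percent of usual intakes below the EAR (scalar or per-child)."""
    y = np.asarray(intakes, dtype=float)
    e = np.asarray(ear, dtype=float)
    if y.size == 0:
        raise InputValidationError("no intakes supplied")
    if np.isnan(e).any() or (e <= 0).any():
        raise InvalidReferenceError("EAR must be positive and defined")
    return float(100.0 * np.mean(y < e))


def full_probability_prevalence(
    intakes, rni, dist: RequirementDistribution | None = None
) -> float:
    """Percent inadequate as the mean per-child probability that the
    requirement exceeds usual intake."""
    dist = dist or RequirementDistribution()
    p = dist.prob_requirement_exceeds(np.asarray(intakes, dtype=float),
                                      np.asarray(rni, dtype=float))
    return float(100.0 * p.mean())


def amdr_classify(
    grams, energy_kcal, lo: float, hi: float, macro: str
) -> tuple[pd.Series, dict[str, float]]:
    """Classify each child's macronutrient %E against inclusive AMDR bounds.

    Returns the per-child category series (``below``/``within``/``above``;
    children with zero energy are excluded as NaN) and the population
    percentages over classifiable children.
    """
    if macro not in ATWATER:
        raise InputValidationError(f"no Atwater factor for '{macro}'")
    g = pd.Series(np.asarray(grams, dtype=float))
    e = pd.Series(np.asarray(energy_kcal, dtype=float))
    ok = e > 0
    pct_e = pd.Series(np.nan, index=g.index)
    pct_e[ok] = g[ok] * ATWATER[macro] / e[ok] * 100.0
    cat = pd.Series(np.nan, index=g.index, dtype=object)
    cat[ok & (pct_e < lo)] = "below"
    cat[ok & (pct_e >= lo) & (pct_e <= hi)] = "within"
    cat[ok & (pct_e > hi)] = "above"
    n = int(ok.sum())
    if n == 0:
        raise InputValidationError("no children with positive energy intake")
    pcts = {k: float(100.0 * (cat == k).sum() / n)
            for k in ("below", "within", "above")}
    return cat, pcts


def ul_exceedance(intakes, ul, fraction=None) -> float:
    """Percent of children above the tolerable upper intake level.

    ``fraction`` converts total intake to the UL-relevant form (the
    preformed-retinol share for vitamin A, the folic-acid share for
    folate); pass precomputed amounts with ``fraction=None``.
    """
    y = np.asarray(intakes, dtype=float)
    u = np.asarray(ul, dtype=float)
    if np.isnan(u).any() or (u <= 0).any():
        raise InvalidReferenceError("UL must be positive and defined")
    if fraction is not None:
        y = y * np.asarray(fraction, dtype=float)
    return float(100.0 * np.mean(y > u))


def compare_scenarios(
    baseline: pd.DataFrame, scenario: pd.DataFrame
) -> pd.DataFrame:
    """Absolute (pp) and relative (%) reduction in inadequacy per nutrient.

    Both inputs are adequacy summaries indexed by nutrient with a
    ``pct_below`` column over the same population.  Relative reduction is
    100 x (p0 - p1) / p0, not applicable (NaN) where p0 = 0.
    """
    b = baseline.set_index("nutrient") if "nutrient" in baseline.columns else baseline
    s = scenario.set_index("nutrient") if "nutrient" in scenario.columns else scenario
    if set(b.index) != set(s.index):
        raise InputValidationError("baseline and scenario nutrient sets differ")
    if "n" in b.columns and "n" in s.columns and not (b["n"] == s["n"]).all():
        raise InputValidationError("baseline and scenario populations differ")
    p0 = b["pct_below"].astype(float)
    p1 = s["pct_below"].reindex(b.index).astype(float)
    out = pd.DataFrame({
        "baseline_pct": p0,
        "scenario_pct": p1,
        "absolute_reduction_pp": p0 - p1,
        "relative_reduction_pct": np.where(p0 > 0, 100.0 * (p0 - p1) / p0, np.nan),
    })
    out.index.name = "nutrient"
    return out


def _adjusted(childday: pd.DataFrame, config: UsualIntakeConfig | None,
              nutrient_cols: list[str]) -> pd.DataFrame:
    if config is None:
        return childday
    out = childday.copy()
    for n in nutrient_cols:
        out[n] = shrink_to_usual(childday[n], config, nutrient=n)
    return out


def summarize_adequacy(
    childday: pd.DataFrame,
    refs: pd.DataFrame | None = None,
    usual_config: UsualIntakeConfig | None = None,
    req_dist: RequirementDistribution | None = None,
    label: str = "baseline",
) -> pd.DataFrame:
    """Per-nutrient adequacy summary for one population.

    One ``amount`` row per nutrient (mean, SE of the mean on observed
    intakes, % below EAR — full probability method for iron — and %
    above UL where defined) plus a ``pct_energy`` row per AMDR
    macronutrient (% below/within/above the range).  When a usual-intake
    config is given, prevalences are computed on adjusted intakes while
    means/SEs describe the observed day.
    """
    if refs is None:
        refs = load_references()
    req_dist = req_dist or RequirementDistribution()
    cols = list(NUTRIENTS) + ["preformed_retinol_ug", "folic_acid_ug"]
    adj = _adjusted(childday, usual_config, cols)
    n = len(childday)
    rows = []
    for nutrient in NUTRIENTS:
        obs = childday[nutrient]
        rec = {"nutrient": nutrient, "basis": "amount", "population": label,
               "n": n, "mean": obs.mean(),
               "se": obs.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
               "pct_below": np.nan, "pct_above": np.nan, "method": ""}
        if nutrient == "energy_kcal":
            rows.append(rec)
            continue
        if nutrient == "iron_mg":
            rni = per_child_reference(childday, nutrient, "rni", refs)
            rec["pct_below"] = full_probability_prevalence(
                adj[nutrient], rni, req_dist)
            rec["method"] = "full_probability"
        else:
            ear = per_child_reference(childday, nutrient, "ear", refs)
            if ear.notna().all():
                rec["pct_below"] = ear_cutpoint_prevalence(adj[nutrient], ear)
                rec["method"] = "ear_cutpoint"
        ul = per_child_reference(childday, nutrient, "ul", refs)
        if ul.notna().all():
            if nutrient == "vitamin_a_ug_rae":
                rec["pct_above"] = ul_exceedance(adj["preformed_retinol_ug"], ul)
            elif nutrient == "folate_ug_dfe":
                rec["pct_above"] = ul_exceedance(adj["folic_acid_ug"], ul)
            else:
                rec["pct_above"] = ul_exceedance(adj[nutrient], ul)
        rows.append(rec)
    for macro in AMDR_MACROS:
        lo = per_child_reference(childday, macro, "amdr_lo", refs).iloc[0]
        hi = per_child_reference(childday, macro, "amdr_hi", refs).iloc[0]
        _, pcts = amdr_classify(adj[macro].to_numpy(),
                                adj["energy_kcal"].to_numpy(),
                                float(lo), float(hi), macro)
        ok = adj["energy_kcal"] > 0
        pct_e = adj.loc[ok, macro] * ATWATER[macro] / adj.loc[ok, "energy_kcal"] * 100.0
        rows.append({
            "nutrient": macro, "basis": "pct_energy", "population": label,
            "n": n, "mean": pct_e.mean(),
            "se": pct_e.std(ddof=1) / np.sqrt(len(pct_e)) if len(pct_e) > 1 else np.nan,
            "pct_below": pcts["below"], "pct_above": pcts["above"],
            "method": "amdr",
        })
    return pd.DataFrame(rows)
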