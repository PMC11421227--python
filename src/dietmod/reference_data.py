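"""Dietary reference values, serving definitions and milk compositions.

The packaged ``data/references.csv`` carries, per nutrient x age band x sex:
the EAR (estimated average requirement), UL (tolerable upper intake level),
AMDR bounds (% of energy, macronutrients only), FAO moderate-activity EER
(energy only, by single year of age and sex) and, for iron and zinc, the
WHO RNI assuming low bioavailability (5% for iron) together with the
WHO/FAO fortification-guideline conversion factor used to derive an EAR
from the RNI.

Age bands follow the survey convention: 5-8 y vs 9 y for every nutrient
except iron and zinc, whose WHO references split at 5-6 y vs 7-9 y.
Vitamin A's age-9 EAR is sex-specific (420 ug RAE F / 445 M).

Users may substitute their own reference CSV or milk-composition YAML; the
packaged milk values are typical literature values, not tied to any single
survey database (see ``data/milks.yaml``).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import CompositionError, InvalidReferenceError, ReferenceLookupError
from .nutrients import ATWATER, NUTRIENTS

__all__ = [
    "MilkComposition",
    "ServingRule",
    "ear_from_rni",
    "load_milks",
    "load_references",
    "lookup_reference",
]

AGE_RANGE = (5, 9)


class ServingRule(BaseModel):
    """Dairy serving definition from the Pakistani dietary guidelines."""

    grams_per_serving: float = Field(default=250.0, gt=0)
    recommended_lo: float = 2.0
    recommended_hi: float = 3.0

    @model_validator(mode="after")
    def _ordered(self) -> "ServingRule":
        if self.recommended_lo > self.recommended_hi:
            raise InvalidReferenceError(
                "recommended servings lower bound exceeds upper bound"
            )
        return self


class MilkComposition(BaseModel):
    """Per-100 g composition of one milk kind.

    ``retinol_fraction`` is the preformed-retinol share of vitamin A RAE
    (the vitamin A UL applies to preformed retinol only);
    ``folic_acid_fraction`` is the synthetic folic-acid share of folate DFE
    (the folate UL applies to folic acid only).
    """

    kind: str
    per_100g: dict[str, float]
    retinol_fraction: float = Field(ge=0.0, le=1.0)
    folic_acid_fraction: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _consistent(self) -> "MilkComposition":
        missing = [n for n in NUTRIENTS if n not in self.per_100g]
        if missing:
            raise CompositionError(f"milk '{self.kind}' missing components: {missing}")
        if any(v < 0 for v in self.per_100g.values()):
            raise CompositionError(f"milk '{self.kind}' has negative amounts")
        atwater = sum(self.per_100g[m] * f for m, f in ATWATER.items())
        energy = self.per_100g["energy_kcal"]
        if energy > 0 and abs(atwater - energy) > 0.15 * energy:
            raise CompositionError(
                f"milk '{self.kind}': Atwater energy {atwater:.1f} kcal deviates "
                f"more than 15% from declared {energy:.1f} kcal"
            )
        return self

    def vector(self) -> pd.Series:
        """Per-100 g amounts as a Series in canonical nutrient order."""
        return pd.Series({n: self.per_100g[n] for n in NUTRIENTS}, dtype=float)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("dietmod").joinpath("data", name)))


def load_references(path: str | Path | None = None) -> pd.DataFrame:
    """Load the reference table (packaged default or a user override).

    Validates the structural invariants: EAR > 0 where present, UL > EAR
    where both present, AMDR lower < upper, and that every non-energy
    nutrient of the intake vector has at least an EAR or an AMDR row.
    """
    path = _data_path("references.csv") if path is None else Path(path)
    refs = pd.read_csv(path)
    required = {"nutrient", "age_lo", "age_hi", "sex", "ear", "ul", "amdr_lo",
                "amdr_hi", "eer", "rni", "conversion_factor"}
    if not required.issubset(refs.columns):
        raise InvalidReferenceError(
            f"reference table missing columns: {sorted(required - set(refs.columns))}"
        )
    ear, ul = refs["ear"], refs["ul"]
    if (ear.dropna() <= 0).any():
        raise InvalidReferenceError("EAR values must be positive")
    both = ear.notna() & ul.notna()
    if (ul[both] <= ear[both]).any():
        raise InvalidReferenceError("UL must exceed EAR where both are defined")
    amdr = refs.dropna(subset=["amdr_lo", "amdr_hi"])
    if (amdr["amdr_lo"] >= amdr["amdr_hi"]).any():
        raise InvalidReferenceError("AMDR lower bound must be below upper bound")
    covered = set(refs.loc[refs["ear"].notna() | refs["amdr_lo"].notna()
                           | refs["rni"].notna(), "nutrient"])
    # fatty-acid fractions carry no EAR/AMDR; they are reported descriptively
    descriptive_only = {"sfa_g", "mufa_g", "pufa_g"}
    missing = [n for n in NUTRIENTS[1:] if n not in covered | descriptive_only]
    if missing:
        raise InvalidReferenceError(f"no EAR/AMDR/RNI entry for: {missing}")
    return refs


def ear_from_rni(rni: float, conversion_factor: float) -> float:
    """Derive an EAR from a WHO RNI via a fortification conversion factor.

    Returns ``rni / conversion_factor`` rounded to one decimal, the
    precision at which derived EARs are reported (e.g. zinc at low
    bioavailability: 9.6 / 1.2 = 8.0 mg/d for ages 5-6 y).
    """
    if rni <= 0 or conversion_factor <= 0:
        raise InvalidReferenceError(
            f"rni and conversion_factor must be positive, got ({rni}, {conversion_factor})"
        )
    return round(rni / conversion_factor, 1)


def lookup_reference(
    nutrient: str,
    age_years: float,
    sex: str = "any",
    refs: pd.DataFrame | None = None,
) -> pd.Series:
    """Return the reference record for one nutrient, age and sex.

    Band resolution is data-driven: a row matches when
    ``age_lo <= floor(age) <= age_hi`` and its sex is ``any`` or equals
    ``sex``.  Sex-specific rows take precedence over ``any`` rows.
    """
    if refs is None:
        refs = load_references()
    if not (AGE_RANGE[0] <= age_years <= AGE_RANGE[1] + 1 - 1e-9):
        raise ReferenceLookupError(f"age {age_years} outside the {AGE_RANGE} y scope")
    age = int(np.floor(age_years))
    rows = refs[(refs["nutrient"] == nutrient)
                & (refs["age_lo"] <= age) & (age <= refs["age_hi"])]
    if rows.empty:
        raise ReferenceLookupError(f"no reference entry for nutrient '{nutrient}', age {age}")
    sexed = rows[rows["sex"] == sex]
    if sexed.empty:
        sexed = rows[rows["sex"] == "any"]
    if sexed.empty:
        raise ReferenceLookupError(
            f"no reference entry for '{nutrient}', age {age}, sex '{sex}'"
        )
    return sexed.iloc[0]


def load_milks(path: str | Path | None = None) -> dict[str, MilkComposition]:
    """Load milk compositions from YAML (packaged defaults or user file)."""
    path = _data_path("milks.yaml") if path is None else Path(path)
    raw = yaml.safe_load(Path(path).read_text())
    milks: dict[str, MilkComposition] = {}
    for kind, comp in raw.items():
        comp = dict(comp)
        retinol = comp.pop("retinol_fraction", 1.0)
        folic = comp.pop("folic_acid_fraction", 0.0)
        milks[kind] = MilkComposition(
            kind=kind, per_100g=comp,
            retinol_fraction=retinol, folic_acid_fraction=folic,
        )
    return milks
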