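"""Substitution and tiered-addition scenario rules."""

import numpy as np
import pandas as pd
import pytest

import dietmod as dm
from dietmod.errors import InputValidationError
from dietmod.nutrients import NUTRIENTS


SUB = dm.ScenarioSpec(kind="substitution")
ADD2 = dm.ScenarioSpec(kind="addition", milk="buffalo", cap_servings=2.0)
ADD1 = dm.ScenarioSpec(kind="addition", milk="fortified", cap_servings=1.0)


def test_substitution_eligibility_arithmetic():
    # 4950 milk consumers of whom 89 already drink fortified milk
    n = 5842
    cd = pd.DataFrame({
        "milk_consumer": [True] * 4950 + [False] * (n - 4950),
        "fortified_consumer": [True] * 89 + [False] * (n - 89),
        "dairy_servings": 0.5,
    })
    assert int(dm.select_eligible(cd, SUB).sum()) == 4950 - 89 == 4861


def test_addition_eligibility_includes_nonconsumers(toy_childday):
    mask = dm.select_eligible(toy_childday, ADD2)
    cd = toy_childday.set_index("child_id")
    sel = set(toy_childday.loc[mask, "child_id"])
    assert "T07" in sel                       # dairy non-consumer
    assert "T05" not in sel                   # already at 2.2 servings
    assert "T06" in sel                       # fortified consumer still eligible
    assert (toy_childday.loc[mask, "dairy_servings"] < 2).all()


def test_nonmilk_dairy_only_consumer_roles():
    cd = pd.DataFrame({
        "milk_consumer": [False], "fortified_consumer": [False],
        "dairy_servings": [0.4],
    })
    assert not dm.select_eligible(cd, SUB).iloc[0]
    assert dm.select_eligible(cd, ADD2).iloc[0]


@pytest.mark.parametrize(
    "servings, added",
    [(0.0, 2.0), (0.4, 2.0), (0.499, 2.0), (0.5, 1.5), (0.9, 1.5),
     (0.99, 1.5), (1.0, 1.0), (1.49, 1.0), (1.5, 0.5), (1.7, 0.5),
     (1.99, 0.5), (2.0, 0.0), (2.3, 0.0)],
)
def test_tier_addition_bands(servings, added):
    assert dm.tier_addition(servings) == pytest.approx(added)


def test_tier_addition_cap_binds_first():
    assert dm.tier_addition(0.4, cap=1.0) == 1.0
    assert dm.tier_addition(1.7, cap=1.0) == 0.5


def test_tier_addition_rejects_negative():
    with pytest.raises(InputValidationError):
        dm.tier_addition(-0.1)


def test_uncapped_addition_reaches_two_to_under_2p5_servings():
    # enumerate a fine grid of current servings in [0, 2)
    grid = np.arange(0.0, 2.0, 0.01)
    post = grid + dm.tier_addition(pd.Series(grid)).to_numpy()
    assert (post >= 2.0).all() and (post < 2.5).all()


class TestSubstitution:
    def test_child_without_milk_unchanged(self, toy_childday, milks):
        cd = toy_childday.set_index("child_id")
        none = cd.loc[["T07"]].reset_index()
        out = dm.substitute_milk(none, milks)
        for n in NUTRIENTS:
            assert out.loc[0, n] == pytest.approx(none.loc[0, n])

    def test_delta_is_linear_in_grams(self, milks):
        cd = pd.DataFrame([{**{n: 0.0 for n in NUTRIENTS},
                            **{f"g_{t}": 0.0 for t in
                               ("milk_buffalo", "milk_cow", "milk_goat",
                                "milk_fortified", "tea_milk", "yogurt",
                                "ice_cream", "dairy_dessert", "milkshake")},
                            "g_milk_buffalo": 135.0,
                            "preformed_retinol_ug": 0.0, "folic_acid_ug": 0.0,
                            "milk_consumer": True, "fortified_consumer": False}])
        out = dm.substitute_milk(cd, milks)
        fort, buff = milks["fortified"], milks["buffalo"]
        for n in NUTRIENTS:
            want = 1.35 * (fort.per_100g[n] - buff.per_100g[n])
            assert out.loc[0, n] == pytest.approx(want, abs=1e-9)

    def test_fixture_cow_milk_calcium_hand_computed(self, toy_childday, milks):
        # T02 drinks 150 g cow milk: new calcium = old - 1.5*cow + 1.5*fortified
        cd = toy_childday.set_index("child_id")
        row = cd.loc[["T02"]].reset_index()
        out = dm.substitute_milk(row, milks)
        want = (row.loc[0, "calcium_mg"]
                + 1.5 * (milks["fortified"].per_100g["calcium_mg"]
                         - milks["cow"].per_100g["calcium_mg"]))
        assert out.loc[0, "calcium_mg"] == pytest.approx(want)

    def test_preserves_total_dairy_grams(self, small_childday, milks):
        eligible = small_childday[dm.select_eligible(small_childday, SUB)]
        out = dm.substitute_milk(eligible, milks)
        np.testing.assert_allclose(out["dairy_g"], eligible["dairy_g"])
        assert (out["g_milk_buffalo"] == 0).all()
        assert out["fortified_consumer"].all()


class TestAddition:
    def test_child_at_target_unchanged(self, milks):
        cols = {**{n: 10.0 for n in NUTRIENTS},
                **{f"g_{t}": 0.0 for t in
                   ("milk_buffalo", "milk_cow", "milk_goat", "milk_fortified",
                    "tea_milk", "yogurt", "ice_cream", "dairy_dessert",
                    "milkshake")},
                "g_milk_buffalo": 500.0, "dairy_g": 500.0,
                "dairy_servings": 2.0, "preformed_retinol_ug": 0.0,
                "folic_acid_ug": 0.0, "dairy_consumer": True,
                "milk_consumer": True, "fortified_consumer": False}
        cd = pd.DataFrame([cols])
        out = dm.apply_addition(cd, milks, ADD2)
        assert out.loc[0, "dairy_g"] == 500.0
        assert out.loc[0, "energy_kcal"] == pytest.approx(10.0)

    def test_one_serving_added_at_one_serving(self, milks, toy_childday):
        cd = toy_childday.set_index("child_id")
        row = cd.loc[["T03"]].reset_index()   # 1.2 servings
        out = dm.apply_addition(row, milks, ADD2)
        assert out.loc[0, "dairy_g"] == pytest.approx(row.loc[0, "dairy_g"] + 250.0)
        extra = 2.5 * milks["buffalo"].per_100g["energy_kcal"]
        assert out.loc[0, "energy_kcal"] == pytest.approx(
            row.loc[0, "energy_kcal"] + extra)

    def test_mass_balance_and_idempotence(self, small_childday, milks):
        eligible = small_childday[dm.select_eligible(small_childday, ADD2)]
        once = dm.apply_addition(eligible, milks, ADD2)
        added = dm.tier_addition(eligible["dairy_servings"])
        np.testing.assert_allclose(once["dairy_g"],
                                   eligible["dairy_g"] + 250.0 * added)
        assert (once["dairy_servings"] >= 2.0).all()
        assert (once["dairy_servings"] < 2.5).all()
        twice = dm.apply_addition(once, milks, ADD2)
        np.testing.assert_allclose(twice["dairy_g"], once["dairy_g"])

    def test_capped_variant_adds_at_most_one_serving(self, small_childday, milks):
        eligible = small_childday[dm.select_eligible(small_childday, ADD1)]
        out = dm.apply_addition(eligible, milks, ADD1)
        added_g = out["dairy_g"] - eligible["dairy_g"]
        assert (added_g <= 250.0 + 1e-9).all()
        assert (added_g >= 0).all()


def test_apply_scenario_returns_eligible_subset(small_childday, milks):
    out, mask = dm.apply_scenario(small_childday, SUB, milks)
    assert len(out) == int(mask.sum())
    # nutrient deltas only ever touch eligible rows by construction
    assert (small_childday.loc[~mask, "g_milk_buffalo"]
            == small_childday.loc[~mask, "g_milk_buffalo"]).all()
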