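"""Adequacy estimators: EAR cut-point, full probability, AMDR, UL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietmod as dm
from dietmod.adequacy_stats import per_child_reference
from dietmod.errors import InvalidReferenceError


class TestEarCutpoint:
    def test_all_below_is_100(self):
        assert dm.ear_cutpoint_prevalence([1.0, 2.0, 3.0], 10.0) == 100.0

    def test_symmetric_sample_is_about_50(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100.0, 10.0, size=20000)
        assert dm.ear_cutpoint_prevalence(x, 100.0) == pytest.approx(50.0, abs=1.0)

    def test_matches_lognormal_cdf_closed_form(self):
        gm, gsd, ear = 300.0, 1.6, 250.0
        rng = np.random.default_rng(1)
        x = rng.lognormal(np.log(gm), np.log(gsd), size=50000)
        closed = 100.0 * stats.norm.cdf(np.log(ear / gm) / np.log(gsd))
        assert dm.ear_cutpoint_prevalence(x, ear) == pytest.approx(closed, abs=1.0)

    def test_missing_ear_is_explicit_error_never_zero(self):
        with pytest.raises(InvalidReferenceError):
            dm.ear_cutpoint_prevalence([1.0] * 10, np.nan)


class TestFullProbability:
    def test_intakes_far_above_rni_are_adequate(self):
        dist = dm.RequirementDistribution()
        assert dm.full_probability_prevalence([126.0] * 20, 12.6, dist) < 0.1

    def test_intake_at_requirement_median_gives_50(self):
        dist = dm.RequirementDistribution(log_sd=0.25)
        median = float(np.exp(dist.mu(12.6)))
        assert dm.full_probability_prevalence([median] * 5, 12.6, dist) \
            == pytest.approx(50.0, abs=1e-6)

    def test_anchor_puts_rni_at_97_5th_percentile(self):
        dist = dm.RequirementDistribution(log_sd=0.3)
        # a child eating exactly the RNI is inadequate w.p. 2.5%
        assert dm.full_probability_prevalence([17.8], 17.8, dist) \
            == pytest.approx(2.5, abs=1e-6)

    def test_monte_carlo_oracle_agreement(self):
        # independent oracle: draw 1e5 requirements per child, count exceedances
        rng = np.random.default_rng(3)
        intakes = rng.lognormal(np.log(6.6), np.log(1.6), size=100)
        rni = np.where(rng.random(100) < 0.4, 12.6, 17.8)
        dist = dm.RequirementDistribution(log_sd=0.25)
        draws = rng.lognormal(dist.mu(rni), dist.log_sd, size=(100_000, 100))
        mc = 100.0 * (draws > intakes).mean()
        exact = dm.full_probability_prevalence(intakes, rni, dist)
        assert exact == pytest.approx(mc, abs=0.5)

    def test_degenerate_spread_recovers_ear_cutpoint_at_anchor(self):
        # as the requirement spread vanishes the distribution collapses
        # onto its anchor and the method reduces to a cut-point there
        rng = np.random.default_rng(4)
        intakes = rng.lognormal(np.log(10.0), 0.4, size=2000)
        dist = dm.RequirementDistribution(log_sd=1e-6)
        assert dm.full_probability_prevalence(intakes, 12.6, dist) \
            == pytest.approx(dm.ear_cutpoint_prevalence(intakes, 12.6), abs=0.1)

    def test_zero_intake_is_certainly_inadequate(self):
        dist = dm.RequirementDistribution()
        assert dm.full_probability_prevalence([0.0], 12.6, dist) == 100.0


class TestAmdr:
    def test_protein_below_range(self):
        cat, pcts = dm.amdr_classify([31.8], [1283.0], 10.0, 30.0, "protein_g")
        pct_e = 31.8 * 4 / 1283.0 * 100
        assert pct_e == pytest.approx(9.9, abs=0.05)
        assert cat.iloc[0] == "below" and pcts["below"] == 100.0

    def test_upper_bound_inclusive(self):
        grams = 35.0 / 100.0 * 2000.0 / 9.0   # exactly 35 %E of fat
        cat, _ = dm.amdr_classify([grams], [2000.0], 25.0, 35.0, "fat_g")
        assert cat.iloc[0] == "within"

    def test_zero_fat_below(self):
        cat, _ = dm.amdr_classify([0.0], [1500.0], 25.0, 35.0, "fat_g")
        assert cat.iloc[0] == "below"

    def test_zero_energy_child_excluded(self):
        cat, pcts = dm.amdr_classify([10.0, 50.0], [0.0, 2000.0],
                                     10.0, 30.0, "protein_g")
        assert pd.isna(cat.iloc[0])
        assert pcts["below"] + pcts["within"] + pcts["above"] == 100.0


class TestUlExceedance:
    def test_zero_preformed_fraction_never_exceeds(self):
        rae = [5000.0] * 50
        assert dm.ul_exceedance(rae, 900.0, fraction=0.0) == 0.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        retinol = rng.lognormal(np.log(600.0), 0.5, size=1000)
        want = 100.0 * (retinol > 900.0).sum() / 1000
        assert dm.ul_exceedance(retinol, 900.0) == pytest.approx(want)

    def test_missing_ul_rejected(self):
        with pytest.raises(InvalidReferenceError):
            dm.ul_exceedance([1.0], np.nan)


class TestCompareScenarios:
    def _summary(self, p):
        return pd.DataFrame({"nutrient": list(p), "pct_below": list(p.values()),
                             "n": 100})

    def test_printed_example(self):
        cmp_df = dm.compare_scenarios(self._summary({"vitamin_c_mg": 36.0}),
                                      self._summary({"vitamin_c_mg": 5.0}))
        assert cmp_df.loc["vitamin_c_mg", "relative_reduction_pct"] \
            == pytest.approx(86.1, abs=0.1)
        assert cmp_df.loc["vitamin_c_mg", "absolute_reduction_pp"] == 31.0

    def test_equal_prevalences_give_zero(self):
        cmp_df = dm.compare_scenarios(self._summary({"x": 20.0}),
                                      self._summary({"x": 20.0}))
        assert cmp_df.loc["x", "relative_reduction_pct"] == 0.0

    def test_zero_baseline_not_applicable(self):
        cmp_df = dm.compare_scenarios(self._summary({"x": 0.0}),
                                      self._summary({"x": 0.0}))
        assert np.isnan(cmp_df.loc["x", "relative_reduction_pct"])

    def test_hundred_percent_reduction_iff_scenario_zero(self):
        cmp_df = dm.compare_scenarios(self._summary({"x": 40.0}),
                                      self._summary({"x": 0.0}))
        assert cmp_df.loc["x", "relative_reduction_pct"] == 100.0


def test_per_child_reference_resolves_bands_and_weight(refs):
    cd = pd.DataFrame({
        "age": [5, 9, 9, 6], "sex": ["M", "F", "M", "F"],
        "weight_kg": [20.0, 27.0, 27.0, 20.0],
    })
    vita = per_child_reference(cd, "vitamin_a_ug_rae", "ear", refs)
    assert list(vita) == [275.0, 420.0, 445.0, 275.0]
    protein = per_child_reference(cd, "protein_g", "ear", refs)
    assert protein.iloc[0] == pytest.approx(0.76 * 20.0)
    sfa = per_child_reference(cd, "sfa_g", "ear", refs)
    assert sfa.isna().all()


def test_summarize_adequacy_structure(small_childday, refs):
    cfg = dm.UsualIntakeConfig(variance_ratio=0.73)
    summary = dm.summarize_adequacy(small_childday, refs, cfg)
    amount = summary[summary["basis"] == "amount"].set_index("nutrient")
    assert amount.loc["iron_mg", "method"] == "full_probability"
    assert amount.loc["calcium_mg", "method"] == "ear_cutpoint"
    pe = summary[summary["basis"] == "pct_energy"]
    assert set(pe["nutrient"]) == {"protein_g", "carbohydrate_g", "fat_g"}
    pcts = summary[["pct_below", "pct_above"]].stack().dropna()
    assert ((pcts >= 0) & (pcts <= 100)).all()
    # fatty-acid fractions have no references: explicit NA, never zero
    assert np.isnan(amount.loc["sfa_g", "pct_below"])
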