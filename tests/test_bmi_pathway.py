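"""BMI distribution reconstruction, counterfactual shift and indirect PAFs."""

import numpy as np
import pytest

from ssb_burden import (
    BMIDistribution,
    BMIEffectModel,
    BMIProfile,
    ExposureDistribution,
    RiskFunction,
    ValidationError,
    attributable_weight_cases,
    counterfactual_bmi,
    fit_bmi_distribution,
    paf_indirect,
)

EFFECT = BMIEffectModel()


def _point_dist(values, child=False, key=("female", 18, 200)):
    v = np.asarray(values, float)
    return BMIDistribution(key, v, np.full(v.size, 1 / v.size), is_child=child)


class TestFit:
    def test_adult_profile_reproduces_all_five_moments(self):
        # adult women overall: mean 28.4, ow 30%, ob1 22%, ob2 9%, ob3 7%
        profile = BMIProfile(("female", 18, 200), 28.4, 0.30, 0.22, 0.09, 0.07)
        dist = fit_bmi_distribution(profile, n_points=4000, seed=0)
        assert dist.mean == pytest.approx(28.4, abs=0.05)
        masses = dist.category_masses()
        for cat, target in zip(
            ("overweight", "obesity_1", "obesity_2", "obesity_3"),
            profile.prevalences,
        ):
            assert masses[cat] == pytest.approx(target, abs=0.005)

    def test_all_fixture_profiles_fit_within_tolerance(self, argentina):
        for profile in argentina.bmi.values():
            dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
            masses = list(dist.category_masses().values())
            targets = (
                [profile.prev_overweight, profile.prev_ob1]
                if dist.is_child
                else list(profile.prevalences)
            )
            for got, want in zip(masses, targets):
                assert got == pytest.approx(want, abs=0.005)
            if profile.mean_bmi is not None:
                assert dist.mean == pytest.approx(profile.mean_bmi, abs=0.05)

    def test_degenerate_normal_weight_population_stays_below_25(self):
        profile = BMIProfile(("female", 18, 200), 22.0, 0.0, 0.0, 0.0, 0.0)
        dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
        assert np.all(dist.values < 25.0)
        assert dist.mean == pytest.approx(22.0, abs=0.05)

    def test_deterministic_for_fixed_seed(self):
        profile = BMIProfile(("male", 18, 44), 26.9, 0.355, 0.171, 0.056, 0.020)
        a = fit_bmi_distribution(profile, n_points=2000, seed=7)
        b = fit_bmi_distribution(profile, n_points=2000, seed=7)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.weights, b.weights)

    def test_category_masses_equal_direct_point_counting(self):
        profile = BMIProfile(("female", 45, 64), 29.4, 0.296, 0.273, 0.090, 0.065)
        dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
        cuts = [25.0, 30.0, 35.0, 40.0, np.inf]
        for (cat, mass), lo, hi in zip(
            dist.category_masses().items(), cuts[:-1], cuts[1:]
        ):
            # independent oracle: brute-force re-classification of the points
            counted = dist.weights[(dist.values >= lo) & (dist.values < hi)].sum()
            assert mass == counted

    def test_small_point_count_rejected(self):
        profile = BMIProfile(("female", 18, 200), 28.0, 0.3, 0.2, 0.05, 0.02)
        with pytest.raises(ValidationError):
            fit_bmi_distribution(profile, n_points=100)


class TestCounterfactual:
    def test_adult_above_25_uses_high_delta(self):
        dist = _point_dist([26.0])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(2.0), EFFECT, is_adult=True
        )
        assert cf.values[0] == pytest.approx(26.0 - 2 * 0.23, abs=1e-12)

    def test_adult_below_25_uses_low_delta(self):
        dist = _point_dist([24.0])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(2.0), EFFECT, is_adult=True
        )
        assert cf.values[0] == pytest.approx(24.0 - 2 * 0.10, abs=1e-12)

    def test_zero_consumption_identity(self):
        dist = _point_dist([22.0, 27.0, 33.0])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(0.0), EFFECT, is_adult=True
        )
        assert np.array_equal(cf.values, dist.values)

    def test_child_contrast_at_observed_serving_change(self):
        dist = _point_dist([20.0], child=True, key=("male", 5, 17))
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(1.7), EFFECT, is_adult=False
        )
        assert dist.values[0] - cf.values[0] == pytest.approx(0.57, abs=1e-12)

    def test_floor_at_13(self):
        dist = _point_dist([13.05])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(5.0), EFFECT, is_adult=True
        )
        assert cf.values[0] == 13.0

    def test_delta_chosen_from_baseline_not_iterated(self):
        # baseline just above 25 keeps the high delta even when the shift
        # crosses the threshold
        dist = _point_dist([25.1])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(2.0), EFFECT, is_adult=True
        )
        assert cf.values[0] == pytest.approx(25.1 - 2 * 0.23, abs=1e-12)

    def test_pointwise_never_above_baseline(self, argentina):
        profile = argentina.bmi[("male", 18, 44)]
        dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(1.7), EFFECT, is_adult=True
        )
        assert np.all(cf.values <= dist.values + 1e-12)

    def test_adult_child_flag_mismatch_rejected(self):
        dist = _point_dist([20.0], child=True)
        with pytest.raises(ValidationError):
            counterfactual_bmi(
                dist, ExposureDistribution.point_mass(1.0), EFFECT, is_adult=True
            )


class TestAttributableCases:
    def test_identical_distributions_give_zero(self):
        dist = _point_dist([22.0, 27.0, 31.0])
        cases = attributable_weight_cases(dist, dist, 1e6)
        assert all(v == 0.0 for v in cases.values())

    def test_counts_match_brute_force_reclassification(self):
        profile = BMIProfile(("female", 18, 44), 26.7, 0.274, 0.149, 0.069, 0.037)
        dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(1.1), EFFECT, is_adult=True
        )
        pop = 8.4e6
        cases = attributable_weight_cases(dist, cf, pop)
        cuts = {"overweight": (25, 30), "obesity_1": (30, 35),
                "obesity_2": (35, 40), "obesity_3": (40, np.inf)}
        for cat, (lo, hi) in cuts.items():
            base_n = dist.weights[(dist.values >= lo) & (dist.values < hi)].sum()
            cf_n = cf.weights[(cf.values >= lo) & (cf.values < hi)].sum()
            assert cases[cat] == pytest.approx((base_n - cf_n) * pop, abs=1e-6)

    def test_linear_in_population_and_additive(self):
        dist = _point_dist([24.9, 25.2, 31.0, 36.0])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(1.0), EFFECT, is_adult=True
        )
        one = attributable_weight_cases(dist, cf, 1e5)
        two = attributable_weight_cases(dist, cf, 2e5)
        for cat in one:
            assert two[cat] == pytest.approx(2 * one[cat], rel=1e-12)

    def test_fixture_run_adult_cases_inside_published_interval(self, argentina_run):
        """All-strata run lands within the published 95% interval for adult
        attributable overweight+obesity cases."""
        adult = argentina_run[
            (argentina_run["group"] == "owob_adult")
            & (argentina_run["measure"] == "events")
        ]
        total = adult["attributable"].sum()
        assert 361_044 <= total <= 890_222

    def test_summary_frame_reports_both_scenarios(self):
        from ssb_burden.bmi import summary_frame

        dist = _point_dist([24.0, 27.0, 31.0])
        cf = counterfactual_bmi(
            dist, ExposureDistribution.point_mass(1.0), EFFECT, is_adult=True
        )
        frame = summary_frame(dist, cf)
        assert frame.loc[0, "mean_counterfactual"] < frame.loc[0, "mean_baseline"]
        assert frame.loc[0, "overweight_baseline"] == pytest.approx(1 / 3)

    def test_excess_weight_mass_never_increases_under_counterfactual(self, argentina):
        for key, profile in argentina.bmi.items():
            dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
            servings = argentina.consumption[key].mean_servings
            cf = counterfactual_bmi(
                dist, ExposureDistribution.point_mass(servings), EFFECT,
                is_adult=not dist.is_child,
            )
            base, after = dist.category_masses(), cf.category_masses()
            # cumulative mass above each cutoff can only shrink
            cats = list(base)
            for i in range(len(cats)):
                above_base = sum(base[c] for c in cats[i:])
                above_cf = sum(after[c] for c in cats[i:])
                assert above_cf <= above_base + 1e-12


class TestIndirectPaf:
    RISK = RiskFunction(
        "osteoarthritis", "bmi_mediated", "incidence", 1.10, 1.05, 1.15,
        reference_bmi=22.0,
    )

    def test_identical_distributions_give_zero(self):
        dist = _point_dist([24.0, 28.0])
        assert paf_indirect(dist, dist, self.RISK) == 0.0

    def test_all_mass_below_reference_gives_zero(self):
        base = _point_dist([20.0, 21.0])
        cf = _point_dist([19.0, 20.0])
        assert paf_indirect(base, cf, self.RISK) == 0.0

    def test_two_point_hand_computation(self):
        base = _point_dist([24.0, 30.0])
        cf = _point_dist([23.5, 29.5])
        expected = 1 - (1.1**1.5 + 1.1**7.5) / (1.1**2.0 + 1.1**8.0)
        assert paf_indirect(base, cf, self.RISK) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_consumption(self, argentina):
        profile = argentina.bmi[("female", 45, 64)]
        dist = fit_bmi_distribution(profile, n_points=2000, seed=0)
        pafs = []
        for servings in (0.0, 0.5, 1.0, 2.0):
            cf = counterfactual_bmi(
                dist, ExposureDistribution.point_mass(servings), EFFECT, True
            )
            pafs.append(paf_indirect(dist, cf, self.RISK))
        assert pafs == sorted(pafs)
        assert pafs[0] == 0.0
        assert all(0 <= p < 1 for p in pafs)

    def test_direct_risk_rejected(self):
        direct = RiskFunction("diabetes", "direct", "incidence", 1.37, 1.2, 1.5)
        dist = _point_dist([26.0])
        with pytest.raises(ValidationError):
            paf_indirect(dist, dist, direct)
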