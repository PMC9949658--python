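"""Dose-response scaling and the population attributable fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssb_burden import (
    ExposureDistribution,
    ValidationError,
    paf,
    paf_table_direct,
    rr_at_dose,
)
from ssb_burden.synthetic import generate_known_truth


class TestRrAtDose:
    @pytest.mark.parametrize(
        "theta, x, expected",
        [
            (1.37, 1.0, 1.37),  # per-serving RR at one serving
            (1.08, 0.0, 1.0),  # zero dose, unit RR
            (1.08, 2.0, 1.1664),  # 1.08**2
        ],
    )
    def test_exponential_scaling(self, theta, x, expected):
        assert rr_at_dose(theta, x) == pytest.approx(expected, abs=1e-12)

    def test_linear_alternative(self):
        assert rr_at_dose(1.4, 2.0, form="linear") == pytest.approx(1.8)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValidationError):
            rr_at_dose(0.0, 1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            rr_at_dose(1.1, -0.5)


class TestPaf:
    def test_point_mass_one_serving_diabetes(self):
        # closed form: 1 - 1/1.37
        value = paf(ExposureDistribution.point_mass(1.0), 1.37)
        assert value == pytest.approx(1 - 1 / 1.37, abs=1e-12)
        assert round(value, 5) == 0.27007

    def test_zero_exposure_gives_zero(self):
        assert paf(ExposureDistribution.point_mass(0.0), 1.37) == 0.0

    def test_two_point_exposure_hand_computation(self):
        exp = ExposureDistribution(np.array([0.5, 1.5]), np.array([0.5, 0.5]))
        expected = 1 - 1 / (0.5 * 1.08**0.5 + 0.5 * 1.08**1.5)
        assert paf(exp, 1.08) == pytest.approx(expected, abs=1e-12)

    def test_empty_exposure_rejected(self):
        with pytest.raises(ValidationError):
            ExposureDistribution(np.array([]), np.array([]))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            ExposureDistribution(np.array([1.0, 2.0]), np.array([0.5, 0.2]))

    def test_protective_theta_warns_and_goes_negative(self):
        with pytest.warns(UserWarning):
            value = paf(ExposureDistribution.point_mass(1.0), 0.9)
        assert value < 0  # retained unclipped

    @given(
        theta=st.floats(1.0, 3.0),
        servings=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_below_one(self, theta, servings):
        exp = ExposureDistribution.from_sample(np.array(servings))
        assert 0.0 <= paf(exp, theta) < 1.0

    @given(
        lo=st.floats(1.01, 2.0),
        bump=st.floats(0.01, 1.0),
        servings=st.lists(st.floats(0.1, 5.0), min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_theta(self, lo, bump, servings):
        exp = ExposureDistribution.from_sample(np.array(servings))
        assert paf(exp, lo + bump) > paf(exp, lo)

    @given(
        shift=st.floats(0.01, 2.0),
        servings=st.lists(st.floats(0.0, 5.0), min_size=1, max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_increasing_under_exposure_shift(self, shift, servings):
        base = np.array(servings)
        assert paf(
            ExposureDistribution.from_sample(base + shift), 1.2
        ) > paf(ExposureDistribution.from_sample(base), 1.2) - 1e-15

    def test_matches_brute_force_oracle_on_sampled_exposures(self):
        rng = np.random.default_rng(42)
        for n in (10, 1000, 10_000):
            x = rng.gamma(2.0, 0.6, size=n)
            theta = 1.0 + rng.uniform(0.01, 0.5)
            # independent brute force: 1 - n / sum(theta**x_i)
            expected = 1.0 - n / np.sum(theta**x)
            got = paf(ExposureDistribution.from_sample(x), theta)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_merging_identical_strata_leaves_paf_unchanged(self):
        x = np.array([0.3, 1.1, 2.4])
        single = paf(ExposureDistribution.from_sample(x), 1.25)
        merged = paf(ExposureDistribution.from_sample(np.tile(x, 2)), 1.25)
        assert merged == pytest.approx(single, abs=1e-14)


class TestPafTableDirect:
    def test_diabetes_same_paf_for_events_and_deaths(self):
        inputs, _ = generate_known_truth(1 - 1 / 1.37, seed=0)
        table = paf_table_direct(inputs)
        key = inputs.strata[0].key
        inc = table.get("target_disease", key, "incidence")
        mort = table.get("target_disease", key, "mortality")
        assert inc == pytest.approx(1 - 1 / 1.37, abs=1e-12)
        assert mort == inc  # single RR moves all outcomes alike

    def test_cvd_mortality_paf_at_one_serving(self, argentina):
        table = paf_table_direct(argentina)
        # male 45-64 consumes 1.2 servings/day
        got = table.get("stroke", ("male", 45, 64), "mortality")
        assert got == pytest.approx(1 - 1.08**-1.2, abs=1e-12)

    def test_zero_consumption_gives_zero_paf(self):
        inputs, _ = generate_known_truth(0.3, seed=0)
        key = inputs.strata[0].key
        from ssb_burden import ConsumptionProfile

        zeroed = inputs.with_overrides(
            consumption={key: ConsumptionProfile(key, 0.0, 0.0)}
        )
        table = paf_table_direct(zeroed)
        assert all(v == 0.0 for v in table.entries.values())

    def test_export_frame_shape(self, argentina):
        frame = paf_table_direct(argentina).to_frame()
        assert set(frame.columns) == {
            "disease", "sex", "age_lo", "age_hi", "outcome", "paf"
        }
        # 6 direct diseases x 6 adult strata x 2 outcomes
        assert len(frame) == 6 * 6 * 2
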