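"""Input schema, validation rules and the packaged country fixture."""

import filecmp

import pytest

from ssb_burden import (
    BMIEffectModel,
    BMIProfile,
    ConsumptionProfile,
    DiseaseEpi,
    DoubleCountingError,
    EconomicConfig,
    ModelConfig,
    ModelInputs,
    RiskFunction,
    Stratum,
    ValidationError,
    read_inputs,
    write_fixture,
    write_inputs,
)
from ssb_burden.synthetic import _flat_life_table


class TestFixtureContents:
    def test_adult_population_totals_30_2_million(self, argentina):
        assert argentina.total_population(adults=True) == pytest.approx(30.2e6)

    def test_child_population_matches_printed_overall(self, argentina):
        # printed band populations are rounded to 0.1M, so the sum of four
        # bands may differ from the printed 13.0M overall by up to 0.2M
        assert argentina.total_population(adults=False) == pytest.approx(13.0e6, abs=0.2e6)

    def test_overall_adult_consumption_row_is_one_serving(self, argentina):
        row = next(
            c
            for c in argentina.consumption_overall
            if c.stratum == ("both", 18, 200)
        )
        assert row.mean_servings == 1.0

    def test_diabetes_prevalent_cost(self, argentina):
        assert argentina.diseases["diabetes"].cost_prevalent == 1414

    def test_child_obesity_annual_cost(self, argentina):
        assert argentina.weight_costs[("child", "obesity")] == 24

    def test_exchange_rate(self, argentina):
        assert argentina.economics.exchange_rate == 48.14


class TestRoundTrip:
    def test_write_then_read_reproduces_inputs(self, argentina, tmp_path):
        write_inputs(argentina, tmp_path / "a")
        reread = read_inputs(tmp_path / "a")
        write_inputs(reread, tmp_path / "b")
        files = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False
        )
        assert not mismatch and not errors and sorted(match) == sorted(files)

    def test_fixture_write_includes_observed_burden_table(self, tmp_path):
        paths = write_fixture(tmp_path)
        names = {p.name for p in paths}
        assert "burden_table.csv" in names and "config.json" in names
        reread = read_inputs(tmp_path)
        assert reread.total_population(adults=True) == pytest.approx(30.2e6)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_inputs(tmp_path)

    def test_missing_directory_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            read_inputs(tmp_path / "nope")


def _minimal_inputs(**overrides):
    s = Stratum("female", 18, 200, 1000.0)
    base = dict(
        strata=[s],
        consumption={s.key: ConsumptionProfile(s.key, 1.0, 0.1)},
        bmi={},
        bmi_effect=BMIEffectModel(),
        risk_functions=[
            RiskFunction("diabetes", "direct", "incidence", 1.37, 1.2, 1.5)
        ],
        diseases={
            "diabetes": DiseaseEpi("diabetes", "diabetes", 100, 1000, 10, 0.1)
        },
        economics=EconomicConfig(),
        life_table=_flat_life_table(),
        config=ModelConfig(groups={"diabetes": "diabetes"}),
    )
    base.update(overrides)
    return ModelInputs(**base)


class TestValidation:
    def test_minimal_inputs_pass(self):
        _minimal_inputs().validate()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            DiseaseEpi("x", "other", -1, 0, 0, 0.1)

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            Stratum("female", 18, 200, -5.0)

    def test_direct_rr_for_non_cvd_disease_rejected(self):
        inputs = _minimal_inputs(
            diseases={"asthma": DiseaseEpi("asthma", "asthma", 100, 1000, 1, 0.05)},
            risk_functions=[
                RiskFunction("asthma", "direct", "incidence", 1.2, 1.1, 1.3)
            ],
            config=ModelConfig(groups={"asthma": "asthma"}),
        )
        with pytest.raises(DoubleCountingError):
            inputs.validate()

    def test_bmi_mediated_rr_for_diabetes_rejected(self):
        inputs = _minimal_inputs(
            risk_functions=[
                RiskFunction(
                    "diabetes", "bmi_mediated", "incidence", 1.1, 1.05, 1.15,
                    reference_bmi=22.5,
                )
            ],
            bmi={
                ("female", 18, 200): BMIProfile(
                    ("female", 18, 200), 27.0, 0.3, 0.1, 0.02, 0.01
                )
            },
        )
        with pytest.raises(DoubleCountingError):
            inputs.validate()

    def test_stratum_without_consumption_listed_in_error(self):
        inputs = _minimal_inputs(consumption={})
        with pytest.raises(ValidationError, match=r"female.*18.*200"):
            inputs.validate()

    def test_age_gap_rejected(self):
        inputs = _minimal_inputs(
            strata=[
                Stratum("female", 18, 40, 500.0),
                Stratum("female", 45, 200, 500.0),
            ]
        )
        with pytest.raises(ValidationError, match="gap"):
            inputs.validate()

    def test_prevalences_over_one_rejected(self):
        with pytest.raises(ValidationError):
            BMIProfile(("female", 18, 200), 28.0, 0.6, 0.5, 0.1, 0.0)

    def test_rr_ci_ordering_enforced(self):
        with pytest.raises(ValidationError):
            RiskFunction("diabetes", "direct", "incidence", 1.37, 1.5, 1.2)
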