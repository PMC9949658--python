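"""Delimited-table input schema: readers and writers.

One UTF-8 CSV per entity, header row required:

``population.csv``
    sex, age_lo, age_hi, population
``consumption.csv``
    sex, age_lo, age_hi, mean_servings, se_servings, is_overall
``bmi.csv``
    sex, age_lo, age_hi, mean_bmi (blank for children), prev_overweight,
    prev_ob1, prev_ob2, prev_ob3
``disease_epi.csv``
    disease, group, sex (blank = both), incidence_rate, prevalence_rate,
    mortality_rate, disability_weight, cost_incident, cost_prevalent
``risk_functions.csv``
    disease, pathway, outcome, rr_per_unit, ci_lo, ci_hi, reference_bmi
``weight_costs.csv``
    kind (adult|child), category, annual_cost
``life_table.csv``
    sex, age, ex
``config.json``
    schema_version, economics, bmi_effect, events_basis, dose_response,
    reference_bmi

Rates are per 100,000; costs are in the currency declared by
``config.json`` (``currency``: "USD" or "local", converted at the declared
exchange rate when reporting).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from . import fixtures
from .types import (
    BMIEffectModel,
    BMIProfile,
    ConsumptionProfile,
    DiseaseEpi,
    EconomicConfig,
    LifeTable,
    ModelConfig,
    ModelInputs,
    RiskFunction,
    Stratum,
    ValidationError,
)

__all__ = ["read_inputs", "write_inputs", "write_fixture", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

_TABLES = (
    "population",
    "consumption",
    "bmi",
    "disease_epi",
    "risk_functions",
    "weight_costs",
    "life_table",
)


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        raise ValidationError(f"missing input table {path}")
    return pd.read_csv(path, float_precision="round_trip")


def _opt(value):
    """None for missing CSV cells."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def read_inputs(directory: str | Path, schema_version: str = SCHEMA_VERSION) -> ModelInputs:
    """Read and validate a full model-input directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"input directory {directory} does not exist")
    if schema_version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported schema version {schema_version!r}")

    cfg_path = directory / "config.json"
    if not cfg_path.exists():
        raise ValidationError(f"missing {cfg_path}")
    cfg = json.loads(cfg_path.read_text())

    strata = [
        Stratum(r.sex, int(r.age_lo), int(r.age_hi), float(r.population))
        for r in _read_table(directory, "population").itertuples()
    ]

    consumption, overall = {}, []
    for r in _read_table(directory, "consumption").itertuples():
        profile = ConsumptionProfile(
            (r.sex, int(r.age_lo), int(r.age_hi)),
            float(r.mean_servings),
            float(r.se_servings),
            is_overall=bool(r.is_overall),
        )
        if profile.is_overall:
            overall.append(profile)
        else:
            consumption[profile.stratum] = profile

    bmi = {}
    for r in _read_table(directory, "bmi").itertuples():
        key = (r.sex, int(r.age_lo), int(r.age_hi))
        mean = _opt(r.mean_bmi)
        bmi[key] = BMIProfile(
            key,
            None if mean is None else float(mean),
            float(r.prev_overweight),
            float(r.prev_ob1),
            float(r.prev_ob2),
            float(r.prev_ob3),
        )

    diseases = {}
    for r in _read_table(directory, "disease_epi").itertuples():
        diseases[r.disease] = DiseaseEpi(
            disease=r.disease,
            group=r.group,
            sex=_opt(r.sex),
            incidence_rate=float(r.incidence_rate),
            prevalence_rate=float(r.prevalence_rate),
            mortality_rate=float(r.mortality_rate),
            disability_weight=float(r.disability_weight),
            cost_incident=float(r.cost_incident),
            cost_prevalent=float(r.cost_prevalent),
        )

    risks = []
    for r in _read_table(directory, "risk_functions").itertuples():
        ref = _opt(r.reference_bmi)
        risks.append(
            RiskFunction(
                disease=r.disease,
                pathway=r.pathway,
                outcome=r.outcome,
                rr_per_unit=float(r.rr_per_unit),
                ci_lo=float(r.ci_lo),
                ci_hi=float(r.ci_hi),
                reference_bmi=None if ref is None else float(ref),
            )
        )

    weight_costs = {
        (r.kind, r.category): float(r.annual_cost)
        for r in _read_table(directory, "weight_costs").itertuples()
    }

    life_table = LifeTable(_read_table(directory, "life_table"))

    eco = cfg.get("economics", {})
    economics = EconomicConfig(
        exchange_rate=float(eco.get("exchange_rate", 48.14)),
        gdp_per_capita=float(eco.get("gdp_per_capita", 0.0)),
        health_expenditure_share=float(eco.get("health_expenditure_share", 0.0)),
        currency=eco.get("currency", "USD"),
    )
    eff = cfg.get("bmi_effect", {})
    bmi_effect = BMIEffectModel(
        delta_low=float(eff.get("delta_low", 0.10)),
        delta_low_ci=tuple(eff.get("delta_low_ci", (0.05, 0.15))),
        delta_high=float(eff.get("delta_high", 0.23)),
        delta_high_ci=tuple(eff.get("delta_high_ci", (0.14, 0.32))),
        delta_child=float(eff.get("delta_child", 0.57 / 1.7)),
        delta_child_ci=tuple(eff.get("delta_child_ci", (0.2, 0.47))),
    )
    config = ModelConfig(
        groups={d: e.group for d, e in diseases.items()},
        events_basis=dict(cfg.get("events_basis", {})),
        dose_response=cfg.get("dose_response", "exponential"),
        reference_bmi=float(cfg.get("reference_bmi", 22.5)),
    )

    return ModelInputs(
        strata=strata,
        consumption=consumption,
        bmi=bmi,
        bmi_effect=bmi_effect,
        risk_functions=risks,
        diseases=diseases,
        economics=economics,
        life_table=life_table,
        config=config,
        consumption_overall=overall,
        weight_costs=weight_costs,
    ).validate()


def write_inputs(inputs: ModelInputs, target: str | Path) -> list[Path]:
    """Write a ModelInputs to the delimited-table schema; returns the paths."""
    target = Path(target)
    target.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        # normalise integer columns to float so a written file re-writes
        # identically after a read (ages stay integral)
        for col in frame.columns:
            if frame[col].dtype.kind == "i" and col not in ("age_lo", "age_hi", "age"):
                frame[col] = frame[col].astype(float)
        path = target / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)

    emit(
        "population",
        pd.DataFrame(
            [
                {"sex": s.sex, "age_lo": s.age_lo, "age_hi": s.age_hi,
                 "population": s.population}
                for s in inputs.strata
            ]
        ),
    )
    cons_rows = [
        {"sex": c.stratum[0], "age_lo": c.stratum[1], "age_hi": c.stratum[2],
         "mean_servings": c.mean_servings, "se_servings": c.se_servings,
         "is_overall": c.is_overall}
        for c in list(inputs.consumption.values()) + list(inputs.consumption_overall)
    ]
    emit("consumption", pd.DataFrame(cons_rows))
    emit(
        "bmi",
        pd.DataFrame(
            [
                {"sex": p.stratum[0], "age_lo": p.stratum[1], "age_hi": p.stratum[2],
                 "mean_bmi": p.mean_bmi, "prev_overweight": p.prev_overweight,
                 "prev_ob1": p.prev_ob1, "prev_ob2": p.prev_ob2,
                 "prev_ob3": p.prev_ob3}
                for p in inputs.bmi.values()
            ]
        ),
    )
    emit(
        "disease_epi",
        pd.DataFrame(
            [
                {"disease": e.disease, "group": e.group, "sex": e.sex,
                 "incidence_rate": e.incidence_rate,
                 "prevalence_rate": e.prevalence_rate,
                 "mortality_rate": e.mortality_rate,
                 "disability_weight": e.disability_weight,
                 "cost_incident": e.cost_incident,
                 "cost_prevalent": e.cost_prevalent}
                for e in inputs.diseases.values()
            ]
        ),
    )
    emit(
        "risk_functions",
        pd.DataFrame(
            [
                {"disease": r.disease, "pathway": r.pathway, "outcome": r.outcome,
                 "rr_per_unit": r.rr_per_unit, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
                 "reference_bmi": r.reference_bmi}
                for r in inputs.risk_functions
            ]
        ),
    )
    emit(
        "weight_costs",
        pd.DataFrame(
            [
                {"kind": k, "category": c, "annual_cost": v}
                for (k, c), v in inputs.weight_costs.items()
            ]
        ),
    )
    emit("life_table", inputs.life_table.frame)

    cfg = {
        "schema_version": SCHEMA_VERSION,
        "economics": {
            "exchange_rate": inputs.economics.exchange_rate,
            "gdp_per_capita": inputs.economics.gdp_per_capita,
            "health_expenditure_share": inputs.economics.health_expenditure_share,
            "currency": inputs.economics.currency,
        },
        "bmi_effect": {
            "delta_low": inputs.bmi_effect.delta_low,
            "delta_low_ci": list(inputs.bmi_effect.delta_low_ci),
            "delta_high": inputs.bmi_effect.delta_high,
            "delta_high_ci": list(inputs.bmi_effect.delta_high_ci),
            "delta_child": inputs.bmi_effect.delta_child,
            "delta_child_ci": list(inputs.bmi_effect.delta_child_ci),
        },
        "events_basis": dict(inputs.config.events_basis),
        "dose_response": inputs.config.dose_response,
        "reference_bmi": inputs.config.reference_bmi,
    }
    cfg_path = target / "config.json"
    cfg_path.write_text(json.dumps(cfg, indent=2))
    written.append(cfg_path)
    return written


def write_fixture(target: str | Path) -> list[Path]:
    """Emit the packaged Argentina 2020 fixture (inputs + observed burden table)."""
    target = Path(target)
    written = write_inputs(fixtures.argentina_inputs(), target)
    obs_path = target / "burden_table.csv"
    fixtures.table3_observed().to_csv(obs_path, index=False)
    written.append(obs_path)
    return written
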