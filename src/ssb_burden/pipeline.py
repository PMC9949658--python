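"""Deterministic end-to-end run of the comparative risk assessment.

One call to :func:`run_point` executes, for a fixed set of parameter values:

1. direct-pathway PAFs (per-serving RRs for diabetes and CVD),
2. the BMI counterfactual shift and the indirect PAFs it implies,
3. attributable overweight/obesity cases (adults and children) and their
   annual costs,
4. attribution of events, deaths, DALYs and costs per condition x stratum.

Baseline BMI distributions depend only on the BMI profiles, not on sampled
parameters, so they are fitted once and reused across Monte Carlo
iterations via ``prepare_bmi_baselines``.
"""

from __future__ import annotations

import pandas as pd

from .bmi import (
    BMIDistribution,
    attributable_weight_cases,
    counterfactual_bmi,
    fit_bmi_distribution,
    paf_indirect,
)
from .burden import attribute, convert_currency, total_burden
from .paf import ExposureDistribution, paf_table_direct
from .types import INCIDENCE, MORTALITY, ModelInputs, StratumKey

__all__ = ["prepare_bmi_baselines", "run_point", "RESULT_COLUMNS"]

RESULT_COLUMNS = [
    "disease",
    "group",
    "sex",
    "age_lo",
    "age_hi",
    "measure",
    "attributable",
    "total",
]

#: measures carried in the long-format result frame
MEASURES = ("events", "deaths", "ylds", "ylls", "dalys", "cost")

OWOB_ADULT = "owob_adult"
OWOB_CHILD = "owob_child"


def prepare_bmi_baselines(
    inputs: ModelInputs, n_points: int = 2000, seed: int = 0
) -> dict[StratumKey, BMIDistribution]:
    """Fit the baseline BMI distribution of every stratum with a BMI profile."""
    return {
        key: fit_bmi_distribution(profile, n_points=n_points, seed=seed)
        for key, profile in inputs.bmi.items()
    }


def _usd(amount: float, inputs: ModelInputs) -> float:
    if inputs.economics.currency == "USD":
        return amount
    return convert_currency(amount, inputs.economics)


def _weight_rows(
    inputs: ModelInputs, baselines: dict[StratumKey, BMIDistribution]
) -> list[dict]:
    """Attributable overweight/obesity cases and costs per stratum."""
    rows = []
    for stratum in inputs.strata:
        base = baselines.get(stratum.key)
        if base is None:
            continue
        exposure = ExposureDistribution.point_mass(
            inputs.consumption[stratum.key].mean_servings
        )
        cf = counterfactual_bmi(base, exposure, inputs.bmi_effect, stratum.is_adult)
        cases = attributable_weight_cases(base, cf, stratum.population)
        base_mass = base.category_masses()
        kind = "adult" if stratum.is_adult else "child"
        group = OWOB_ADULT if stratum.is_adult else OWOB_CHILD

        attr_events = sum(cases.values())
        total_events = sum(base_mass.values()) * stratum.population
        attr_cost = sum(
            cases[cat] * inputs.weight_costs.get((kind, cat), 0.0) for cat in cases
        )
        total_cost = sum(
            base_mass[cat]
            * stratum.population
            * inputs.weight_costs.get((kind, cat), 0.0)
            for cat in base_mass
        )
        common = {
            "disease": group,
            "group": group,
            "sex": stratum.sex,
            "age_lo": stratum.age_lo,
            "age_hi": stratum.age_hi,
        }
        rows.append(
            common | {"measure": "events", "attributable": attr_events, "total": total_events}
        )
        rows.append(
            common
            | {
                "measure": "cost",
                "attributable": _usd(attr_cost, inputs),
                "total": _usd(total_cost, inputs),
            }
        )
    return rows


def run_point(
    inputs: ModelInputs,
    bmi_baselines: dict[StratumKey, BMIDistribution] | None = None,
    n_points: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full deterministic pipeline at the inputs' point values.

    Returns a long-format frame (one row per condition x stratum x measure)
    with attributable and all-cause total columns; costs are in USD.
    """
    if bmi_baselines is None:
        bmi_baselines = prepare_bmi_baselines(inputs, n_points=n_points, seed=seed)

    rows: list[dict] = []
    direct = paf_table_direct(inputs) if inputs.direct_risks() else None

    # counterfactual BMI distributions for adult strata (indirect pathway)
    cf_cache: dict[StratumKey, BMIDistribution] = {}
    for stratum in inputs.adult_strata:
        base = bmi_baselines.get(stratum.key)
        if base is not None:
            exposure = ExposureDistribution.point_mass(
                inputs.consumption[stratum.key].mean_servings
            )
            cf_cache[stratum.key] = counterfactual_bmi(
                base, exposure, inputs.bmi_effect, is_adult=True
            )

    direct_diseases = {r.disease for r in inputs.direct_risks()}
    indirect_by_disease = {r.disease: r for r in inputs.indirect_risks()}

    for disease, epi in inputs.diseases.items():
        basis = inputs.config.basis_of(disease)
        for stratum in inputs.adult_strata:
            if epi.sex is not None and stratum.sex != epi.sex:
                continue
            totals = total_burden(epi, stratum, inputs.life_table, basis=basis)
            if disease in direct_diseases:
                paf_inc = direct.get(disease, stratum.key, INCIDENCE)
                paf_mort = direct.get(disease, stratum.key, MORTALITY)
            elif disease in indirect_by_disease:
                base = bmi_baselines[stratum.key]
                paf_inc = paf_mort = paf_indirect(
                    base, cf_cache[stratum.key], indirect_by_disease[disease]
                )
            else:
                continue  # condition carried in the tables but not modelled
            attr = attribute(
                paf_inc, totals, disease, stratum.key, paf_mortality=paf_mort
            )
            common = {
                "disease": disease,
                "group": inputs.config.group_of(disease),
                "sex": stratum.sex,
                "age_lo": stratum.age_lo,
                "age_hi": stratum.age_hi,
            }
            for measure in MEASURES:
                total_v = getattr(totals, measure)
                attr_v = getattr(attr, measure)
                if measure == "cost":
                    total_v = _usd(total_v, inputs)
                    attr_v = _usd(attr_v, inputs)
                rows.append(
                    common
                    | {"measure": measure, "attributable": attr_v, "total": total_v}
                )

    rows.extend(_weight_rows(inputs, bmi_baselines))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
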