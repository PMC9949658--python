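"""Synthetic input generation with known ground truth.

Generators emit complete, internally consistent ``ModelInputs`` so every
pipeline stage is testable without external data:

* consumption means are Gamma-distributed (non-negative, right-skewed, like
  survey intake data);
* BMI summaries are derived from an actual log-normal, so the printed mean
  and category prevalences are always mutually feasible;
* disease rates are drawn log-uniformly within the ranges spanned by the
  packaged country table.

``generate_known_truth`` inverts the PAF equation: it picks theta so that
``1 - 1/theta**x`` equals a requested PAF exactly, yielding inputs whose
attributable burden is known in closed form for parameter-recovery and
interval-coverage tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

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

__all__ = ["StrataSpec", "generate_population", "generate_known_truth", "KnownTruth"]

#: flat synthetic life table: residual life expectancy 40 y at every age
_FLAT_EX = 40.0


def _flat_life_table(ex: float = _FLAT_EX) -> LifeTable:
    rows = [(s, a, ex) for s in ("female", "male") for a in (0, 100)]
    return LifeTable(pd.DataFrame(rows, columns=["sex", "age", "ex"]))


@dataclass(frozen=True)
class StrataSpec:
    """Layout of a synthetic population: (sex, age_lo, age_hi, population)."""

    cells: tuple[tuple[str, int, int, float], ...]

    @classmethod
    def argentina_like(cls) -> "StrataSpec":
        return cls(tuple((s[0], s[1], s[2], s[3]) for s in fixtures._STRATA))

    @classmethod
    def minimal(cls) -> "StrataSpec":
        return cls((("female", 18, 200, 1e6),))


def _synthetic_bmi_profile(
    rng: np.random.Generator, key, child: bool
) -> BMIProfile:
    """Draw log-normal parameters, then report its exact summary statistics."""
    if child:
        mu = rng.uniform(np.log(17.5), np.log(21.0))
        sigma = rng.uniform(0.14, 0.20)
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        ow = float(dist.cdf(30.0) - dist.cdf(25.0))
        ob = float(dist.sf(30.0))
        # keep both categories populated so the two-parameter fit is exact
        ow, ob = max(ow, 0.01), max(ob, 0.005)
        return BMIProfile(key, None, ow, ob)
    mu = rng.uniform(np.log(25.0), np.log(29.0))
    sigma = rng.uniform(0.15, 0.22)
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    mean = float(dist.mean())
    cuts = [25.0, 30.0, 35.0, 40.0, np.inf]
    masses = [float(dist.cdf(b) - dist.cdf(a)) for a, b in zip(cuts[:-1], cuts[1:])]
    return BMIProfile(key, mean, *masses)


def generate_population(
    spec: StrataSpec | str = "argentina2020", seed: int = 0
) -> ModelInputs:
    """Generate a complete synthetic input set (deterministic per seed).

    ``spec`` may be a :class:`StrataSpec` or a preset name:
    ``"argentina2020"`` (the packaged country fixture, returned as-is),
    ``"argentina-like"`` (the country's strata layout with generated
    epidemiology) or ``"minimal"`` (one closed-form-checkable stratum).
    """
    if spec == "argentina2020":
        return fixtures.argentina_inputs()
    if spec == "argentina-like":
        spec = StrataSpec.argentina_like()
    elif spec == "minimal":
        spec = StrataSpec.minimal()
    if not isinstance(spec, StrataSpec) or not spec.cells:
        raise ValidationError("empty or invalid strata specification")

    rng = np.random.default_rng(seed)
    strata, consumption, bmi = [], {}, {}
    for sex, lo, hi, pop in spec.cells:
        s = Stratum(sex, lo, hi, pop)
        strata.append(s)
        mean = float(rng.gamma(shape=4.0, scale=0.3))  # mean 1.2 servings/day
        consumption[s.key] = ConsumptionProfile(s.key, mean, max(0.05 * mean, 0.02))
        bmi[s.key] = _synthetic_bmi_profile(rng, s.key, child=not s.is_adult)

    # one direct-pathway condition plus a few BMI-mediated ones, with rates
    # log-uniform within the country table's ranges
    def rates():
        return (
            float(np.exp(rng.uniform(np.log(15), np.log(1000)))),  # incidence
            float(np.exp(rng.uniform(np.log(100), np.log(15000)))),  # prevalence
            float(np.exp(rng.uniform(np.log(1), np.log(400)))),  # mortality
        )

    diseases, risks = {}, []
    inc, prev, mort = rates()
    diseases["diabetes_like"] = DiseaseEpi(
        "diabetes_like", "diabetes", inc, prev, mort,
        float(rng.uniform(0.02, 0.2)),
        cost_incident=0.0, cost_prevalent=float(rng.uniform(100, 2000)),
    )
    risks.append(
        RiskFunction(
            "diabetes_like", "direct", "incidence",
            *(lambda r: (r, r - 0.1, r + 0.1))(float(rng.uniform(1.2, 1.5))),
        )
    )
    for i in range(3):
        name = f"bmi_condition_{i}"
        inc, prev, mort = rates()
        diseases[name] = DiseaseEpi(
            name, "other", inc, prev, mort,
            float(rng.uniform(0.0, 0.3)),
            cost_incident=float(rng.uniform(0, 10000)),
            cost_prevalent=float(rng.uniform(50, 5000)),
        )
        rr = float(rng.uniform(1.02, 1.10))
        risks.append(
            RiskFunction(name, "bmi_mediated", "incidence",
                         rr, rr - 0.01, rr + 0.01, reference_bmi=22.5)
        )

    config = ModelConfig(
        groups={d: e.group for d, e in diseases.items()},
        events_basis={"diabetes_like": "prevalent"},
    )
    return ModelInputs(
        strata=strata,
        consumption=consumption,
        bmi=bmi,
        bmi_effect=BMIEffectModel(),
        risk_functions=risks,
        diseases=diseases,
        economics=EconomicConfig(),
        life_table=_flat_life_table(),
        config=config,
        weight_costs=dict(fixtures._WEIGHT_COSTS),
    ).validate()


# ---------------------------------------------------------------------------
# known-truth construction


@dataclass(frozen=True)
class KnownTruth:
    """Closed-form attributable burden implied by a constructed input set."""

    paf: float
    events: float
    deaths: float
    ylds: float
    ylls: float
    dalys: float
    cost: float
    total_events: float
    total_deaths: float


def generate_known_truth(
    paf_target: float,
    seed: int = 0,
    population: float = 1e6,
    consumption_se: float = 0.05,
    rr_ci_halfwidth: float = 0.05,
) -> tuple[ModelInputs, KnownTruth]:
    """Construct inputs whose attributable burden is known analytically.

    With a point-mass exposure at 1 serving/day and theta = 1/(1 - paf),
    the direct-pathway PAF is exactly ``paf_target``; every attributable
    quantity is then PAF x the closed-form all-cause total.  The returned
    uncertainty specification (consumption SE, RR CI) is centred on the true
    values, for interval-coverage testing.
    """
    if not (0 <= paf_target < 1):
        raise ValidationError(f"paf_target must be in [0, 1), got {paf_target}")
    rng = np.random.default_rng(seed)
    theta = 1.0 / (1.0 - paf_target)

    s = Stratum("female", 18, 200, population)
    inc = float(rng.uniform(100, 500))
    prev = float(rng.uniform(1000, 12000))
    mort = float(rng.uniform(10, 100))
    dw = float(rng.uniform(0.02, 0.2))
    cost_prev = float(rng.uniform(100, 2000))

    half = min(rr_ci_halfwidth, 0.5 * (theta - 1e-3))
    inputs = ModelInputs(
        strata=[s],
        consumption={s.key: ConsumptionProfile(s.key, 1.0, consumption_se)},
        bmi={},
        bmi_effect=BMIEffectModel(),
        risk_functions=[
            RiskFunction("target_disease", "direct", "incidence",
                         theta, theta - half, theta + half)
        ],
        diseases={
            "target_disease": DiseaseEpi(
                "target_disease", "diabetes", inc, prev, mort, dw,
                cost_incident=0.0, cost_prevalent=cost_prev,
            )
        },
        economics=EconomicConfig(),
        life_table=_flat_life_table(),
        config=ModelConfig(
            groups={"target_disease": "diabetes"},
            events_basis={"target_disease": "prevalent"},
        ),
    ).validate()

    prevalent = prev * population / 1e5
    deaths = mort * population / 1e5
    ylds = prevalent * dw
    ylls = deaths * _FLAT_EX
    truth = KnownTruth(
        paf=paf_target,
        events=paf_target * prevalent,
        deaths=paf_target * deaths,
        ylds=paf_target * ylds,
        ylls=paf_target * ylls,
        dalys=paf_target * (ylds + ylls),
        cost=paf_target * prevalent * cost_prev,
        total_events=prevalent,
        total_deaths=deaths,
    )
    return inputs, truth
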