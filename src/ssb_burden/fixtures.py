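"""Packaged Argentina 2020 input fixture.

These constants transcribe the published country tables: population, mean
daily SSB intake and BMI summaries by sex and age band; per-condition rates
(per 100,000), disability weights and per-case costs in 2020 USD (exchange
rate ARS 48.14 per USD); the published per-serving relative risks for the
direct pathway; and the published per-condition attributable/total burden
table consumed by the reporting stage.

Quantities the publication does not print are shipped as clearly labelled
SYNTHETIC placeholders so the pipeline is runnable end to end:

* standard errors of SSB consumption (5% of the stratum mean, floor 0.02),
* the 95% CI of the diabetes per-serving RR (the point value 1.37 is
  published without one),
* BMI-mediated per-kg/m^2 RRs above a reference BMI of 22.5 (the source
  cites GBD values without printing them),
* an abridged residual life expectancy table.

Country users replace these through the same delimited-table schema.
"""

from __future__ import annotations

import pandas as pd

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
)

OPEN_AGE = 200  # sentinel for open-ended age bands

# (sex, age_lo, age_hi, population, servings/day, mean BMI, ow, ob1, ob2, ob3)
_STRATA = [
    ("female", 18, 44, 8.4e6, 1.1, 26.7, 0.274, 0.149, 0.069, 0.037),
    ("female", 45, 64, 4.3e6, 0.8, 29.4, 0.296, 0.273, 0.090, 0.065),
    ("female", 65, OPEN_AGE, 2.8e6, 0.5, 29.8, 0.339, 0.263, 0.108, 0.063),
    ("male", 18, 44, 8.7e6, 1.7, 26.9, 0.355, 0.171, 0.056, 0.020),
    ("male", 45, 64, 4.0e6, 1.2, 29.5, 0.427, 0.279, 0.096, 0.026),
    ("male", 65, OPEN_AGE, 2.0e6, 0.6, 29.2, 0.430, 0.287, 0.090, 0.021),
    # children: no mean BMI published; two categories (overweight, obesity)
    ("female", 0, 4, 1.8e6, 0.7, None, 0.110, 0.031, 0.0, 0.0),
    ("female", 5, 17, 4.5e6, 1.6, None, 0.223, 0.176, 0.0, 0.0),
    ("male", 0, 4, 1.9e6, 0.7, None, 0.091, 0.040, 0.0, 0.0),
    ("male", 5, 17, 4.7e6, 1.9, None, 0.193, 0.229, 0.0, 0.0),
]

#: published summary consumption rows (not engine strata)
_CONSUMPTION_OVERALL = [
    ("female", 18, OPEN_AGE, 0.8),
    ("male", 18, OPEN_AGE, 1.1),
    ("both", 18, OPEN_AGE, 1.0),
    ("female", 0, 17, 1.4),
    ("male", 0, 17, 1.6),
    ("both", 0, 17, 1.5),
]

# disease, group, sex, incidence, prevalence, mortality, DW, cost_inc, cost_prev
_DISEASES = [
    ("dementia", "other", None, 798, 4311, 483, 0.15, 0, 1206),
    ("asthma", "asthma", None, 251, 4118, 4.84, 0.04, 0, 869),
    ("atrial_fibrillation", "cardiac", None, 139, 2462, 63.11, 0.08, 573, 1804),
    ("ischemic_heart_disease", "cardiac", None, 835, 3409, 476, 0.03, 7613, 1209),
    ("chronic_kidney_disease", "ckd", None, 152, 3019, 21.15, 0.04, 0, 869),
    ("colorectal_cancer", "other", None, 101, 283, 82.01, 0.06, 8780, 1146),
    ("diabetes", "diabetes", None, 356, 12363, 71.91, 0.07, 0, 1414),
    ("esophageal_cancer", "other", None, 16.39, 14.20, 16.16, 0.20, 13529, 9163),
    ("gallbladder_biliary_disease", "other", None, 245, 1010, 12.46, 0.0, 0, 162),
    ("gallbladder_cancer", "other", None, 20.04, 12.13, 19.62, 0.28, 10952, 7497),
    ("hypertensive_heart_disease", "cardiac", None, 812, 1296, 121, 0.08, 0, 1058),
    ("stroke", "cerebrovascular", None, 184, 1371, 133, 0.15, 0, 1718),
    ("subarachnoid_hemorrhage", "cerebrovascular", None, 36.33, 234, 17.28, 0.15, 0, 3298),
    ("kidney_cancer", "other", None, 24.40, 99.26, 13.92, 0.07, 11597, 8122),
    ("low_back_pain", "musculoskeletal", None, 6282, 15901, 0, 0.11, 0, 10),
    ("osteoarthritis", "musculoskeletal", None, 346, 10592, 0, 0.03, 0, 223),
    ("uterine_cancer", "other", "female", 21.87, 120, 10.41, 0.07, 5492, 543),
]

#: annual cost (USD) per prevalent overweight/obesity case
_WEIGHT_COSTS = {
    ("adult", "overweight"): 0.0,
    ("adult", "obesity_1"): 10.0,
    ("adult", "obesity_2"): 139.0,
    ("adult", "obesity_3"): 536.0,
    ("child", "overweight"): 8.0,
    ("child", "obesity"): 24.0,
}

_CVD_DISEASES = (
    "atrial_fibrillation",
    "ischemic_heart_disease",
    "hypertensive_heart_disease",
    "stroke",
    "subarachnoid_hemorrhage",
)

#: diabetes RR CI is SYNTHETIC (point value published without one)
_DIABETES_CI = (1.22, 1.54)

#: BMI-mediated per-kg/m^2 RRs above the reference BMI — SYNTHETIC plausible
#: GBD-like magnitudes; not published values.
_INDIRECT_RRS = {
    "chronic_kidney_disease": (1.06, 1.04, 1.08),
    "asthma": (1.03, 1.02, 1.05),
    "low_back_pain": (1.04, 1.02, 1.06),
    "osteoarthritis": (1.05, 1.03, 1.07),
    "colorectal_cancer": (1.03, 1.02, 1.04),
    "esophageal_cancer": (1.05, 1.02, 1.08),
    "uterine_cancer": (1.09, 1.05, 1.13),
    "kidney_cancer": (1.06, 1.04, 1.08),
    "gallbladder_cancer": (1.05, 1.02, 1.08),
    "gallbladder_biliary_disease": (1.05, 1.03, 1.07),
    "dementia": (1.02, 1.01, 1.04),
}

REFERENCE_BMI = 22.5

_EVENTS_BASIS = {
    "diabetes": "prevalent",
    "low_back_pain": "prevalent",
    "osteoarthritis": "prevalent",
}

#: SYNTHETIC abridged residual life expectancy (years), Argentina-like
_LIFE_TABLE = [
    ("female", 0, 80.0), ("female", 20, 61.0), ("female", 30, 51.5),
    ("female", 40, 42.0), ("female", 50, 33.0), ("female", 60, 24.5),
    ("female", 70, 16.5), ("female", 80, 9.5), ("female", 90, 4.5),
    ("female", 100, 2.0),
    ("male", 0, 73.0), ("male", 20, 55.0), ("male", 30, 45.5),
    ("male", 40, 36.5), ("male", 50, 28.0), ("male", 60, 20.0),
    ("male", 70, 13.0), ("male", 80, 7.5), ("male", 90, 4.0),
    ("male", 100, 2.0),
]


def _consumption_se(mean: float) -> float:
    """SYNTHETIC SE of mean consumption: 5% of the mean, floored at 0.02."""
    return max(0.05 * mean, 0.02)


def argentina_inputs() -> ModelInputs:
    """Build the validated Argentina 2020 model inputs."""
    strata, consumption, bmi = [], {}, {}
    for sex, lo, hi, pop, servings, mean_bmi, ow, ob1, ob2, ob3 in _STRATA:
        s = Stratum(sex, lo, hi, pop)
        strata.append(s)
        consumption[s.key] = ConsumptionProfile(
            s.key, servings, _consumption_se(servings)
        )
        bmi[s.key] = BMIProfile(s.key, mean_bmi, ow, ob1, ob2, ob3)

    overall = [
        ConsumptionProfile((sex, lo, hi), m, _consumption_se(m), is_overall=True)
        for sex, lo, hi, m in _CONSUMPTION_OVERALL
    ]

    risks = [
        RiskFunction("diabetes", "direct", "incidence", 1.37, *_DIABETES_CI)
    ]
    for d in _CVD_DISEASES:
        risks.append(RiskFunction(d, "direct", "incidence", 1.08, 1.04, 1.13))
        risks.append(RiskFunction(d, "direct", "mortality", 1.08, 1.02, 1.14))
    for d, (rr, lo, hi) in _INDIRECT_RRS.items():
        risks.append(
            RiskFunction(d, "bmi_mediated", "incidence", rr, lo, hi, REFERENCE_BMI)
        )

    diseases = {
        row[0]: DiseaseEpi(
            disease=row[0], group=row[1], sex=row[2],
            incidence_rate=row[3], prevalence_rate=row[4], mortality_rate=row[5],
            disability_weight=row[6], cost_incident=row[7], cost_prevalent=row[8],
        )
        for row in _DISEASES
    }

    config = ModelConfig(
        groups={d: e.group for d, e in diseases.items()},
        events_basis=dict(_EVENTS_BASIS),
        reference_bmi=REFERENCE_BMI,
    )
    life_table = LifeTable(pd.DataFrame(_LIFE_TABLE, columns=["sex", "age", "ex"]))

    return ModelInputs(
        strata=strata,
        consumption=consumption,
        bmi=bmi,
        bmi_effect=BMIEffectModel(),
        risk_functions=risks,
        diseases=diseases,
        economics=EconomicConfig(),
        life_table=life_table,
        config=config,
        consumption_overall=overall,
        weight_costs=dict(_WEIGHT_COSTS),
    ).validate()


# ---------------------------------------------------------------------------
# published attributable/total burden table (reporting-stage fixture)
#
# group, sex, measure, attributable, total, ci_lo, ci_hi
# measures: events (cases), deaths, dalys (years), cost (million USD)

TABLE3_ROWS = [
    ("owob_child", "female", "events", 318855, 2053392, 153592, 503791),
    ("owob_child", "male", "events", 455164, 2251656, 219252, 719159),
    ("owob_child", "female", "cost", 5.77, 29.4, 4.2, 8.2),
    ("owob_child", "male", "cost", 9.0, 36.0, 3.6, 15.0),
    ("owob_adult", "female", "events", 169061, 9897071, 117209, 288925),
    ("owob_adult", "male", "events", 351702, 10212675, 243835, 601058),
    ("owob_adult", "female", "cost", 28.08, 619.86, 27.0, 49.0),
    ("owob_adult", "male", "cost", 19.2, 350.0, 18.0, 34.0),
    ("diabetes", "female", "events", 281984, 1406057, 126846, 417421),
    ("diabetes", "male", "events", 356887, 1349033, 169944, 505523),
    ("diabetes", "female", "deaths", 563, 3388, 246, 856),
    ("diabetes", "male", "deaths", 754, 3633, 341, 1114),
    ("diabetes", "female", "dalys", 27007, 139603, 12291, 40445),
    ("diabetes", "male", "dalys", 34925, 138834, 16904, 50282),
    ("diabetes", "female", "cost", 398.80, 1988.55, 181.0, 597.0),
    ("diabetes", "male", "cost", 504.74, 1908.0, 244.0, 727.0),
    ("cardiac", "female", "events", 18456, 437411, 8746, 28439),
    ("cardiac", "male", "events", 35119, 588503, 16866, 53402),
    ("cardiac", "female", "deaths", 740, 18153, 350, 1141),
    ("cardiac", "male", "deaths", 1061, 18844, 508, 1618),
    ("cardiac", "female", "dalys", 7225, 159545, 3420, 11119),
    ("cardiac", "male", "dalys", 15664, 208848, 7528, 23834),
    ("cardiac", "female", "cost", 32.6, 772.0, 15.0, 50.0),
    ("cardiac", "male", "cost", 65.1, 1074.0, 31.0, 99.0),
    ("cerebrovascular", "female", "events", 13606, 283518, 6481, 20855),
    ("cerebrovascular", "male", "events", 15425, 231778, 7453, 23316),
    ("cerebrovascular", "female", "deaths", 482, 11235, 229, 743),
    ("cerebrovascular", "male", "deaths", 574, 9920, 275, 873),
    ("cerebrovascular", "female", "dalys", 8072, 161099, 3843, 12367),
    ("cerebrovascular", "male", "dalys", 10652, 153406, 5155, 16125),
    ("cerebrovascular", "female", "cost", 27.90, 572.93, 13.0, 43.0),
    ("cerebrovascular", "male", "cost", 29.6, 435.0, 15.0, 45.0),
    ("ckd", "female", "events", 11920, 1087740, 7937, 19198),
    ("ckd", "male", "events", 9508, 581952, 6254, 15250),
    ("ckd", "female", "deaths", 37, 3645, 25, 60),
    ("ckd", "male", "deaths", 53, 3536, 35, 87),
    ("ckd", "female", "dalys", 708, 58643, 457, 1104),
    ("ckd", "male", "dalys", 963, 52808, 604, 1473),
    ("ckd", "female", "cost", 10.37, 945.51, 7.0, 16.0),
    ("ckd", "male", "cost", 8.3, 506.0, 5.0, 12.0),
    ("asthma", "female", "events", 7878, 968062, 5223, 12395),
    ("asthma", "male", "events", 8111, 626449, 5330, 12570),
    ("asthma", "female", "deaths", 2, 303, 2, 4),
    ("asthma", "male", "deaths", 2, 183, 1, 3),
    ("asthma", "female", "dalys", 334, 40245, 216, 513),
    ("asthma", "male", "dalys", 341, 25749, 220, 519),
    ("asthma", "female", "cost", 6.86, 841.44, 4.0, 11.0),
    ("asthma", "male", "cost", 7.0, 545.0, 5.0, 11.0),
    ("musculoskeletal", "female", "events", 14652, 5313518, 9741, 23101),
    ("musculoskeletal", "male", "events", 19125, 4143750, 12556, 29894),
    ("musculoskeletal", "female", "deaths", 0, 0, 0, 0),
    ("musculoskeletal", "male", "deaths", 0, 0, 0, 0),
    ("musculoskeletal", "female", "dalys", 1011, 361979, 655, 1554),
    ("musculoskeletal", "male", "dalys", 1386, 294635, 892, 2125),
    ("musculoskeletal", "female", "cost", 0.85, 325.86, 0.55, 1.31),
    ("musculoskeletal", "male", "cost", 0.8, 195.0, 0.5, 1.2),
    ("other", "female", "events", 6311, 581030, 4195, 9877),
    ("other", "male", "events", 2870, 280495, 1889, 4612),
    ("other", "female", "deaths", 81, 19838, 53, 131),
    ("other", "male", "deaths", 76, 13122, 50, 128),
    ("other", "female", "dalys", 910, 191118, 590, 1389),
    ("other", "male", "dalys", 1093, 155555, 694, 1695),
    ("other", "female", "cost", 3.26, 553.22, 2.0, 5.0),
    ("other", "male", "cost", 3.6, 489.0, 3.0, 6.0),
]

TABLE3_COLUMNS = ["group", "sex", "measure", "attributable", "total", "lo", "hi"]


def table3_observed() -> pd.DataFrame:
    """Published per-condition, per-sex attributable/total burden rows."""
    return pd.DataFrame(TABLE3_ROWS, columns=TABLE3_COLUMNS)
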