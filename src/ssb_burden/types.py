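"""Domain types for the comparative risk assessment model.

The model is organised around population strata (sex x age band), each
carrying an SSB consumption summary and, for the BMI-mediated pathway, a
BMI profile.  Diseases carry epidemiological rates (per 100,000), a
disability weight and a per-case cost schedule.  Relative risks come in two
flavours: *direct* dose-response RRs per daily serving (type-2 diabetes and
cardiovascular disease) and *BMI-mediated* RRs per kg/m^2 above a reference
BMI (all other modelled conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "DoubleCountingError",
    "FEMALE",
    "MALE",
    "SEXES",
    "ADULT_AGE",
    "BMI_CUTOFFS",
    "ADULT_CATEGORIES",
    "CHILD_CATEGORIES",
    "StratumKey",
    "Stratum",
    "ConsumptionProfile",
    "RiskFunction",
    "BMIEffectModel",
    "BMIProfile",
    "DiseaseEpi",
    "EconomicConfig",
    "LifeTable",
    "ModelConfig",
    "PafTable",
    "ModelInputs",
]


class ValidationError(ValueError):
    """Raised when model inputs violate the schema or an invariant."""


class DoubleCountingError(ValidationError):
    """Raised when a risk function would count an effect twice.

    The direct per-serving pathway covers type-2 diabetes and cardiovascular
    disease; supplying a BMI-mediated RR for those conditions (or a direct RR
    for any other condition) would double-count the exposure effect.
    """


FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: age (in completed years) at which the adult pathway starts
ADULT_AGE = 18

#: WHO BMI category cutoffs (kg/m^2): overweight / obesity grades 1-3
BMI_CUTOFFS = (25.0, 30.0, 35.0, 40.0)
ADULT_CATEGORIES = ("overweight", "obesity_1", "obesity_2", "obesity_3")
CHILD_CATEGORIES = ("overweight", "obesity")

#: (sex, age_lo, age_hi) triple used to key per-stratum tables
StratumKey = tuple[str, int, int]


@dataclass(frozen=True)
class Stratum:
    """One (sex, age band) population cell."""

    sex: str
    age_lo: int
    age_hi: int  # inclusive; open-ended bands use a large sentinel (e.g. 200)
    population: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_lo < 0 or self.age_hi < self.age_lo:
            raise ValidationError(
                f"bad age band [{self.age_lo}, {self.age_hi}] for {self.sex}"
            )
        if not np.isfinite(self.population) or self.population < 0:
            raise ValidationError(f"population must be >= 0, got {self.population}")

    @property
    def key(self) -> StratumKey:
        return (self.sex, self.age_lo, self.age_hi)

    @property
    def is_adult(self) -> bool:
        return self.age_lo >= ADULT_AGE

    @property
    def midpoint_age(self) -> float:
        hi = min(self.age_hi, 90)  # cap open-ended bands for life-table lookup
        return 0.5 * (self.age_lo + hi)


@dataclass(frozen=True)
class ConsumptionProfile:
    """Mean daily SSB intake for a stratum (1 serving = 240 ml)."""

    stratum: StratumKey
    mean_servings: float
    se_servings: float = 0.0
    is_overall: bool = False  # printed summary row, excluded from the engine

    def __post_init__(self) -> None:
        if self.mean_servings < 0 or self.se_servings < 0:
            raise ValidationError(
                f"consumption mean/se must be >= 0 for stratum {self.stratum}"
            )


DIRECT = "direct"
BMI_MEDIATED = "bmi_mediated"
INCIDENCE = "incidence"
MORTALITY = "mortality"


@dataclass(frozen=True)
class RiskFunction:
    """A dose-response relative risk.

    ``rr_per_unit`` is per daily serving for the direct pathway, and per
    kg/m^2 of BMI above ``reference_bmi`` for the BMI-mediated pathway.
    """

    disease: str
    pathway: str  # "direct" | "bmi_mediated"
    outcome: str  # "incidence" | "mortality"
    rr_per_unit: float
    ci_lo: float
    ci_hi: float
    reference_bmi: float | None = None

    def __post_init__(self) -> None:
        if self.pathway not in (DIRECT, BMI_MEDIATED):
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if self.outcome not in (INCIDENCE, MORTALITY):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if not (0 < self.ci_lo <= self.rr_per_unit <= self.ci_hi):
            raise ValidationError(
                f"RR CI must satisfy 0 < lo <= rr <= hi for {self.disease}: "
                f"{self.ci_lo}, {self.rr_per_unit}, {self.ci_hi}"
            )
        if self.pathway == BMI_MEDIATED and self.reference_bmi is None:
            raise ValidationError(
                f"bmi_mediated risk for {self.disease} needs a reference_bmi"
            )

    @property
    def rr_sd(self) -> float:
        """Normal-approximation SD from the 95% CI: (hi - lo) / 3.92."""
        return (self.ci_hi - self.ci_lo) / 3.92


@dataclass(frozen=True)
class BMIEffectModel:
    """Per-serving BMI shift (kg/m^2 per daily serving).

    Adults gain 0.10 kg/m^2 per serving when baseline BMI < 25 and
    0.23 kg/m^2 when baseline BMI >= 25; children gain 0.57/1.7 kg/m^2
    per serving (a 0.57 kg/m^2 contrast observed for a 1.7 serving change,
    assumed linear).
    """

    delta_low: float = 0.10
    delta_low_ci: tuple[float, float] = (0.05, 0.15)
    delta_high: float = 0.23
    delta_high_ci: tuple[float, float] = (0.14, 0.32)
    delta_child: float = 0.57 / 1.7
    delta_child_ci: tuple[float, float] = (0.2, 0.47)

    def __post_init__(self) -> None:
        if min(self.delta_low, self.delta_high, self.delta_child) < 0:
            raise ValidationError("BMI deltas must be >= 0")


@dataclass(frozen=True)
class BMIProfile:
    """Mean BMI and WHO category prevalences for a stratum.

    ``mean_bmi`` may be None for child strata (only category prevalences are
    used there); adults require it.  Children use two categories
    (overweight, obesity) carried in ``prev_overweight`` / ``prev_ob1``.
    """

    stratum: StratumKey
    mean_bmi: float | None
    prev_overweight: float
    prev_ob1: float
    prev_ob2: float = 0.0
    prev_ob3: float = 0.0

    def __post_init__(self) -> None:
        prevs = self.prevalences
        if any(not (0 <= p <= 1) for p in prevs):
            raise ValidationError(f"prevalences must be in [0,1] for {self.stratum}")
        if sum(prevs) > 1 + 1e-9:
            raise ValidationError(
                f"category prevalences sum to {sum(prevs):.4f} > 1 for {self.stratum}"
            )

    @property
    def prevalences(self) -> tuple[float, float, float, float]:
        return (self.prev_overweight, self.prev_ob1, self.prev_ob2, self.prev_ob3)

    @property
    def prev_excess(self) -> float:
        """Total overweight-or-obese mass (BMI >= 25)."""
        return sum(self.prevalences)


@dataclass(frozen=True)
class DiseaseEpi:
    """One condition's rates (per 100,000), disability weight and costs."""

    disease: str
    group: str
    incidence_rate: float
    prevalence_rate: float
    mortality_rate: float
    disability_weight: float
    cost_incident: float = 0.0
    cost_prevalent: float = 0.0
    sex: str | None = None  # restrict to one sex (e.g. uterine cancer)

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"{self.disease}: unknown sex restriction {self.sex!r}")
        for name in ("incidence_rate", "prevalence_rate", "mortality_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.disease}: {name} must be >= 0")
        if not (0 <= self.disability_weight <= 1):
            raise ValidationError(f"{self.disease}: disability weight not in [0,1]")
        if self.cost_incident < 0 or self.cost_prevalent < 0:
            raise ValidationError(f"{self.disease}: costs must be >= 0")


@dataclass(frozen=True)
class EconomicConfig:
    """Currency and macro-economic context for cost reporting."""

    exchange_rate: float = 48.14  # local currency units per USD
    gdp_per_capita: float = 9912.0
    health_expenditure_share: float = 0.091
    currency: str = "USD"  # currency of the cost inputs: "USD" | "local"

    def __post_init__(self) -> None:
        if self.exchange_rate <= 0:
            raise ValidationError("exchange_rate must be > 0")


class LifeTable:
    """Residual life expectancy by sex and age, linearly interpolated."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "ex"}
        if not required.issubset(table.columns):
            raise ValidationError(f"life table needs columns {sorted(required)}")
        self._by_sex = {
            sex: g.sort_values("age")[["age", "ex"]].to_numpy(dtype=float)
            for sex, g in table.groupby("sex")
        }
        self.frame = table.reset_index(drop=True)

    def residual_le(self, sex: str, age: float) -> float:
        if sex not in self._by_sex:
            raise ValidationError(f"life table does not cover sex {sex!r}")
        ages, ex = self._by_sex[sex].T
        if age > ages[-1]:
            raise ValidationError(f"life table does not cover age {age} for {sex}")
        return float(np.interp(age, ages, ex))


@dataclass(frozen=True)
class ModelConfig:
    """Engine configuration.

    ``groups`` maps each disease to a reporting group; ``events_basis`` maps a
    disease to "incident" or "prevalent" (which rate counts as "events");
    ``dose_response`` selects the direct-pathway RR scaling ("exponential"
    theta**x, or "linear" 1 + (theta-1)x for sensitivity analysis).
    """

    groups: Mapping[str, str] = field(default_factory=dict)
    events_basis: Mapping[str, str] = field(default_factory=dict)
    dose_response: str = "exponential"
    reference_bmi: float = 22.5
    sample_bmi_deltas: bool = False

    #: groups reachable by the direct per-serving pathway
    direct_groups: tuple[str, ...] = ("diabetes", "cardiac", "cerebrovascular")

    def group_of(self, disease: str) -> str:
        try:
            return self.groups[disease]
        except KeyError:
            raise ValidationError(f"disease {disease!r} not mapped to a group")

    def basis_of(self, disease: str) -> str:
        return self.events_basis.get(disease, "incident")


class PafTable:
    """PAF per (disease, stratum, outcome)."""

    def __init__(self, entries: dict[tuple[str, StratumKey, str], float] | None = None):
        self.entries: dict[tuple[str, StratumKey, str], float] = dict(entries or {})

    def set(self, disease: str, stratum: StratumKey, outcome: str, paf: float) -> None:
        self.entries[(disease, stratum, outcome)] = float(paf)

    def get(self, disease: str, stratum: StratumKey, outcome: str) -> float:
        return self.entries[(disease, stratum, outcome)]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "disease": d,
                "sex": s[0],
                "age_lo": s[1],
                "age_hi": s[2],
                "outcome": o,
                "paf": p,
            }
            for (d, s, o), p in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["disease", "sex", "age_lo", "age_hi", "outcome", "paf"]
        )


@dataclass
class ModelInputs:
    """Validated, cross-referenced model inputs."""

    strata: list[Stratum]
    consumption: dict[StratumKey, ConsumptionProfile]
    bmi: dict[StratumKey, BMIProfile]
    bmi_effect: BMIEffectModel
    risk_functions: list[RiskFunction]
    diseases: dict[str, DiseaseEpi]
    economics: EconomicConfig
    life_table: LifeTable
    config: ModelConfig
    consumption_overall: list[ConsumptionProfile] = field(default_factory=list)
    #: annual cost per prevalent case, keyed by ("adult"|"child", category)
    weight_costs: dict[tuple[str, str], float] = field(default_factory=dict)

    # -- convenience -------------------------------------------------------

    def stratum(self, key: StratumKey) -> Stratum:
        for s in self.strata:
            if s.key == key:
                return s
        raise KeyError(key)

    @property
    def adult_strata(self) -> list[Stratum]:
        return [s for s in self.strata if s.is_adult]

    @property
    def child_strata(self) -> list[Stratum]:
        return [s for s in self.strata if not s.is_adult]

    def total_population(self, adults: bool | None = None) -> float:
        return sum(
            s.population
            for s in self.strata
            if adults is None or s.is_adult == adults
        )

    def direct_risks(self) -> list[RiskFunction]:
        return [r for r in self.risk_functions if r.pathway == DIRECT]

    def indirect_risks(self) -> list[RiskFunction]:
        return [r for r in self.risk_functions if r.pathway == BMI_MEDIATED]

    def with_overrides(self, **kwargs) -> "ModelInputs":
        return replace(self, **kwargs)

    # -- validation --------------------------------------------------------

    def validate(self) -> "ModelInputs":
        if not self.strata:
            raise ValidationError("no population strata supplied")
        seen: set[StratumKey] = set()
        for s in self.strata:
            if s.key in seen:
                raise ValidationError(f"duplicate stratum {s.key}")
            seen.add(s.key)
        _check_age_coverage(self.strata)

        missing = [s.key for s in self.strata if s.key not in self.consumption]
        if missing:
            raise ValidationError(f"strata without consumption data: {missing}")

        risk_diseases = {r.disease for r in self.risk_functions}
        unknown = risk_diseases - set(self.diseases)
        if unknown:
            raise ValidationError(f"risk functions for unknown diseases: {sorted(unknown)}")
        for d in self.diseases.values():
            self.config.group_of(d.disease)  # raises if unmapped

        for r in self.risk_functions:
            grp = self.config.group_of(r.disease)
            if r.pathway == DIRECT and grp not in self.config.direct_groups:
                raise DoubleCountingError(
                    f"direct RR supplied for {r.disease} (group {grp}); the direct "
                    "pathway is restricted to diabetes and cardiovascular disease"
                )
            if r.pathway == BMI_MEDIATED and grp in self.config.direct_groups:
                raise DoubleCountingError(
                    f"BMI-mediated RR supplied for {r.disease} (group {grp}); "
                    "diabetes and cardiovascular disease already carry direct RRs"
                )

        if self.indirect_risks() or self.bmi:
            missing_bmi = [
                s.key
                for s in self.strata
                if s.key not in self.bmi
            ]
            if missing_bmi:
                raise ValidationError(f"strata without BMI profile: {missing_bmi}")
            for s in self.adult_strata:
                if self.bmi[s.key].mean_bmi is None:
                    raise ValidationError(f"adult stratum {s.key} lacks mean BMI")
        return self


def _check_age_coverage(strata: Iterable[Stratum]) -> None:
    """Age bands within one sex must not overlap and must leave no gap."""
    by_sex: dict[str, list[Stratum]] = {}
    for s in strata:
        by_sex.setdefault(s.sex, []).append(s)
    for sex, cells in by_sex.items():
        cells = sorted(cells, key=lambda s: s.age_lo)
        for a, b in zip(cells, cells[1:]):
            if b.age_lo <= a.age_hi:
                raise ValidationError(
                    f"overlapping age bands for {sex}: "
                    f"[{a.age_lo},{a.age_hi}] and [{b.age_lo},{b.age_hi}]"
                )
            if b.age_lo != a.age_hi + 1:
                raise ValidationError(
                    f"age gap for {sex} between {a.age_hi} and {b.age_lo}"
                )
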