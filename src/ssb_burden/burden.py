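"""Attribution of disease burden: events, deaths, DALYs and costs.

All-cause totals per condition and stratum are computed from rates per
100,000 (counts = rate x population / 100,000); YLD = prevalent cases x
disability weight, YLL = deaths x residual life expectancy at the stratum
age midpoint, DALY = YLD + YLL.  The attributable share of each quantity is
PAF x total, applied per stratum (attribution is linear, so it commutes with
aggregation over strata).
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import (
    DiseaseEpi,
    EconomicConfig,
    LifeTable,
    Stratum,
    ValidationError,
)

__all__ = ["Totals", "AttributableBurden", "total_burden", "attribute", "convert_currency"]


@dataclass(frozen=True)
class Totals:
    """All-cause quantities for one condition in one stratum."""

    events: float
    deaths: float
    ylds: float
    ylls: float
    cost: float

    @property
    def dalys(self) -> float:
        return self.ylds + self.ylls


@dataclass(frozen=True)
class AttributableBurden:
    """Attributable quantities for one condition in one stratum."""

    disease: str
    stratum: tuple
    events: float
    deaths: float
    ylds: float
    ylls: float
    cost: float

    @property
    def dalys(self) -> float:
        return self.ylds + self.ylls


def total_burden(
    epi: DiseaseEpi,
    stratum: Stratum,
    life_table: LifeTable,
    basis: str = "incident",
) -> Totals:
    """All-cause events, deaths, YLD/YLL and cost for a condition x stratum.

    ``basis`` selects whether "events" counts incident cases per year or
    prevalent cases (chronic-state conditions such as diabetes).
    """
    if basis not in ("incident", "prevalent"):
        raise ValidationError(f"unknown events basis {basis!r}")
    pop = stratum.population
    incident = epi.incidence_rate * pop / 1e5
    prevalent = epi.prevalence_rate * pop / 1e5
    deaths = epi.mortality_rate * pop / 1e5
    ylds = prevalent * epi.disability_weight
    ylls = (
        deaths * life_table.residual_le(stratum.sex, stratum.midpoint_age)
        if deaths > 0
        else 0.0
    )
    cost = incident * epi.cost_incident + prevalent * epi.cost_prevalent
    return Totals(
        events=incident if basis == "incident" else prevalent,
        deaths=deaths,
        ylds=ylds,
        ylls=ylls,
        cost=cost,
    )


def attribute(
    paf: float,
    totals: Totals,
    disease: str = "",
    stratum: tuple = (),
    paf_mortality: float | None = None,
) -> AttributableBurden:
    """Attributable burden = PAF x total, per quantity.

    A separate mortality PAF may be supplied (cardiovascular disease carries
    its own mortality RR); it scales deaths and YLL, while events, YLD and
    cost follow the incidence/prevalence PAF.
    """
    paf_m = paf if paf_mortality is None else paf_mortality
    return AttributableBurden(
        disease=disease,
        stratum=stratum,
        events=paf * totals.events,
        deaths=paf_m * totals.deaths,
        ylds=paf * totals.ylds,
        ylls=paf_m * totals.ylls,
        cost=paf * totals.cost,
    )


def convert_currency(amount: float, config: EconomicConfig) -> float:
    """Convert a local-currency amount to USD at the configured rate."""
    if config.exchange_rate <= 0:
        raise ValidationError("exchange rate must be > 0")
    return amount / config.exchange_rate
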