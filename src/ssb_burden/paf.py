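"""Population attributable fraction (PAF) engine for the direct pathway.

The PAF compares the current burden of a condition with the burden under a
counterfactual of zero SSB consumption:

    PAF = 1 - 1 / E[RR(X; theta)]

where X is daily SSB consumption (servings) over the population and
``theta`` is the relative risk per one daily serving.  Dose-response is
log-linear by default, RR(x) = theta**x, matching RRs reported per one-unit
serving increase; a linear alternative 1 + (theta - 1) x is available for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import (
    INCIDENCE,
    MORTALITY,
    ModelInputs,
    PafTable,
    ValidationError,
)

__all__ = ["ExposureDistribution", "rr_at_dose", "paf", "paf_table_direct"]


@dataclass(frozen=True)
class ExposureDistribution:
    """A discrete consumption distribution (servings/day with weights).

    ``point_mass(m)`` builds the one-point distribution used when only a
    stratum mean is available; ``from_sample`` builds an equally weighted
    empirical distribution.
    """

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)
        if v.size == 0:
            raise ValidationError("empty exposure distribution")
        if v.shape != w.shape:
            raise ValidationError("exposure values and weights differ in shape")
        if np.any(v < 0):
            raise ValidationError("exposure values must be >= 0")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("exposure weights must be >= 0 and sum to 1")

    @classmethod
    def point_mass(cls, servings: float) -> "ExposureDistribution":
        return cls(np.array([float(servings)]), np.array([1.0]))

    @classmethod
    def from_sample(cls, servings: np.ndarray) -> "ExposureDistribution":
        v = np.asarray(servings, dtype=float)
        return cls(v, np.full(v.shape, 1.0 / v.size))

    @property
    def mean(self) -> float:
        return float(self.values @ self.weights)


def rr_at_dose(theta: float, x, form: str = "exponential"):
    """Relative risk at dose ``x`` servings/day for a per-serving RR ``theta``."""
    if theta <= 0:
        raise ValidationError(f"theta must be > 0, got {theta}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("dose must be >= 0")
    if form == "exponential":
        out = theta ** x
    elif form == "linear":
        out = 1.0 + (theta - 1.0) * x
    else:
        raise ValidationError(f"unknown dose-response form {form!r}")
    return float(out) if out.ndim == 0 else out


def paf(exposure: ExposureDistribution, theta: float, form: str = "exponential") -> float:
    """PAF for a discrete exposure distribution: 1 - 1 / E[RR].

    For theta >= 1 the result lies in [0, 1).  A protective theta < 1 is
    accepted (it arises when sampling RRs inside Monte Carlo) and yields a
    negative PAF, retained unclipped with a warning.
    """
    mean_rr = float(rr_at_dose(theta, exposure.values, form=form) @ exposure.weights)
    value = 1.0 - 1.0 / mean_rr
    if theta >= 1:
        return max(0.0, value)  # guard float round-off at zero dose
    if theta < 1 and value < 0:
        warnings.warn(
            f"theta={theta} < 1 yields a negative PAF ({value:.4g}); retained",
            stacklevel=2,
        )
    return value


def paf_table_direct(inputs: ModelInputs) -> PafTable:
    """Direct-pathway PAFs per (disease, stratum, outcome).

    An incidence RR is applied to events and prevalence; where no separate
    mortality RR is configured for a disease (type-2 diabetes), the incidence
    RR also covers deaths — a single per-serving association is assumed to
    move prevalent cases and mortality alike.
    """
    table = PafTable()
    form = inputs.config.dose_response
    by_disease: dict[str, dict[str, float]] = {}
    for r in inputs.direct_risks():
        by_disease.setdefault(r.disease, {})[r.outcome] = r.rr_per_unit

    for stratum in inputs.adult_strata:
        profile = inputs.consumption.get(stratum.key)
        if profile is None:
            raise ValidationError(f"no consumption data for stratum {stratum.key}")
        exposure = ExposureDistribution.point_mass(profile.mean_servings)
        for disease, thetas in by_disease.items():
            theta_inc = thetas.get(INCIDENCE)
            if theta_inc is None:
                raise ValidationError(
                    f"direct risk for {disease} lacks an incidence RR"
                )
            theta_mort = thetas.get(MORTALITY, theta_inc)
            table.set(disease, stratum.key, INCIDENCE, paf(exposure, theta_inc, form))
            table.set(disease, stratum.key, MORTALITY, paf(exposure, theta_mort, form))
    return table
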