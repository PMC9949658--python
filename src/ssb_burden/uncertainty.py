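"""Monte Carlo propagation of input uncertainty.

Per iteration, each relative risk is redrawn from a normal distribution with
SD = (CI_hi - CI_lo)/3.92 (one draw per unique RR specification, shared by
all strata — the RR is a global parameter), and each stratum's mean
consumption is redrawn from normal(mean, SE), truncated at zero.  The full
deterministic pipeline then runs and aggregated outputs are collected; the
report carries the iteration mean and the 2.5/97.5 percentile interval.

RR draws are floored at 1e-6 (positive support); a log-normal sampling
alternative is available.  Per-serving BMI deltas can optionally be sampled
from their CIs (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import prepare_bmi_baselines, run_point
from .reporting import BurdenResult, aggregate
from .types import (
    BMIEffectModel,
    ConsumptionProfile,
    ModelInputs,
    RiskFunction,
    ValidationError,
)

__all__ = ["McConfig", "McResult", "run_mc"]

RR_FLOOR = 1e-6


@dataclass(frozen=True)
class McConfig:
    n_iter: int = 1000
    seed: int = 0
    rr_sampling: str = "normal"  # "normal" | "lognormal"
    sample_bmi_deltas: bool = False
    n_points: int = 2000
    keep_trace: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if self.rr_sampling not in ("normal", "lognormal"):
            raise ValidationError(f"unknown rr_sampling {self.rr_sampling!r}")


@dataclass
class McResult:
    """Aggregated burden with Monte Carlo intervals."""

    report: BurdenResult
    n_iter: int
    n_truncated_draws: int
    trace: pd.DataFrame | None = None


def _rr_spec(r: RiskFunction) -> tuple:
    return (r.pathway, r.outcome, r.rr_per_unit, r.ci_lo, r.ci_hi, r.reference_bmi)


def _draw_rr(rng: np.random.Generator, r: RiskFunction, sampling: str) -> float:
    if sampling == "normal":
        return float(rng.normal(r.rr_per_unit, r.rr_sd))
    log_sd = (np.log(r.ci_hi) - np.log(r.ci_lo)) / 3.92
    return float(np.exp(rng.normal(np.log(r.rr_per_unit), log_sd)))


def _draw_interval(rng: np.random.Generator, point: float, ci: tuple[float, float]) -> float:
    return float(rng.normal(point, (ci[1] - ci[0]) / 3.92))


def run_mc(inputs: ModelInputs, config: McConfig = McConfig()) -> McResult:
    """Run the Monte Carlo uncertainty analysis (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    baselines = prepare_bmi_baselines(inputs, n_points=config.n_points)

    # point-estimate run fixes the detail-row layout and the all-cause totals
    point_frame = run_point(inputs, bmi_baselines=baselines)
    point = aggregate(point_frame)
    layout = point.frame[["group", "sex", "measure"]]
    totals = point.frame["total"].to_numpy(float)

    # aggregation matrix: report row = masked sum over detail rows; the
    # detail-row order is deterministic, so one matrix serves all iterations
    d_group = point_frame["group"].to_numpy()
    d_sex = point_frame["sex"].to_numpy()
    d_measure = point_frame["measure"].to_numpy()
    agg_matrix = np.stack(
        [
            (d_measure == m)
            & ((d_group == g) | (g == "all"))
            & ((d_sex == s) | (s == "both"))
            for g, s, m in layout.itertuples(index=False)
        ]
    ).astype(float)

    point_attr = agg_matrix @ point_frame["attributable"].to_numpy(float)
    assert np.allclose(point_attr, point.frame["attributable"].to_numpy(float))

    specs = sorted({_rr_spec(r) for r in inputs.risk_functions})
    samples = np.empty((config.n_iter, len(layout)))
    truncated = 0

    for it in range(config.n_iter):
        drawn = {}
        for spec in specs:
            proto = next(r for r in inputs.risk_functions if _rr_spec(r) == spec)
            v = _draw_rr(rng, proto, config.rr_sampling)
            if v < RR_FLOOR:
                truncated += 1
                v = RR_FLOOR
            drawn[spec] = v
        risks = [
            replace(r, rr_per_unit=drawn[_rr_spec(r)],
                    ci_lo=drawn[_rr_spec(r)], ci_hi=drawn[_rr_spec(r)])
            for r in inputs.risk_functions
        ]

        consumption = {}
        for key, profile in inputs.consumption.items():
            v = float(rng.normal(profile.mean_servings, profile.se_servings))
            if v < 0:
                truncated += 1
                v = 0.0
            consumption[key] = ConsumptionProfile(key, v, profile.se_servings)

        effect = inputs.bmi_effect
        if config.sample_bmi_deltas:
            effect = BMIEffectModel(
                delta_low=max(0.0, _draw_interval(rng, effect.delta_low, effect.delta_low_ci)),
                delta_low_ci=effect.delta_low_ci,
                delta_high=max(0.0, _draw_interval(rng, effect.delta_high, effect.delta_high_ci)),
                delta_high_ci=effect.delta_high_ci,
                delta_child=max(0.0, _draw_interval(rng, effect.delta_child, effect.delta_child_ci)),
                delta_child_ci=effect.delta_child_ci,
            )

        it_inputs = inputs.with_overrides(
            risk_functions=risks, consumption=consumption, bmi_effect=effect
        )
        frame = run_point(it_inputs, bmi_baselines=baselines)
        samples[it] = agg_matrix @ frame["attributable"].to_numpy(float)

    central = samples.mean(axis=0)
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)

    out = layout.copy()
    out["attributable"] = central
    out["total"] = totals
    out["lo"] = lo
    out["hi"] = hi
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct"] = 100.0 * out["attributable"] / out["total"]
    out.loc[~np.isfinite(out["pct"]), "pct"] = np.nan

    trace = None
    if config.keep_trace:
        trace = pd.DataFrame(samples, columns=pd.MultiIndex.from_frame(layout))
        trace.index.name = "iteration"
        trace = trace.melt(ignore_index=False).reset_index()
        trace.columns = ["iteration", "group", "sex", "measure", "attributable"]

    return McResult(
        report=BurdenResult(out[BurdenResult.COLUMNS]),
        n_iter=config.n_iter,
        n_truncated_draws=truncated,
        trace=trace,
    )
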