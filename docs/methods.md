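# Methods

## Model structure

The engine is a comparative risk assessment: current burden is compared
with a counterfactual population identical in every respect except that
SSB consumption is zero. Attribution is multiplicative and per stratum
(sex × age band): for each condition, outcome (events vs deaths) and
stratum, an attributable fraction multiplies the all-cause total. Because
attribution is linear, summing attributable burden over strata equals
attributing the burden-weighted mean PAF — aggregation and attribution
commute, which the tests exploit.

### Direct pathway

Per-serving relative risks apply to type-2 diabetes (incidence RR also
used for prevalence and mortality: a single per-serving association is
assumed to move prevalent cases and deaths alike) and to the
cardiovascular conditions (one RR for incidence/prevalence, a separate one
with its own CI for mortality). Dose-response is log-linear, RR(x) = θ^x,
the natural reading of meta-analytic RRs reported "per one serving/day";
a linear alternative 1 + (θ−1)x is available behind
`ModelConfig.dose_response = "linear"` for sensitivity analysis.

The PAF formula `1 − 1/E[RR(X)]` takes the expectation of the relative
risk over the stratum's consumption distribution. When only a stratum
mean is available (the packaged country tables), the exposure is a point
mass at the mean; sampled exposures use the full empirical distribution.
A literal sum of RRs over individuals would exceed one and break PAF
semantics, so the mean-RR reading is used throughout.

### BMI-mediated pathway

Counterfactual BMI is `baseline − servings × delta`, with delta chosen
once from the *baseline* BMI (0.10 kg/m² per serving below 25, 0.23 at or
above 25; no re-evaluation when the shift crosses the threshold, since no
iteration rule is defined for that case) and floored at 13 kg/m².
Children use 0.57/1.7 kg/m² per serving — a single observed contrast
(0.57 kg/m² for a 1.7 serving change) assumed linear in servings.

Attributable overweight/obesity cases are the difference in WHO category
masses (cutoffs 25/30/35/40 kg/m²) between baseline and counterfactual,
times population. For the remaining conditions, the BMI-mediated PAF is

    PAF = 1 − E[RR(BMI_cf)] / E[RR(BMI_base)],
    RR(b) = r^max(0, b − b_ref)

log-linear above a reference BMI (default 22.5 kg/m², the midpoint of the
GBD minimum-risk window) and flat below it. Diabetes and cardiovascular
disease are barred from this pathway (validation raises a
double-counting error), because their direct RRs are not BMI-adjusted.

### Reconstructing BMI distributions

Country tables summarise BMI as a stratum mean plus category prevalences,
so a continuous distribution must be reconstructed. The fit is a
location-shifted log-normal (positive support above the shift,
right-skewed like empirical BMI):

1. for a candidate shift, the aggregate BMI ≥ 25 and BMI ≥ 30 masses pin
   the log-normal's two parameters in closed form;
2. the shift is solved (Brent) so that the *category-re-weighted* mean
   equals the stated mean BMI — re-weighting forces each category
   prevalence to match exactly, so the mean must be matched *after*
   re-weighting, not on the raw density;
3. points are laid on a per-category quantile grid (midpoint rule), which
   makes category masses exact and the construction deterministic; the
   seed only shuffles point order;
4. any residual mean error (some printed category patterns are not
   exactly reachable by this family — the worst stratum is ~0.06 kg/m²
   off — plus discretisation error) is absorbed by translating the
   normal-weight (< 25) cell, whose only constraints are its bounds.

The result reproduces every category prevalence to machine precision and
the mean to well under the 0.05 kg/m² fit tolerance. Child strata carry
no mean BMI: their two printed prevalences (overweight, obesity) pin the
two log-normal parameters exactly, with zero shift and no re-weighting.
Degenerate profiles (all prevalences zero) fall back to a truncated fit
entirely below 25 kg/m² with a fixed log-SD of 0.12.

### Totals, DALYs and costs

Counts are `rate × population / 100,000`. The "events" basis per
condition is configurable: prevalent for chronic-state conditions
(diabetes, low back pain, osteoarthritis in the packaged set), incident
otherwise — chosen to keep the packaged rate and burden tables coherent.
DALY construction is GBD-style with no age-weighting or discounting:
YLD = prevalent cases × disability weight, YLL = deaths × residual life
expectancy interpolated at the stratum age midpoint (open-ended bands are
capped at 90 for the lookup). Costs are
`incident cases × first-year cost + prevalent cases × annual cost`;
inputs declared in local currency are converted at the configured
exchange rate (48.14 ARS/USD in the packaged set, whose costs are already
stored in USD).

## Uncertainty propagation

Per iteration, every unique RR specification gets one normal draw
(SD = CI width / 3.92) shared by all strata — the RR is a global
parameter, so e.g. all five cardiovascular conditions move together —
and each stratum's mean consumption gets an independent normal draw.
Draws are truncated at their physical support (consumption at 0, RRs at
1e-6) and truncations are counted and logged. Negative PAFs from
protective RR draws are retained unclipped inside the Monte Carlo to
avoid biasing intervals; deterministic point estimates with θ ≥ 1 are
never negative. The central value is the iteration mean and the interval
the 2.5/97.5 percentiles. Normal sampling is the default; log-normal RR
sampling (epidemiologically conventional) is available, as is optional
sampling of the BMI-shift deltas from their CIs (off by default).
Baseline BMI distributions depend only on the profiles, so they are
fitted once and shared across iterations; per-iteration aggregation uses
a precomputed masked-sum matrix, which makes a 1000-iteration run on the
full packaged input set take a few seconds.

## Synthetic data and what passing tests show

The generator emits complete input sets from documented distributions:
consumption means ~ Gamma(4, 0.3) (non-negative, right-skewed, mean 1.2
servings/day), BMI summaries computed from an actual log-normal (so the
printed summary is always mutually feasible), disease rates log-uniform
within the ranges of the packaged country table. `generate_known_truth`
inverts the PAF equation — θ = 1/(1 − PAF*) at a unit point-mass exposure
— so the attributable burden is known in closed form; the deterministic
pipeline recovers it to 1e-9 and Monte Carlo intervals cover it in ≥ 93%
of seeded replicates (measured at 200 replicates × 200 iterations).

Synthetic inputs emulate the *structure* of survey-derived tables, not
real data: strata are internally homogeneous (a point-mass exposure per
stratum), consumption and BMI are independent within a stratum, disease
rates are not age-graded within a band, and no survey design effects
exist. Passing recovery tests therefore demonstrates that the arithmetic
chain is correct, not that the packaged epidemiological inputs are.

## Numerical choices

* BMI support (10, 80) kg/m²; counterfactual floor 13 kg/m²; category
  edges half-open [lo, hi).
* Exposure weights must sum to 1 within 1e-9; BMI point count ≥ 1000 so
  the discretised mean stays within the 0.05 kg/m² fit tolerance
  (default 2000).
* RR SD from a 95% CI is (hi − lo)/3.92 on the natural scale (log scale
  for log-normal sampling, centred on the point value as the median).
* Interval bounds of aggregated *observed* tables are summed across
  cells — a conservative approximation, used only for presentation.
* Reports keep full precision in CSV/JSON; markdown rounds counts to
  integers and shares to the printed style (integer percent at ≥ 2%, one
  decimal below).

## Known limitations

* The packaged fixture ships clearly labelled synthetic placeholders
  where the source tables print none: consumption SEs (5% of the mean,
  floor 0.02), the diabetes RR CI, the BMI-mediated per-kg/m² RRs, and
  an abridged residual life-expectancy table. Country users should
  replace all of them.
* Band-level inputs (five age bands per sex) are coarser than the
  single-year tables used for the original country estimates, so a full
  pipeline run reproduces magnitudes, not printed point values: adult
  attributable overweight/obesity lands inside the published 95%
  interval, while shares for steep dose-response conditions (diabetes)
  run higher than single-year estimates.
* No exposure measurement-error correction, no lag/TMREL modelling for
  the direct pathway, no longitudinal weight dynamics or caloric
  compensation, no indirect/productivity costs, no discounting.
* The published burden table contains two internal arithmetic
  inconsistencies (an "other conditions" total-deaths denominator and the
  grand-total cost row); aggregated reports state the recomputed values.
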