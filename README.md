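# ssb-burden

Comparative risk assessment (CRA) of the health and economic burden
attributable to sugar-sweetened beverage (SSB) consumption.

The package estimates the deaths, disease events, DALYs, overweight/obesity
cases and direct medical costs that a population would avoid under a
counterfactual of **zero SSB consumption**, with Monte Carlo uncertainty
propagation. It is aimed at health economists and epidemiologists running
country-level burden-of-disease analyses: all inputs are plain delimited
tables (population, consumption, BMI summaries, disease rates, relative
risks, costs), so swapping in another country's data is a matter of editing
CSV files. An Argentina 2020 input set is packaged as a worked fixture.

## Model

Attribution works through the population attributable fraction. For a
disease with per-serving relative risk θ and a consumption distribution
X (servings/day, 1 serving = 240 ml):

    PAF = 1 − 1 / E[RR(X; θ)],      RR(x; θ) = θ^x

and every attributable quantity is `PAF × all-cause total` per sex × age
stratum. Two causal pathways are modelled:

* **direct** — SSB consumption raises type-2 diabetes risk (θ = 1.37 per
  serving/day) and cardiovascular disease risk (θ = 1.08 for
  incidence/prevalence, θ = 1.08 with its own CI for mortality),
  independently of body weight;
* **BMI-mediated** — each serving/day raises attained BMI by 0.10 kg/m²
  (baseline BMI < 25) or 0.23 kg/m² (BMI ≥ 25) in adults, and by
  0.57/1.7 ≈ 0.34 kg/m² in under-18s. Shifting each stratum's BMI
  distribution to its zero-SSB counterfactual yields (a) attributable
  overweight/obesity cases by WHO category re-classification and (b) PAFs
  for the remaining conditions via GBD-style RRs per kg/m² above a
  reference BMI. Diabetes and cardiovascular disease are excluded from the
  BMI-mediated pathway to avoid double counting.

Children are modelled for overweight/obesity prevalence and cost only —
never deaths or DALYs. DALYs = YLD + YLL with YLD = prevalent cases ×
disability weight and YLL = deaths × residual life expectancy. Costs
combine first-year (incident) and annual (prevalent) schedules and are
reported in USD. Uncertainty in consumption (normal, mean ± SE) and in
every RR (normal, SD = CI width / 3.92) is propagated by Monte Carlo
(1000 iterations by default; 2.5/97.5 percentile intervals).

## Worked example

```python
>>> import ssb_burden as sb

# PAF closed form: diabetes at one serving/day
>>> sb.paf(sb.ExposureDistribution.point_mass(1.0), 1.37)
0.27007299270072993

# aggregate the packaged per-condition burden table to totals
>>> report = sb.aggregate(sb.table3_observed())
>>> report.attributable("all", "both", "deaths")
4425.0
>>> round(report.pct("diabetes", "both", "events"))
23
```

4,425 deaths per year are attributable to SSB consumption across all
modelled adult conditions, and 23% of all prevalent type-2 diabetes cases.
The full pipeline (BMI counterfactual included) runs from the shell:

```sh
ssb-burden fixture inputs/           # emit the packaged CSV inputs
ssb-burden run --inputs inputs/ --out report/ --format markdown
ssb-burden mc  --inputs inputs/ --out report_mc/ --n-iter 1000 --seed 1
```

The deterministic run prints, e.g., an adult overweight/obesity row of
`605,700 / 19,926,600 (3%)` — attributable cases / all cases (share) —
and a `manifest.json` recording the seed and an input checksum. Synthetic
input sets with known ground truth come from `ssb-burden synth` or
`ssb_burden.generate_known_truth`.

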