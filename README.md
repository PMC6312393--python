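# wheatgains

Genetic-gain and breeding-economics analysis of unbalanced wheat
variety-trial panels.

Public breeding programs must demonstrate what part of observed yield
growth is attributable to their genetics rather than to agronomy, weather,
or site effects. `wheatgains` implements the full evaluation chain used for
the South African Agricultural Research Council's wheat breeding program:
it estimates yield gains embodied in successive variety releases from
multi-environment trial data, converts the estimate into cumulative
genetic-gain series, and values those gains for producers and consumers.
It is a library for agricultural economists and breeding-program analysts,
used from Python (see `examples/`) or through a thin `wheatgains` CLI.

## The model

Yield and yield risk are modelled jointly with a Just-Pope stochastic
production function on replicate-level trial records. For plot *j*, trial
year *t*, wheat type *w*:

```
Y_jtw     = β0 + β1·LNRLYR_jtw + β2·PLANTING_jtw + δ_t + φ_j + e_jtw      (mean)
ln(e_jtw)² = α0 + α1·LNRLYR_jtw + α2·PLANTING_jtw + δ*_t + φ*_j + ε_jtw   (variance)
```

`LNRLYR` is the log of a variety's *vintage index* — its release year
re-encoded ordinally so the first release of each wheat type is 1 — and
`PLANTING` flags the optimal (1) versus late (0) planting window; δ and φ
are trial-year and plot fixed effects. The pair is estimated per wheat
type (winter, spring irrigated, spring dryland, facultative) by feasible
GLS: OLS on the mean equation, OLS of log squared residuals on the same
covariates, then weighted least squares with weights 1/exp(fitted
log-variance). Standard errors are clustered on the year × production
region interaction (two-way clustering is available). β1 measures the
kg/ha of mean yield embodied per unit log vintage; α1 tells whether newer
releases are riskier.

Downstream, the vintage coefficient becomes a cumulative gain series
g(t) = β1·ln(t − y0 + 1) from the type's first release year y0, and the
economics layer values g(t) on the area actually sown at real prices,
computes discounted benefit-cost ratios, converts extra kilograms into
per-person wheat rations, and decomposes an assumed supply shift into
consumer/producer surplus.

Because the original 25,690-row trial dataset was never deposited, the
package ships a first-class synthetic-trials generator
(`wheatgains.synthetic_trials`) that draws unbalanced panels from exactly
this data-generating process at the study's scale (125 plots, 1998–2014,
26 varieties, four-replicate trials, ~43% late plantings), so the
estimator is validated by oracle equivalence and parameter-recovery
simulation. The published summary series (areas, prices, costs, per-type
coefficients) are packaged as CSV fixtures and drive the economics layer.

## Worked example

```python
from wheatgains import datasets, economics, genetic_gain

ref  = datasets.load_reference_coefficients()
econ = datasets.load_econ_series()

gains = {
    wt: genetic_gain.cumulative_gain(
        float(ref.loc[wt, "jp_yield"]),
        int(ref.loc[wt, "first_release_year"]), 2015, wheat_type=wt)
    for wt in datasets.ECON_TYPES
}
print(round(gains["winter"].gain_at(1993), 2))   # 112.98
print(round(gains["winter"].terminal, 2))        # 518.02

benefits = economics.producer_benefits(econ, gains)
print(round(benefits.total))                     # 106410162
costs = datasets.load_program_costs()
print(round(economics.benefit_cost_ratio(
    benefits.per_year["total"], costs, r=0.0), 2))  # 5.1
```

The winter program's second year carries ln(2)·163 = 112.98 kg/ha of
cumulative gain; by 2015 winter varieties embody 518 kg/ha over the 1992
first release (≈16.6%, or 21.6 kg/ha per year). Valued on the observed
area at real 2016 USD prices, the program generated about $106.4 million
in producer benefits over 1992–2015 against $20.9 million of costs — an
undiscounted benefit-cost ratio of 5.1 — and, at 60.9 kg per person per
year, roughly 253,000 additional wheat rations annually
(`examples/03_breeding_economics.py` prints the full set).

`examples/01_simulate_and_fit.py` shows the estimation half: simulate a
study-scale panel and recover the per-type vintage coefficients with the
FGLS machinery.

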