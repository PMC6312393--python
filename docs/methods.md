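# Methods

## Model and estimation

The package treats replicate-level variety-trial yields as draws from a
Just-Pope stochastic production function: a linear conditional-mean
equation in the log vintage index (`LNRLYR`), a planting-window indicator,
and trial-year and plot fixed effects, together with a log-linear
conditional-variance equation in the same covariates. The two-equation
form lets a covariate raise mean yield while raising or lowering yield
risk, which is the question of interest for modern-variety criticism:
newer releases may yield more but vary more.

Vintage is encoded ordinally: within each wheat type, the first commercial
release has index 1 and a variety released *k* years later has index
*k* + 1; `LNRLYR` is the natural log of this index. The encoding makes the
first release of each type the zero point of the gain series and gives the
familiar concave (log) progress curve. Spring wheat is split into
irrigated and dryland sub-panels using the irrigation flag, giving four
independent model fits (winter, spring irrigated, spring dryland,
facultative); both spring sub-panels share the spring type's first release
as their vintage origin.

Estimation is the canonical two-stage feasible GLS:

1. OLS of yield on the mean-equation design;
2. OLS of ln(ê²) on the same design, where ê are the stage-1 residuals;
3. WLS of the mean equation with weights 1/exp(fitted log-variance),
   normalized to unit mean (WLS is invariant to positive rescaling of the
   weights).

One reweighting pass is the default (`ModelSpec.fgls_iterations`
configurable). Fixed effects enter as explicit indicator columns (the
first trial year and the first plot are the omitted base levels); at 125
plots and 17 years the design is desk-scale and explicit columns keep the
effect estimates reportable. Rank deficiency is detected by pivoted QR on
the column-scaled design and reported by column name rather than silently
dropped — squared-vintage terms, for example, are collinear with the
vintage index in short panels.

Numerical details of the variance stage: residual magnitudes below the
1st percentile of the nonzero magnitudes (configurable) are floored before
logging, and the floored count is reported, so near-interpolating fits
cannot produce infinite log responses or infinite weights. If every
residual is exactly zero the variance equation is refused as degenerate.
Stage-2 OLS of ln(ê²) estimates the variance slopes consistently; its
intercept absorbs the mean of ln χ²₁ (≈ −1.27) and is not interpreted.

Inference is cluster-robust. The default scheme is one-way clustering on
the trial-year × production-region interaction (at most 51 clusters in
the study geometry); a two-way year/region scheme via inclusion-exclusion
is available, as the verbal description "clustered by year and the three
regions" is ambiguous between the two. The sandwich uses the
G/(G−1)·(n−1)/(n−k) correction, so singleton clusters reduce exactly to
HC1, and p-values use a t distribution with G−1 degrees of freedom.
Clustered covariances are used for both the mean and variance equations;
whether published variance-equation p-values were clustered is unstated,
so the choice is flagged in the output tables.

## Synthetic trial panels

The raw trial dataset (25,690 usable observations) is not public, so the
generator in `synthetic_trials` emulates it from the model's own
data-generating process. Yields are Normal on the kg/ha scale — the
standard Just-Pope testbed, under which FGLS consistency is provable —
with variance exp(α0 + α1·LNRLYR + α2·PLANTING + irrigation shift + fixed
effects). Varieties enter trials one year after release (configurable lag)
and persist to the panel end (configurable exit age), producing the
entry/exit unbalance of real trial networks. Per-cell inclusion draws thin
the variety × year × plot grid to the target observation count; planting
window and irrigation status are Bernoulli draws at configured rates.
Fixed effects left unspecified are drawn Normal(0, sd) deterministically
from the seed, so the realized truth is available to recovery tests.
Negative draws are truncated at zero and counted.

`study_scale_config()` reproduces the study's conditions: 125 plots over
1998–2014, four replicates, the 26 released varieties with their published
release years and types, the observed late-planting share (10,949/25,690 ≈
0.426), per-type irrigated shares from the published descriptive table,
and per-type inclusion probabilities targeting the published per-variety
counts scaled to the 25,690 usable records (the per-variety counts sum to
36,507, the study's larger raw total). Mean shifts by type and an
irrigation effect (+3,100 kg/ha) place the per-type means near their
published values (winter ≈ 2,760, spring irrigated ≈ 6,700 kg/ha).

What the generator does not emulate: real yield distributions are
right-skewed and bounded at zero, not truncated Normal; at the study's
full dispersion (CVs near 50%) about 2% of Normal draws truncate, which
lifts fitted vintage coefficients slightly because newer vintages carry
higher variance. Recovery tests therefore use `winter_panel_config()`, the
same winter panel geometry (five releases, ~4,300 rows, 30 plots) at a
milder noise scale where truncation is below 0.1% and the estimator is
effectively unbiased. Passing recovery tests consequently demonstrate
correctness of the estimator under its own assumptions, not robustness to
skewness, spatial correlation, or weather covariates — none of which are
modelled.

## Gain series and annualization

Cumulative genetic gain for calendar year *t* is g(t) = β1·ln(t − y0 + 1)
with y0 the type's first release year; g(y0) = 0, increments are positive
and strictly decreasing, and increments telescope exactly to the terminal
value. The annual average divides the terminal gain by a year count *T*,
default *T* = horizon − y0 + 1. *T* is an explicit parameter because
published annualizations are inconsistent about whether the release year
counts: the winter figure (21.58 kg/ha over 1992–2015) implies *T* = 24,
while the spring-irrigated figure (9.53) implies *T* = 21 and the
facultative (7.38) *T* = 22 over the same 1994–2015 span. Percentage
gains divide the terminal gain by the observed mean yield of the type's
first release(s) — 3,123 kg/ha for winter, 6,561.41 for spring irrigated,
2,755.51 for facultative.

## Economics

All dollar computations are in real 2016 USD as given; no deflator is
implemented. Producer benefits value the cumulative gain on the area
actually sown: benefit_t = Σ_types area_t · g(t)/1000 · price_t (gain in
kg/ha, price per metric ton). Years before a type's first release
contribute nothing; years beyond a gain series' horizon are an error.

The benefit-cost ratio discounts both series from a base year (default:
the first shared year): Σ B_t(1+r)^−t / Σ C_t(1+r)^−t. The published
headline ratio (5.10) equals the ratio of undiscounted totals even though
the accompanying description names a 10.25% rate, so the pipeline reports
both r = 0 and r = 0.1025 and the reproduction checks use r = 0.

Rations divide each year's additional kilograms by annual per-capita
consumption (default 60.9 kg); the unrounded series conserves mass
exactly, with rounding applied only for display.

The surplus step converts a proportional supply shift K (default 0.51%),
demand elasticity 0.22 and supply elasticity 0.68 (absolute values) into
welfare changes, in two variants because the published table's negative
producer surplus is irreproducible under textbook parallel-shift algebra:

* `parallel-alston`: Z = Kε/(ε+η), ΔCS = PQZ(1+0.5Zη),
  ΔPS = PQ(K−Z)(1+0.5Zη) ≥ 0 — the standard parallel-shift closed economy
  model, in which producers cannot lose;
* `incidence` (default): ΔCS as above with ΔPS = −ΔCS·η/ε, which
  reproduces the published table's constant consumer-to-producer
  incidence ratio ε/η ≈ 3.0909 and its producer losses.

Surplus dollar levels additionally require the national production
quantity Q, an external series not packaged here; Q is therefore an
optional input and the incidence-ratio property is what the tests assert.
K is likewise a parameter, not a computed quantity.

## Problem sizes and tolerances in the test suite

Oracle checks (explicit normal-equations solves) run on a fixed 30-row
panel at 1e-8 relative tolerance. Recovery simulations use 200 seeded
replicates of ~4,300-row winter panels (β1 = 163, α1 = 0.12), asserting
95%-interval coverage within [90%, 99%] for both parameters and that the
FGLS replicate SD does not exceed the OLS replicate SD; smaller
Monte-Carlo checks (homoscedastic-null coverage, equal-weights FGLS/OLS
agreement, clustered-vs-classical SE behaviour) use 100 replicates of
panels between ~200 and ~3,600 rows. Desk arithmetic downstream of the
coefficients is checked at ±0.02 kg/ha on gain values (the vintage
coefficient is published rounded to 163.00) and ±0.5% on dollar and
ration aggregates (published tables round per cell); recomputing the
benefit total from the printed inputs lands 0.04% below the printed
total, inside that band.

## Known limitations

* No spatial or temporal error correlation beyond what clustering absorbs;
  no mixed/random-effects variants; no weather covariates.
* The Normal yield DGP truncates at zero; at realistic dispersion this
  biases vintage coefficients upward by a few percent (see above).
* Discount timing uses beginning-of-base-year convention; alternative
  timing conventions change the BCR slightly at r > 0.
* Gains are never extrapolated past the configured horizon, and no
  plateau test beyond the imposed log concavity is offered.
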