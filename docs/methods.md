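# Methods

`riverwqi` implements a complete water-quality assessment pipeline for annual
river-monitoring panels: index aggregation, classification, trend screening,
clustering, and extraction of representative regional/temporal index series.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic benchmark does and does not
demonstrate.

## The monitoring panel

The raw input is a long-format table of annual values for eight parameters —
temperature (°C), pH, electrical conductivity (µmhos/cm), dissolved oxygen
(mg/L), biochemical oxygen demand (mg/L), nitrate+nitrite (mg/L), fecal and
total coliform (MPN/100 mL) — at a set of stations over a run of years.
Missing measurements are absent rows, never zeros, and are excluded from all
test counts: an absent measurement is neither a passed nor a failed test
(counting absences as passes would inflate every index). Years are unitless
ordered integers; station labels are opaque, and the given order is treated
as downstream order where an order matters (the year-wise trend test runs
over stations in that order).

## Objectives, standards, ideals

Each parameter carries an objective (the pass/fail limit), a standard value
`S_i` and an ideal value `V_0`. Dissolved oxygen uses lower-limit semantics
(a value *below* the objective fails); pH uses a range; the concentration-
type parameters use upper limits. The shipped defaults are guideline-derived
assumptions (CPCB designated-best-use bathing class and BIS drinking-water
limits) so the pipeline runs out of the box; any real assessment should
supply its own YAML. `V_0 = 7.0` for pH and `V_0 = 14.6` mg/L for DO follow
the classical weighted-index convention; `V_0 = 0` elsewhere. Per-index
inclusion flags let users reproduce analyses in which only a subset of
parameters carried objectives; the defaults include pH, DO, BOD and FC in the
CCME index (a core sanitary set) and everything except temperature in the BC
index, with all eight in the weighted index.

## The three indices

**CCME WQI** = `100 − sqrt(F1² + F2² + F3²)/1.732`, where `F1` is the
percentage of parameters with at least one failed test (scope), `F2` the
percentage of failed tests (frequency), and `F3 = nse/(0.01·nse + 0.01)`
rescales the mean excursion `nse` (total excursion / total tests) into
[0, 100). An excursion is `value/objective − 1` for an exceeded upper limit
and `objective/value − 1` for an undershot lower limit; for a range objective
the violated bound's rule applies. The `1.732 ≈ √3` divisor leaves a tiny
negative residue (≈ −0.003) in the all-fail worst case, so the value is
clamped into [0, 100]. Excursions against a zero bound (or a zero measurement
under a lower limit) are undefined; they are capped at a configurable
`excursion_cap` (default 100) with a warning — relevant because coliform
objectives can be small.

**BC WQI** = `sqrt(F1² + F2² + (F3/3)²)/1.453` with `F3` = 100 × the maximum
single excursion, capped at 100. Zero is best water; the 1.453 divisor maps
the worst case `F1 = F2 = F3 = 100` to ≈ 99.998.

**Weighted arithmetic WQI** = `Σ w_i Q_i` with sub-indices
`Q_i = 100·|V_i − V_0| / |S_i − V_0|` (V_i the slice mean of the parameter)
and inverse-standard weights `w_i = (1/S_i)/Σ(1/S_i)`. Two conventions are
deliberate: the weights are used in normalized form (algebraically identical
to dividing the weighted sum by `Σ w_i`), and `Q_i` uses absolute deviations
so that pH below its ideal 7.0, or DO above 14.6, cannot produce a negative
sub-index on a scale where 0 is ideal. When some parameters are missing from
a slice the weights are renormalized over those available, so a slice sitting
exactly at every standard always scores 100.

A *slice* is either one station across all years (station-wise assessment
over the study period) or one year across all stations (year-wise
assessment); both views share one implementation.

## Classification scales and gap labels

The published class scales are closed integer-bounded bins: CCME (higher is
better) 95–100 Excellent, 80–94 Good, 65–79 Fair, 45–64 Marginal, 0–44 Poor;
BC (lower is better) 0–3 Excellent, 4–17 Good, 18–43 Fair, 44–59 Borderline,
60–100 Poor; weighted (lower is better) 0–25 Excellent, 26–50 Good, 51–75
Poor, 76–100 Very Poor, above 100 Unsuitable. Real-valued indices land in the
open gaps between bins (e.g. BC 43.57 in (43, 44)); the default policy labels
such values with both adjacent classes, better quality first
("Fair/Borderline", "Good/Poor"), which is how published assessment tables
print them. `nearest` and `truncate` policies are provided for users of the
conventional scales. Endpoints are inclusive and values are compared at full
precision, never rounded first.

## Trend screening

The Mann–Kendall statistic `S` sums the signs of all pairwise differences;
its variance uses the standard tie correction
`Var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18`, and the z-score applies the
±1 continuity correction. The default significance level is 0.05 two-sided
(configurable). The normal approximation is used even at the short panel
lengths (n = 17) typical of annual series; an exact permutation null (via the
inversion-count generating polynomial) is available for n ≤ 10 without ties
but is off by default. Sen's slope — the median of all pairwise slopes
`(x_j − x_i)/(j − i)` — is reported only when the null is rejected, matching
the dash convention of trend tables ("−" is read as p > α, not as slope ≈ 0);
`force_sen` overrides this.

Kruskal–Wallis (scipy's tie-corrected implementation behind the module
surface) tests whether one parameter's series at different sites, or in
different years, share a distribution.

Loess is implemented as k-nearest-neighbour locally weighted polynomial
regression: at each target the `⌈α·n⌉` nearest points get tricube weights
`(1 − (d/d_max)³)³` and a degree-1 or degree-2 polynomial is solved by
weighted least squares. Degree 2 is the default (the usual loess convention);
the spans 0.10/0.25/0.50 used in the analysis scripts give a local, an
intermediate and a smooth view of each series. The spatio-temporal curve runs
over the panel flattened in station-major order (each station's years as a
consecutive block); the order is configurable. A boundary neighbour at
exactly `d_max` receives a vanishing (1e-12) rather than zero weight so the
design matrix stays full-rank at tiny spans.

## Clustering and the cluster-count vote

Entities (stations or years) are described by their three index values,
column-standardized to mean 0 / unit sample sd (zero-variance columns are
centered only, with a warning), and clustered agglomeratively on Euclidean
distances. Average linkage is the default — the agglomerative-coefficient
convention this mirrors comes from the classical agnes-style analysis, whose
default is average linkage — with ward/complete/single available. The
agglomerative coefficient is the mean over entities of
`1 − h_first/h_final`, where `h_first` is the height at which the entity
first merges and `h_final` the final merge height; values near 1 indicate
strong structure.

The cluster count is chosen by majority vote over five internal validity
indices — silhouette, Calinski–Harabasz, Davies–Bouldin (negated so larger is
better), the gap statistic (20 uniform reference draws over the bounding box,
seeded), and Dunn — each voting for its best k over the candidate range; vote
ties go to the smaller k. This reduced panel replaces the 28-algorithm
batteries sometimes used for the same purpose, which are out of proportion to
the role the vote plays; the majority-vote semantics are preserved.

## Representative regional and temporal series

Given the periods × stations matrix of *yearly weighted-index values per
station*, the regional series is built by (1) clustering the stations,
(2) taking the cluster with the most members (ties broken toward the cluster
with the smallest mean pairwise distance between member series), and
(3) averaging the member values at each period. Goodness of fit is reported
against **every** station (members and non-members): MAE, RMSE and MAPE (in
percent; flagged `NA` for an entity with a zero observed value). RMSE ≥ MAE
always holds (power-mean inequality) and is asserted in tests. The temporal
'global' series applies the identical rule to the transposed matrix, so years
are clustered and the representative runs over stations. "MSE" is accepted as
an alias for RMSE in metric lookups, since the root form is sometimes named
that way; the implementation always computes the root.

## Synthetic panels and what the benchmark shows

The generator draws each station × parameter series from its own seeded
substream (so adding stations never perturbs existing series) as
`baseline + group shift + station effect + slope·(t − t0) + noise`, with
normal noise for temperature/pH/DO/nitrate+nitrite and lognormal noise (the
same structure on the log scale, trend as a log-linear drift of the median)
for EC/BOD/FC/TC. Outliers are injected with a per-parameter probability —
additive (multiplier × sd) in the normal family, multiplicative in the
lognormal family, up to 50× for total coliform, emulating the coliform spikes
that dominate real sanitary surveys. The default scenario is a 10-station ×
17-year (2003–2019) panel with plausible large-river baselines and trend
signs chosen to match published large-river assessments qualitatively:
nitrate+nitrite rising at all stations, conductivity falling, total coliform
trendless. The exceedance calibrator shifts a parameter's baseline so the
model-implied tail probability beyond the objective equals a target, solving
the normal (or log-normal) tail equation directly.

The recovery benchmark (500 replicates, n = 17) verifies that the Mann–
Kendall type-I error sits in [0.03, 0.07] at α = 0.05, power reaches ≥ 0.8 by
slope = 1 sd/year, and the median Sen estimate lands within 10% of the
injected slope for slopes ≥ 0.5 sd. A designed two-group station layout with
10× separation is recovered perfectly and wins the k = 2 vote.

What the synthetic panel does **not** emulate: intra-year seasonality (the
series are annual), autocorrelation, cross-parameter dependence (each
parameter draws independently), flow/monsoon dynamics, and real exceedance
co-occurrence structure. Passing tests therefore demonstrate the correctness
and calibration of the pipeline's statistics, not the realism of any
particular river's assessment.

## Numerical conventions and degenerate inputs

- Index computations raise on zero tests or zero included parameters rather
  than returning a default.
- CCME clamping to [0, 100]; BC F3 capped at 100; excursion cap at zero
  bounds (default 100, configurable).
- Classification compares at full precision; negative values are errors.
- Mann–Kendall requires n ≥ 4 after removing missing values; Sen's slope
  skips missing pairs but keeps original index spacing in denominators.
- Kruskal–Wallis drops all-missing groups with a warning and needs ≥ 2
  groups, total n ≥ 5; identical-constant groups return H = 0 directly.
- Cluster-count vote ties break toward smaller k; the gap statistic's
  reference draws are seeded for reproducibility.
- The full pipeline is deterministic: the same seed and configuration
  produce byte-identical CSV outputs.

## Problem sizes

The analysis scripts and the test suite run on the default 10 × 17 × 8 panel;
the statistical calibration and recovery suites use 500 replicates of
length-17 series (1000 for the Kruskal–Wallis type-I check), sizes at which
the binomial confidence bands on the measured rates are comfortably inside
the asserted intervals.
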