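# Methods

This note records the models, estimators, parameter choices and numerical
decisions behind `forestdyn`, and what the synthetic tests do and do not
establish about real inventory data.

## Census data model

A plot series is an ordered set of full stand remeasurements. Dates are
decimal calendar years, so census-interval lengths are plain differences.
The status vocabulary is deliberately closed (`alive`, `dead`,
`recruit_first_record`, `absent_prior`); richer field codes must be mapped by
the input dialect, which keeps the demographic logic unambiguous. Death is
absorbing: a tree recorded dead and later recorded alive is a hard error at
load time, because every downstream estimator depends on it.

The inclusion rule is dbh ≥ 10.0 cm (configurable). Field protocols measure
in millimetres and include 100 mm stems, so the boundary stem is kept. A tree
first reaching the threshold after the series' first census is relabelled a
recruit at that census; once recruited, a tree stays tracked through death
even if a later recorded diameter falls below the threshold (shrinkage across
the threshold is far more often a measurement artefact than a real exit).
Series spanning less than 2 years of monitoring, or with a single census, are
flagged unusable for dynamic analyses but still usable for stocks.

## Allometry

Tree dry biomass is 0.0509·ρ·D²·H (kg), with height from a region-specific
Weibull curve H = a(1 − e^(−bD^c)) rather than any climate-based height
model: within lowland moist forest the dominant height/diameter contrast is
compositional (the tall-statured Guiana Shield forests), not climatic. The
shipped per-region coefficients are plausible defaults — a real analysis must
substitute fitted curves; all quantitative tests construct their own
coefficients.

Wood density resolves species → genus mean → family mean → plot mean (over
taxon-matched trees of the same plot), with the match level recorded. Stand
totals convert to carbon as 50% of dry mass, inflated by 6.2% for unmeasured
small stems. The two factors commute, so their order is an arbitrary
documentation choice, not a numerical one.

## Demographic estimators

**Mortality.** μ = 100·[ln n₀ − ln(n₀ − n_d)]/t, the exponential per-capita
coefficient. Because heterogeneous stands yield interval-length-dependent
estimates, each interval's μ is standardized by μ_std = μ·(t/t_ref)^λ with
λ = 0.08 and t_ref = 1 yr (both configurable). Per-plot rates are computed
per interval, standardized, then averaged weighted by interval length — in
that order. An interval in which every stem dies leaves μ undefined (log 0);
the error message says to pool intervals rather than silently dropping data.

**Productivity.** W_P per interval is the sum of four components:
(i) growth of surviving stems matched by id; (ii) estimated growth of stems
that died, grown at the plot-mean survivor diameter growth rate for t/2
before death; (iii) recruit growth from a baseline diameter (the census
threshold by default) to the observed size; (iv) the expected contribution
of stems that both recruited and died unobserved, with expected count
(annual recruits)·(annual death probability)·t²/2 and each assigned the
median recruit increment accrued over t/4. The annual death probability is
1 − e^(−μ/100). W_L sums the biomass of observed deaths (at their last
measured diameter), component (ii), and the whole-tree biomass of the
expected unobserved recruit-deaths. With no survivors the plot-mean growth
rate falls back to 0 with a warning rather than failing the interval.

Diameter growth rates below −0.5 cm yr⁻¹ are treated as measurement or
point-of-measurement error: the increment is flagged and contributes zero to
productivity. Mild negative increments are retained as measured.

**Residence time.** τ_w = AGB/W_P, meaningful for a stand at steady state.
Plot AGB here is the time-mean over censuses (not the final census),
matching the steady-state framing; τ_w is reported missing when W_P ≤ 0.
For gridded fields both the mean of cellwise ratios and the ratio of
cellwise means are emitted and labelled — they differ in general and both
conventions appear in basin syntheses.

**Summaries.** Regional means carry SE = sd/√n. The basin mean is available
under two schemes — equal-weight pooling of plots, and plot-count-weighted
averaging of regional means — because published basin figures do not always
state which was used (for stem mortality the two differ noticeably).
Across-region contrasts use one-way fixed-effects ANOVA, df = (k−1, n−k).

## Spatial statistics

Distances are great-circle kilometres; across a ~30° network planar degrees
distort badly. The empirical semivariogram bins half squared differences up
to half the maximum separation by default; variogram models (Gaussian,
exponential, spherical) are fitted by least squares weighted by pair counts.
Ordinary kriging uses a global neighbourhood (the network is a few hundred
points at most), solving the standard constrained system per target cell;
exactly duplicated locations are averaged first with a warning, and negative
weights are logged, not hidden. Leave-one-out cross-validation reuses the
full-data variogram by default (a refit-per-fold flag exists); the headline
figure is the median of 100·|pred − obs|/obs, with the signed variant also
reported since "percentage bias" is ambiguous.

GLS fits use maximum likelihood with the Gaussian correlation
corr(d) = (1−g)·e^(−(d/r)²) and the range r (and optional nugget proportion
g) profiled out numerically; given the correlation, coefficients and error
variance have closed forms via Cholesky whitening. ML rather than REML is
deliberate: the candidate set varies fixed effects, and only ML log-
likelihoods make the AIC comparison valid. AIC counts the coefficients, the
error variance, the range, and the nugget when estimated. The profile
surface has a degenerate local optimum at r → 0 (the independence model), so
the search is a coarse grid — jointly over range and nugget when the nugget
is estimated — followed by local refinement. Coefficient standard errors use
the bias-corrected variance (n/(n−p)); they are conditional on the estimated
correlation parameters, which is the conventional (slightly anti-
conservative) choice. Pseudo-R² is the squared Pearson correlation of fitted
versus observed response; no canonical definition exists for GLS, and this
one is monotone, bounded and cheap. Candidate designs are built without a
formula engine: region enters as treatment-coded dummies (first level by
sort order as reference) and interactions as slope-by-region products, with
mortality terms natural-log transformed; rank deficiency is reported with
the aliased columns named.

## Gridded comparison

Grids live on 1° cells with centres on half-degree offsets; misregistered
input is rejected with the measured offset. Total woody NPP converts to its
above-ground part by AG = total/(1 + 0.21), the below-ground:above-ground
allocation ratio. The comparison mask is the set of cells containing at
least one plot; statistics are mean ± SE across cells (an across-years SE
would need per-year fields, which are out of scope), RMSE, and percent bias
of means. The ensemble mean is unweighted across sources. For models that
split NPP between growth and areal 'spreading', a per-cell growth-fraction
field can rescale NPP; absent that diagnostic the grid passes through with a
warning.

## Synthetic data

The census simulator is individual-based with annual steps: each live stem
draws a diameter increment N(mean, sd) truncated at zero, then dies with a
fixed annual probability; recruits arrive as a Poisson stream entering at
the threshold diameter. Censuses snapshot the stand at fixed intervals, and
stems that recruit and die between censuses are never observed — exactly the
information loss the interval corrections estimate. Biomass truth uses the
same allometry as the pipeline on purpose: the tests isolate demographic
estimation error, not allometric error. Default regional parameters (annual
death probabilities 1.4–3.1%, initial size distributions as truncated power
laws with exponents near 3, wood density means 0.58–0.69 g cm⁻³) were chosen
once to bracket the observed basin ranges qualitatively — correct regional
orderings and rough magnitudes of AGB, W_P, μ and wood density — not to
reproduce any network's standard errors.

The network generator places plots uniformly in four contiguous regional
blocks and perturbs regional means with spatially correlated noise
(covariance g·I + (1−g)·e^(−(d/r)²), drawn by Cholesky factorization) —
additively for AGB, multiplicatively and mean-preserving on the log scale
for the positive rates. The regression-test generator builds AGB from a
known linear model with a productivity slope, region offsets and
region-specific log-mortality slopes plus spatially correlated errors, i.e.
the interaction structure the model-selection machinery should find.

What the passing tests show: the estimators recover known hazards, slopes
and variogram ranges under the generating assumptions, and the interval
corrections beat naive estimators when the generating process matches their
logic. What they do not show: robustness to point-of-measurement changes,
multi-stem individuals, palm allometry, plot-size heterogeneity, drought or
blowdown pulses, or taxonomic misidentification — none of which the
generator emulates.

## Problem sizes and determinism

Statistical checks run at desk scale chosen once: mortality recovery uses
100 plots × 500 stems over one 5-year interval; the interval-correction
check 100 replicates of a 300-stem stand; kriging cross-validation a
200-point field; slope-recovery coverage 100 replicates of a 167-plot
network. All generators take explicit seeds or `numpy` Generators and emit
truth records alongside data; re-running any stage with the same seed and
configuration reproduces numerically identical artifacts.

## Known limitations

- The unobserved-component sub-rules ((ii) t/2 growth, (iv) t²/2 expected
  count and t/4 accrual) are stated conventions; alternative published
  variants differ in detail, and all the durations and baselines are
  configurable.
- The GLS nugget is off by default (the fitted correlation is then pure
  Gaussian); with spatially unstructured measurement noise in the response,
  enable nugget estimation or standard errors will be understated.
- Kriging assumes second-order stationarity and a global variogram; sharp
  edaphic boundaries are smoothed over, and extreme plot values are
  under-predicted — interpolated maps are evaluation tools, not truth.
- Shipped Weibull coefficients and the wood-density fall-through assume the
  user supplies real fitted curves and a real density database for any
  production analysis.
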