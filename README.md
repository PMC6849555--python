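# forestdyn

Carbon stocks and demographic rates of tropical forest stands from repeated
census data, with spatial interpolation and benchmarking of gridded
vegetation-model output.

Permanent inventory plots — every stem ≥ 10 cm diameter identified, measured
and re-measured over years — are the primary ground truth for how much carbon
lowland tropical forests store and how fast it turns over. `forestdyn`
implements the full chain from raw census tables to basin-scale statistics
for researchers working with plot networks and vegetation modellers
evaluating their simulations against such observations.

## What it computes

For each plot and census interval, with stem diameter *D* (cm), taxon-based
wood density *ρ* (g cm⁻³) and height *H* (m) from a regional Weibull curve
*H* = *a*(1 − e^(−bD^c)):

- **Above-ground biomass** (Mg C ha⁻¹) from the moist-forest allometry
  AGB = Σ 0.0509 *ρD²H* / 1000, converted to carbon at 50% of dry mass with
  a +6.2% allowance for unmeasured stems < 10 cm.
- **Stem mortality rate** μ = 100·[ln *n₀* − ln(*n₀* − *n_d*)]/*t* (% yr⁻¹),
  standardized across census-interval lengths by μ_std = μ·*t*^0.08.
- **Above-ground woody productivity** *W_P* (Mg C ha⁻¹ yr⁻¹), corrected for
  census-interval bias as the sum of survivor growth plus the estimated
  growth of trees that died, recruited, or did both unobserved within the
  interval; and the **woody biomass loss rate** *W_L*.
- **Woody residence time** τ_w = AGB / *W_P* (years) for a stand at steady
  state.
- **Regional summaries** (mean ± SE per substrate region, one-way ANOVA),
  **ordinary kriging** of plot values onto a 1° grid with leave-one-out
  validation, **generalized least squares** regressions of AGB on
  productivity and mortality terms with a Gaussian spatial correlation
  structure and AIC model selection, and **comparison statistics**
  (mean ± SE, RMSE, percent bias, ensemble means, τ_w maps) between the
  interpolated observations and gridded vegetation-model fields.

A seed-deterministic synthetic module (individual-based census simulator,
spatially correlated plot networks, biased model-like grids) provides known
ground truth, so every stage runs and is tested without external data.

## Worked example

```python
import numpy as np
from forestdyn.allometry import AllometryContext, load_weibull_coefficients
from forestdyn.dynamics import analyze_plot
from forestdyn.synthetic import DEFAULT_REGION_PARAMS, simulate_census_series

params = DEFAULT_REGION_PARAMS["GuianaShield"]
coeffs = load_weibull_coefficients()["GuianaShield"]
series, wood_density, truth = simulate_census_series(
    params, n_censuses=3, interval=4.0, seed=11, coeffs=coeffs)
ctx = AllometryContext(coeffs=coeffs, wood_density=wood_density)
result = analyze_plot(series, ctx)
print(f"AGB   {result.agb:6.1f} Mg C/ha")
print(f"W_P   {result.wp:6.2f} Mg C/ha/yr   (realized {truth['true_wp_mean']:.2f})")
print(f"mu    {result.mu_std:6.2f} %/yr         (hazard  {truth['true_mu']:.2f})")
print(f"tau_w {result.tau_w:6.1f} yr")
```

prints

```
AGB    190.1 Mg C/ha
W_P     3.55 Mg C/ha/yr   (realized 3.58)
mu      1.69 %/yr         (hazard  1.65)
tau_w   53.6 yr
```

— the interval-corrected productivity estimate sits within 1% of the
simulator's realized annual growth, and the mortality estimate within
sampling error of the generating hazard.

The same chain is available as a CLI over CSV artifacts:

```bash
forestdyn --seed 1 --out run1 simulate   # census, metadata, wood density, truth
forestdyn --seed 1 --out run1 metrics    # per-plot AGB, W_P, W_L, mu, tau_w
forestdyn --seed 1 --out run1 summarize  # regional means +/- SE, ANOVA
forestdyn --seed 1 --out run1 krige      # 1-degree map + leave-one-out stats
forestdyn --seed 1 --out run1 gls        # spatially correlated model selection
```

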