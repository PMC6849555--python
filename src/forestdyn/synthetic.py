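"""Seed-deterministic generators with known ground truth.

Three generators cover the pipeline's inputs:

* an individual-based census simulator (annual growth, Bernoulli death,
  Poisson recruitment at the diameter threshold) emitting the same series
  format the census reader produces, together with a truth record of the
  realized annual productivity, deaths and recruits;
* a plot-network generator placing plots in four contiguous regional blocks
  with spatially correlated plot-to-plot noise drawn from a Gaussian
  variogram, used to exercise the kriging and regression stages;
* a model-like grid generator that biases a truth field by configured
  factors to exercise the gridded-comparison stage.

Biomass truth uses the same allometry module as the pipeline, so tests of
the demographic estimators isolate demographic error, not allometric error.

Default regional parameters are set to bracket the observed basin ranges
qualitatively (stem mortality 1.4-3.2 % yr^-1, woody productivity roughly
2.4-3.5 Mg C ha^-1 yr^-1, AGB roughly 110-210 Mg C ha^-1, Guiana Shield
densest wood and lowest mortality, Brazilian Shield the reverse), not to
reproduce any particular network's standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from forestdyn.allometry import (
    AllometryConfig,
    WeibullCoefficients,
    WoodDensityTable,
    estimate_height,
    tree_agb,
)
from forestdyn.census import PlotMetadata, PlotSeries, Status, TreeObservation
from forestdyn.gridcompare import ModelGrid
from forestdyn.spatial import distance_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionParams:
    """True demographic parameters of one simulated region.

    ``mortality`` is the annual per-stem death probability (the matching
    exponential hazard is ``-100*ln(1-mortality)`` % yr^-1). Growth is an
    annual diameter increment draw, truncated at zero. The initial size
    structure is a truncated power law on [threshold, dbh_max].
    """

    name: str
    mortality: float  # annual death probability
    growth_mean: float  # cm yr^-1
    growth_sd: float
    size_exponent: float  # power-law exponent of the initial dbh distribution
    dbh_max: float  # cm
    wd_mean: float  # g cm^-3
    wd_sd: float
    recruitment_rate: float  # stems ha^-1 yr^-1 crossing the threshold
    stems_per_ha: float
    n_plots: int
    plot_area: float = 1.0  # ha

    def __post_init__(self) -> None:
        if not 0 <= self.mortality < 1:
            raise ValueError(f"mortality must be a probability, got {self.mortality}")
        for f_ in ("growth_sd", "dbh_max", "wd_mean", "recruitment_rate",
                   "stems_per_ha", "plot_area"):
            if not getattr(self, f_) > 0:
                raise ValueError(f"{f_} must be positive")

    @property
    def true_mu(self) -> float:
        """The exponential stem mortality coefficient implied, % yr^-1."""
        return -100.0 * math.log(1.0 - self.mortality)


DEFAULT_REGION_PARAMS: dict[str, RegionParams] = {
    "GuianaShield": RegionParams(
        name="GuianaShield", mortality=0.0164, growth_mean=0.27, growth_sd=0.18,
        size_exponent=2.95, dbh_max=180.0, wd_mean=0.69, wd_sd=0.06,
        recruitment_rate=9.2, stems_per_ha=560, n_plots=41),
    "EastCentral": RegionParams(
        name="EastCentral", mortality=0.0137, growth_mean=0.22, growth_sd=0.14,
        size_exponent=3.0, dbh_max=170.0, wd_mean=0.67, wd_sd=0.06,
        recruitment_rate=8.1, stems_per_ha=590, n_plots=37),
    "Western": RegionParams(
        name="Western", mortality=0.0259, growth_mean=0.34, growth_sd=0.20,
        size_exponent=2.97, dbh_max=150.0, wd_mean=0.58, wd_sd=0.06,
        recruitment_rate=15.0, stems_per_ha=580, n_plots=76),
    "BrazilianShield": RegionParams(
        name="BrazilianShield", mortality=0.0314, growth_mean=0.31, growth_sd=0.16,
        size_exponent=3.08, dbh_max=140.0, wd_mean=0.61, wd_sd=0.06,
        recruitment_rate=16.3, stems_per_ha=520, n_plots=13),
}


@dataclass(frozen=True)
class FieldParams:
    """Gaussian-variogram parameters of between-plot spatial noise.

    ``nugget`` is the proportion of noise variance that is spatially
    unstructured; ``range_km`` the Gaussian correlation range.
    """

    nugget: float = 0.2
    range_km: float = 400.0

    def __post_init__(self) -> None:
        if not 0 <= self.nugget <= 1:
            raise ValueError(f"nugget proportion must lie in [0, 1], got {self.nugget}")
        if not self.range_km > 0:
            raise ValueError(f"range must be positive, got {self.range_km}")


# ---------------------------------------------------------------------------
# Species pool / wood density
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPool:
    """Synthetic taxa with known wood densities for one region."""

    families: list[str]
    genera: list[str]
    species: list[str]
    densities: np.ndarray

    def to_wood_density_table(self) -> WoodDensityTable:
        return WoodDensityTable(pd.DataFrame({
            "family": self.families, "genus": self.genera,
            "species": self.species, "density": self.densities,
        }))


def make_species_pool(params: RegionParams, n_species: int = 40,
                      rng: np.random.Generator | None = None) -> SpeciesPool:
    """Draw a species pool with densities ~ N(wd_mean, wd_sd), clipped."""
    rng = rng or np.random.default_rng(0)
    dens = np.clip(rng.normal(params.wd_mean, params.wd_sd, n_species),
                   0.15, 1.3)
    tag = params.name[:4].lower()
    return SpeciesPool(
        families=[f"fam{i % 8:02d}" for i in range(n_species)],
        genera=[f"{tag}_gen{i:03d}" for i in range(n_species)],
        species=["indet"] * n_species,
        densities=dens,
    )


# ---------------------------------------------------------------------------
# Individual-based census simulation
# ---------------------------------------------------------------------------

def _sample_truncated_power_law(rng, n, exponent, dmin, dmax):
    """Inverse-CDF draw from pdf ~ D^-exponent on [dmin, dmax]."""
    u = rng.random(n)
    a = 1.0 - exponent
    lo, hi = dmin ** a, dmax ** a
    return (lo + u * (hi - lo)) ** (1.0 / a)


def simulate_census_series(
    params: RegionParams,
    n_censuses: int = 3,
    interval: float = 5.0,
    seed: int | np.random.Generator = 0,
    coeffs: WeibullCoefficients | None = None,
    allometry_config: AllometryConfig | None = None,
    pool: SpeciesPool | None = None,
    plot_id: str = "SYN-001",
    longitude: float = -60.0,
    latitude: float = -3.0,
    start_date: float = 2000.0,
) -> tuple[PlotSeries, WoodDensityTable, dict]:
    """Simulate one plot's census series with an annual individual-based model.

    Every simulated year each live tree draws a diameter increment
    (N(growth_mean, growth_sd), truncated at 0), then dies with probability
    ``mortality``; new stems cross the threshold at a Poisson rate.
    Censuses snapshot the stand every ``interval`` years: live stems carry
    their current dbh, stems that died since the previous census appear once
    as dead records with their last measured dbh, and stems that both
    recruited and died between censuses are never observed -- exactly the
    information loss the census-interval corrections target.

    Returns the series, the wood-density table resolving its taxa, and a
    truth record with the realized annual productivity (same allometry and
    carbon units as the pipeline), death and recruit counts, and the true
    hazard.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    coeffs = coeffs or WeibullCoefficients(params.name, 45.0, 0.048, 0.85)
    config = allometry_config or AllometryConfig()
    pool = pool or make_species_pool(params, rng=rng)
    threshold = config.diameter_threshold

    n0 = int(round(params.stems_per_ha * params.plot_area))
    dbh = _sample_truncated_power_law(rng, n0, params.size_exponent,
                                      threshold, params.dbh_max)
    sp = rng.integers(0, len(pool.densities), n0)
    alive = np.ones(n0, dtype=bool)
    # bookkeeping for census records
    observed_alive = np.zeros(n0, dtype=bool)
    last_obs_dbh = np.full(n0, np.nan)
    death_reported = np.zeros(n0, dtype=bool)

    def biomass(d, s):
        rho = pool.densities[s]
        return tree_agb(d, rho, estimate_height(d, coeffs), config)

    carbon = config.carbon_factor / 1000.0 / params.plot_area  # kg DW -> Mg C/ha

    def snapshot(date):
        trees = {}
        for i in np.nonzero(alive)[0]:
            status = Status.ALIVE if observed_alive[i] else Status.RECRUIT
            trees[f"t{i:06d}"] = TreeObservation(
                plot_id=plot_id, tree_id=f"t{i:06d}", census_date=date,
                dbh=round(float(dbh[i]), 2), status=status,
                family=pool.families[sp[i]], genus=pool.genera[sp[i]],
                species=pool.species[sp[i]])
        newly_dead = np.nonzero(~alive & observed_alive & ~death_reported)[0]
        for i in newly_dead:
            trees[f"t{i:06d}"] = TreeObservation(
                plot_id=plot_id, tree_id=f"t{i:06d}", census_date=date,
                dbh=round(float(last_obs_dbh[i]), 2), status=Status.DEAD,
                family=pool.families[sp[i]], genus=pool.genera[sp[i]],
                species=pool.species[sp[i]])
            death_reported[i] = True
        for i in np.nonzero(alive)[0]:
            observed_alive[i] = True
            last_obs_dbh[i] = dbh[i]
        return trees

    censuses = [(start_date, snapshot(start_date))]
    annual_wp: list[float] = []
    annual_deaths: list[int] = []
    annual_recruits: list[int] = []

    n_years = int(round((n_censuses - 1) * interval))
    next_census = 1
    for year in range(1, n_years + 1):
        live_idx = np.nonzero(alive)[0]
        inc = np.maximum(rng.normal(params.growth_mean, params.growth_sd,
                                    live_idx.size), 0.0)
        before = biomass(dbh[live_idx], sp[live_idx])
        dbh[live_idx] += inc
        after = biomass(dbh[live_idx], sp[live_idx])
        wp_year = float(np.sum(after - before)) * carbon

        dies = rng.random(live_idx.size) < params.mortality
        alive[live_idx[dies]] = False
        annual_deaths.append(int(dies.sum()))

        n_new = rng.poisson(params.recruitment_rate * params.plot_area)
        if n_new:
            dbh = np.append(dbh, np.full(n_new, threshold))
            sp = np.append(sp, rng.integers(0, len(pool.densities), n_new))
            alive = np.append(alive, np.ones(n_new, dtype=bool))
            observed_alive = np.append(observed_alive, np.zeros(n_new, dtype=bool))
            last_obs_dbh = np.append(last_obs_dbh, np.full(n_new, np.nan))
            death_reported = np.append(death_reported, np.zeros(n_new, dtype=bool))
        annual_recruits.append(int(n_new))
        annual_wp.append(wp_year)

        if math.isclose(year, next_census * interval, abs_tol=1e-9):
            date = start_date + year
            censuses.append((date, snapshot(date)))
            next_census += 1

    metadata = PlotMetadata(plot_id=plot_id, longitude=longitude,
                            latitude=latitude, area=params.plot_area,
                            region=params.name)
    series = PlotSeries(metadata=metadata, censuses=censuses)
    truth = {
        "annual_wp": annual_wp,
        "annual_deaths": annual_deaths,
        "annual_recruits": annual_recruits,
        "true_wp_mean": float(np.mean(annual_wp)) if annual_wp else 0.0,
        "true_mu": params.true_mu,
        "params": params,
    }
    return series, pool.to_wood_density_table(), truth


def simulate_region(
    params: RegionParams,
    n_censuses: int = 3,
    interval: float = 5.0,
    seed: int = 0,
    coeffs: WeibullCoefficients | None = None,
    allometry_config: AllometryConfig | None = None,
    lon_range: tuple[float, float] = (-62.0, -54.0),
    lat_range: tuple[float, float] = (-6.0, 2.0),
    start_date: float = 2000.0,
) -> tuple[list[PlotSeries], WoodDensityTable, list[dict]]:
    """Simulate all of a region's plots on a shared species pool."""
    rng = np.random.default_rng(seed)
    pool = make_species_pool(params, rng=rng)
    series_list, truths = [], []
    for k in range(params.n_plots):
        lon = float(rng.uniform(*lon_range))
        lat = float(rng.uniform(*lat_range))
        s, _, t = simulate_census_series(
            params, n_censuses=n_censuses, interval=interval, seed=rng,
            coeffs=coeffs, allometry_config=allometry_config, pool=pool,
            plot_id=f"{params.name[:4].upper()}-{k + 1:03d}",
            longitude=lon, latitude=lat, start_date=start_date)
        series_list.append(s)
        truths.append(t)
    return series_list, pool.to_wood_density_table(), truths


# ---------------------------------------------------------------------------
# Plot-network generator (spatially correlated plot values)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkRegion:
    """One regional block of the synthetic plot network."""

    name: str
    lon_range: tuple[float, float]
    lat_range: tuple[float, float]
    n_plots: int
    means: Mapping[str, float]  # variable -> regional mean


#: Contiguous regional blocks loosely mimicking the basin's four strata,
#: with regional means bracketing the observed ranges.
DEFAULT_NETWORK_REGIONS: list[NetworkRegion] = [
    NetworkRegion("GuianaShield", (-61.0, -52.0), (1.0, 7.0), 41,
                  {"agb": 212.0, "wp": 3.51, "mu": 1.66, "wl": 3.06}),
    NetworkRegion("EastCentral", (-60.0, -48.0), (-8.0, 0.0), 37,
                  {"agb": 168.0, "wp": 2.41, "mu": 1.38, "wl": 2.12}),
    NetworkRegion("Western", (-78.0, -66.0), (-13.0, 1.0), 76,
                  {"agb": 126.0, "wp": 3.06, "mu": 2.62, "wl": 2.43}),
    NetworkRegion("BrazilianShield", (-62.0, -50.0), (-16.0, -9.0), 13,
                  {"agb": 108.0, "wp": 2.40, "mu": 3.19, "wl": 1.57}),
]

#: Plot-to-plot noise scales: absolute sd for agb, log-scale sd for the
#: positive-constrained rates.
DEFAULT_NOISE = {"agb": 28.0, "wp": 0.18, "mu": 0.30, "wl": 0.35}
LOG_SCALE_VARS = frozenset({"wp", "mu", "wl"})


def correlated_noise(lon, lat, field_params: FieldParams,
                     rng: np.random.Generator, n_draws: int = 1) -> np.ndarray:
    """Unit-variance draws with Gaussian-variogram spatial correlation.

    Covariance = nugget * I + (1 - nugget) * exp(-(d/range)^2), factorized
    by Cholesky. Returns shape (n_points, n_draws).
    """
    d = distance_matrix(lon, lat)
    C = ((1.0 - field_params.nugget)
         * np.exp(-((d / field_params.range_km) ** 2)))
    np.fill_diagonal(C, 1.0)
    C[np.diag_indices_from(C)] += 1e-10
    L = np.linalg.cholesky(C)
    return L @ rng.standard_normal((len(C), n_draws))


def place_plots(regions: Sequence[NetworkRegion],
                rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for reg in regions:
        for k in range(reg.n_plots):
            rows.append({
                "plot_id": f"{reg.name[:4].upper()}-{k + 1:03d}",
                "longitude": float(rng.uniform(*reg.lon_range)),
                "latitude": float(rng.uniform(*reg.lat_range)),
                "region": reg.name,
            })
    return pd.DataFrame(rows)


def generate_network(
    regions: Sequence[NetworkRegion] | None = None,
    field_params: FieldParams | None = None,
    seed: int = 0,
    noise: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a plot table of spatially correlated regional values.

    Plots are placed uniformly within contiguous regional blocks. Each
    variable is its regional mean perturbed by spatially correlated noise:
    additively for AGB, multiplicatively (log scale, mean-preserving) for
    the positive rates. Returns the table and a truth record of the
    generating means and field parameters.
    """
    regions = list(regions) if regions is not None else DEFAULT_NETWORK_REGIONS
    field_params = field_params or FieldParams()
    noise = dict(noise) if noise is not None else dict(DEFAULT_NOISE)
    rng = np.random.default_rng(seed)
    table = place_plots(regions, rng)
    mean_by_region = {reg.name: reg.means for reg in regions}

    variables = sorted({v for reg in regions for v in reg.means})
    z = correlated_noise(table["longitude"], table["latitude"], field_params,
                         rng, n_draws=len(variables))
    for j, var in enumerate(variables):
        mu = table["region"].map(lambda r: mean_by_region[r][var]).to_numpy()
        sd = noise.get(var, 0.0)
        if var in LOG_SCALE_VARS:
            values = mu * np.exp(sd * z[:, j] - sd ** 2 / 2.0)
        else:
            values = np.maximum(mu + sd * z[:, j], 1.0)
        table[var] = values
    truth = {"regions": regions, "field_params": field_params, "noise": noise}
    return table, truth


@dataclass(frozen=True)
class GLSTruth:
    """Generating coefficients for a synthetic spatial regression data set."""

    intercept: float = 260.0
    wp_slope: float = 8.0
    log_mu_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"GuianaShield": -95.0, "EastCentral": -75.0,
                                 "Western": -35.0, "BrazilianShield": -60.0})
    region_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"GuianaShield": 35.0, "EastCentral": 0.0,
                                 "Western": -10.0, "BrazilianShield": -25.0})
    error_sd: float = 20.0


def generate_gls_dataset(
    regions: Sequence[NetworkRegion] | None = None,
    field_params: FieldParams | None = None,
    truth: GLSTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GLSTruth]:
    """Plot table whose AGB follows a known spatial regression.

    Predictors (wp, mu, wl) are drawn as in :func:`generate_network`; the
    response is built from the generating model

        agb = intercept + region_offset + wp_slope * wp
              + log_mu_slope[region] * ln(mu) + e,

    with spatially correlated Gaussian errors -- the region-by-mortality
    interaction structure of the best-supported observational model.
    """
    truth = truth or GLSTruth()
    field_params = field_params or FieldParams()
    table, _ = generate_network(regions, field_params, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    e = correlated_noise(table["longitude"], table["latitude"], field_params,
                         rng)[:, 0] * truth.error_sd
    agb = (truth.intercept
           + table["region"].map(truth.region_offsets).to_numpy()
           + truth.wp_slope * table["wp"].to_numpy()
           + table["region"].map(truth.log_mu_slopes).to_numpy()
           * np.log(table["mu"].to_numpy())
           + e)
    table["agb"] = np.maximum(agb, 1.0)
    return table, truth


# ---------------------------------------------------------------------------
# Model-like grids
# ---------------------------------------------------------------------------

def generate_model_like_grids(
    truth_grid: ModelGrid,
    biases: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, ModelGrid]:
    """Grids that over/underestimate a truth field by configured factors.

    Each named source gets ``truth * factor`` plus optional white noise --
    e.g. a factor of 3.34 emulates a model overestimating productivity by
    234%. Exercises the comparison statistics with known biases.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for source, factor in biases.items():
        values = truth_grid.values * factor
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, values.shape)
        out[source] = ModelGrid(source=source, variable=truth_grid.variable,
                                lon=truth_grid.lon, lat=truth_grid.lat,
                                values=values, period=truth_grid.period)
    return out
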