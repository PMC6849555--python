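"""Demographic rates and carbon fluxes per census interval and per plot.

The estimators implemented here:

* the exponential stem mortality coefficient
  ``mu = 100 * [ln(n0) - ln(n0 - nd)] / t`` (% yr^-1), standardized to a
  common census-interval length with the power law ``mu_std = mu * t^0.08``;
* census-interval-corrected above-ground woody productivity ``W_P``, the sum
  of (i) survivor growth plus the estimated growth of (ii) trees that died,
  (iii) trees that recruited and (iv) trees that both recruited and died
  unobserved within the interval;
* the absolute woody biomass loss rate ``W_L`` (dead-tree biomass plus the
  unobserved growth components of dying trees);
* interval-length-weighted plot means, the woody residence time
  ``tau_w = AGB / W_P`` of a stand at steady state, and regional summaries
  with one-way ANOVA across regions.

All carbon fluxes are in Mg C per hectare per year; stocks in Mg C per
hectare.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from forestdyn.allometry import AllometryContext, KG_PER_MG
from forestdyn.census import CensusInterval, PlotSeries, Status

logger = logging.getLogger(__name__)


class DynamicsError(ValueError):
    """Raised for undefined demographic quantities."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Tunable parameters of the demographic estimators.

    standardization_exponent
        Exponent of the census-interval power-law correction for mortality
        (0.08, dimensionless); 0 disables standardization.
    reference_interval
        Interval length (years) that standardized rates refer to.
    recruit_baseline_diameter
        Diameter (cm) a recruit is assumed to have had on crossing the census
        threshold; defaults to the threshold itself when None.
    negative_growth_tolerance
        Diameter growth rates below this (cm yr^-1) are treated as
        measurement error and contribute zero growth to productivity.
    """

    standardization_exponent: float = 0.08
    reference_interval: float = 1.0
    recruit_baseline_diameter: float | None = None
    negative_growth_tolerance: float = -0.5

    def __post_init__(self) -> None:
        if self.standardization_exponent < 0:
            raise DynamicsError("standardization_exponent must be >= 0")
        if not self.reference_interval > 0:
            raise DynamicsError("reference_interval must be positive")


# ---------------------------------------------------------------------------
# Scalar estimators
# ---------------------------------------------------------------------------

def stem_mortality_rate(n0: int, nd: int, t: float) -> float:
    """Exponential mortality coefficient, % yr^-1.

    ``mu = 100 * [ln(n0) - ln(n0 - nd)] / t`` for ``n0`` stems alive at the
    interval start of which ``nd`` die during the ``t``-year interval.
    """
    if n0 <= 0:
        raise DynamicsError(f"n0 must be positive, got {n0}")
    if not 0 <= nd <= n0:
        raise DynamicsError(f"nd must lie in [0, n0], got nd={nd}, n0={n0}")
    if not t > 0:
        raise DynamicsError(f"interval length must be positive, got {t}")
    if nd == n0:
        raise DynamicsError(
            "all stems died during the interval; the exponential coefficient "
            "is undefined (log 0) -- pool this interval with its neighbours")
    return 100.0 * (math.log(n0) - math.log(n0 - nd)) / t


def standardize_mortality(mu: float, t: float,
                          config: DynamicsConfig | None = None) -> float:
    """Standardize a mortality rate to the reference census-interval length.

    Heterogeneous populations yield interval-dependent rate estimates; the
    correction is the power law ``mu_std = mu * (t/t_ref)^lambda`` with
    lambda = 0.08 by default. Identity for ``t == t_ref`` or lambda = 0.
    """
    config = config or DynamicsConfig()
    if mu < 0:
        raise DynamicsError(f"mortality rate must be non-negative, got {mu}")
    if not t > 0:
        raise DynamicsError(f"interval length must be positive, got {t}")
    return mu * (t / config.reference_interval) ** config.standardization_exponent


def interval_weighted_mean(values: Sequence[float], lengths: Sequence[float]) -> float:
    """Mean of per-interval values weighted by census-interval length."""
    if len(values) == 0:
        raise DynamicsError("cannot average an empty list of intervals")
    if len(values) != len(lengths):
        raise DynamicsError("values and interval lengths differ in length")
    v = np.asarray(values, dtype=float)
    t = np.asarray(lengths, dtype=float)
    if np.any(t <= 0):
        raise DynamicsError("interval lengths must be positive")
    return float(np.sum(v * t) / np.sum(t))


def residence_time(agb: float, wp: float) -> float:
    """Woody residence time ``tau_w = AGB / W_P`` (years) at steady state.

    Undefined (nan, with a warning) when ``W_P`` is not positive.
    """
    if wp > 0:
        return agb / wp
    logger.warning("residence time undefined for W_P = %s; reporting nan", wp)
    return float("nan")


# ---------------------------------------------------------------------------
# Interval analysis
# ---------------------------------------------------------------------------

@dataclass
class IntervalDynamics:
    """Counts, rates and corrected fluxes for one census interval."""

    plot_id: str
    interval: CensusInterval
    n0: int
    nd: int
    nr: int
    mu_raw: float
    mu_std: float
    wp: float
    wp_components: tuple[float, float, float, float]  # (i)..(iv)
    wl: float
    agb_start: float
    agb_end: float
    n_flagged_negative_growth: int = 0


def _live(trees: dict) -> dict:
    return {tid: o for tid, o in trees.items() if o.status in
            (Status.ALIVE, Status.RECRUIT)}


def analyze_interval(
    series: PlotSeries,
    index: int,
    ctx: AllometryContext,
    config: DynamicsConfig | None = None,
) -> IntervalDynamics:
    """Full demographic and flux analysis of one census interval of a plot.

    Survivors are matched by tree id between the interval's two censuses.
    Unobserved growth is estimated following the standard inventory
    correction: trees that died grow at the plot-mean survivor diameter
    growth rate for half the interval before death; recruits grow from the
    baseline diameter to their observed size; the expected number of stems
    that both recruited and died unobserved is
    (annual recruits) * (annual death probability) * t^2 / 2, each carrying
    the median recruit increment accrued over a quarter interval.
    """
    config = config or DynamicsConfig()
    area = series.metadata.area
    date0, trees0 = series.censuses[index]
    date1, trees1 = series.censuses[index + 1]
    interval = CensusInterval(date0, date1)
    t = interval.t

    live0 = _live(trees0)
    live1 = _live(trees1)
    all_obs = list(trees0.values()) + list(trees1.values())

    survivors = sorted(set(live0) & set(live1))
    deaths = []
    for tid, obs0 in live0.items():
        if tid in live1:
            continue
        obs1 = trees1.get(tid)
        if obs1 is not None and obs1.status is Status.DEAD:
            deaths.append(tid)
        else:
            logger.warning(
                "plot %s: tree %s alive at %s is absent at %s; treating as a death",
                series.plot_id, tid, date0, date1)
            deaths.append(tid)
    recruits = sorted(set(live1) - set(trees0))

    n0, nd, nr = len(live0), len(deaths), len(recruits)
    mu_raw = stem_mortality_rate(n0, nd, t) if n0 > 0 and nd < n0 else float("nan")
    mu_std = (standardize_mortality(mu_raw, t, config)
              if math.isfinite(mu_raw) else float("nan"))

    rho = {o.tree_id: ctx.density_for(o, all_obs)
           for o in {**trees0, **trees1}.values()}
    biomass = ctx.tree_biomass_kg
    baseline = (config.recruit_baseline_diameter
                if config.recruit_baseline_diameter is not None
                else ctx.config.diameter_threshold)

    # (i) survivor growth; growth rates below tolerance contribute zero.
    comp_i_kg = 0.0
    growth_rates = []
    n_flagged = 0
    for tid in survivors:
        d0, d1 = trees0[tid].dbh, trees1[tid].dbh
        rate = (d1 - d0) / t
        if rate < config.negative_growth_tolerance:
            n_flagged += 1
            rate = 0.0
            d1 = d0
        growth_rates.append(rate)
        comp_i_kg += biomass(d1, rho[tid]) - biomass(d0, rho[tid])

    if growth_rates:
        mean_growth = float(np.mean(growth_rates))
    else:
        mean_growth = 0.0
        if deaths:
            logger.warning("plot %s interval %s-%s: no survivors; plot-mean "
                           "growth falls back to 0", series.plot_id, date0, date1)

    # (ii) growth of dying trees before death, at plot-mean rate for t/2.
    comp_ii_kg = 0.0
    dead_biomass_kg = 0.0
    for tid in deaths:
        d_last = (trees1[tid].dbh if tid in trees1 and trees1[tid].dbh > 0
                  else trees0[tid].dbh)
        dead_biomass_kg += biomass(d_last, rho[tid])
        comp_ii_kg += (biomass(d_last + max(mean_growth, 0.0) * t / 2.0, rho[tid])
                       - biomass(d_last, rho[tid]))

    # (iii) recruit growth from the baseline diameter to observed size.
    comp_iii_kg = 0.0
    recruit_increments = []
    recruit_rates = []
    for tid in recruits:
        d1 = trees1[tid].dbh
        inc = max(biomass(d1, rho[tid]) - biomass(baseline, rho[tid]), 0.0)
        comp_iii_kg += inc
        recruit_increments.append(inc)
        recruit_rates.append(max(d1 - baseline, 0.0) / t)

    # (iv) stems that recruited and died unobserved within the interval.
    annual_recruits = nr / t
    annual_death_prob = (1.0 - math.exp(-mu_raw / 100.0)
                         if math.isfinite(mu_raw) else 0.0)
    n_unobserved = annual_recruits * annual_death_prob * t ** 2 / 2.0
    if recruit_rates and n_unobserved > 0:
        g_r = float(np.median(recruit_rates))
        rho_med = float(np.median([rho[tid] for tid in recruits]))
        inc_iv = biomass(baseline + g_r * t / 4.0, rho_med) - biomass(baseline, rho_med)
        unobs_tree_biomass = biomass(baseline + g_r * t / 4.0, rho_med)
    else:
        inc_iv = 0.0
        unobs_tree_biomass = 0.0
        n_unobserved = 0.0 if not recruit_rates else n_unobserved
    comp_iv_kg = n_unobserved * inc_iv

    # kg dry weight -> Mg C ha^-1 yr^-1
    scale = ctx.config.carbon_factor / KG_PER_MG / area / t
    components = tuple(c * scale for c in
                       (comp_i_kg, comp_ii_kg, comp_iii_kg, comp_iv_kg))
    wp = interval_productivity(components)
    wl = (dead_biomass_kg + comp_ii_kg + n_unobserved * unobs_tree_biomass) * scale

    agb_start = ctx.stand_agb(trees0.values(), area)
    agb_end = ctx.stand_agb(trees1.values(), area)

    return IntervalDynamics(
        plot_id=series.plot_id, interval=interval, n0=n0, nd=nd, nr=nr,
        mu_raw=mu_raw, mu_std=mu_std, wp=wp,
        wp_components=components, wl=wl,
        agb_start=agb_start, agb_end=agb_end,
        n_flagged_negative_growth=n_flagged,
    )


def interval_productivity(components: Sequence[float]) -> float:
    """W_P as the sum of growth components (i)-(iv)."""
    if len(components) != 4:
        raise DynamicsError("expected the four growth components (i)-(iv)")
    return float(sum(components))


# ---------------------------------------------------------------------------
# Plot-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class PlotDynamics:
    """Interval-weighted plot-level rates and the residence time."""

    plot_id: str
    mu_std: float
    wp: float
    wl: float
    agb: float  # time-mean over censuses
    tau_w: float
    intervals: list[IntervalDynamics] = field(default_factory=list)


def analyze_plot(
    series: PlotSeries,
    ctx: AllometryContext,
    config: DynamicsConfig | None = None,
) -> PlotDynamics:
    """Per-plot rates: per-interval estimates, standardized, then averaged
    weighted by census-interval length; AGB is the time-mean over censuses
    and ``tau_w`` the ratio of the two means."""
    config = config or DynamicsConfig()
    if series.n_censuses < 2:
        raise DynamicsError(
            f"plot {series.plot_id} has {series.n_censuses} census(es); "
            "dynamic analysis needs at least 2")
    ivals = [analyze_interval(series, i, ctx, config)
             for i in range(series.n_censuses - 1)]
    lengths = [iv.interval.t for iv in ivals]

    mus = [iv.mu_std for iv in ivals]
    finite = [i for i, m in enumerate(mus) if math.isfinite(m)]
    mu = (interval_weighted_mean([mus[i] for i in finite],
                                 [lengths[i] for i in finite])
          if finite else float("nan"))
    wp = interval_weighted_mean([iv.wp for iv in ivals], lengths)
    wl = interval_weighted_mean([iv.wl for iv in ivals], lengths)

    agb_per_census = [ivals[0].agb_start] + [iv.agb_end for iv in ivals]
    agb = float(np.mean(agb_per_census))
    tau = residence_time(agb, wp)
    return PlotDynamics(plot_id=series.plot_id, mu_std=mu, wp=wp, wl=wl,
                        agb=agb, tau_w=tau, intervals=ivals)


def basal_area(observations: Iterable, area: float) -> float:
    """Live-stem basal area in m^2 ha^-1 (diameters in cm)."""
    if not area > 0:
        raise DynamicsError(f"plot area must be positive, got {area}")
    d = np.asarray([o.dbh for o in observations if o.is_live], dtype=float)
    return float(np.sum(np.pi * (d / 2.0) ** 2) * 1e-4 / area)


def plot_table(
    series_list: Iterable[PlotSeries],
    ctx_for: "AllometryContext | dict[str, AllometryContext]",
    config: DynamicsConfig | None = None,
) -> pd.DataFrame:
    """Per-plot interchange table: the input to kriging and GLS.

    ``ctx_for`` is either a single :class:`AllometryContext` or a mapping
    region -> context (region-specific height curves). Columns: plot_id,
    longitude, latitude, region, agb, wp, wl, mu, tau_w, wood_density,
    basal_area.
    """
    rows = []
    for series in series_list:
        region = series.metadata.region
        ctx = ctx_for[region] if isinstance(ctx_for, dict) else ctx_for
        pdyn = analyze_plot(series, ctx, config)
        last_live = list(series.live_trees(series.n_censuses - 1).values())
        rho = [ctx.density_for(o, last_live) for o in last_live]
        rows.append({
            "plot_id": series.plot_id,
            "longitude": series.metadata.longitude,
            "latitude": series.metadata.latitude,
            "region": region,
            "agb": pdyn.agb,
            "wp": pdyn.wp,
            "wl": pdyn.wl,
            "mu": pdyn.mu_std,
            "tau_w": pdyn.tau_w,
            "wood_density": float(np.mean(rho)) if rho else float("nan"),
            "basal_area": basal_area(last_live, series.metadata.area),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regional summaries and ANOVA
# ---------------------------------------------------------------------------

def pooled_weighted_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of group means (the pooled overall mean)."""
    m = np.asarray(means, dtype=float)
    n = np.asarray(ns, dtype=float)
    if m.shape != n.shape or m.size == 0:
        raise DynamicsError("means and group sizes must be equal-length, non-empty")
    return float(np.sum(m * n) / np.sum(n))


def regional_summary(
    data: pd.DataFrame,
    variables: Sequence[str],
    region_col: str = "region",
    basin_scheme: str = "plots",
) -> pd.DataFrame:
    """Mean +/- SE and n per region plus a basin row, for each variable.

    ``basin_scheme`` selects how the basin mean is formed: ``"plots"`` pools
    every plot with equal weight; ``"weighted_regional"`` weights the regional
    means by their plot counts (identical when no data are missing, but both
    are provided because published basin figures do not always state the
    averaging scheme).
    """
    if basin_scheme not in ("plots", "weighted_regional"):
        raise DynamicsError(f"unknown basin_scheme {basin_scheme!r}")
    rows = []
    for var in variables:
        sub = data[[region_col, var]].dropna()
        reg_means, reg_ns = [], []
        for region, grp in sub.groupby(region_col, sort=False):
            vals = grp[var].to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                logger.warning("region %s has no data for %s; omitted", region, var)
                continue
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append({"variable": var, "region": region,
                         "mean": float(np.mean(vals)), "se": se, "n": n})
            reg_means.append(float(np.mean(vals)))
            reg_ns.append(n)
        vals = sub[var].to_numpy(dtype=float)
        if basin_scheme == "plots":
            basin_mean = float(np.mean(vals))
        else:
            basin_mean = pooled_weighted_mean(reg_means, reg_ns)
        basin_se = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                    if len(vals) > 1 else float("nan"))
        rows.append({"variable": var, "region": "Basin",
                     "mean": basin_mean, "se": basin_se, "n": int(len(vals))})
    return pd.DataFrame(rows)


def region_anova(values: Sequence[float], labels: Sequence[str]
                 ) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA across regions.

    Returns ``(F, (df_between, df_within), p)``; with 167 plots in 4 regions
    the degrees of freedom are (3, 163).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise DynamicsError("values and labels must have equal length")
    groups = [v[lab == g] for g in pd.unique(lab)]
    if len(groups) < 2:
        raise DynamicsError("ANOVA needs at least two groups")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = len(v) - len(groups)
    return float(f), (df1, df2), float(p)
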