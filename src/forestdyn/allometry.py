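"""Tree- and stand-level above-ground biomass estimation.

Per-tree dry biomass follows the moist-forest allometry

    AGB_tree [kg DW] = 0.0509 * rho * D^2 * H

with ``D`` the stem diameter (cm), ``rho`` the taxon-assigned wood density
(g cm^-3) and ``H`` the tree height (m) modelled from diameter with a
region-specific Weibull curve ``H = a * (1 - exp(-b * D^c))``. Stand totals
are converted to carbon assuming carbon is 50% of dry mass and inflated by
6.2% to account for unmeasured stems below the 10 cm census threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from forestdyn.census import TreeObservation

logger = logging.getLogger(__name__)

KG_PER_MG = 1000.0


class AllometryConfigError(ValueError):
    """Raised for invalid allometric configuration."""


class WoodDensityError(LookupError):
    """Raised when no wood density can be assigned to a tree."""


@dataclass(frozen=True)
class WeibullCoefficients:
    """Region-specific height-diameter Weibull parameters.

    ``a`` is the asymptotic height (m); ``b`` and ``c`` control how quickly
    the asymptote is approached with diameter.
    """

    region: str
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise AllometryConfigError(
                f"Weibull coefficients for {self.region!r} must all be "
                f"positive, got a={self.a}, b={self.b}, c={self.c}"
            )


@dataclass(frozen=True)
class AllometryConfig:
    """Constants of the biomass calculation; every one is overridable."""

    equation_constant: float = 0.0509
    carbon_fraction: float = 0.5
    small_tree_correction: float = 0.062
    diameter_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (self.equation_constant > 0 and self.small_tree_correction >= 0
                and self.diameter_threshold >= 0):
            raise AllometryConfigError("allometry constants must be positive")
        if not 0 < self.carbon_fraction < 1:
            raise AllometryConfigError(
                f"carbon_fraction must lie in (0, 1), got {self.carbon_fraction}")

    @property
    def carbon_factor(self) -> float:
        """Dry mass -> carbon including the small-tree inflation."""
        return self.carbon_fraction * (1.0 + self.small_tree_correction)


def estimate_height(D, coeffs: WeibullCoefficients):
    """Modelled tree height (m) from diameter (cm): ``a*(1 - exp(-b*D^c))``.

    Vectorized over ``D``; monotone increasing, 0 at D=0, asymptote ``a``.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("diameter must be non-negative")
    H = coeffs.a * (1.0 - np.exp(-coeffs.b * np.power(D, coeffs.c)))
    return float(H) if H.ndim == 0 else H


def tree_agb(D, rho, H, config: AllometryConfig | None = None):
    """Per-tree above-ground dry biomass in kg: ``const * rho * D^2 * H``."""
    config = config or AllometryConfig()
    D = np.asarray(D, dtype=float)
    rho = np.asarray(rho, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(D < 0) or np.any(rho < 0) or np.any(H < 0):
        raise ValueError("diameter, wood density and height must be non-negative")
    agb = config.equation_constant * rho * D ** 2 * H
    return float(agb) if agb.ndim == 0 else agb


def stand_agb(
    dbh,
    rho,
    area: float,
    coeffs: WeibullCoefficients,
    config: AllometryConfig | None = None,
) -> float:
    """Stand above-ground carbon stock in Mg C per hectare.

    ``dbh`` and ``rho`` are per-(live-)tree arrays; heights come from the
    regional Weibull curve. The dry-mass sum is scaled by the carbon fraction
    and the small-tree correction (their order is immaterial).
    """
    config = config or AllometryConfig()
    if not area > 0:
        raise ValueError(f"plot area must be positive, got {area}")
    dbh = np.asarray(dbh, dtype=float)
    if dbh.size == 0:
        return 0.0
    H = estimate_height(dbh, coeffs)
    total_kg = float(np.sum(tree_agb(dbh, rho, H, config)))
    return total_kg / KG_PER_MG / area * config.carbon_factor


# ---------------------------------------------------------------------------
# Wood density
# ---------------------------------------------------------------------------

class WoodDensityTable:
    """Taxon -> wood density lookup with species/genus/family fall-through.

    Built from a 4-column table (family, genus, species, density in g cm^-3);
    genus and family means are precomputed on load.
    """

    MIN_DENSITY, MAX_DENSITY = 0.1, 1.5

    def __init__(self, df: pd.DataFrame):
        required = {"family", "genus", "species", "density"}
        missing = required - set(df.columns)
        if missing:
            raise AllometryConfigError(
                f"wood-density table missing column(s): {', '.join(sorted(missing))}")
        bad = df[(df["density"] <= self.MIN_DENSITY) | (df["density"] >= self.MAX_DENSITY)]
        if len(bad):
            raise AllometryConfigError(
                f"{len(bad)} wood-density entries outside "
                f"({self.MIN_DENSITY}, {self.MAX_DENSITY}) g cm^-3")
        self._df = df
        self._species = {
            (g, s): d for g, s, d in
            zip(df["genus"], df["species"], df["density"]) if pd.notna(s)
        }
        self._genus = df.groupby("genus")["density"].mean().to_dict()
        self._family = df.groupby("family")["density"].mean().to_dict()

    @classmethod
    def from_csv(cls, path: str | Path) -> "WoodDensityTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    def lookup(self, family: str | None, genus: str | None,
               species: str | None) -> tuple[float, str] | None:
        """Best-available density and its match level, or None."""
        if genus and species and (genus, species) in self._species:
            return self._species[(genus, species)], "species"
        if genus and genus in self._genus:
            return self._genus[genus], "genus"
        if family and family in self._family:
            return self._family[family], "family"
        return None


def assign_wood_density(
    obs: TreeObservation,
    table: WoodDensityTable,
    plot_mean: float | None = None,
) -> tuple[float, str]:
    """Density for one tree: species, then genus, then family, then plot mean.

    ``plot_mean`` must be the mean density of taxon-matched trees in the same
    plot; it backs trees with missing or unmatched taxonomy.
    """
    hit = table.lookup(obs.family, obs.genus, obs.species)
    if hit is not None:
        return hit
    if plot_mean is not None and np.isfinite(plot_mean):
        return plot_mean, "plot_mean"
    raise WoodDensityError(
        f"tree {obs.tree_id} in plot {obs.plot_id} has no usable taxonomy and "
        "no plot-mean density is available; supply a network-wide default"
    )


def plot_mean_density(
    observations: Iterable[TreeObservation], table: WoodDensityTable
) -> float:
    """Mean density over taxon-matched trees of a plot (nan if none match)."""
    values = []
    for obs in observations:
        hit = table.lookup(obs.family, obs.genus, obs.species)
        if hit is not None:
            values.append(hit[0])
    return float(np.mean(values)) if values else float("nan")


# ---------------------------------------------------------------------------
# Per-plot evaluation context
# ---------------------------------------------------------------------------

@dataclass
class AllometryContext:
    """Bundle of everything needed to turn observations into biomass.

    Caches the plot-mean wood density lazily per plot so repeated interval
    computations stay cheap.
    """

    coeffs: WeibullCoefficients
    wood_density: WoodDensityTable
    config: AllometryConfig = field(default_factory=AllometryConfig)
    _plot_means: dict[str, float] = field(default_factory=dict, repr=False)

    def density_for(self, obs: TreeObservation,
                    plot_observations: Iterable[TreeObservation] | None = None) -> float:
        hit = self.wood_density.lookup(obs.family, obs.genus, obs.species)
        if hit is not None:
            return hit[0]
        if obs.plot_id not in self._plot_means:
            if plot_observations is None:
                raise WoodDensityError(
                    f"tree {obs.tree_id}: no taxon match and no plot "
                    "observations supplied to compute a plot mean")
            self._plot_means[obs.plot_id] = plot_mean_density(
                plot_observations, self.wood_density)
        rho, _ = assign_wood_density(obs, self.wood_density,
                                     self._plot_means[obs.plot_id])
        return rho

    def tree_biomass_kg(self, dbh: float, rho: float) -> float:
        """Dry biomass (kg) of one tree at the given diameter."""
        return float(tree_agb(dbh, rho, estimate_height(dbh, self.coeffs), self.config))

    def stand_agb(self, observations: Iterable[TreeObservation], area: float) -> float:
        """Mg C ha^-1 over the live trees of one census."""
        obs_list = [o for o in observations if o.is_live]
        dbh = [o.dbh for o in obs_list]
        rho = [self.density_for(o, obs_list) for o in obs_list]
        return stand_agb(dbh, rho, area, self.coeffs, self.config)


# ---------------------------------------------------------------------------
# Shipped per-region Weibull defaults
# ---------------------------------------------------------------------------

def load_weibull_coefficients(path: str | Path | None = None) -> dict[str, WeibullCoefficients]:
    """Load region -> Weibull coefficients from CSV (region, a, b, c).

    Without ``path``, the packaged defaults are used. These are plausible
    regional curves (Guiana Shield tallest-statured) intended as a starting
    configuration; any real analysis should substitute fitted coefficients.
    """
    if path is None:
        ref = resources.files("forestdyn").joinpath("data/weibull_coefficients.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return {
        str(row["region"]): WeibullCoefficients(
            region=str(row["region"]), a=float(row["a"]),
            b=float(row["b"]), c=float(row["c"]))
        for _, row in df.iterrows()
    }
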