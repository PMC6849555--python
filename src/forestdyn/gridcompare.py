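"""Benchmarking gridded vegetation-model output against observations.

Gridded fields (a vegetation model's AGB or above-ground woody NPP, or the
kriged observations) live on a common 1-degree lon/lat grid with cell centers
on half-degree offsets. Comparison statistics are computed over a cell mask,
normally the cells that contain at least one inventory plot: mean +/- SE,
RMSE against observations, mean percent bias, the unweighted ensemble mean
across models, and cellwise residence-time (tau_w = AGB / W_P) maps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)


class GridError(ValueError):
    """Raised for malformed or misregistered gridded input."""


@dataclass(frozen=True)
class GridRegistration:
    """Registration of the reference grid: cell size and center offset."""

    cell_size: float = 1.0
    offset: float = 0.5  # cell centers at integer + offset
    tolerance: float = 1e-6

    def check(self, lon: np.ndarray, lat: np.ndarray) -> None:
        for name, coord in (("longitude", lon), ("latitude", lat)):
            frac = np.mod((coord - self.offset) / self.cell_size, 1.0)
            off = np.minimum(frac, 1.0 - frac)
            if np.any(off > self.tolerance):
                raise GridError(
                    f"{name} cell centers are offset from the reference "
                    f"registration by up to {float(off.max()):.4g} cells "
                    f"(expected centers at multiples of {self.cell_size} "
                    f"plus {self.offset})")


@dataclass
class ModelGrid:
    """One source's 1-degree field of a single variable.

    ``values`` is (n_lat, n_lon); missing cells are NaN. ``variable`` is one
    of ``agb`` (Mg C ha^-1), ``wp`` (above-ground woody NPP, Mg C ha^-1
    yr^-1) or ``tau_w`` (yr).
    """

    source: str
    variable: str
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    period: str | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lat.size, self.lon.size):
            raise GridError(
                f"values shape {self.values.shape} does not match "
                f"(n_lat={self.lat.size}, n_lon={self.lon.size})")

    def aligned_with(self, other: "ModelGrid") -> bool:
        return (self.lon.shape == other.lon.shape
                and self.lat.shape == other.lat.shape
                and np.allclose(self.lon, other.lon)
                and np.allclose(self.lat, other.lat))

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values, coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"), name=self.variable,
            attrs={"source": self.source, "period": self.period or ""})

    def to_csv(self, path: str | Path) -> None:
        """Long-format lon/lat/value CSV (the text interchange format)."""
        glon, glat = np.meshgrid(self.lon, self.lat)
        pd.DataFrame({
            "longitude": glon.ravel(), "latitude": glat.ravel(),
            "value": self.values.ravel(),
        }).to_csv(path, index=False)

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataarray().to_dataset().to_netcdf(path, engine="scipy")


def load_grid(
    path: str | Path,
    variable: str,
    source: str = "unknown",
    registration: GridRegistration | None = None,
    period: str | None = None,
) -> ModelGrid:
    """Read a gridded field from lon/lat/value CSV or NetCDF.

    The grid is checked against the reference 1-degree registration; offset
    grids are rejected with the measured offset in the message.
    """
    registration = registration or GridRegistration()
    path = Path(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        ds = xr.open_dataset(path, engine="scipy")
        da = ds[variable] if variable in ds else ds[list(ds.data_vars)[0]]
        lon = np.asarray(da["lon"], dtype=float)
        lat = np.asarray(da["lat"], dtype=float)
        values = np.asarray(da, dtype=float)
    else:
        df = pd.read_csv(path)
        required = {"longitude", "latitude", "value"}
        if not required <= set(df.columns):
            raise GridError(f"{path}: expected columns {sorted(required)}")
        lon = np.sort(df["longitude"].unique())
        lat = np.sort(df["latitude"].unique())
        pivot = df.pivot_table(index="latitude", columns="longitude",
                               values="value", dropna=False)
        pivot = pivot.reindex(index=lat, columns=lon)
        values = pivot.to_numpy(dtype=float)
    registration.check(lon, lat)
    return ModelGrid(source=source, variable=variable, lon=lon, lat=lat,
                     values=values, period=period)


def to_aboveground_wood(grid: ModelGrid, ratio: float = 0.21) -> ModelGrid:
    """Convert total woody NPP to its above-ground part.

    Splits the total using a below-ground:above-ground allocation ratio:
    ``AG = total / (1 + ratio)``, default ratio 0.21.
    """
    if ratio < 0:
        raise GridError(f"allocation ratio must be non-negative, got {ratio}")
    return ModelGrid(source=grid.source, variable=grid.variable,
                     lon=grid.lon, lat=grid.lat,
                     values=grid.values / (1.0 + ratio), period=grid.period)


def rescale_jules_npp(grid: ModelGrid,
                      spreading_fraction: ModelGrid | None = None) -> ModelGrid:
    """Undo a growth/'spreading' NPP split using a per-cell fraction field.

    Some land-surface schemes route part of NPP into expanding vegetated
    area rather than biomass growth; given the per-cell fraction actually
    used for growth, the woody NPP is rescaled as value / fraction. Without
    the diagnostic field the grid passes through unchanged with a warning.
    """
    if spreading_fraction is None:
        logger.warning("no growth-fraction field supplied for %s; NPP passed "
                       "through unrescaled", grid.source)
        return grid
    if not grid.aligned_with(spreading_fraction):
        raise GridError("growth-fraction field is not aligned with the NPP grid")
    frac = spreading_fraction.values
    if np.any(frac <= 0) or np.any(frac > 1):
        raise GridError("growth fractions must lie in (0, 1]")
    return ModelGrid(source=grid.source, variable=grid.variable,
                     lon=grid.lon, lat=grid.lat,
                     values=grid.values / frac, period=grid.period)


def plot_cell_mask(grid: ModelGrid, plot_lon, plot_lat) -> np.ndarray:
    """Boolean mask of grid cells containing at least one plot."""
    plot_lon = np.asarray(plot_lon, dtype=float)
    plot_lat = np.asarray(plot_lat, dtype=float)
    half = 0.5  # 1-degree cells
    mask = np.zeros((grid.lat.size, grid.lon.size), dtype=bool)
    for plon, plat in zip(plot_lon, plot_lat):
        i = np.argmin(np.abs(grid.lat - plat))
        j = np.argmin(np.abs(grid.lon - plon))
        if (abs(grid.lat[i] - plat) <= half) and (abs(grid.lon[j] - plon) <= half):
            mask[i, j] = True
    return mask


@dataclass
class ComparisonStats:
    """Mask-restricted statistics of one model grid against observations."""

    source: str
    variable: str
    n_cells: int
    model_mean: float
    model_se: float
    obs_mean: float
    obs_se: float
    rmse: float
    pct_bias: float


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    se = (float(np.std(values, ddof=1) / math.sqrt(len(values)))
          if len(values) > 1 else float("nan"))
    return mean, se


def compare_at_cells(model: ModelGrid, obs: ModelGrid,
                     mask: np.ndarray) -> ComparisonStats:
    """Mean +/- SE, RMSE and percent bias over the masked cells.

    ``pct_bias = 100 * (mean_model - mean_obs) / mean_obs``; SEs are across
    cells. Cells with a missing value in either grid are dropped.
    """
    if not model.aligned_with(obs):
        raise GridError(f"{model.source} grid is not aligned with observations")
    if mask.shape != model.values.shape:
        raise GridError("mask shape does not match the grids")
    sel = mask & np.isfinite(model.values) & np.isfinite(obs.values)
    if not np.any(sel):
        raise GridError("comparison mask selects no valid cells")
    m = model.values[sel]
    o = obs.values[sel]
    model_mean, model_se = _mean_se(m)
    obs_mean, obs_se = _mean_se(o)
    rmse = float(np.sqrt(np.mean((m - o) ** 2)))
    pct_bias = 100.0 * (model_mean - obs_mean) / obs_mean
    return ComparisonStats(
        source=model.source, variable=model.variable, n_cells=int(sel.sum()),
        model_mean=model_mean, model_se=model_se,
        obs_mean=obs_mean, obs_se=obs_se, rmse=rmse, pct_bias=pct_bias)


def comparison_report(models: Sequence[ModelGrid], obs: ModelGrid,
                      mask: np.ndarray) -> pd.DataFrame:
    """Per-model comparison table plus the ensemble-mean row."""
    stats = [compare_at_cells(m, obs, mask) for m in models]
    rows = [{
        "source": s.source, "variable": s.variable, "n_cells": s.n_cells,
        "model_mean": s.model_mean, "model_se": s.model_se,
        "rmse": s.rmse, "pct_bias": s.pct_bias,
    } for s in stats]
    if len(stats) >= 2:
        rows.append({
            "source": "ensemble", "variable": obs.variable,
            "n_cells": stats[0].n_cells,
            "model_mean": ensemble_mean([s.model_mean for s in stats]),
            "model_se": float("nan"), "rmse": float("nan"),
            "pct_bias": float("nan"),
        })
    return pd.DataFrame(rows)


def ensemble_mean(source_means: Sequence[float]) -> float:
    """Unweighted mean across model sources."""
    if len(source_means) < 2:
        raise GridError("an ensemble needs at least two sources")
    return float(np.mean(np.asarray(source_means, dtype=float)))


def tau_map(agb: ModelGrid, wp: ModelGrid) -> tuple[ModelGrid, dict[str, float]]:
    """Cellwise residence time tau_w = AGB / W_P, with two basin summaries.

    Cells with non-positive W_P are masked (NaN). The summary reports both
    the mean of cellwise ratios and the ratio of cellwise means -- they
    differ in general and both conventions appear in basin syntheses.
    """
    if not agb.aligned_with(wp):
        raise GridError("AGB and W_P grids are not aligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(wp.values > 0, agb.values / wp.values, np.nan)
    grid = ModelGrid(source=agb.source, variable="tau_w",
                     lon=agb.lon, lat=agb.lat, values=tau, period=agb.period)
    ok = np.isfinite(tau)
    ok_means = np.isfinite(agb.values) & np.isfinite(wp.values) & (wp.values > 0)
    summary = {
        "mean_of_ratios": float(np.mean(tau[ok])) if ok.any() else float("nan"),
        "ratio_of_means": (float(np.mean(agb.values[ok_means])
                                 / np.mean(wp.values[ok_means]))
                           if ok_means.any() else float("nan")),
    }
    return grid, summary
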