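"""Shipped reference datasets.

Two small summary tables from the basin-wide Amazon plot-network synthesis
ship with the package as inputs for cross-checks and worked examples:

* ``regional_summary_published`` — per-region mean, standard error and plot
  count for above-ground biomass (``agb``, Mg C ha^-1), above-ground woody
  productivity (``wp``, Mg C ha^-1 yr^-1), stem mortality rate (``mu``,
  % yr^-1), woody biomass loss (``wl``, Mg C ha^-1 yr^-1), mean wood density
  (g cm^-3) and basal area (m^2 ha^-1), across the four substrate regions.
* ``dgvm_basin_means_published`` — basin mean +/- SE (over plot-containing
  1-degree cells, 2000-2008) of AGB and above-ground woody NPP for four
  dynamic global vegetation models, the RMSE of each against the kriged
  observations, and the corresponding observed means.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("forestdyn").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def regional_summary_published() -> pd.DataFrame:
    """Published per-region plot-network summary statistics."""
    return _load("regional_summary_published.csv")


def dgvm_basin_means_published() -> pd.DataFrame:
    """Published basin means of four vegetation models and the observations."""
    return _load("dgvm_basin_means_published.csv")
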