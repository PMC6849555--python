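import numpy as np
import pandas as pd
import pytest

from forestdyn.allometry import (
    AllometryConfig,
    AllometryContext,
    WeibullCoefficients,
    WoodDensityTable,
)
from forestdyn.census import PlotMetadata, PlotSeries, Status, TreeObservation


@pytest.fixture
def coeffs():
    return WeibullCoefficients(region="test", a=40.0, b=0.03, c=0.8)


@pytest.fixture
def wood_density_table():
    return WoodDensityTable(pd.DataFrame({
        "family": ["Fabaceae", "Fabaceae", "Lecythidaceae", "Moraceae"],
        "genus": ["Dicorynia", "Eperua", "Eschweilera", "Brosimum"],
        "species": ["guianensis", "falcata", "coriacea", "rubescens"],
        "density": [0.65, 0.70, 0.80, 0.62],
    }))


@pytest.fixture
def ctx(coeffs, wood_density_table):
    return AllometryContext(coeffs=coeffs, wood_density=wood_density_table,
                            config=AllometryConfig())


def make_obs(tree_id, date, dbh, status=Status.ALIVE, plot_id="P1",
             genus="Eperua", species="falcata", family="Fabaceae"):
    return TreeObservation(plot_id=plot_id, tree_id=tree_id, census_date=date,
                           dbh=dbh, status=status, family=family, genus=genus,
                           species=species)


def make_series(censuses, plot_id="P1", area=1.0, region="GuianaShield",
                lon=-58.0, lat=4.0):
    """Build a PlotSeries from {date: [(tree_id, dbh, status), ...]}."""
    meta = PlotMetadata(plot_id=plot_id, longitude=lon, latitude=lat,
                        area=area, region=region)
    out = []
    for date in sorted(censuses):
        trees = {}
        for tree_id, dbh, status in censuses[date]:
            trees[tree_id] = make_obs(tree_id, date, dbh, status, plot_id)
        out.append((date, trees))
    return PlotSeries(metadata=meta, censuses=out)


@pytest.fixture
def two_census_series():
    """Three trees over two censuses: one grows, one dies, one recruits."""
    return make_series({
        2000.0: [("t1", 20.0, Status.ALIVE), ("t2", 30.0, Status.ALIVE)],
        2005.0: [("t1", 22.0, Status.ALIVE), ("t2", 30.0, Status.DEAD),
                 ("t3", 12.0, Status.RECRUIT)],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
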