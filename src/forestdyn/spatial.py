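"""Spatial interpolation and spatially correlated regression.

Two halves:

* **Ordinary kriging** of plot-level variables onto a 1-degree grid — an
  empirical semivariogram on great-circle distances, a weighted least-squares
  fit of a bounded variogram model, the constrained kriging solve (weights
  sum to one) and leave-one-out cross-validation with median percentage bias.
* **Generalized least squares** with a Gaussian spatial correlation function
  ``corr(d) = (1-g) * exp(-(d/r)^2)``, estimated by maximum likelihood with
  the correlation range profiled out, plus AIC-based selection across a
  candidate model set relating AGB to productivity and mortality terms.

ML (not REML) estimation is used throughout so AIC values are comparable
across different fixed-effects structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


class SpatialError(ValueError):
    """Raised for invalid spatial inputs or failed fits."""


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km (vectorized over inputs)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_matrix(lon, lat, lon2=None, lat2=None):
    """Pairwise great-circle distances (km) between point sets."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon2 is None:
        lon2, lat2 = lon, lat
    else:
        lon2 = np.asarray(lon2, dtype=float)
        lat2 = np.asarray(lat2, dtype=float)
    return great_circle_km(lon[:, None], lat[:, None], lon2[None, :], lat2[None, :])


# ---------------------------------------------------------------------------
# Semivariogram
# ---------------------------------------------------------------------------

def empirical_semivariogram(
    lon: Sequence[float],
    lat: Sequence[float],
    values: Sequence[float],
    n_bins: int = 15,
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram on great-circle distances.

    For each lag bin, gamma(h) is the mean of half squared differences over
    all point pairs whose separation falls in the bin. Returns a DataFrame
    with columns ``lag`` (bin center, km), ``gamma`` and ``n_pairs``;
    empty bins are dropped.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SpatialError("semivariogram needs at least 2 points")
    d = distance_matrix(lon, lat)
    iu = np.triu_indices(v.size, k=1)
    dist = d[iu]
    if np.all(dist == 0):
        raise SpatialError("all points are coincident; no spatial structure")
    gamma = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    if max_lag is None:
        max_lag = float(dist.max()) / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(n_bins):
        sel = which == b
        if not np.any(sel):
            continue
        rows.append({"lag": 0.5 * (edges[b] + edges[b + 1]),
                     "gamma": float(gamma[sel].mean()),
                     "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariogramModel:
    """Bounded variogram: gamma(h) = nugget + psill * shape(h/range)."""

    model_type: str  # gaussian | exponential | spherical
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.model_type not in ("gaussian", "exponential", "spherical"):
            raise SpatialError(f"unknown variogram model {self.model_type!r}")
        if self.nugget < 0 or self.partial_sill < 0 or not self.range_km > 0:
            raise SpatialError(
                f"invalid variogram parameters: nugget={self.nugget}, "
                f"partial_sill={self.partial_sill}, range={self.range_km}")

    def gamma(self, h):
        """Semivariance at lag h (km); gamma(0) = 0, jumping to the nugget."""
        h = np.asarray(h, dtype=float)
        x = h / self.range_km
        if self.model_type == "gaussian":
            shape = 1.0 - np.exp(-(x ** 2))
        elif self.model_type == "exponential":
            shape = 1.0 - np.exp(-x)
        else:  # spherical
            shape = np.where(x < 1.0, 1.5 * x - 0.5 * x ** 3, 1.0)
        g = np.where(h > 0, self.nugget + self.partial_sill * shape, 0.0)
        return float(g) if g.ndim == 0 else g


def fit_variogram_model(
    empirical: pd.DataFrame,
    model_type: str = "gaussian",
) -> VariogramModel:
    """Weighted least-squares fit of (nugget, partial sill, range).

    Weights are the pair counts per bin. Needs at least 3 non-empty bins.
    """
    if len(empirical) < 3:
        raise SpatialError(
            f"variogram fit needs >= 3 non-empty lag bins, got {len(empirical)}")
    h = empirical["lag"].to_numpy(dtype=float)
    g = empirical["gamma"].to_numpy(dtype=float)
    w = np.sqrt(empirical["n_pairs"].to_numpy(dtype=float))

    def resid(params):
        nugget, psill, rng = params
        m = VariogramModel(model_type, max(nugget, 0.0), max(psill, 0.0),
                           max(rng, 1e-6))
        return w * (m.gamma(h) - g)

    sill0 = max(float(g.max()), 1e-12)
    x0 = np.array([0.1 * sill0, 0.9 * sill0, float(h.mean())])
    res = optimize.least_squares(
        resid, x0, bounds=([0.0, 0.0, 1e-6],
                           [np.inf, np.inf, 10.0 * float(h.max())]))
    if not res.success:
        raise SpatialError(f"variogram fit did not converge: {res.message} "
                           f"(x={res.x}, cost={res.cost})")
    nugget, psill, rng = res.x
    return VariogramModel(model_type, float(nugget), float(psill), float(rng))


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

@dataclass
class KrigingResult:
    """1-degree-grid ordinary-kriging predictions and variances."""

    grid_lon: np.ndarray  # 1D cell-center longitudes
    grid_lat: np.ndarray  # 1D cell-center latitudes
    prediction: np.ndarray  # (n_lat, n_lon)
    variance: np.ndarray  # (n_lat, n_lon)
    mask: np.ndarray  # bool, cells actually predicted


def _dedupe(lon, lat, values):
    """Average values at exactly duplicated coordinates (singular system)."""
    df = pd.DataFrame({"lon": lon, "lat": lat, "v": values})
    out = df.groupby(["lon", "lat"], as_index=False)["v"].mean()
    if len(out) < len(df):
        logger.warning("kriging input contains %d duplicated locations; "
                       "averaged before solving", len(df) - len(out))
    return (out["lon"].to_numpy(), out["lat"].to_numpy(), out["v"].to_numpy())


def _kriging_system(lon, lat, model: VariogramModel):
    n = len(lon)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model.gamma(distance_matrix(lon, lat))
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def kriging_weights(lon, lat, model: VariogramModel, lon0: float, lat0: float):
    """Solve the ordinary-kriging system for one target location.

    Returns ``(weights, lagrange_multiplier)``; the weights sum to 1 by the
    unbiasedness constraint.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    A = _kriging_system(lon, lat, model)
    b = np.empty(n + 1)
    b[:n] = model.gamma(great_circle_km(lon, lat, lon0, lat0))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise SpatialError(f"singular kriging system: {exc}") from exc
    return sol[:n], float(sol[n])


def krige_at_points(lon, lat, values, model: VariogramModel,
                    target_lon, target_lat):
    """Ordinary-kriging predictions and variances at arbitrary targets."""
    lon, lat, values = _dedupe(np.asarray(lon, dtype=float),
                               np.asarray(lat, dtype=float),
                               np.asarray(values, dtype=float))
    n = len(lon)
    if n < 1:
        raise SpatialError("kriging needs at least one data point")
    target_lon = np.atleast_1d(np.asarray(target_lon, dtype=float))
    target_lat = np.atleast_1d(np.asarray(target_lat, dtype=float))
    A = _kriging_system(lon, lat, model)
    B = np.empty((n + 1, target_lon.size))
    B[:n, :] = model.gamma(distance_matrix(lon, lat, target_lon, target_lat))
    B[n, :] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        # fall back to least squares for marginally singular systems
        sol = np.linalg.lstsq(A, B, rcond=None)[0]
    w = sol[:n, :]
    if np.any(w < -1e-8):
        logger.info("negative kriging weights occurred (min %.3g); "
                    "predictions may leave the data range", float(w.min()))
    pred = w.T @ values
    var = np.einsum("ij,ij->j", sol, B)
    return pred, np.maximum(var, 0.0)


def ordinary_krige(
    lon, lat, values,
    grid_lon, grid_lat,
    model: VariogramModel,
    mask: np.ndarray | None = None,
) -> KrigingResult:
    """Ordinary kriging of plot values onto a lon/lat cell-center grid.

    A global neighbourhood (all points) is used; the plot network is small
    enough that locality brings nothing but non-determinism.
    """
    grid_lon = np.asarray(grid_lon, dtype=float)
    grid_lat = np.asarray(grid_lat, dtype=float)
    glon, glat = np.meshgrid(grid_lon, grid_lat)
    if mask is None:
        mask = np.ones(glon.shape, dtype=bool)
    pred = np.full(glon.shape, np.nan)
    var = np.full(glon.shape, np.nan)
    sel = mask.ravel()
    p, v = krige_at_points(lon, lat, values, model,
                           glon.ravel()[sel], glat.ravel()[sel])
    pred.ravel()[sel] = p
    var.ravel()[sel] = v
    return KrigingResult(grid_lon=grid_lon, grid_lat=grid_lat,
                         prediction=pred, variance=var, mask=mask)


def loo_crossvalidate(
    lon, lat, values,
    model: VariogramModel | None = None,
    model_type: str = "gaussian",
    refit_per_fold: bool = False,
    n_bins: int = 15,
    max_lag: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-out cross-validation of the kriging interpolator.

    Each site in turn is predicted from all the others. By default the
    variogram is fitted once on the full data set and reused across folds;
    ``refit_per_fold`` refits it without the held-out site.

    Returns the per-site table (observed, predicted, pct_error) and summary
    statistics: ``median_abs_pct_bias`` (median of 100*|pred-obs|/obs, the
    headline figure) and ``median_signed_pct_bias``. Sites with a zero
    observation are excluded from the percentage summaries.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise SpatialError("leave-one-out cross-validation needs >= 3 points")
    if model is None and not refit_per_fold:
        emp = empirical_semivariogram(lon, lat, values, n_bins=n_bins,
                                      max_lag=max_lag)
        model = fit_variogram_model(emp, model_type)
    preds = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        m = model
        if refit_per_fold:
            emp = empirical_semivariogram(lon[rest], lat[rest], values[rest],
                                          n_bins=n_bins, max_lag=max_lag)
            m = fit_variogram_model(emp, model_type)
        preds[i] = krige_at_points(lon[rest], lat[rest], values[rest], m,
                                   lon[i], lat[i])[0][0]
    zero = values == 0
    if np.any(zero):
        logger.warning("%d site(s) with zero observation excluded from "
                       "percentage-bias summaries", int(zero.sum()))
        keep &= ~zero
    pct = np.full(n, np.nan)
    pct[keep] = 100.0 * (preds[keep] - values[keep]) / values[keep]
    table = pd.DataFrame({"longitude": lon, "latitude": lat,
                          "observed": values, "predicted": preds,
                          "pct_error": pct})
    stats = {
        "median_abs_pct_bias": float(np.nanmedian(np.abs(pct))),
        "median_signed_pct_bias": float(np.nanmedian(pct)),
    }
    return table, stats


# ---------------------------------------------------------------------------
# Gaussian spatial correlation + GLS
# ---------------------------------------------------------------------------

def gaussian_correlation(lon, lat, range_km: float, nugget: float = 0.0,
                         jitter: float = 1e-10) -> np.ndarray:
    """Gaussian spatial correlation matrix on great-circle distances.

    ``corr(d) = (1-g) * exp(-(d/r)^2)`` for d > 0 and exactly 1 on the
    diagonal. A tiny diagonal jitter guarantees positive definiteness.
    """
    if not range_km > 0:
        raise SpatialError(f"correlation range must be positive, got {range_km}")
    if not 0 <= nugget < 1:
        raise SpatialError(f"nugget proportion must lie in [0, 1), got {nugget}")
    d = distance_matrix(lon, lat)
    C = (1.0 - nugget) * np.exp(-((d / range_km) ** 2))
    np.fill_diagonal(C, 1.0)
    C[np.diag_indices_from(C)] += jitter
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise SpatialError(
            "Gaussian correlation matrix is not positive definite even after "
            f"jitter (range={range_km} km, nugget={nugget})") from exc
    return C


NUMERIC_TERMS = {"wp": "wp", "log_mu": "mu", "log_wl": "wl"}


@dataclass(frozen=True)
class GLSModelSpec:
    """Descriptor of one candidate fixed-effects structure.

    ``terms`` are drawn from {"wp", "log_mu", "log_wl", "region"};
    ``interactions`` pair a numeric term with "region". Mortality terms are
    natural-log transformed when the design is built.
    """

    name: str
    response: str = "agb"
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def describe(self) -> str:
        parts = list(self.terms)
        parts += [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "1"


def build_design(data: pd.DataFrame, spec: GLSModelSpec
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector and design matrix (with intercept) for a model spec."""
    y = data[spec.response].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}

    def numeric(term: str) -> np.ndarray:
        src = NUMERIC_TERMS[term]
        x = data[src].to_numpy(dtype=float)
        if term.startswith("log_"):
            if np.any(x <= 0):
                raise SpatialError(
                    f"{src} must be positive for log transformation")
            x = np.log(x)
        return x

    region_dummies: dict[str, np.ndarray] = {}
    if "region" in spec.terms or any(b == "region" for _, b in spec.interactions):
        levels = sorted(data["region"].unique())
        for lev in levels[1:]:
            region_dummies[lev] = (data["region"] == lev).to_numpy(dtype=float)

    for term in spec.terms:
        if term == "region":
            for lev, d in region_dummies.items():
                cols[f"region[{lev}]"] = d
        elif term in NUMERIC_TERMS:
            cols[term] = numeric(term)
        else:
            raise SpatialError(f"unknown model term {term!r}")
    for a, b in spec.interactions:
        if b != "region" or a not in NUMERIC_TERMS:
            raise SpatialError(f"unsupported interaction {a!r} x {b!r}")
        x = numeric(a)
        for lev, d in region_dummies.items():
            cols[f"{a}:region[{lev}]"] = x * d

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting
        _, R = np.linalg.qr(X)
        small = [names[j] for j in range(X.shape[1])
                 if abs(R[min(j, R.shape[0] - 1), j]) < 1e-8]
        raise SpatialError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased term(s): {', '.join(small) or 'undetermined'}")
    return y, X, names


@dataclass
class GLSFit:
    """A fitted spatially correlated regression model."""

    spec: GLSModelSpec
    params: pd.Series
    bse: pd.Series
    range_km: float
    nugget: float
    sigma2: float
    loglik: float
    aic: float
    pseudo_r2: float
    n_obs: int
    fitted: np.ndarray = field(repr=False)
    n_parameters: int = 0


def _gls_profile(y, X, C) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray]:
    """ML estimates given a fixed correlation matrix C.

    Returns (beta, sigma2_ml, loglik, fitted, XtVinvX_inv).
    """
    n = len(y)
    L = np.linalg.cholesky(C)
    yt = solve_triangular(L, y, lower=True)
    Xt = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)
    XtX_inv = np.linalg.inv(Xt.T @ Xt)
    fitted = X @ beta
    return beta, sigma2, loglik, fitted, XtX_inv


def pseudo_r2(fitted, observed) -> float:
    """Squared Pearson correlation between fitted and observed response."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if np.std(observed) == 0:
        raise SpatialError("pseudo-R^2 undefined for a zero-variance response")
    if np.std(fitted) == 0:
        return 0.0
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)


def fit_gls(
    spec: GLSModelSpec,
    data: pd.DataFrame,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    correlation: str | None = "gaussian",
    estimate_nugget: bool = False,
    range_bounds_km: tuple[float, float] | None = None,
) -> GLSFit:
    """Fit one candidate model by maximum likelihood.

    The spatial correlation range (and optionally a nugget proportion) is
    profiled out with a bounded scalar / Nelder-Mead search; the regression
    coefficients and error variance have closed forms given the correlation.
    ``correlation=None`` fits the independent-errors (OLS) model.
    """
    y, X, names = build_design(data, spec)
    n, p = X.shape
    lon = data[lon_col].to_numpy(dtype=float)
    lat = data[lat_col].to_numpy(dtype=float)

    if correlation is None:
        C = np.eye(n)
        beta, sigma2, loglik, fitted, XtX_inv = _gls_profile(y, X, C)
        range_km, nugget = 0.0, 0.0
        k = p + 1
    elif correlation == "gaussian":
        d = distance_matrix(lon, lat)
        pos = d[d > 0]
        if pos.size == 0:
            raise SpatialError("all observations are coincident")
        if range_bounds_km is None:
            range_bounds_km = (max(float(pos.min()) / 10.0, 1e-3),
                               4.0 * float(pos.max()))
        lo, hi = math.log(range_bounds_km[0]), math.log(range_bounds_km[1])

        def negll(params):
            log_r = params[0]
            g = 1.0 / (1.0 + math.exp(-params[1])) if len(params) > 1 else 0.0
            try:
                C = gaussian_correlation(lon, lat, math.exp(log_r), g)
                return -_gls_profile(y, X, C)[2]
            except (np.linalg.LinAlgError, SpatialError):
                return 1e12

        # coarse grid then local refinement keeps the profile search robust
        # against the degenerate zero-range (independence) local optimum
        grid = np.linspace(lo, hi, 25)
        best_logr = min(grid, key=lambda lr: negll([lr]))
        res = optimize.minimize_scalar(
            lambda lr: negll([lr]),
            bounds=(max(lo, best_logr - 1.5), min(hi, best_logr + 1.5)),
            method="bounded", options={"xatol": 1e-6})
        log_r, nugget = float(res.x), 0.0
        if estimate_nugget:
            g_grid = (0.01, 0.1, 0.2, 0.35, 0.5, 0.7)
            starts = [(lr, g) for lr in np.linspace(lo, hi, 13)
                      for g in g_grid]
            lr0, g0 = min(starts, key=lambda s: negll(
                [s[0], math.log(s[1] / (1 - s[1]))]))
            res2 = optimize.minimize(
                negll, x0=[lr0, math.log(g0 / (1 - g0))],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8})
            if res2.fun <= res.fun:
                log_r = float(res2.x[0])
                nugget = 1.0 / (1.0 + math.exp(-res2.x[1]))
        range_km = math.exp(log_r)
        C = gaussian_correlation(lon, lat, range_km, nugget)
        beta, sigma2, loglik, fitted, XtX_inv = _gls_profile(y, X, C)
        k = p + 2 + (1 if estimate_nugget else 0)
    else:
        raise SpatialError(f"unknown correlation structure {correlation!r}")

    sigma2_unbiased = sigma2 * n / max(n - p, 1)
    bse = np.sqrt(np.diag(sigma2_unbiased * XtX_inv))
    aic = -2.0 * loglik + 2.0 * k
    return GLSFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        range_km=range_km, nugget=nugget, sigma2=sigma2,
        loglik=loglik, aic=aic,
        pseudo_r2=pseudo_r2(fitted, y),
        n_obs=n, fitted=fitted, n_parameters=k,
    )


def table2_model_set() -> list[GLSModelSpec]:
    """The nine-candidate fixed-effects set relating AGB to its drivers.

    (A) single flux/rate predictors with region; (B) productivity plus the
    stem mortality rate, with each slope-by-region interaction; (C)
    productivity plus the biomass loss rate, likewise.
    """
    return [
        GLSModelSpec("1", terms=("log_mu", "region")),
        GLSModelSpec("2", terms=("log_wl", "region")),
        GLSModelSpec("3", terms=("wp", "region")),
        GLSModelSpec("4", terms=("wp", "log_mu", "region")),
        GLSModelSpec("5", terms=("wp", "log_mu", "region"),
                     interactions=(("log_mu", "region"),)),
        GLSModelSpec("6", terms=("wp", "log_mu", "region"),
                     interactions=(("wp", "region"),)),
        GLSModelSpec("7", terms=("wp", "log_wl", "region")),
        GLSModelSpec("8", terms=("wp", "log_wl", "region"),
                     interactions=(("log_wl", "region"),)),
        GLSModelSpec("9", terms=("wp", "log_wl", "region"),
                     interactions=(("wp", "region"),)),
    ]


def model_selection_table(
    specs: Sequence[GLSModelSpec],
    data: pd.DataFrame,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every candidate on the same rows and rank by AIC.

    Failed fits are kept in the table with ``failed=True``. The minimum-AIC
    model is flagged ``best``.
    """
    rows = []
    for spec in specs:
        try:
            fit = fit_gls(spec, data, **fit_kwargs)
            rows.append({"model": spec.name, "terms": spec.describe(),
                         "n_parameters": fit.n_parameters,
                         "loglik": fit.loglik, "aic": fit.aic,
                         "pseudo_r2": fit.pseudo_r2, "failed": False})
        except (SpatialError, np.linalg.LinAlgError) as exc:
            logger.warning("model %s failed to fit: %s", spec.name, exc)
            rows.append({"model": spec.name, "terms": spec.describe(),
                         "n_parameters": np.nan, "loglik": np.nan,
                         "aic": np.nan, "pseudo_r2": np.nan, "failed": True})
    table = pd.DataFrame(rows)
    table["best"] = False
    ok = table["aic"].notna()
    if ok.any():
        table.loc[table.loc[ok, "aic"].idxmin(), "best"] = True
    return table
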