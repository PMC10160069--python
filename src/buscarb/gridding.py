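"""Trend normalization and ordinary kriging of surface pCO2 with
autocorrelation-aware error propagation.

Observations spanning several decades are first normalized to a reference
year with the piecewise secular trend of surface-ocean pCO2 (1.5 uatm/yr up
to 1992, 1.9 uatm/yr afterwards). Normalized records are interpolated onto
a regular grid (default 0.1 deg) by ordinary kriging: a sample variogram is
computed, a model (spherical / exponential / gaussian) is fitted by weighted
least squares, and each cell is predicted from neighbours within a maximum
spherical distance (default 0.5 deg arc) under the unbiasedness constraint,
yielding a prediction and a kriging variance v (sigma = sqrt(v)) per cell.

The aggregate standard error of a gridded region is

    SE = sqrt(sum_i sigma_i^2) / sqrt(N_eff)

where N_eff is the effective number of grid cells after thinning at the
autocorrelation length scale read from the fitted variogram (the distance
where the semivariance levels off). The formula is applied exactly as
printed in the source analysis; note it does not reduce to sigma/sqrt(N)
for uniform sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from buscarb import geo

TREND_BOUNDARY_YEAR = 1992
TREND_RATE_EARLY = 1.5  # uatm/yr up to the boundary year
TREND_RATE_LATE = 1.9  # uatm/yr from the boundary year onward


def normalize_pco2(pco2_obs, year_obs, year_ref: int = 2020):
    """Normalize pCO2 observations to a reference year.

    Adds the piecewise-linear secular trend: years before the 1992 boundary
    accumulate 1.5 uatm/yr, years from 1992 to the reference year 1.9 uatm/yr.
    """
    pco2_obs = np.asarray(pco2_obs, dtype=float)
    year_obs = np.asarray(year_obs)
    if np.any(year_obs > year_ref):
        raise ValueError("observation year is after the reference year")
    early = np.clip(TREND_BOUNDARY_YEAR - year_obs, 0, None)
    early = np.minimum(early, year_ref - year_obs)
    late = year_ref - np.maximum(year_obs, TREND_BOUNDARY_YEAR)
    late = np.clip(late, 0, None)
    out = pco2_obs + TREND_RATE_EARLY * early + TREND_RATE_LATE * late
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# variograms


@dataclass
class EmpiricalVariogram:
    """Binned sample (Matheron) variogram."""

    lag_deg: np.ndarray
    semivariance: np.ndarray
    n_pairs: np.ndarray
    max_lag_deg: float

    @property
    def reliable(self) -> np.ndarray:
        """Bins with at least 10 contributing pairs."""
        return self.n_pairs >= 10


def empirical_variogram(
    lon,
    lat,
    values,
    n_lags: int = 15,
    max_lag_deg: float = 1.5,
    max_points: int = 4000,
    seed: int = 0,
) -> EmpiricalVariogram:
    """Classical Matheron estimator gamma(h) = mean((z_i - z_j)^2)/2 per lag
    bin of great-circle separation. Surveys larger than ``max_points`` are
    subsampled deterministically."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    values = np.asarray(values, dtype=float)
    if lon.size < 30:
        raise ValueError("at least 30 records required for a sample variogram")
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        raise ValueError("all coordinates identical")
    if lon.size > max_points:
        idx = np.random.default_rng(seed).choice(lon.size, max_points, replace=False)
        lon, lat, values = lon[idx], lat[idx], values[idx]

    vec = geo.unit_vectors(lon, lat)
    edges = np.linspace(0.0, max_lag_deg, n_lags + 1)
    gamma_sum = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=np.int64)
    chunk = 500
    for i0 in range(0, lon.size, chunk):
        i1 = min(i0 + chunk, lon.size)
        cos_angle = np.clip(vec[i0:i1] @ vec.T, -1.0, 1.0)
        h = np.degrees(np.arccos(cos_angle))
        dz2 = (values[i0:i1, None] - values[None, :]) ** 2
        # upper triangle only (global index j > i)
        jj = np.arange(lon.size)[None, :]
        mask = jj > np.arange(i0, i1)[:, None]
        h, dz2 = h[mask], dz2[mask]
        keep = (h > 0) & (h <= max_lag_deg)
        bins = np.minimum((h[keep] / max_lag_deg * n_lags).astype(int), n_lags - 1)
        np.add.at(gamma_sum, bins, dz2[keep] / 2.0)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, gamma_sum / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    valid = counts > 0
    return EmpiricalVariogram(centers[valid], gamma[valid], counts[valid], max_lag_deg)


_FAMILIES = ("spherical", "exponential", "gaussian")


def _unit_semivariance(family: str, h, range_deg: float):
    """Semivariance of a unit-sill model; ``range_deg`` is the practical
    range (distance where the model levels off) for every family."""
    h = np.asarray(h, dtype=float)
    a = max(range_deg, 1e-12)
    if family == "spherical":
        r = np.clip(h / a, 0.0, 1.0)
        return 1.5 * r - 0.5 * r**3
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * h / a)
    if family == "gaussian":
        return 1.0 - np.exp(-3.0 * (h / a) ** 2)
    raise ValueError(f"unknown variogram family: {family}")


@dataclass
class VariogramModel:
    """Fitted variogram: gamma(h) = nugget + partial_sill * g(h / range)."""

    family: str
    nugget: float  # uatm^2
    partial_sill: float  # uatm^2
    range_deg: float  # practical range, degrees of arc
    wrss: float = np.nan  # weighted residual sum of squares of the fit
    fallback: bool = False  # True when the WLS fit failed to converge

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family: {self.family}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_deg <= 0:
            raise ValueError("nugget/partial_sill must be >= 0 and range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def semivariance(self, h):
        h = np.asarray(h, dtype=float)
        gamma = self.nugget + self.partial_sill * _unit_semivariance(self.family, h, self.range_deg)
        return np.where(h <= 0, 0.0, gamma)  # gamma(0) = 0 by definition

    def autocorrelation_range_deg(self) -> float:
        """Distance where spatial dependence levels off; with the practical-
        range parameterization used here this is ``range_deg`` for every
        family."""
        return self.range_deg


def fit_variogram(emp: EmpiricalVariogram, families=_FAMILIES) -> VariogramModel:
    """Weighted least-squares fit over the candidate families; weights are
    pair counts / lag^2, and the family with the lowest weighted residual
    wins. Falls back to an exponential model with moment-based parameters
    (flagged) if no fit converges."""
    good = np.isfinite(emp.semivariance)
    lag = emp.lag_deg[good]
    gamma = emp.semivariance[good]
    npairs = emp.n_pairs[good]
    if lag.size < 5:
        raise ValueError("at least 5 valid lag bins required")
    w = np.sqrt(npairs / np.maximum(lag, lag[lag > 0].min() / 2) ** 2)

    sill0 = max(float(np.max(gamma)), 1e-12)
    nug0 = min(max(float(gamma[0]), 0.0), sill0)
    reach = np.nonzero(gamma >= 0.8 * sill0)[0]
    rng0 = float(lag[reach[0]]) if reach.size else float(lag[-1])
    rng0 = min(max(rng0, lag[0]), emp.max_lag_deg)

    best = None
    for family in families:
        def resid(p):
            nugget, psill, a = p
            return w * (nugget + psill * _unit_semivariance(family, lag, a) - gamma)

        try:
            sol = least_squares(
                resid,
                x0=[nug0, max(sill0 - nug0, 1e-9), rng0],
                bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 4.0 * emp.max_lag_deg]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if not sol.success and not np.isfinite(sol.cost):
            continue
        wrss = float(2.0 * sol.cost)
        if best is None or wrss < best.wrss:
            nugget, psill, a = (float(v) for v in sol.x)
            if psill <= 1e-8 * max(nugget, 1.0):
                # flat (pure-nugget) input: range is unidentifiable
                psill, a = 0.0, emp.max_lag_deg
            best = VariogramModel(family, nugget, psill, a, wrss=wrss)
    if best is None:
        return VariogramModel(
            "exponential", nug0, max(sill0 - nug0, 0.0), rng0, fallback=True
        )
    return best


# ---------------------------------------------------------------------------
# ordinary kriging


@dataclass
class GridSpec:
    """Regular lon/lat grid; cells are centred at min + (i + 1/2) * res."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.1

    def centers(self):
        lon = np.arange(self.lon_min + self.resolution / 2, self.lon_max, self.resolution)
        lat = np.arange(self.lat_min + self.resolution / 2, self.lat_max, self.resolution)
        return lon, lat

    @classmethod
    def around(cls, lon, lat, resolution: float = 0.1, pad: float = 0.05):
        return cls(
            float(np.min(lon)) - pad,
            float(np.max(lon)) + pad,
            float(np.min(lat)) - pad,
            float(np.max(lat)) + pad,
            resolution,
        )


@dataclass
class KrigingResult:
    """Gridded predictions with per-cell kriging variance.

    Arrays are (lat, lon); unpredicted cells (insufficient neighbours) are
    NaN. ``n_negative_var`` counts variances clamped to zero (round-off).
    """

    lon: np.ndarray
    lat: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    n_obs_used: np.ndarray
    model: VariogramModel
    n_duplicates_merged: int = 0
    n_negative_var: int = 0

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.variance)

    @property
    def n_predicted(self) -> int:
        return int(np.sum(np.isfinite(self.prediction)))

    def predicted_cells(self):
        """(lon, lat, sigma) of predicted cells in row-major scan order."""
        lon2d, lat2d = np.meshgrid(self.lon, self.lat)
        mask = np.isfinite(self.prediction)
        return lon2d[mask], lat2d[mask], self.sigma[mask]

    def to_dataset(self, name: str = "pco2") -> xr.Dataset:
        ds = xr.Dataset(
            {
                f"{name}_pred": (("lat", "lon"), self.prediction),
                f"{name}_var": (("lat", "lon"), self.variance),
                "n_obs": (("lat", "lon"), self.n_obs_used),
            },
            coords={"lon": self.lon, "lat": self.lat},
        )
        ds["lon"].attrs.update(standard_name="longitude", units="degrees_east")
        ds["lat"].attrs.update(standard_name="latitude", units="degrees_north")
        return ds

    def to_frame(self, name: str = "pco2") -> pd.DataFrame:
        lon2d, lat2d = np.meshgrid(self.lon, self.lat)
        return pd.DataFrame(
            {
                "lon": lon2d.ravel(),
                "lat": lat2d.ravel(),
                f"{name}_pred": self.prediction.ravel(),
                f"{name}_var": self.variance.ravel(),
                "n_obs": self.n_obs_used.ravel(),
            }
        )


def _merge_duplicates(lon, lat, values):
    key = np.round(lon, 9) + 1j * np.round(lat, 9)
    uniq, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    if uniq.size == lon.size:
        return lon, lat, values, 0
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, values)
    first = np.full(uniq.size, -1, dtype=int)
    first[inverse[::-1]] = np.arange(lon.size)[::-1]
    return lon[first], lat[first], sums / counts, int(lon.size - uniq.size)


def krige_grid(
    records: pd.DataFrame,
    model: VariogramModel,
    grid: GridSpec,
    value_col: str = "pco2",
    max_dist_deg: float = 0.5,
    min_neighbors: int = 5,
    max_neighbors: int = 40,
) -> KrigingResult:
    """Ordinary kriging of ``records[value_col]`` onto ``grid``.

    Per cell, the nearest observations (capped at ``max_neighbors``) within
    a great-circle arc of ``max_dist_deg`` enter the ordinary-kriging system
    with the unbiasedness (Lagrange-multiplier) constraint. Cells with fewer
    than ``min_neighbors`` observations in range stay unpredicted. Exact
    duplicate locations are averaged first (counted, to keep the system
    nonsingular); negative round-off variances are clamped to 0 and counted.
    """
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    values = records[value_col].to_numpy(dtype=float)
    lon, lat, values, n_dup = _merge_duplicates(lon, lat, values)

    obs_vec = geo.unit_vectors(lon, lat)
    tree = cKDTree(obs_vec)
    glon, glat = grid.centers()
    lon2d, lat2d = np.meshgrid(glon, glat)
    cell_vec = geo.unit_vectors(lon2d.ravel(), lat2d.ravel())

    pred = np.full(cell_vec.shape[0], np.nan)
    var = np.full(cell_vec.shape[0], np.nan)
    nobs = np.zeros(cell_vec.shape[0], dtype=int)
    n_negative = 0

    radius = geo.chord_length(max_dist_deg)
    dists, idxs = tree.query(
        cell_vec, k=min(max_neighbors, lon.size), distance_upper_bound=radius
    )
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)

    for c in range(cell_vec.shape[0]):
        valid = np.isfinite(dists[c])
        nb = idxs[c][valid]
        if nb.size < min_neighbors:
            continue
        nobs[c] = nb.size
        # semivariance among neighbours and to the target
        cosn = np.clip(obs_vec[nb] @ obs_vec[nb].T, -1.0, 1.0)
        h_nn = np.degrees(np.arccos(cosn))
        h_n0 = np.degrees(np.arcsin(np.clip(dists[c][valid] / 2.0, -1.0, 1.0))) * 2.0
        n = nb.size
        a = np.empty((n + 1, n + 1))
        a[:n, :n] = model.semivariance(h_nn)
        a[:n, :n][np.diag_indices(n)] = 0.0
        a[n, :] = 1.0
        a[:, n] = 1.0
        a[n, n] = 0.0
        b = np.empty(n + 1)
        b[:n] = model.semivariance(h_n0)
        b[n] = 1.0
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(a, b, rcond=None)[0]
        w, mu = sol[:n], sol[n]
        pred[c] = w @ values[nb]
        v = float(w @ b[:n] + mu)
        if v < 0:
            n_negative += 1
            v = 0.0
        var[c] = v

    shape = (glat.size, glon.size)
    return KrigingResult(
        lon=glon,
        lat=glat,
        prediction=pred.reshape(shape),
        variance=var.reshape(shape),
        n_obs_used=nobs.reshape(shape),
        model=model,
        n_duplicates_merged=n_dup,
        n_negative_var=n_negative,
    )


# ---------------------------------------------------------------------------
# effective sample size and aggregate standard error


def effective_n(lon, lat, autocorr_range_deg: float) -> int:
    """Effective number of grid cells by greedy thinning.

    Cells are scanned in the given (row-major) order; a cell is counted iff
    its great-circle distance to every previously counted cell exceeds the
    autocorrelation range. Floor of 1.
    """
    lon = np.asarray(lon, dtype=float).ravel()
    lat = np.asarray(lat, dtype=float).ravel()
    if lon.size == 0:
        raise ValueError("empty cell set")
    if autocorr_range_deg <= 0:
        raise ValueError("autocorrelation range must be > 0")
    vec = geo.unit_vectors(lon, lat)
    min_cos = np.cos(np.radians(autocorr_range_deg))
    kept = np.empty((lon.size, 3))
    kept[0] = vec[0]
    n_kept = 1
    for i in range(1, lon.size):
        if np.max(kept[:n_kept] @ vec[i]) < min_cos:
            kept[n_kept] = vec[i]
            n_kept += 1
    return n_kept


def aggregate_se(sigmas, n_eff: int) -> float:
    """Aggregate standard error SE = sqrt(sum sigma_i^2)/sqrt(n_eff),
    applied exactly as printed."""
    sigmas = np.asarray(sigmas, dtype=float)
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be >= 0")
    return float(np.sqrt(np.sum(sigmas**2)) / np.sqrt(n_eff))


@dataclass
class GridUncertainty:
    """Aggregate SE of a kriged region, with the N_eff bookkeeping."""

    se: float
    n: int
    n_eff: int
    autocorr_range_deg: float
    used_fallback: bool  # True when N_eff < 5% of N and N was used instead


def grid_uncertainty(result: KrigingResult, autocorr_range_deg: float | None = None) -> GridUncertainty:
    """SE of a kriged field with autocorrelation-corrected degrees of freedom.

    When the fitted variogram has so long a range that N_eff falls below 5%
    of N (degenerate thinning), the uncorrected N is used instead, flagged.
    """
    if autocorr_range_deg is None:
        autocorr_range_deg = result.model.autocorrelation_range_deg()
    lon, lat, sigma = result.predicted_cells()
    if lon.size == 0:
        raise ValueError("no predicted cells")
    n = lon.size
    n_eff = effective_n(lon, lat, autocorr_range_deg)
    fallback = n_eff < 0.05 * n
    eff = n if fallback else n_eff
    return GridUncertainty(aggregate_se(sigma, eff), n, n_eff, autocorr_range_deg, fallback)
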