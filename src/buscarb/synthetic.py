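"""Synthetic underway surveys and CTD bottle profiles.

The generator encodes the structure the downstream analysis assumes for an
eastern-boundary upwelling shelf: highest pCO2 nearshore where carbon-rich
water upwells, an exponential decline offshore as the water degasses and
biology draws carbon down, spatially autocorrelated noise whose variance
shrinks offshore with the upwelling signal, and a seasonal modulation.
Bottle profiles realize the forward model of the nutrient decomposition:
theta-S on the SACW/ESACW mixing lines and nutrients built from a configured
preformed concentration plus AOU times the fixed oxidation ratios, so that
the decomposition must recover the configured truth exactly in the
noise-free case.

Closed-form accessors (`mean_pco2`, `noise_sd`, `analytic_sd_crossing`,
`analytic_zone_mean_pco2`) expose the noise-free truth the generator is
built on, for use as independent references in tests and end-to-end checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from buscarb import geo, nutrients

# season convention: September-March = austral spring-summer,
# April-August = austral autumn-winter
SPRING_SUMMER_MONTHS = (9, 10, 11, 12, 1, 2, 3)
AUTUMN_WINTER_MONTHS = (4, 5, 6, 7, 8)


def season_of_month(month):
    """Map calendar months to 'spring_summer' / 'autumn_winter'."""
    month = np.asarray(month)
    out = np.where(np.isin(month, AUTUMN_WINTER_MONTHS), "autumn_winter", "spring_summer")
    return out.item() if out.ndim == 0 else out


def _default_coastline():
    # schematic meridional coastline off the Namibian/South African shelf
    return ((14.0, -16.0), (14.0, -34.0))


@dataclass
class SurveyConfig:
    """Configuration of a synthetic underway survey.

    The deterministic mean field is
    ``pco2(d) = pco2_offshore + (pco2_nearshore - pco2_offshore) * exp(-d/decay_scale_km)``
    with ``d`` the distance to the coast. The noise field is a zero-mean
    Gaussian random field with an exponential variogram (sill ``noise_sill``,
    practical range ``noise_range_deg``); its variance decays offshore in
    proportion to the mean anomaly, i.e. var(d) = noise_sill * exp(-d/decay).
    A seasonal sinusoid of amplitude ``seasonal_amplitude`` (peaking in the
    austral winter) is added by timestamp month.
    """

    coastline: tuple = field(default_factory=_default_coastline)
    lat_range: tuple = (-34.0, -16.0)
    offshore_max_km: float = 400.0
    pco2_nearshore: float = 800.0  # uatm
    pco2_offshore: float = 380.0  # uatm
    decay_scale_km: float = 80.0
    noise_sill: float = 3600.0  # uatm^2 at the coast
    noise_range_deg: float = 0.5
    seasonal_amplitude: float = 15.0  # uatm
    sst_source: float = 13.0  # deg C at the coast
    sst_offshore: float = 19.0  # deg C at offshore_max_km
    sss_mean: float = 35.2
    sss_sd: float = 0.08
    sst_noise_sd: float = 0.3
    wind_mean: float = 7.0  # m/s
    wind_sd: float = 2.0
    # 36 tracks cycle the calendar exactly three times, keeping the seasonal
    # modulation balanced in annual aggregates
    n_tracks: int = 36
    points_per_track: int = 100
    year: int = 2020
    seed: int = 0

    def __post_init__(self):
        coast = np.asarray(self.coastline, dtype=float)
        if coast.ndim != 2 or coast.shape[0] < 2:
            raise ValueError("coastline must have at least 2 vertices")
        if self.decay_scale_km <= 0:
            raise ValueError("decay_scale_km must be > 0")
        if self.noise_range_deg <= 0:
            raise ValueError("noise_range_deg must be > 0")
        if self.pco2_nearshore < self.pco2_offshore:
            raise ValueError("pco2_nearshore must be >= pco2_offshore")

    # ---- closed-form truth -------------------------------------------------

    def mean_pco2(self, dist_km):
        """Noise-free cross-shelf mean field (uatm)."""
        d = np.asarray(dist_km, dtype=float)
        return self.pco2_offshore + (self.pco2_nearshore - self.pco2_offshore) * np.exp(
            -d / self.decay_scale_km
        )

    def mean_sst(self, dist_km):
        """SST warming linearly from the source value at the coast."""
        d = np.asarray(dist_km, dtype=float)
        frac = np.clip(d / self.offshore_max_km, 0.0, 1.0)
        return self.sst_source + (self.sst_offshore - self.sst_source) * frac

    def noise_var(self, dist_km):
        """Marginal noise variance (uatm^2), decaying with the mean anomaly."""
        d = np.asarray(dist_km, dtype=float)
        return self.noise_sill * np.exp(-d / self.decay_scale_km)

    def noise_sd(self, dist_km):
        return np.sqrt(self.noise_var(dist_km))

    def analytic_sd_crossing(self, sd_threshold: float = 30.0) -> float:
        """Distance (km) where the noise s.d. envelope crosses the threshold."""
        if self.noise_sill <= sd_threshold**2:
            return 0.0
        return self.decay_scale_km * np.log(self.noise_sill / sd_threshold**2)

    def analytic_zone_mean_pco2(self, boundary_km: float) -> float:
        """Mean of the noise-free field over [0, boundary_km]."""
        d = boundary_km
        amp = self.pco2_nearshore - self.pco2_offshore
        el = self.decay_scale_km
        return self.pco2_offshore + amp * (el / d) * (1.0 - np.exp(-d / el))

    def analytic_zone_mean_sst(self, boundary_km: float) -> float:
        frac = min(boundary_km, self.offshore_max_km) / self.offshore_max_km
        return self.sst_source + (self.sst_offshore - self.sst_source) * frac / 2.0


def seasonal_term(month, amplitude: float):
    """Seasonal pCO2 modulation by month; peaks in June (austral winter)."""
    month = np.asarray(month, dtype=float)
    return amplitude * np.cos(2.0 * np.pi * (month - 6.0) / 12.0)


def _exponential_field(vectors: np.ndarray, range_deg: float, rng) -> np.ndarray:
    """Unit-variance Gaussian field with exponential variogram, exact via
    Cholesky of the covariance on the observation points."""
    cos_angle = np.clip(vectors @ vectors.T, -1.0, 1.0)
    h = np.degrees(np.arccos(cos_angle))
    cov = np.exp(-3.0 * h / range_deg)  # practical range = range_deg
    cov[np.diag_indices_from(cov)] += 1e-9
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(vectors.shape[0])


def generate_underway_survey(config: SurveyConfig) -> pd.DataFrame:
    """Generate one synthetic underway survey.

    Returns a DataFrame with columns lon, lat, time, pco2, sst, sss, wind10,
    dist_coast_km; tracks are cross-shelf transects at random latitudes,
    months cycling through the year. Bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    lat0, lat1 = sorted(config.lat_range)
    coast = np.asarray(config.coastline, dtype=float)
    coast_lon = float(np.mean(coast[:, 0]))

    rows = []
    for track in range(config.n_tracks):
        lat = float(rng.uniform(lat0, lat1))
        month = track % 12 + 1
        # points from near the coast out to offshore_max, slight jitter
        d = np.linspace(1.0, config.offshore_max_km, config.points_per_track)
        d = d + rng.uniform(-0.4, 0.4, d.size) * np.diff(d, prepend=0.0)
        d = np.clip(d, 0.2, config.offshore_max_km)
        dlon = d / (geo.KM_PER_ARC_DEG * np.cos(np.radians(lat)))
        lon = coast_lon - dlon  # ocean to the west of the coast
        lats = np.full(d.size, lat) + rng.uniform(-0.01, 0.01, d.size)
        t0 = pd.Timestamp(year=config.year, month=month, day=15, hour=6)
        times = t0 + pd.to_timedelta(np.arange(d.size) * 5, unit="min")
        rows.append(
            pd.DataFrame(
                {"lon": lon, "lat": lats, "time": times, "track": track, "month": month}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["dist_coast_km"] = geo.dist_to_coast_km(df["lon"].to_numpy(), df["lat"].to_numpy(), coast)

    d = df["dist_coast_km"].to_numpy()
    mean = config.mean_pco2(d)
    if config.noise_sill > 0:
        z = _exponential_field(
            geo.unit_vectors(df["lon"].to_numpy(), df["lat"].to_numpy()),
            config.noise_range_deg,
            rng,
        )
        noise = np.sqrt(config.noise_var(d)) * z
    else:
        rng.standard_normal(len(df))  # keep the stream position stable
        noise = 0.0
    df["pco2"] = mean + noise + seasonal_term(df["month"].to_numpy(), config.seasonal_amplitude)
    df["sst"] = config.mean_sst(d) + rng.normal(0.0, config.sst_noise_sd, len(df))
    df["sss"] = config.sss_mean + rng.normal(0.0, config.sss_sd, len(df))
    df["wind10"] = np.clip(rng.normal(config.wind_mean, config.wind_sd, len(df)), 0.0, None)
    df["pco2"] = df["pco2"].clip(lower=1.0)
    return df.drop(columns=["track"])


@dataclass
class ProfileConfig:
    """Configuration of synthetic CTD/bottle profiles.

    Bottles lie on the mixture of the SACW and ESACW theta-S lines
    (``f_sacw`` weighting SACW), oxygen follows O2 = O2_sat(theta, S) - AOU
    with AOU saturating with depth, and nutrients are constructed as
    preformed truth + oxidation-ratio * AOU -- the exact forward model of
    the preformed/regenerated decomposition.
    """

    f_sacw: float = 0.7
    surface_t: float = 16.0
    surface_s: float = 35.2
    o2_deficit_max: float = 120.0  # umol/kg AOU at depth
    aou_efold_m: float = 150.0
    n_pref_true: float = 7.0  # umol/kg
    p_pref_true: float = 0.7
    n_stations: int = 12
    depths: tuple = (25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 500.0)
    sal_shallow: float = 35.4
    sal_deep: float = 34.5
    ta_slope: float = 62.0  # umol/kg per salinity unit
    ta_intercept: float = 120.0
    noise_sd: dict = field(
        default_factory=lambda: {
            "theta": 0.05,
            "sal": 0.01,
            "o2": 2.0,
            "no3": 0.3,
            "po4": 0.03,
            "ta": 4.0,
            "dic": 4.0,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_sacw <= 1.0:
            raise ValueError("f_sacw must lie in [0, 1]")

    def aou_profile(self, depth_m):
        depth = np.asarray(depth_m, dtype=float)
        return self.o2_deficit_max * (1.0 - np.exp(-depth / self.aou_efold_m))


def generate_ctd_profiles(config: ProfileConfig) -> pd.DataFrame:
    """Generate bottle samples for ``n_stations`` stations.

    Returns a DataFrame with columns station, depth_m, temp_c, sal,
    o2_umolkg, no3_umolkg, po4_umolkg, ta_umolkg, dic_umolkg. Negative
    nutrient draws are clipped at 0; the clip count is reported in
    ``df.attrs["n_clipped_negative"]``.
    """
    rng = np.random.default_rng(config.seed)
    ns = config.noise_sd
    rows = []
    for st in range(config.n_stations):
        depth = np.asarray(config.depths, dtype=float)
        frac = (depth - depth.min()) / max(depth.max() - depth.min(), 1.0)
        sal = config.sal_shallow + (config.sal_deep - config.sal_shallow) * frac
        theta_mix = config.f_sacw * nutrients.theta_sacw(sal) + (
            1.0 - config.f_sacw
        ) * nutrients.theta_esacw(sal)
        sal = sal + rng.normal(0.0, ns["sal"], depth.size)
        theta = theta_mix + rng.normal(0.0, ns["theta"], depth.size)
        aou = config.aou_profile(depth)
        o2 = nutrients.o2_saturation(theta, sal) - aou + rng.normal(0.0, ns["o2"], depth.size)
        no3 = config.n_pref_true + nutrients.R_N_O2 * aou + rng.normal(0.0, ns["no3"], depth.size)
        po4 = config.p_pref_true + nutrients.R_P_O2 * aou + rng.normal(0.0, ns["po4"], depth.size)
        ta = config.ta_slope * sal + config.ta_intercept + rng.normal(0.0, ns["ta"], depth.size)
        dic = 0.93 * ta + (106.0 / 138.0) * aou + rng.normal(0.0, ns["dic"], depth.size)
        rows.append(
            pd.DataFrame(
                {
                    "station": st,
                    "depth_m": depth,
                    "temp_c": theta,
                    "sal": sal,
                    "o2_umolkg": o2,
                    "no3_umolkg": no3,
                    "po4_umolkg": po4,
                    "ta_umolkg": ta,
                    "dic_umolkg": dic,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    n_clipped = int((df["no3_umolkg"] < 0).sum() + (df["po4_umolkg"] < 0).sum())
    df["no3_umolkg"] = df["no3_umolkg"].clip(lower=0.0)
    df["po4_umolkg"] = df["po4_umolkg"].clip(lower=0.0)
    df.attrs["n_clipped_negative"] = n_clipped
    return df
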