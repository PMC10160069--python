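"""Air-sea CO2 fluxes under six gas-transfer-velocity parameterizations.

The flux across the air-sea interface is

    FCO2 = K0 * k * (pCO2_sw - pCO2_at)

with K0 the CO2 solubility and k the gas transfer velocity, a polynomial in
10 m wind speed scaled by (Sc/660)^-1/2, where Sc is the Schmidt number of
CO2 in seawater and 660 its value at 20 deg C. Positive flux = outgassing
(sea to air). Six published wind-speed parameterizations of k are carried
as data entries so the spread across them can be quantified; the quadratic
coefficient 0.251 (KW14) is the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from buscarb.zones import UpwellingZone

MOLAR_MASS_C = 12.011  # g/mol
SECONDS_PER_YEAR = 3.1536e7
HOURS_PER_YEAR = SECONDS_PER_YEAR / 3600.0
RHO_SURFACE = 1025.0  # kg/m3, converts per-kg solubility to per-m3

# Schmidt number of CO2 in seawater, 4th-order polynomial in t (deg C),
# Wanninkhof (2014) seawater fit.
SCHMIDT_COEFFS = (2116.8, -136.25, 4.7353, -0.092307, 0.0007555)


@dataclass(frozen=True)
class GasTransferParam:
    """k660 = a0 + a1*u + a2*u^2 + a3*u^3 (cm/h), times (Sc/660)^-1/2."""

    name: str
    a0: float
    a1: float
    a2: float
    a3: float
    citation: str

    def k660(self, u):
        u = np.asarray(u, dtype=float)
        return self.a0 + self.a1 * u + self.a2 * u**2 + self.a3 * u**3


GAS_TRANSFER_PARAMS = {
    p.name: p
    for p in (
        GasTransferParam("KW14", 0.0, 0.0, 0.251, 0.0, "Wanninkhof 2014, Limnol. Oceanogr. Methods 12"),
        GasTransferParam("KW92", 0.0, 0.0, 0.31, 0.0, "Wanninkhof 1992, JGR 97 (short-term winds)"),
        GasTransferParam("WM99", 0.0, 0.0, 0.0, 0.0283, "Wanninkhof & McGillis 1999, GRL 26"),
        GasTransferParam("N2000", 0.0, 0.333, 0.222, 0.0, "Nightingale et al. 2000, GBC 14"),
        GasTransferParam("McG2001", 3.3, 0.0, 0.0, 0.026, "McGillis et al. 2001, JGR 106"),
        GasTransferParam("Ho2006", 0.0, 0.0, 0.266, 0.0, "Ho et al. 2006, GRL 33"),
    )
}


def schmidt_number(temp):
    """Schmidt number of CO2 in seawater at temp (deg C)."""
    temp = np.asarray(temp, dtype=float)
    if np.any((temp < -2.0) | (temp > 40.0)):
        raise ValueError("temperature outside the Schmidt-number fit range")
    out = sum(c * temp**i for i, c in enumerate(SCHMIDT_COEFFS))
    return float(out) if out.ndim == 0 else out


def gas_transfer_velocity(u, sc, param="KW14"):
    """Gas transfer velocity k (cm/h) for wind speed u (m/s) and Schmidt
    number sc, under the named parameterization."""
    if isinstance(param, str):
        try:
            param = GAS_TRANSFER_PARAMS[param]
        except KeyError:
            raise ValueError(f"unknown gas transfer parameterization: {param!r}") from None
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    sc = np.asarray(sc, dtype=float)
    out = param.k660(u) * (sc / 660.0) ** -0.5
    return float(out) if out.ndim == 0 else out


def co2_flux(pco2_sw, pco2_at, k0, k_cmh, rho=RHO_SURFACE):
    """Air-sea CO2 flux (mol C m-2 yr-1), positive = outgassing.

    Unit chain: K0 [mol kg-1 atm-1] * rho [kg m-3] -> mol m-3 atm-1;
    k [cm/h] -> m/yr; delta-pCO2 [uatm] -> atm.
    """
    k0 = np.asarray(k0, dtype=float)
    k_cmh = np.asarray(k_cmh, dtype=float)
    if np.any(k0 <= 0) or np.any(k_cmh < 0):
        raise ValueError("K0 must be > 0 and k >= 0")
    dp = (np.asarray(pco2_sw, dtype=float) - np.asarray(pco2_at, dtype=float)) * 1e-6
    out = k0 * rho * (k_cmh * 0.01 * HOURS_PER_YEAR) * dp
    return float(out) if out.ndim == 0 else out


def total_from_mean_flux(mean_flux_molm2yr: float, area_km2: float) -> float:
    """Area-integrated flux in Tg C/yr from a mean areal flux."""
    return mean_flux_molm2yr * area_km2 * 1e6 * MOLAR_MASS_C / 1e12


@dataclass
class FluxEstimate:
    """An area-integrated air-sea CO2 flux for one subsystem/season/k-form."""

    subsystem: str
    season: str  # "annual" | "spring_summer" | "autumn_winter"
    param: str
    mean_flux_molm2yr: float
    area_km2: float
    total_tgc_yr: float
    se_total_tgc_yr: float = np.nan
    inputs: dict = field(default_factory=dict)


def flux_from_region_means(
    pco2_sw: float,
    pco2_at: float,
    sst: float,
    sss: float,
    wind: float,
    zone: UpwellingZone,
    param: str = "KW14",
    season: str = "annual",
    pco2_se: float = 0.0,
) -> FluxEstimate:
    """Region-average flux: K0, Sc and k evaluated at the zone-mean SST, SSS
    and wind, applied to the zone-mean delta-pCO2, then integrated over the
    zone area. The SE of the zone-mean pCO2 propagates linearly."""
    from buscarb.carbonate import solubility_k0

    k0 = solubility_k0(sst, sss)
    k = gas_transfer_velocity(wind, schmidt_number(sst), param)
    mean_flux = co2_flux(pco2_sw, pco2_at, k0, k)
    total = total_from_mean_flux(mean_flux, zone.area_km2)
    se_flux = co2_flux(pco2_se, 0.0, k0, k) if pco2_se else 0.0
    return FluxEstimate(
        subsystem=zone.name,
        season=season,
        param=param if isinstance(param, str) else param.name,
        mean_flux_molm2yr=mean_flux,
        area_km2=zone.area_km2,
        total_tgc_yr=total,
        se_total_tgc_yr=total_from_mean_flux(se_flux, zone.area_km2),
        inputs={
            "pco2_sw_uatm": pco2_sw,
            "pco2_at_uatm": pco2_at,
            "sst_c": sst,
            "sss": sss,
            "wind10_ms": wind,
            "k0_mol_kg_atm": k0,
            "k_cm_h": k,
            "pco2_se_uatm": pco2_se,
        },
    )


def integrate_flux(flux_field, zone_mask, zone: UpwellingZone, param: str = "cellwise", season: str = "annual") -> FluxEstimate:
    """Cell-wise alternative: mean of per-cell fluxes inside the zone times
    the zone area. Offered because wind-pCO2 covariance matters; the
    region-average mode is the reference behaviour."""
    flux_field = np.asarray(flux_field, dtype=float)
    zone_mask = np.asarray(zone_mask, dtype=bool)
    vals = flux_field[zone_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty zone: no finite flux cells")
    mean_flux = float(np.mean(vals))
    return FluxEstimate(
        subsystem=zone.name,
        season=season,
        param=param,
        mean_flux_molm2yr=mean_flux,
        area_km2=zone.area_km2,
        total_tgc_yr=total_from_mean_flux(mean_flux, zone.area_km2),
        inputs={"n_cells": int(vals.size)},
    )


def parameterization_spread(estimates) -> tuple[float, float, float]:
    """(min, max, percent spread) of |area-integrated flux| across k-forms.

    percent = (max - min) / min * 100 on flux magnitudes; all estimates must
    share subsystem and season (identical input grids).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("at least 2 estimates required")
    keys = {(e.subsystem, e.season) for e in estimates}
    if len(keys) > 1:
        raise ValueError(f"estimates mix subsystems/seasons: {sorted(keys)}")
    mags = np.array([abs(e.total_tgc_yr) for e in estimates])
    lo, hi = float(mags.min()), float(mags.max())
    if lo == 0.0:
        raise ValueError("zero-magnitude flux estimate; spread undefined")
    return lo, hi, (hi - lo) / lo * 100.0


def percent_spread(low: float, high: float) -> float:
    """Percent spread (max-min)/min*100 on two flux magnitudes."""
    lo, hi = sorted((abs(low), abs(high)))
    if lo == 0.0:
        raise ValueError("zero-magnitude flux; spread undefined")
    return (hi - lo) / lo * 100.0
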