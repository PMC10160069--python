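"""Seawater CO2-system solver: TA/DIC/pCO2 interconversion, the TA-salinity
relation, and the source-water validation / non-thermal pCO2 reconstruction.

The solver works on the total hydrogen-ion scale at surface pressure with
the carbonic-acid dissociation constants of Mehrbach et al. as refit by
Dickson & Millero (1987), the borate constant of Dickson (1990), the water
constant of Millero (1995), and CO2 solubility after Weiss (1974). Total
boron follows Uppstroem (1974). Phosphate and silicate alkalinity are
neglected, consistent with a surface application in which TA itself is
reconstructed from salinity.

Total alkalinity is modelled as

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_F - [HSO4-] - [HF]

and pH is found by safeguarded bisection on [4, 11] (tolerance 1e-8),
after which pCO2 = [CO2*]/K0 or DIC = [CO2*](1 + K1/[H] + K1K2/[H]^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from buscarb.nutrients import REDFIELD_C_N

T_KELVIN = 273.15
PH_LO, PH_HI = 4.0, 11.0
PH_TOL = 1e-8


def _check_ts(temp, sal):
    temp = np.asarray(temp, dtype=float)
    sal = np.asarray(sal, dtype=float)
    if np.any((temp < -2.0) | (temp > 40.0)) or np.any((sal < 0.0) | (sal > 42.0)):
        raise ValueError("temperature/salinity outside the fitted range")
    return temp, sal


def solubility_k0(temp, sal):
    """CO2 solubility K0 (mol kg-1 atm-1), Weiss (1974) fit."""
    temp, sal = _check_ts(temp, sal)
    tk100 = (temp + T_KELVIN) / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / tk100
        + 23.3585 * np.log(tk100)
        + sal * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2)
    )
    out = np.exp(ln_k0)
    return float(out) if out.ndim == 0 else out


@dataclass
class EquilibriumConstants:
    """Equilibrium constants at given temp/sal; K1, K2, KB, KW on the total
    scale, KS and KF on the free scale (used for scale conversion only).
    BT/ST/FT are total boron/sulfate/fluoride (mol/kg)."""

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    ks: float
    kf: float
    bt: float
    st: float
    ft: float


def equilibrium_constants(temp, sal) -> EquilibriumConstants:
    temp, sal = _check_ts(temp, sal)
    tk = temp + T_KELVIN
    ln_tk = np.log(tk)
    sqrt_s = np.sqrt(sal)

    # total concentrations, mol/kg-sw
    bt = 0.0004157 * sal / 35.0  # Uppstroem 1974
    st = (0.14 / 96.062) * sal / 1.80655  # Morris & Riley 1966
    ft = (0.000067 / 18.998) * sal / 1.80655  # Riley 1965

    # bisulfate, Dickson 1990a, free scale
    ion_s = 19.924 * sal / (1000.0 - 1.005 * sal)
    ln_ks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * ln_tk
        + (-13856.0 / tk + 324.57 - 47.986 * ln_tk) * np.sqrt(ion_s)
        + (35474.0 / tk - 771.54 + 114.723 * ln_tk) * ion_s
        - (2698.0 / tk) * ion_s**1.5
        + (1776.0 / tk) * ion_s**2
        + np.log(1.0 - 0.001005 * sal)
    )
    ks = np.exp(ln_ks)

    # hydrogen fluoride, Dickson & Riley 1979, free scale
    ln_kf = 1590.2 / tk - 12.641 + 1.525 * np.sqrt(ion_s) + np.log(1.0 - 0.001005 * sal)
    kf = np.exp(ln_kf)

    sws_to_total = (1.0 + st / ks) / (1.0 + st / ks + ft / kf)

    # carbonic acid, Mehrbach et al. refit by Dickson & Millero 1987 (SWS)
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * ln_tk - 0.0118 * sal + 0.000116 * sal**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * sal + 0.000118 * sal**2
    k1 = 10.0**-pk1 * sws_to_total
    k2 = 10.0**-pk2 * sws_to_total

    # boric acid, Dickson 1990b (total scale)
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * sal + 1.728 * sal**1.5 - 0.0996 * sal**2) / tk
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * sal
        - (24.4344 + 25.085 * sqrt_s + 0.2474 * sal) * ln_tk
        + 0.053105 * sqrt_s * tk
    )
    kb = np.exp(ln_kb)

    # water, Millero 1995 (SWS)
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sqrt_s
        - 0.01615 * sal
    )
    kw = np.exp(ln_kw) * sws_to_total

    return EquilibriumConstants(
        k0=solubility_k0(temp, sal), k1=k1, k2=k2, kb=kb, kw=kw, ks=ks, kf=kf, bt=bt, st=st, ft=ft
    )


def _minor_alkalinity(h, k: EquilibriumConstants):
    """Borate + water - free-H - bisulfate - HF contributions (mol/kg);
    ``h`` on the total scale."""
    h_free = h / (1.0 + k.st / k.ks)
    boh4 = k.bt * k.kb / (k.kb + h)
    oh = k.kw / h
    hso4 = k.st * h_free / (k.ks + h_free)
    hf = k.ft * h_free / (k.kf + h_free)
    return boh4 + oh - h_free - hso4 - hf


def _bisect_ph(residual, shape):
    """Vectorized safeguarded bisection of ``residual`` (decreasing in pH
    numerically as written: residual is monotone in h) over [PH_LO, PH_HI]."""
    lo = np.full(shape, PH_LO)
    hi = np.full(shape, PH_HI)
    r_lo = residual(10.0**-lo)
    r_hi = residual(10.0**-hi)
    ok = (r_lo <= 0) & (r_hi >= 0)
    # ~50 halvings take the bracket width far below PH_TOL
    n_iter = int(np.ceil(np.log2((PH_HI - PH_LO) / PH_TOL))) + 2
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = residual(10.0**-mid)
        take_hi = r_mid <= 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    ph = 0.5 * (lo + hi)
    return np.where(ok, ph, np.nan)


def _finish(out, on_fail: str, what: str):
    bad = ~np.isfinite(out)
    if on_fail == "raise" and np.any(bad):
        raise ValueError(f"no pH root in [{PH_LO}, {PH_HI}] for {what}")
    if out.ndim == 0:
        return float(out)
    return out


def pco2_from_ta_dic(ta, dic, temp, sal, on_fail: str = "raise"):
    """pCO2 (uatm) from total alkalinity and DIC (umol/kg) at temp (deg C)
    and practical salinity. ``on_fail='nan'`` converts bracket failures to
    NaN instead of raising (used for per-cell grid work)."""
    ta = np.asarray(ta, dtype=float) * 1e-6
    dic = np.asarray(dic, dtype=float) * 1e-6
    if np.any((ta < 1000e-6) | (ta > 3500e-6)) or np.any((dic < 800e-6) | (dic > 3200e-6)):
        raise ValueError("TA/DIC outside the supported range")
    k = equilibrium_constants(temp, sal)

    def residual(h):
        den = h**2 + k.k1 * h + k.k1 * k.k2
        carb_alk = dic * (k.k1 * h + 2.0 * k.k1 * k.k2) / den
        return (carb_alk + _minor_alkalinity(h, k)) - ta

    ph = _bisect_ph(residual, np.broadcast(ta, dic, np.asarray(temp), np.asarray(sal)).shape)
    h = 10.0**-ph
    co2_star = dic * h**2 / (h**2 + k.k1 * h + k.k1 * k.k2)
    return _finish(co2_star / k.k0 * 1e6, on_fail, "pco2_from_ta_dic")


def dic_from_ta_pco2(ta, pco2, temp, sal, on_fail: str = "raise"):
    """DIC (umol/kg) from total alkalinity (umol/kg) and pCO2 (uatm)."""
    ta = np.asarray(ta, dtype=float) * 1e-6
    pco2 = np.asarray(pco2, dtype=float)
    if np.any((ta < 1000e-6) | (ta > 3500e-6)):
        raise ValueError("TA outside the supported range")
    k = equilibrium_constants(temp, sal)
    co2_star = k.k0 * pco2 * 1e-6

    def residual(h):
        carb_alk = co2_star * (k.k1 / h + 2.0 * k.k1 * k.k2 / h**2)
        return (carb_alk + _minor_alkalinity(h, k)) - ta

    ph = _bisect_ph(residual, np.broadcast(ta, pco2, np.asarray(temp), np.asarray(sal)).shape)
    h = 10.0**-ph
    dic = co2_star * (1.0 + k.k1 / h + k.k1 * k.k2 / h**2)
    return _finish(dic * 1e6, on_fail, "dic_from_ta_pco2")


def ph_from_ta_dic(ta, dic, temp, sal, on_fail: str = "raise"):
    """Total-scale pH from TA and DIC (umol/kg)."""
    ta = np.asarray(ta, dtype=float) * 1e-6
    dic = np.asarray(dic, dtype=float) * 1e-6
    k = equilibrium_constants(temp, sal)

    def residual(h):
        den = h**2 + k.k1 * h + k.k1 * k.k2
        return dic * (k.k1 * h + 2.0 * k.k1 * k.k2) / den + _minor_alkalinity(h, k) - ta

    ph = _bisect_ph(residual, np.broadcast(ta, dic, np.asarray(temp), np.asarray(sal)).shape)
    return _finish(ph, on_fail, "ph_from_ta_dic")


def fco2_to_pco2(fco2, temp):
    """Convert CO2 fugacity to partial pressure (both uatm) with the virial
    correction (Weiss 1974); ~0.3-0.4% at surface conditions."""
    fco2 = np.asarray(fco2, dtype=float)
    tk = np.asarray(temp, dtype=float) + T_KELVIN
    b = -1636.75 + 12.0408 * tk - 3.27957e-2 * tk**2 + 3.16528e-5 * tk**3  # cm3/mol
    delta = 57.7 - 0.118 * tk
    fugfac = np.exp((b + 2.0 * delta) * 1e-6 * 101325.0 / (8.31446 * tk))
    out = fco2 / fugfac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# TA-salinity relation


@dataclass
class TaSalinityRegression:
    """OLS fit TA = slope * S + intercept over the sampled salinity range."""

    slope: float
    intercept: float
    r2: float
    n: int
    sal_min: float
    sal_max: float
    margin: float = 1.0  # salinity units beyond the fitted range still accepted

    def predict(self, sal):
        """Predicted TA (umol/kg); NaN outside the fitted range +- margin."""
        sal = np.asarray(sal, dtype=float)
        out = self.slope * sal + self.intercept
        valid = (sal >= self.sal_min - self.margin) & (sal <= self.sal_max + self.margin)
        out = np.where(valid, out, np.nan)
        return float(out) if out.ndim == 0 else out


def fit_ta_salinity(sal, ta) -> TaSalinityRegression:
    sal = np.asarray(sal, dtype=float)
    ta = np.asarray(ta, dtype=float)
    if sal.size < 3:
        raise ValueError("at least 3 (salinity, TA) pairs required")
    if np.ptp(sal) == 0:
        raise ValueError("degenerate design: all salinities identical")
    res = stats.linregress(sal, ta)
    return TaSalinityRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=int(sal.size),
        sal_min=float(sal.min()),
        sal_max=float(sal.max()),
    )


# ---------------------------------------------------------------------------
# source waters


@dataclass
class SourceWater:
    """Mean characteristics of an upwelling source water mass with standard
    errors (used for first-order uncertainty propagation)."""

    label: str  # "SACW" | "ESACW" or a subsystem tag
    temp: float
    sal: float
    ta: float  # umol/kg
    dic: float  # umol/kg
    no3: float = 0.0  # umol/kg
    po4: float = 0.0
    n_pref: float = 0.0
    se: dict = field(default_factory=dict)  # e.g. {"ta": 5.0, "dic": 4.0, ...}

    def __post_init__(self):
        if min(self.ta, self.dic, self.no3, self.po4, self.n_pref) < 0:
            raise ValueError("concentrations must be >= 0")
        if self.n_pref > self.no3 + 1e-12:
            raise ValueError("preformed nitrate cannot exceed total nitrate")


_FD_STEPS = {"ta": 1.0, "dic": 1.0, "temp": 0.05, "sal": 0.02, "no3": 0.1}


def _propagate_se(fn, values: dict, se: dict) -> float:
    var = 0.0
    for name, s in se.items():
        if not s or name not in values:
            continue
        step = _FD_STEPS.get(name, 1e-3)
        hi = dict(values)
        lo = dict(values)
        hi[name] += step
        lo[name] -= step
        deriv = (fn(**hi) - fn(**lo)) / (2.0 * step)
        var += (deriv * s) ** 2
    return float(np.sqrt(var))


def source_water_pco2(sw: SourceWater):
    """pCO2 (uatm) of freshly upwelled source water at its own temp/sal,
    with a first-order standard error from the characteristics' s.e.s.

    This is the first validation step: nearshore, where warming and biology
    have not yet acted, measured surface pCO2 should fall in the range of
    this potential pCO2.
    """

    def fn(ta, dic, temp, sal):
        return pco2_from_ta_dic(ta, dic, temp, sal)

    values = {"ta": sw.ta, "dic": sw.dic, "temp": sw.temp, "sal": sw.sal}
    pco2 = fn(**values)
    return pco2, _propagate_se(fn, values, sw.se)


def post_consumption_pco2(
    sw: SourceWater,
    sst: float,
    sss: float,
    redfield_c_n: float = REDFIELD_C_N,
    ta_per_no3: float = 1.0,
):
    """pCO2 (uatm) of upwelled water after its nitrate has been consumed and
    exported, at offshore surface temperature/salinity.

    Biological drawdown removes (106/16) mol DIC per mol nitrate and
    releases ``ta_per_no3`` mol TA (proton consumption during nitrate
    assimilation); warming enters through (sst, sss).
    """

    def fn(ta, dic, no3, temp, sal):
        dic2 = dic - redfield_c_n * no3
        ta2 = ta + ta_per_no3 * no3
        if dic2 <= 0:
            raise ValueError("nutrient drawdown exhausts DIC")
        return pco2_from_ta_dic(ta2, dic2, temp, sal)

    values = {"ta": sw.ta, "dic": sw.dic, "no3": sw.no3, "temp": sst, "sal": sss}
    pco2 = fn(**values)
    return pco2, _propagate_se(fn, values, sw.se)


def nonthermal_pco2_grid(pco2, sst, sss, reg: TaSalinityRegression, source_temp: float, source_sal: float):
    """Reconstruct the non-thermally controlled pCO2 field.

    Per cell: TA from the salinity regression, DIC from (TA, pCO2) at the
    observed surface state, then pCO2 re-solved at the source-water
    temperature and salinity -- removing the warming the water experienced
    since upwelling. Cells missing any input stay NaN; solver failures are
    counted, not fatal.

    Returns ``(pco2_nonthermal, n_failed)``.
    """
    pco2 = np.asarray(pco2, dtype=float)
    sst = np.asarray(sst, dtype=float)
    sss = np.asarray(sss, dtype=float)
    valid = np.isfinite(pco2) & np.isfinite(sst) & np.isfinite(sss)
    out = np.full(pco2.shape, np.nan)
    if not np.any(valid):
        return out, 0
    ta = reg.predict(sss[valid])
    ok = np.isfinite(ta) & (ta > 1000) & (ta < 3500)
    dic = np.full(ta.shape, np.nan)
    if np.any(ok):
        dic[ok] = dic_from_ta_pco2(ta[ok], pco2[valid][ok], sst[valid][ok], sss[valid][ok], on_fail="nan")
    ok2 = ok & np.isfinite(dic) & (dic > 800) & (dic < 3200)
    res = np.full(ta.shape, np.nan)
    if np.any(ok2):
        res[ok2] = pco2_from_ta_dic(ta[ok2], dic[ok2], source_temp, source_sal, on_fail="nan")
    out[valid] = res
    n_failed = int(np.sum(~np.isfinite(res)))
    return out, n_failed
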