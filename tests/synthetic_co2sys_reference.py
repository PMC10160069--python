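"""SYNTHETIC stand-in reference for a CO2SYS-style carbonate solver.

This module is a test-only, independently written reference implementation
used to cross-check ``buscarb.carbonate``. It is a synthetic stand-in
constructed for the test suite (no validated external carbonate package is
bundled): the equilibrium-constant expressions are transcribed here a
second time directly from the primary literature (Weiss 1974; Mehrbach et
al. refit by Dickson & Millero 1987; Dickson 1990a, b; Millero 1995;
Dickson & Riley 1979), and the CO2 system is solved by a *different
algebraic route* than the package -- the total-alkalinity balance is
cleared of denominators into a polynomial in [H+] and solved with
``numpy.roots``, instead of safeguarded bisection.

Sub-nanomolar alkalinity terms (bisulfate, HF, and the free/total
distinction of the -[H+] term) are omitted here; at seawater pH they are
< 0.01 umol/kg, far below the 1 uatm / 1 umol/kg comparison tolerances.
"""

from __future__ import annotations

import numpy as np


def _constants(t_c: float, s: float):
    tk = t_c + 273.15
    ln_tk = np.log(tk)

    tk100 = tk / 100.0
    k0 = np.exp(
        -60.2409 + 93.4517 / tk100 + 23.3585 * np.log(tk100)
        + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2)
    )

    ion_s = 19.924 * s / (1000.0 - 1.005 * s)
    ks = np.exp(
        -4276.1 / tk + 141.328 - 23.093 * ln_tk
        + (-13856.0 / tk + 324.57 - 47.986 * ln_tk) * np.sqrt(ion_s)
        + (35474.0 / tk - 771.54 + 114.723 * ln_tk) * ion_s
        - (2698.0 / tk) * ion_s**1.5 + (1776.0 / tk) * ion_s**2
        + np.log(1.0 - 0.001005 * s)
    )
    kf = np.exp(1590.2 / tk - 12.641 + 1.525 * np.sqrt(ion_s) + np.log(1.0 - 0.001005 * s))
    st = 0.14 / 96.062 * s / 1.80655
    ft = 0.000067 / 18.998 * s / 1.80655
    sws2tot = (1.0 + st / ks) / (1.0 + st / ks + ft / kf)

    pk1 = 3670.7 / tk - 62.008 + 9.7944 * ln_tk - 0.0118 * s + 0.000116 * s**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * s + 0.000118 * s**2
    k1 = 10.0**-pk1 * sws2tot
    k2 = 10.0**-pk2 * sws2tot

    sq = np.sqrt(s)
    kb = np.exp(
        (-8966.90 - 2890.53 * sq - 77.942 * s + 1.728 * s**1.5 - 0.0996 * s**2) / tk
        + 148.0248 + 137.1942 * sq + 1.62142 * s
        - (24.4344 + 25.085 * sq + 0.2474 * s) * ln_tk
        + 0.053105 * sq * tk
    )
    kw = np.exp(
        148.9802 - 13847.26 / tk - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sq - 0.01615 * s
    ) * sws2tot
    bt = 0.0004157 * s / 35.0
    return k0, k1, k2, kb, kw, bt


def _physical_root(coeffs) -> float:
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) <= 1e-8 * (1.0 + np.abs(roots.real))].real
    cand = real[(real > 1e-11) & (real < 1e-4)]
    if cand.size == 0:
        raise ValueError("no physical [H+] root")
    return float(np.min(cand))  # window [pH 4, 11] brackets exactly one root


def ref_pco2_from_ta_dic(ta_umol: float, dic_umol: float, t_c: float, s: float) -> float:
    """Reference pCO2 (uatm) via the polynomial-in-[H+] route."""
    k0, k1, k2, kb, kw, bt = _constants(t_c, s)
    ta = ta_umol * 1e-6
    dic = dic_umol * 1e-6
    # TA*(h^2+K1 h+K1K2)(KB+h) = DIC(K1 h+2K1K2)(KB+h) + BT KB (h^2+K1 h+K1K2)
    #   + (KW/h - h)(h^2+K1 h+K1K2)(KB+h)          ... multiply through by h
    den = np.array([1.0, k1, k1 * k2])  # h^2 + K1 h + K1K2
    carb = np.array([dic * k1, 2.0 * dic * k1 * k2])  # DIC(K1 h + 2K1K2)
    kb_poly = np.array([1.0, kb])  # h + KB
    lhs = ta * np.polymul(np.polymul(den, kb_poly), np.array([1.0, 0.0]))
    rhs = np.polymul(np.polymul(carb, kb_poly), np.array([1.0, 0.0]))
    rhs = np.polyadd(rhs, bt * kb * np.polymul(den, np.array([1.0, 0.0])))
    rhs = np.polyadd(rhs, kw * np.polymul(den, kb_poly))
    rhs = np.polyadd(rhs, -np.polymul(np.polymul(den, kb_poly), np.array([1.0, 0.0, 0.0])))
    h = _physical_root(np.polysub(lhs, rhs))
    co2_star = dic * h**2 / (h**2 + k1 * h + k1 * k2)
    return co2_star / k0 * 1e6


def ref_dic_from_ta_pco2(ta_umol: float, pco2_uatm: float, t_c: float, s: float) -> float:
    """Reference DIC (umol/kg) via the polynomial-in-[H+] route."""
    k0, k1, k2, kb, kw, bt = _constants(t_c, s)
    ta = ta_umol * 1e-6
    co2 = k0 * pco2_uatm * 1e-6
    # TA h^2 (KB+h) = CO2(K1 h + 2K1K2)(KB+h) + BT KB h^2 + KW h (KB+h) - h^3 (KB+h)
    kb_poly = np.array([1.0, kb])
    lhs = ta * np.polymul(np.array([1.0, 0.0, 0.0]), kb_poly)
    rhs = np.polymul(np.array([co2 * k1, 2.0 * co2 * k1 * k2]), kb_poly)
    rhs = np.polyadd(rhs, bt * kb * np.array([1.0, 0.0, 0.0]))
    rhs = np.polyadd(rhs, kw * np.polymul(np.array([1.0, 0.0]), kb_poly))
    rhs = np.polyadd(rhs, -np.polymul(np.array([1.0, 0.0, 0.0, 0.0]), kb_poly))
    h = _physical_root(np.polysub(lhs, rhs))
    return co2 * (1.0 + k1 / h + k1 * k2 / h**2) * 1e6
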