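"""Carbonate-system solver: constants, interconversions, source-water and
non-thermal reconstructions, checked against a test-local synthetic
reference implementation (independent transcription + polynomial root
finding) and published constant values."""

import numpy as np
import pytest

from buscarb import carbonate as cs
from synthetic_co2sys_reference import ref_dic_from_ta_pco2, ref_pco2_from_ta_dic

GRID = dict(
    ta=np.linspace(2150, 2450, 5),
    dic=np.linspace(1900, 2250, 5),
    temp=np.linspace(5, 25, 5),
    sal=np.linspace(33, 36.5, 5),
)


class TestSolubility:
    def test_co2_solubility_decreases_with_warming(self):
        assert cs.solubility_k0(0, 35) > cs.solubility_k0(25, 35)

    def test_salting_out(self):
        assert cs.solubility_k0(20, 0) > cs.solubility_k0(20, 35)

    def test_weiss_value_matches_independent_transcription(self):
        # 4 significant digits against the independently typed Weiss fit
        from synthetic_co2sys_reference import _constants

        mine = cs.solubility_k0(20.0, 35.0)
        ref = _constants(20.0, 35.0)[0]
        assert mine == pytest.approx(ref, rel=1e-6)
        assert mine == pytest.approx(0.03241, rel=5e-4)  # Weiss (1974) magnitude

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.solubility_k0(50, 35)


class TestConstants:
    def test_dissociation_constant_ordering(self):
        k = cs.equilibrium_constants(25, 35)
        assert k.k1 > k.k2
        assert min(k.k0, k.k1, k.k2, k.kb, k.kw, k.ks, k.kf, k.bt) > 0

    def test_pk_values_match_published_total_scale_fit(self):
        # Lueker et al. (2000) total-scale refit of the same titration data:
        # pK1 = 5.8472, pK2 = 8.9660 at 25 C, S = 35
        k = cs.equilibrium_constants(25, 35)
        assert -np.log10(k.k1) == pytest.approx(5.8472, abs=0.005)
        assert -np.log10(k.k2) == pytest.approx(8.9660, abs=0.005)

    def test_constants_continuous_in_temperature(self):
        # KW's steeper Arrhenius slope (~1.6%/0.1 C) gets a wider band
        temps = np.arange(5.0, 30.0, 0.1)
        for name, bound in (("k1", 0.01), ("k2", 0.01), ("kb", 0.01), ("kw", 0.025)):
            vals = np.array([getattr(cs.equilibrium_constants(t, 35), name) for t in temps])
            assert np.all(np.abs(np.diff(vals)) / vals[:-1] < bound)


class TestInterconversion:
    def test_round_trip_stable_to_tenth_uatm(self):
        for ta in GRID["ta"]:
            for temp in GRID["temp"]:
                pco2 = cs.pco2_from_ta_dic(ta, 0.88 * ta, temp, 35)
                dic = cs.dic_from_ta_pco2(ta, pco2, temp, 35)
                back = cs.pco2_from_ta_dic(ta, dic, temp, 35)
                assert back == pytest.approx(pco2, abs=0.1)

    def test_monotone_in_dic_and_ta(self):
        base = cs.pco2_from_ta_dic(2300, 2050, 15, 35)
        assert cs.pco2_from_ta_dic(2300, 2060, 15, 35) > base
        assert cs.pco2_from_ta_dic(2310, 2050, 15, 35) < base
        assert cs.dic_from_ta_pco2(2300, 500, 15, 35) > cs.dic_from_ta_pco2(2300, 400, 15, 35)

    def test_agreement_with_synthetic_reference_grid(self):
        """625-state cross-check against the independent polynomial solver."""
        worst_p, worst_d = 0.0, 0.0
        for ta in GRID["ta"]:
            for dic in GRID["dic"]:
                for temp in GRID["temp"]:
                    for sal in GRID["sal"]:
                        p = cs.pco2_from_ta_dic(ta, dic, temp, sal)
                        worst_p = max(worst_p, abs(p - ref_pco2_from_ta_dic(ta, dic, temp, sal)))
                        d = cs.dic_from_ta_pco2(ta, p, temp, sal)
                        worst_d = max(worst_d, abs(d - ref_dic_from_ta_pco2(ta, p, temp, sal)))
        assert worst_p < 1.0  # uatm
        assert worst_d < 1.0  # umol/kg

    def test_thermal_sensitivity_brackets_takahashi(self):
        # d ln(pCO2)/dT ~ 0.0423 / degC empirically
        for sal in (34.0, 35.0, 36.0):
            for temp in (15.0, 20.0, 24.0):
                dic = cs.dic_from_ta_pco2(2300, 400, temp, sal)
                p0 = cs.pco2_from_ta_dic(2300, dic, temp - 0.5, sal)
                p1 = cs.pco2_from_ta_dic(2300, dic, temp + 0.5, sal)
                sens = np.log(p1 / p0)
                assert 0.03 < sens < 0.05

    def test_unreachable_state_raises_and_nan_mode(self):
        # high TA at near-zero salinity: insufficient proton acceptors below pH 11
        with pytest.raises(ValueError):
            cs.pco2_from_ta_dic(3400, 850, 25, 0.5)
        out = cs.pco2_from_ta_dic(np.array([3400.0]), np.array([850.0]), 25, 0.5, on_fail="nan")
        assert np.isnan(out).all()

    def test_range_validation(self):
        with pytest.raises(ValueError):
            cs.pco2_from_ta_dic(500, 2000, 15, 35)


def test_fugacity_correction_magnitude():
    # pCO2 exceeds fCO2 by ~0.3-0.4% at surface temperatures
    ratio = cs.fco2_to_pco2(400.0, 20.0) / 400.0
    assert 1.003 < ratio < 1.004


class TestTaSalinity:
    def test_exact_line_recovery(self):
        sal = np.array([34.0, 34.5, 35.0, 35.5, 36.0])
        reg = cs.fit_ta_salinity(sal, 60.0 * sal + 200.0)
        assert reg.slope == pytest.approx(60.0)
        assert reg.intercept == pytest.approx(200.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_ta_salinity([35.0, 35.0, 35.0], [2300.0, 2301.0, 2302.0])
        with pytest.raises(ValueError):
            cs.fit_ta_salinity([35.0, 35.1], [2300.0, 2304.0])

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(3)
        sal = rng.uniform(34, 36, 200)
        ta = 62.0 * sal + 120.0 + rng.normal(0, 5.0, sal.size)
        reg = cs.fit_ta_salinity(sal, ta)
        from scipy.stats import linregress

        se = linregress(sal, ta).stderr
        assert abs(reg.slope - 62.0) < 2 * se

    def test_prediction_restricted_to_fitted_range(self):
        reg = cs.fit_ta_salinity([34.0, 35.0, 36.0], [2228.0, 2290.0, 2352.0])
        assert np.isfinite(reg.predict(35.5))
        assert np.isnan(reg.predict(40.0))


@pytest.fixture
def source_water():
    return cs.SourceWater(
        label="SACW", temp=10.0, sal=34.9, ta=2290.0, dic=2220.0, no3=20.0, po4=1.6,
        n_pref=6.4, se={"ta": 6.0, "dic": 6.0, "temp": 0.3, "sal": 0.05, "no3": 0.8},
    )


class TestSourceWater:
    def test_consistency_with_direct_solve(self, source_water):
        pco2, se = cs.source_water_pco2(source_water)
        assert pco2 == pytest.approx(
            cs.pco2_from_ta_dic(2290, 2220, 10.0, 34.9), abs=1e-9
        )
        assert se > 0

    def test_dic_increase_raises_pco2(self, source_water):
        sw2 = cs.SourceWater("SACW", 10.0, 34.9, 2290.0, 2230.0, 20.0, 1.6, 6.4)
        assert cs.source_water_pco2(sw2)[0] > cs.source_water_pco2(source_water)[0]

    def test_matches_synthetic_reference(self, source_water):
        pco2, _ = cs.source_water_pco2(source_water)
        assert pco2 == pytest.approx(ref_pco2_from_ta_dic(2290, 2220, 10.0, 34.9), abs=1.0)

    def test_invalid_preformed_exceeds_total(self):
        with pytest.raises(ValueError):
            cs.SourceWater("SACW", 10, 34.9, 2290, 2220, no3=5.0, n_pref=6.0)


class TestPostConsumption:
    def test_nothing_consumed_no_warming_is_identity(self, source_water):
        sw0 = cs.SourceWater("SACW", 10.0, 34.9, 2290.0, 2220.0, no3=0.0)
        pco2, _ = cs.post_consumption_pco2(sw0, sst=10.0, sss=34.9)
        assert pco2 == pytest.approx(cs.source_water_pco2(sw0)[0], abs=1e-9)

    def test_drawdown_lowers_pco2_at_fixed_temperature(self, source_water):
        with_n, _ = cs.post_consumption_pco2(source_water, sst=10.0, sss=34.9)
        assert with_n < cs.source_water_pco2(source_water)[0]

    def test_warming_ten_degrees_raises_pco2_about_four_percent_per_degree(self):
        sw0 = cs.SourceWater("SACW", 10.0, 34.9, 2290.0, 2220.0, no3=0.0)
        cold, _ = cs.post_consumption_pco2(sw0, sst=10.0, sss=34.9)
        warm, _ = cs.post_consumption_pco2(sw0, sst=20.0, sss=34.9)
        assert 1.35 < warm / cold < 1.65

    def test_drawdown_exhausting_dic_rejected(self):
        sw = cs.SourceWater("X", 10.0, 34.9, 2290.0, 2220.0, no3=400.0)
        with pytest.raises(ValueError):
            cs.post_consumption_pco2(sw, sst=15.0, sss=35.0)


class TestNonthermalGrid:
    def setup_method(self):
        self.reg = cs.TaSalinityRegression(62.0, 120.0, 0.99, 50, 33.0, 37.0)
        rng = np.random.default_rng(5)
        self.pco2 = rng.uniform(380, 600, (4, 5))
        self.sst = rng.uniform(14, 20, (4, 5))
        self.sss = rng.uniform(34.5, 35.5, (4, 5))

    def test_identity_when_source_equals_surface(self):
        out = np.empty_like(self.pco2)
        for i in range(self.pco2.shape[0]):
            for j in range(self.pco2.shape[1]):
                res, nf = cs.nonthermal_pco2_grid(
                    self.pco2[i : i + 1, j : j + 1],
                    self.sst[i : i + 1, j : j + 1],
                    self.sss[i : i + 1, j : j + 1],
                    self.reg, float(self.sst[i, j]), float(self.sss[i, j]),
                )
                out[i, j] = res[0, 0]
        assert np.allclose(out, self.pco2, atol=0.1)

    def test_cooling_lowers_every_cell(self):
        out, n_failed = cs.nonthermal_pco2_grid(self.pco2, self.sst, self.sss, self.reg, 9.0, 34.8)
        assert n_failed == 0
        assert np.all(out < self.pco2)

    def test_matches_cell_by_cell_reference(self):
        out, _ = cs.nonthermal_pco2_grid(self.pco2, self.sst, self.sss, self.reg, 9.0, 34.8)
        i, j = 2, 3
        ta = 62.0 * self.sss[i, j] + 120.0
        dic = ref_dic_from_ta_pco2(ta, self.pco2[i, j], self.sst[i, j], self.sss[i, j])
        expected = ref_pco2_from_ta_dic(ta, dic, 9.0, 34.8)
        assert out[i, j] == pytest.approx(expected, abs=1.0)

    def test_missing_inputs_stay_nan(self):
        pco2 = self.pco2.copy()
        pco2[0, 0] = np.nan
        out, _ = cs.nonthermal_pco2_grid(pco2, self.sst, self.sss, self.reg, 9.0, 34.8)
        assert np.isnan(out[0, 0])
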