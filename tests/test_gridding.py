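"""Normalization, variogram estimation/fitting, ordinary kriging (against a
dense linear-algebra oracle), effective sample size and aggregate SE."""

import numpy as np
import pandas as pd
import pytest

from buscarb import geo, gridding, synthetic


class TestNormalize:
    @pytest.mark.parametrize(
        "pco2, year, expected",
        [
            (400.0, 2020, 400.0),  # zero-span identity
            (400.0, 2010, 419.0),  # 10 yr at 1.9
            (400.0, 1986, 462.2),  # 6 yr at 1.5 + 28 yr at 1.9
            (400.0, 1992, 453.2),  # boundary year: all-recent rate
        ],
    )
    def test_piecewise_trend(self, pco2, year, expected):
        assert gridding.normalize_pco2(pco2, year, 2020) == pytest.approx(expected)

    def test_future_observation_rejected(self):
        with pytest.raises(ValueError):
            gridding.normalize_pco2(400.0, 2021, 2020)

    def test_vectorized(self):
        out = gridding.normalize_pco2(np.array([400.0, 400.0]), np.array([2010, 1986]))
        assert out == pytest.approx([419.0, 462.2])


class TestEmpiricalVariogram:
    def test_pure_nugget_is_flat_at_noise_variance(self):
        rng = np.random.default_rng(0)
        n = 400
        lon = rng.uniform(10, 12, n)
        lat = rng.uniform(-25, -23, n)
        z = rng.normal(0, 5.0, n)
        emp = gridding.empirical_variogram(lon, lat, z, n_lags=10, max_lag_deg=1.0)
        good = emp.reliable
        assert np.all(np.abs(emp.semivariance[good] - 25.0) < 8.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gridding.empirical_variogram([10.0, 10.5], [-25.0, -25.0], [1.0, 2.0])

    def test_identical_coordinates_rejected(self):
        with pytest.raises(ValueError):
            gridding.empirical_variogram(np.full(40, 10.0), np.full(40, -25.0), np.arange(40.0))


class TestFitVariogram:
    def test_exact_spherical_self_consistency(self):
        lags = np.linspace(0.05, 1.4, 12)
        truth = gridding.VariogramModel("spherical", 2.0, 30.0, 0.6)
        emp = gridding.EmpiricalVariogram(lags, truth.semivariance(lags), np.full(12, 200), 1.5)
        model = gridding.fit_variogram(emp)
        assert model.family == "spherical"
        assert model.nugget == pytest.approx(2.0, rel=0.01, abs=0.02)
        assert model.partial_sill == pytest.approx(30.0, rel=0.01)
        assert model.range_deg == pytest.approx(0.6, rel=0.01)

    def test_flat_input_gives_nugget_only_model(self):
        lags = np.linspace(0.05, 1.4, 10)
        emp = gridding.EmpiricalVariogram(lags, np.full(10, 12.0), np.full(10, 100), 1.5)
        model = gridding.fit_variogram(emp)
        assert model.partial_sill == pytest.approx(0.0, abs=1e-6)
        assert model.range_deg == pytest.approx(1.5)
        assert model.nugget == pytest.approx(12.0, rel=0.01)

    def test_too_few_bins_rejected(self):
        emp = gridding.EmpiricalVariogram(
            np.array([0.1, 0.2, 0.3]), np.array([1.0, 2.0, 3.0]), np.full(3, 50), 0.4
        )
        with pytest.raises(ValueError):
            gridding.fit_variogram(emp)

    def test_synthetic_field_range_recovered_within_30_percent(self, small_survey):
        cfg, survey = small_survey
        resid = survey["pco2"].to_numpy() - cfg.mean_pco2(survey["dist_coast_km"].to_numpy())
        # normalize out the offshore variance decay to get a stationary field
        resid = resid / cfg.noise_sd(survey["dist_coast_km"].to_numpy())
        emp = gridding.empirical_variogram(
            survey["lon"].to_numpy(), survey["lat"].to_numpy(), resid, max_lag_deg=1.5
        )
        model = gridding.fit_variogram(emp)
        assert model.range_deg == pytest.approx(cfg.noise_range_deg, rel=0.30)


def brute_force_ok(lon, lat, values, model, lon0, lat0):
    """Dense ordinary-kriging solve: full system, no neighbour capping."""
    n = len(values)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            a[i, j] = model.semivariance(geo.arc_deg(lon[i], lat[i], lon[j], lat[j])) if i != j else 0.0
        a[i, n] = a[n, i] = 1.0
    b = np.append(
        [model.semivariance(geo.arc_deg(lon[i], lat[i], lon0, lat0)) for i in range(n)], 1.0
    )
    sol = np.linalg.solve(a, b)
    return float(sol[:n] @ values), float(sol[:n] @ b[:n] + sol[n])


class TestKriging:
    model = gridding.VariogramModel("exponential", 1.0, 25.0, 0.4)

    def _records(self):
        lon = np.array([10.02, 10.31, 10.18, 10.44, 10.12])
        lat = np.array([-24.95, -25.2, -25.4, -25.05, -25.31])
        val = np.array([420.0, 415.0, 460.0, 430.0, 405.0])
        return pd.DataFrame({"lon": lon, "lat": lat, "pco2": val})

    def test_matches_dense_oracle_to_1e8(self):
        rec = self._records()
        spec = gridding.GridSpec(10.0, 10.5, -25.5, -24.9, 0.1)
        res = gridding.krige_grid(rec, self.model, spec, min_neighbors=1, max_dist_deg=1.0)
        lon_c, lat_c = spec.centers()
        for i, lat0 in enumerate(lat_c):
            for j, lon0 in enumerate(lon_c):
                pred, var = brute_force_ok(
                    rec["lon"].to_numpy(), rec["lat"].to_numpy(), rec["pco2"].to_numpy(),
                    self.model, lon0, lat0,
                )
                assert res.prediction[i, j] == pytest.approx(pred, abs=1e-8)
                assert res.variance[i, j] == pytest.approx(max(var, 0.0), abs=1e-8)

    def test_exact_interpolation_with_zero_nugget(self):
        model = gridding.VariogramModel("spherical", 0.0, 25.0, 0.4)
        # place an observation exactly on a cell centre
        rec = pd.DataFrame(
            {"lon": [10.05, 10.2, 10.3, 10.15, 10.25], "lat": [-24.95] * 5,
             "pco2": [400.0, 410.0, 420.0, 415.0, 405.0]}
        )
        spec = gridding.GridSpec(10.0, 10.1, -25.0, -24.9, 0.1)
        res = gridding.krige_grid(rec, model, spec, min_neighbors=1)
        assert res.prediction[0, 0] == pytest.approx(400.0, abs=1e-8)
        assert res.variance[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_cells_without_neighbors_unpredicted(self):
        rec = self._records()
        spec = gridding.GridSpec(13.0, 13.3, -25.5, -24.9, 0.1)  # far from all data
        res = gridding.krige_grid(rec, self.model, spec, max_dist_deg=0.5)
        assert np.all(np.isnan(res.prediction))
        assert res.n_predicted == 0

    def test_min_neighbor_rule(self):
        rec = self._records()
        spec = gridding.GridSpec(10.0, 10.5, -25.5, -24.9, 0.1)
        res5 = gridding.krige_grid(rec, self.model, spec, max_dist_deg=0.2, min_neighbors=5)
        res1 = gridding.krige_grid(rec, self.model, spec, max_dist_deg=0.2, min_neighbors=1)
        assert res5.n_predicted <= res1.n_predicted

    def test_translation_invariance(self):
        rec = self._records()
        spec = gridding.GridSpec(10.0, 10.5, -25.5, -24.9, 0.1)
        res = gridding.krige_grid(rec, self.model, spec, min_neighbors=1)
        rec2 = rec.assign(pco2=rec["pco2"] + 100.0)
        res2 = gridding.krige_grid(rec2, self.model, spec, min_neighbors=1)
        assert np.allclose(res2.prediction, res.prediction + 100.0, equal_nan=True)
        assert np.allclose(res2.variance, res.variance, equal_nan=True)

    def test_duplicate_points_averaged(self):
        rec = pd.DataFrame(
            {"lon": [10.1, 10.1, 10.3, 10.2, 10.4, 10.15],
             "lat": [-25.0, -25.0, -25.1, -25.2, -25.0, -25.3],
             "pco2": [400.0, 410.0, 420.0, 415.0, 405.0, 412.0]}
        )
        spec = gridding.GridSpec(10.0, 10.5, -25.4, -24.9, 0.1)
        res = gridding.krige_grid(rec, self.model, spec, min_neighbors=1)
        assert res.n_duplicates_merged == 1
        assert res.n_predicted > 0

    def test_variance_calibration_on_simulated_field(self):
        """~95% of cells fall within 2 sigma of the simulated truth."""
        rng = np.random.default_rng(42)
        n_obs, n_tgt = 120, 60
        lon = rng.uniform(10, 12, n_obs + n_tgt)
        lat = rng.uniform(-26, -24, n_obs + n_tgt)
        vec = geo.unit_vectors(lon, lat)
        h = np.degrees(np.arccos(np.clip(vec @ vec.T, -1, 1)))
        sill, rng_deg = 25.0, 0.5
        cov = sill * np.exp(-3.0 * h / rng_deg)
        cov[np.diag_indices_from(cov)] += 1e-8
        field = np.linalg.cholesky(cov) @ rng.standard_normal(n_obs + n_tgt)
        rec = pd.DataFrame({"lon": lon[:n_obs], "lat": lat[:n_obs], "pco2": field[:n_obs]})
        model = gridding.VariogramModel("exponential", 0.0, sill, rng_deg)
        hits = 0
        for m in range(n_tgt):
            spec = gridding.GridSpec(
                lon[n_obs + m] - 0.005, lon[n_obs + m] + 0.005,
                lat[n_obs + m] - 0.005, lat[n_obs + m] + 0.005, 0.01,
            )
            res = gridding.krige_grid(rec, model, spec, min_neighbors=1)
            err = abs(res.prediction[0, 0] - field[n_obs + m])
            hits += err < 2.0 * res.sigma[0, 0]
        assert hits / n_tgt >= 0.88


class TestEffectiveN:
    def _grid(self, n=10, res=0.1):
        lon = 10.0 + res * np.arange(n)
        lat = -25.0 + res * np.arange(n)
        lon2d, lat2d = np.meshgrid(lon, lat)
        return lon2d.ravel(), lat2d.ravel()

    def test_range_below_resolution_keeps_all(self):
        lon, lat = self._grid()
        assert gridding.effective_n(lon, lat, 0.05) == lon.size

    def test_range_beyond_diameter_keeps_one(self):
        lon, lat = self._grid()
        assert gridding.effective_n(lon, lat, 50.0) == 1

    def test_matches_greedy_brute_force(self):
        lon, lat = self._grid(10, 0.1)
        rng_deg = 0.25
        kept = []
        for x, y in zip(lon, lat):  # independent O(n^2) scan
            if all(geo.arc_deg(x, y, kx, ky) > rng_deg for kx, ky in kept):
                kept.append((x, y))
        assert gridding.effective_n(lon, lat, rng_deg) == len(kept)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            gridding.effective_n([], [], 0.5)


class TestAggregateSE:
    def test_uniform_sigma_identity(self):
        # with sigma = s everywhere and n_eff = N, SE reduces to s
        assert gridding.aggregate_se(np.full(50, 3.5), 50) == pytest.approx(3.5)

    def test_single_cell_identity(self):
        assert gridding.aggregate_se([5.0], 1) == pytest.approx(5.0)

    def test_pythagorean_case(self):
        assert gridding.aggregate_se([3.0, 4.0], 1) == pytest.approx(5.0)

    def test_monotone_nonincreasing_in_n_eff(self):
        sig = np.array([2.0, 3.0, 4.0, 1.5])
        ses = [gridding.aggregate_se(sig, k) for k in range(1, 5)]
        assert all(a >= b for a, b in zip(ses, ses[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gridding.aggregate_se([1.0], 0)
        with pytest.raises(ValueError):
            gridding.aggregate_se([-1.0], 2)


def test_grid_uncertainty_neff_fallback(small_survey):
    """A pathologically long autocorrelation range triggers the N fallback."""
    cfg, survey = small_survey
    model = gridding.VariogramModel("exponential", 1.0, 25.0, 0.4)
    spec = gridding.GridSpec.around(survey["lon"].to_numpy(), survey["lat"].to_numpy(), 0.2)
    res = gridding.krige_grid(survey, model, spec)
    unc_ok = gridding.grid_uncertainty(res, 0.4)
    assert not unc_ok.used_fallback and unc_ok.n_eff <= unc_ok.n
    unc_long = gridding.grid_uncertainty(res, 50.0)  # N_eff = 1 < 5% of N
    assert unc_long.used_fallback
    assert unc_long.se == pytest.approx(gridding.aggregate_se(res.predicted_cells()[2], unc_long.n))
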