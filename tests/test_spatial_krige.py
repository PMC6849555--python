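"""Semivariogram estimation, variogram fitting, ordinary kriging, LOO CV."""

import numpy as np
import pytest

from forestdyn.spatial import (
    SpatialError,
    VariogramModel,
    empirical_semivariogram,
    fit_variogram_model,
    great_circle_km,
    krige_at_points,
    kriging_weights,
    loo_crossvalidate,
    ordinary_krige,
)
from forestdyn.synthetic import FieldParams, correlated_noise


class TestGreatCircle:
    def test_one_degree_at_equator(self):
        d = great_circle_km(0.0, 0.0, 1.0, 0.0)
        assert d == pytest.approx(2 * np.pi * 6371.0 / 360.0, rel=1e-6)

    def test_symmetric(self):
        assert great_circle_km(-60, -3, -55, 2) == pytest.approx(
            great_circle_km(-55, 2, -60, -3))


class TestEmpiricalSemivariogram:
    def test_constant_field_zero_gamma(self, rng):
        lon = rng.uniform(-60, -50, 30)
        lat = rng.uniform(-10, 0, 30)
        emp = empirical_semivariogram(lon, lat, np.full(30, 7.0))
        assert np.all(emp["gamma"] == 0.0)

    def test_two_point_pair(self):
        emp = empirical_semivariogram([0.0, 1.0], [0.0, 0.0], [0.0, 2.0],
                                      n_bins=1, max_lag=200.0)
        assert len(emp) == 1
        assert emp["gamma"].iloc[0] == pytest.approx(2.0)  # 0.5 * (2-0)^2
        assert emp["n_pairs"].iloc[0] == 1

    def test_scaling_quadratic(self, rng):
        lon = rng.uniform(-60, -50, 40)
        lat = rng.uniform(-10, 0, 40)
        v = rng.normal(0, 1, 40)
        g1 = empirical_semivariogram(lon, lat, v)["gamma"]
        g2 = empirical_semivariogram(lon, lat, 2 * v)["gamma"]
        assert np.allclose(g2, 4 * g1)

    def test_coincident_points_rejected(self):
        with pytest.raises(SpatialError):
            empirical_semivariogram([0.0, 0.0], [0.0, 0.0], [1.0, 2.0])


class TestFitVariogram:
    def test_recovers_simulated_range(self):
        """A draw from a known Gaussian variogram is recovered within 25%."""
        rng = np.random.default_rng(42)
        lon = rng.uniform(-75, -50, 200)
        lat = rng.uniform(-15, 5, 200)
        true_range = 400.0
        z = correlated_noise(lon, lat, FieldParams(nugget=0.05, range_km=true_range),
                             rng)[:, 0]
        emp = empirical_semivariogram(lon, lat, z, n_bins=15)
        model = fit_variogram_model(emp, "gaussian")
        assert model.range_km == pytest.approx(true_range, rel=0.25)

    def test_pure_nugget_small_partial_sill(self, rng):
        lon = rng.uniform(-75, -50, 150)
        lat = rng.uniform(-15, 5, 150)
        z = rng.normal(0, 1, 150)
        emp = empirical_semivariogram(lon, lat, z, n_bins=12)
        model = fit_variogram_model(emp, "gaussian")
        assert model.partial_sill < 0.35 * (model.nugget + model.partial_sill)

    def test_single_bin_rejected(self):
        import pandas as pd
        emp = pd.DataFrame({"lag": [10.0], "gamma": [1.0], "n_pairs": [5]})
        with pytest.raises(SpatialError):
            fit_variogram_model(emp)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SpatialError):
            VariogramModel("gaussian", -0.1, 1.0, 100.0)
        with pytest.raises(SpatialError):
            VariogramModel("parabolic", 0.0, 1.0, 100.0)


class TestOrdinaryKriging:
    MODEL = VariogramModel("gaussian", nugget=0.0, partial_sill=2.0,
                           range_km=300.0)

    def test_single_point_constant_prediction(self):
        pred, _ = krige_at_points([-60.0], [-3.0], [42.0], self.MODEL,
                                  [-55.0, -70.0], [0.0, -10.0])
        assert np.allclose(pred, 42.0)

    def test_exact_interpolation_zero_nugget(self):
        lon = np.array([-60.0, -58.0, -55.0, -62.0])
        lat = np.array([-3.0, -1.0, -5.0, 0.0])
        v = np.array([1.0, 4.0, 2.0, 3.0])
        pred, var = krige_at_points(lon, lat, v, self.MODEL, lon, lat)
        assert np.allclose(pred, v, atol=1e-8)
        assert np.allclose(var, 0.0, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        lon = rng.uniform(-70, -50, 25)
        lat = rng.uniform(-10, 0, 25)
        for _ in range(10):
            w, _ = kriging_weights(lon, lat, self.MODEL,
                                   float(rng.uniform(-70, -50)),
                                   float(rng.uniform(-10, 0)))
            assert abs(w.sum() - 1.0) < 1e-10

    def test_three_point_weights_match_brute_force(self):
        """Weights equal the directly assembled constrained linear system."""
        lon = np.array([-60.0, -57.0, -59.0])
        lat = np.array([-3.0, -2.0, -6.0])
        lon0, lat0 = -58.5, -3.5
        w, lam = kriging_weights(lon, lat, self.MODEL, lon0, lat0)

        A = np.zeros((4, 4))
        for i in range(3):
            for j in range(3):
                A[i, j] = self.MODEL.gamma(
                    great_circle_km(lon[i], lat[i], lon[j], lat[j]))
            A[i, 3] = 1.0
            A[3, i] = 1.0
        b = np.array([self.MODEL.gamma(
            great_circle_km(lon[i], lat[i], lon0, lat0)) for i in range(3)]
            + [1.0])
        expected = np.linalg.solve(A, b)
        assert np.allclose(w, expected[:3], atol=1e-8)
        assert lam == pytest.approx(expected[3], abs=1e-8)

    def test_duplicate_locations_averaged(self):
        pred, _ = krige_at_points([-60.0, -60.0, -55.0], [-3.0, -3.0, -1.0],
                                  [1.0, 3.0, 5.0], self.MODEL,
                                  [-60.0], [-3.0])
        assert pred[0] == pytest.approx(2.0, abs=1e-6)

    def test_grid_output_shapes(self, rng):
        lon = rng.uniform(-70, -50, 20)
        lat = rng.uniform(-10, 0, 20)
        v = rng.normal(100, 10, 20)
        glon = np.arange(-69.5, -50.0, 1.0)
        glat = np.arange(-9.5, 0.0, 1.0)
        res = ordinary_krige(lon, lat, v, glon, glat, self.MODEL)
        assert res.prediction.shape == (glat.size, glon.size)
        assert np.all(res.variance[res.mask] >= 0.0)


class TestLeaveOneOut:
    def test_constant_field_zero_bias(self, rng):
        lon = rng.uniform(-70, -50, 10)
        lat = rng.uniform(-10, 0, 10)
        model = VariogramModel("gaussian", 0.0, 1.0, 300.0)
        _, stats = loo_crossvalidate(lon, lat, np.full(10, 5.0), model=model)
        assert stats["median_abs_pct_bias"] == pytest.approx(0.0, abs=1e-8)

    def test_bias_centered_near_zero_on_structured_field(self):
        rng = np.random.default_rng(7)
        lon = rng.uniform(-75, -50, 200)
        lat = rng.uniform(-15, 5, 200)
        z = correlated_noise(lon, lat, FieldParams(nugget=0.1, range_km=500.0),
                             rng)[:, 0]
        values = 100.0 + 10.0 * z
        table, stats = loo_crossvalidate(lon, lat, values)
        assert abs(stats["median_signed_pct_bias"]) < 2.0

    def test_bias_decreases_with_density(self):
        """On a smooth deterministic surface, denser sampling shrinks the
        median interpolation error."""
        def run(n, seed):
            rng = np.random.default_rng(seed)
            lon = rng.uniform(-70, -50, n)
            lat = rng.uniform(-10, 0, n)
            v = 100.0 + 2.0 * (lon + 60.0) + 1.5 * (lat + 5.0)
            _, stats = loo_crossvalidate(lon, lat, v)
            return stats["median_abs_pct_bias"]

        assert run(160, 3) < run(20, 3)

    def test_order_independent(self, rng):
        lon = rng.uniform(-70, -50, 30)
        lat = rng.uniform(-10, 0, 30)
        v = 100.0 + 3.0 * (lon + 60.0) + rng.normal(0, 1, 30)
        model = VariogramModel("gaussian", 0.1, 4.0, 400.0)
        t1, _ = loo_crossvalidate(lon, lat, v, model=model)
        perm = rng.permutation(30)
        t2, _ = loo_crossvalidate(lon[perm], lat[perm], v[perm], model=model)
        merged = t1.merge(t2, on=["longitude", "latitude"],
                          suffixes=("_a", "_b"))
        assert len(merged) == 30
        assert np.allclose(merged["predicted_a"], merged["predicted_b"])

    def test_too_few_points_rejected(self):
        with pytest.raises(SpatialError):
            loo_crossvalidate([0.0, 1.0], [0.0, 1.0], [1.0, 2.0])
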