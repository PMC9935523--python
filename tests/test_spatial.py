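"""IDW and ordinary kriging interpolation, rasters, cross-validation."""

import numpy as np
import pandas as pd
import pytest

import soilrisk as sr
from soilrisk.spatial import (InterpolatorConfig, RasterSpec,
                              empirical_variogram, read_esri_ascii,
                              variogram)


def _random_samples(n, seed, extent=2000.0, value_fn=None):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent, n)
    y = rng.uniform(0, extent, n)
    if value_fn is None:
        v = rng.normal(10, 2, n)
    else:
        v = value_fn(x, y, rng)
    return pd.DataFrame({"x": x, "y": y, "v": v})


class TestVariogramFitting:
    def test_simulate_then_recover(self):
        """Data simulated from a known exponential variogram should be
        recovered by the WLS fit within a modest factor."""
        true_sill, true_range = 4.0, 600.0
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 3000, size=(250, 2))
        h = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        cov = true_sill - variogram("exponential", h, 0.0, true_sill,
                                    true_range)
        values = rng.multivariate_normal(np.full(250, 10.0), cov,
                                         method="eigh")
        df = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "v": values})
        cfg = InterpolatorConfig(method="ordinary_kriging",
                                 variogram_model="exponential",
                                 search_radius=3000)
        model = sr.fit_interpolator(df, "v", cfg)
        assert model.sill == pytest.approx(true_sill, rel=0.5)
        assert model.vrange == pytest.approx(true_range, rel=0.5)
        assert model.nugget < 0.25 * true_sill

    def test_empirical_variogram_has_at_least_8_bins(self):
        df = _random_samples(80, 3)
        emp = empirical_variogram(df["x"].to_numpy(), df["y"].to_numpy(),
                                  df["v"].to_numpy())
        assert len(emp) >= 8
        assert (emp["n_pairs"] > 0).all()

    def test_constant_field_degenerates_with_warning(self):
        df = _random_samples(20, 4)
        df["v"] = 7.5
        with pytest.warns(UserWarning, match="constant"):
            model = sr.fit_interpolator(
                df, "v", InterpolatorConfig(method="ordinary_kriging"))
        pred, _ = model.predict([500.0], [500.0])
        assert pred[0] == pytest.approx(7.5)

    def test_idw_fit_is_noop(self):
        df = _random_samples(20, 5)
        model = sr.fit_interpolator(df, "v", InterpolatorConfig(method="idw"))
        assert model.config.method == "idw"

    def test_duplicate_coordinates_averaged(self):
        df = pd.DataFrame({"x": [0, 0, 1, 2, 3, 4.0],
                           "y": [0, 0, 1, 2, 3, 4.0],
                           "v": [1.0, 3.0, 5, 5, 5, 5]})
        model = sr.fit_interpolator(df, "v",
                                    InterpolatorConfig(search_radius=0.5))
        pred, _ = model.predict([0.0], [0.0])
        assert pred[0] == pytest.approx(2.0)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            sr.fit_interpolator(_random_samples(4, 6), "v")


class TestPrediction:
    def test_ok_exact_at_sample_points_zero_nugget(self):
        df = _random_samples(30, 7)
        cfg = InterpolatorConfig(method="ordinary_kriging",
                                 search_radius=5000)
        model = sr.fit_interpolator(df, "v", cfg)
        model.nugget = 0.0
        pred, var = model.predict(df["x"].to_numpy(), df["y"].to_numpy())
        assert np.allclose(pred, df["v"], atol=1e-8)
        assert np.allclose(var, 0.0, atol=1e-8)

    def test_ok_weights_sum_to_one(self):
        df = _random_samples(15, 8)
        cfg = InterpolatorConfig(method="ordinary_kriging",
                                 search_radius=5000)
        model = sr.fit_interpolator(df, "v", cfg)
        rng = np.random.default_rng(1)
        for _ in range(20):
            px, py = rng.uniform(0, 2000, 2)
            w, _ = model.ok_weights(px, py, np.arange(len(df)))
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_idw_bounded_by_neighbour_values(self):
        df = _random_samples(40, 9)
        model = sr.fit_interpolator(df, "v",
                                    InterpolatorConfig(search_radius=5000))
        rng = np.random.default_rng(2)
        pred, _ = model.predict(rng.uniform(0, 2000, 50),
                                rng.uniform(0, 2000, 50))
        assert (pred >= df["v"].min() - 1e-12).all()
        assert (pred <= df["v"].max() + 1e-12).all()

    def test_single_sample_idw_constant_inside_radius(self):
        df = pd.DataFrame({"x": [0, 1, 2, 3, 500.0], "y": [0, 1, 2, 3, 500.0],
                           "v": [5, 5, 5, 5, 9.0]})
        model = sr.fit_interpolator(df, "v",
                                    InterpolatorConfig(search_radius=50))
        near, _ = model.predict([495.0], [495.0])   # only the lone sample
        far, _ = model.predict([1500.0], [1500.0])  # nothing within radius
        assert near[0] == pytest.approx(9.0)
        assert np.isnan(far[0])

    def test_translation_invariance(self):
        df = _random_samples(25, 10)
        cfg = InterpolatorConfig(method="ordinary_kriging",
                                 search_radius=5000)
        m1 = sr.fit_interpolator(df, "v", cfg)
        shifted = df.assign(x=df["x"] + 1e4, y=df["y"] - 5e3)
        m2 = sr.fit_interpolator(shifted, "v", cfg)
        p1, _ = m1.predict([700.0], [900.0])
        p2, _ = m2.predict([700.0 + 1e4], [900.0 - 5e3])
        assert p1[0] == pytest.approx(p2[0], rel=1e-6)

    def test_grid_nodata_outside_radius(self):
        df = pd.DataFrame({"x": [500, 510, 520, 530, 540.0],
                           "y": [500, 510, 520, 530, 540.0],
                           "v": [1, 2, 3, 4, 5.0]})
        model = sr.fit_interpolator(df, "v",
                                    InterpolatorConfig(search_radius=100))
        spec = RasterSpec(0, 0, 50, 40, 40)
        raster, _ = sr.predict_grid(model, spec)
        assert raster.shape == (40, 40)
        assert (raster == spec.nodata).any()
        assert (raster != spec.nodata).any()

    def test_non_overlapping_raster_warns_all_nodata(self):
        df = _random_samples(10, 11, extent=100)
        model = sr.fit_interpolator(df, "v",
                                    InterpolatorConfig(search_radius=50))
        spec = RasterSpec(10_000, 10_000, 10, 5, 5)
        with pytest.warns(UserWarning, match="overlap"):
            raster, _ = sr.predict_grid(model, spec)
        assert (raster == spec.nodata).all()

    def test_fixture_hotspot_maps_above_background(self, fixture_survey):
        """In the fixture towns the IPI_N raster is higher at the designed
        hotspot centre than far from it."""
        per_sample, _ = sr.survey_ipin(fixture_survey, sr.MNS_2019)
        sub = fixture_survey.merge(per_sample[["sample_id", "ipin"]],
                                   on="sample_id")
        sub = sub[sub["town"] == "Baganuur"]
        model = sr.fit_interpolator(
            sub, "ipin", InterpolatorConfig(method="idw", search_radius=1500))
        hot, _ = model.predict([2000.0], [1500.0])   # designed hotspot centre
        corner, _ = model.predict([300.0], [300.0])
        assert hot[0] > corner[0]


class TestCrossValidation:
    def test_constant_field_rmse_zero(self):
        df = _random_samples(12, 12)
        df["v"] = 3.0
        with pytest.warns(UserWarning):
            out = sr.cross_validate(df, "v",
                                    InterpolatorConfig(search_radius=5000))
        assert out["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_rmse_near_noise_sd(self):
        """LOO prediction of spatially-uncorrelated noise can do no better
        than the noise scale: RMSE within 25% of sigma at n = 200."""
        sigma = 2.0
        df = _random_samples(
            200, 13, extent=2000,
            value_fn=lambda x, y, rng: rng.normal(0, sigma, len(x)))
        out = sr.cross_validate(df, "v",
                                InterpolatorConfig(method="idw",
                                                   search_radius=2000))
        assert out["rmse"] == pytest.approx(sigma, rel=0.25)

    def test_deterministic_given_fixed_input(self):
        df = _random_samples(30, 14)
        cfg = InterpolatorConfig(method="idw", search_radius=3000)
        assert sr.cross_validate(df, "v", cfg) == sr.cross_validate(df, "v", cfg)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 10"):
            sr.cross_validate(_random_samples(8, 15), "v")


class TestEsriAscii:
    def test_roundtrip(self, tmp_path):
        spec = RasterSpec(100.0, 200.0, 10.0, 4, 3, -9999.0)
        raster = np.arange(12, dtype=float).reshape(3, 4)
        path = tmp_path / "grid.asc"
        sr.write_esri_ascii(path, raster, spec)
        header = path.read_text().splitlines()[:6]
        assert header[0].split() == ["ncols", "4"]
        assert header[1].split() == ["nrows", "3"]
        data, spec2 = read_esri_ascii(path)
        assert np.allclose(data, raster)
        assert spec2.cell_size == 10.0
        assert spec2.origin_x == 100.0

    def test_shape_mismatch_errors(self, tmp_path):
        spec = RasterSpec(0, 0, 10, 4, 3)
        with pytest.raises(ValueError, match="shape"):
            sr.write_esri_ascii(tmp_path / "g.asc", np.zeros((2, 2)), spec)
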