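"""Density fitting, lookup, pixel substitution and model persistence."""

import json

import numpy as np
import pytest

from pskde import (
    DensityModel,
    density_at,
    fit_density,
    load_model,
    ps_kde_transform,
    save_model,
    scott_bandwidth,
)

from .oracles import gaussian_sum_density, linear_interp


def _model_from_values(values, h=0.1, grid_size=256, **kw):
    """Fit a model from a flat list of masked pixel values."""
    values = np.asarray(values, dtype=float)
    img = values.reshape(1, -1)
    mask = np.ones_like(img, dtype=np.uint8)
    return fit_density([img], [mask], bandwidth=h, grid_size=grid_size, **kw)


class TestFitDensity:
    def test_single_value_sample_is_symmetric_and_peaks_there(self):
        model = _model_from_values([0.5, 0.5, 0.5], h=1.0 / 255.0)
        peak = model.grid[np.argmax(model.density)]
        assert abs(peak - 0.5) <= 1.0 / 255.0
        # symmetry about 0.5 on the symmetric grid
        assert np.allclose(model.density, model.density[::-1], atol=1e-9)

    def test_density_matches_brute_force_gaussian_sum(self):
        values = [0.2, 0.4, 0.4, 0.8]
        model = _model_from_values(values, h=0.1)
        oracle = gaussian_sum_density(values, 0.1, model.grid)
        assert np.allclose(model.density, oracle, atol=1e-9)
        # the spec'd spot check at v = 0.4
        assert density_at(model, 0.4) == pytest.approx(
            linear_interp(model.grid, oracle, 0.4), abs=1e-9
        )

    def test_all_zero_masks_raise(self):
        img = np.full((4, 4), 0.5)
        mask = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="no training pixels for region"):
            fit_density([img], [mask])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="image/mask shape mismatch"):
            fit_density([np.full((4, 4), 0.5)], [np.ones((3, 3), dtype=np.uint8)])

    def test_invalid_bandwidth_raises(self):
        img = np.full((4, 4), 0.5)
        mask = np.ones((4, 4), dtype=np.uint8)
        for bad in (0.0, -0.1):
            with pytest.raises(ValueError, match="invalid bandwidth"):
                fit_density([img], [mask], bandwidth=bad)

    def test_unit_mass_invariant(self, rng):
        for _ in range(10):
            values = rng.uniform(0, 1, size=rng.integers(1, 50))
            model = _model_from_values(values, h=float(rng.uniform(0.02, 0.3)))
            assert abs(np.trapezoid(model.density, model.grid) - 1.0) <= 1e-9

    def test_weighted_histogram_equals_raw_multiset(self, rng):
        """8-bit-quantized pixels: pooled raw fit equals the compressed fit."""
        quantized = rng.integers(0, 256, size=500) / 255.0
        model = _model_from_values(quantized, h=0.1)
        oracle = gaussian_sum_density(quantized, 0.1, model.grid)
        assert np.allclose(model.density, oracle, atol=1e-12)

    def test_scott_rule_default_bandwidth(self):
        values = np.array([0.2, 0.4, 0.4, 0.8])
        model = _model_from_values(values, h="scott")
        expected = values.std(ddof=1) * 4 ** (-0.2)
        assert model.bandwidth == pytest.approx(expected, rel=1e-12)

    def test_degenerate_sample_falls_back_to_quantization_step(self):
        assert scott_bandwidth(np.array([0.3])) == pytest.approx(1 / 255)
        assert scott_bandwidth(np.array([0.3, 0.3, 0.3])) == pytest.approx(1 / 255)


class TestDensityAt:
    def test_grid_point_returns_tabulated_value(self):
        model = _model_from_values([0.2, 0.4, 0.4, 0.8])
        for k in (0, 17, 102, 255):
            assert density_at(model, float(model.grid[k])) == model.density[k]

    def test_midpoint_is_average_of_neighbors(self):
        model = _model_from_values([0.2, 0.4, 0.4, 0.8])
        mid = (model.grid[10] + model.grid[11]) / 2.0
        expected = (model.density[10] + model.density[11]) / 2.0
        assert density_at(model, float(mid)) == pytest.approx(expected, abs=1e-12)

    def test_arbitrary_points_match_interpolation_oracle(self, rng):
        model = _model_from_values([0.2, 0.4, 0.4, 0.8])
        for v in rng.uniform(0, 1, size=200):
            expected = linear_interp(model.grid, model.density, v)
            assert density_at(model, float(v)) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_raises(self):
        model = _model_from_values([0.5])
        for v in (-0.01, 1.01):
            with pytest.raises(ValueError, match="intensity out of range"):
                density_at(model, v)


class TestPsKdeTransform:
    def test_pixels_at_argmax_density_map_to_one(self):
        model = _model_from_values([0.2, 0.4, 0.4, 0.8])
        peak = float(model.grid[np.argmax(model.density)])
        out = ps_kde_transform(np.full((3, 3), peak), model)
        assert np.allclose(out, 1.0)

    def test_equal_inputs_give_equal_outputs(self, rng):
        model = _model_from_values(rng.uniform(0, 1, 30))
        img = np.array([[0.3, 0.7], [0.3, 0.7]])
        out = ps_kde_transform(img, model)
        assert out[0, 0] == out[1, 0]
        assert out[0, 1] == out[1, 1]

    def test_2x2_image_matches_per_pixel_oracle(self):
        values = [0.2, 0.4, 0.4, 0.8]
        model = _model_from_values(values, h=0.1)
        oracle_density = gaussian_sum_density(values, 0.1, model.grid)
        img = np.array([[0.2, 0.4], [0.4, 0.8]])
        out = ps_kde_transform(img, model)
        for idx in np.ndindex(img.shape):
            expected = linear_interp(model.grid, oracle_density, img[idx])
            expected /= oracle_density.max()
            assert out[idx] == pytest.approx(expected, abs=1e-9)

    def test_output_in_unit_interval_and_monotone_in_density(self, rng):
        """Higher intensity density means a higher substituted value."""
        model = _model_from_values(rng.uniform(0, 1, 40))
        vals = rng.uniform(0, 1, size=(2, 500))
        out = ps_kde_transform(vals, model)
        assert out.min() >= 0.0 and out.max() <= 1.0
        da = np.array([density_at(model, float(v)) for v in vals[0]])
        db = np.array([density_at(model, float(v)) for v in vals[1]])
        assert np.array_equal(da > db, out[0] > out[1])


class TestModelPersistence:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        model = _model_from_values(rng.uniform(0, 1, 25), region_label="heart")
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.region_label == model.region_label
        assert np.array_equal(loaded.grid, model.grid)
        assert np.array_equal(loaded.density, model.density)
        assert loaded.bandwidth == model.bandwidth
        assert loaded.n_pixels == model.n_pixels
        assert loaded.max_density == model.max_density

    def test_missing_density_key_raises(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema_version": 1, "grid": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="invalid density model file"):
            load_model(path)

    def test_wrong_schema_version_raises(self, tmp_path):
        path = tmp_path / "v2.json"
        path.write_text(json.dumps({"schema_version": 2}))
        with pytest.raises(ValueError, match="unsupported model version"):
            load_model(path)

    def test_malformed_file_raises(self, tmp_path):
        path = tmp_path / "garbage.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="invalid density model file"):
            load_model(path)

    def test_minimal_two_point_model_loads_and_invariants_fire(self, tmp_path):
        # unit trapezoidal mass on [0, 1] with G=2: (d0 + d1)/2 == 1
        good = {
            "schema_version": 1,
            "region_label": "toy",
            "grid": [0.0, 1.0],
            "density": [0.5, 1.5],
            "bandwidth": 0.1,
            "n_pixels": 3,
        }
        path = tmp_path / "tiny.json"
        path.write_text(json.dumps(good))
        model = load_model(path)
        assert model.max_density == 1.5
        bad = dict(good, density=[1.0, 1.5])  # mass 1.25, not normalized
        path.write_text(json.dumps(bad))
        with pytest.raises(ValueError, match="invalid density model file"):
            load_model(path)

    def test_direct_construction_validates(self):
        with pytest.raises(ValueError):
            DensityModel(
                region_label="x",
                grid=np.linspace(0, 1, 4),
                density=np.array([1.0, 1.0, 1.0, 1.0]),  # mass != 1? mass == 1
                bandwidth=-1.0,  # invalid either way
                n_pixels=1,
            )
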