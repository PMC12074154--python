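"""Index formulas, tasseled-cap dot products, terrain, stack assembly."""

import numpy as np
import pytest

from standagb.raster import GridSpec, Raster
from standagb.spectral_features import (ALL_BAND_NAMES, FEATURE_NAMES,
                                        TASSELED_CAP_COEFFS,
                                        assemble_stack,
                                        compute_vegetation_indices,
                                        resample_to_grid, tasseled_cap,
                                        terrain_features)

G3 = GridSpec(0.0, 90.0, 30.0, 3, 3)


def _bands(values: dict[str, float], shape=(3, 3)) -> dict[str, Raster]:
    return {name: Raster(np.full(shape, values.get(name, 0.1)), G3)
            for name in ALL_BAND_NAMES}


class TestResample:
    def test_constant_raster_stays_constant(self):
        src = Raster(np.full((9, 9), 7.0), GridSpec(0.0, 90.0, 10.0, 9, 9))
        out = resample_to_grid(src, G3)
        assert (out.data == 7.0).all()

    def test_checkerboard_values_come_from_source_set(self):
        rows, cols = np.indices((9, 9))
        src = Raster(((rows + cols) % 2).astype(float),
                     GridSpec(0.0, 90.0, 10.0, 9, 9))
        out = resample_to_grid(src, G3)
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_same_grid_resampling_is_identity(self, rng):
        src = Raster(rng.uniform(0, 1, (3, 3)), G3)
        out = resample_to_grid(src, G3)
        np.testing.assert_array_equal(out.data, src.data)

    def test_crs_mismatch_rejected(self):
        src = Raster(np.ones((3, 3)), GridSpec(0.0, 90.0, 30.0, 3, 3,
                                               crs="other"))
        with pytest.raises(ValueError, match="CRS"):
            resample_to_grid(src, G3)


class TestVegetationIndices:
    def test_ndvi_arithmetic(self):
        idx, _ = compute_vegetation_indices(_bands({"B8": 0.5, "B4": 0.1}))
        assert idx["NDVI"].data[0, 0] == pytest.approx(0.4 / 0.6)

    def test_equal_nir_red_symmetry(self):
        idx, _ = compute_vegetation_indices(_bands({"B8": 0.3, "B4": 0.3}))
        assert idx["NDVI"].data[0, 0] == pytest.approx(0.0)
        assert idx["DVI"].data[0, 0] == pytest.approx(0.0)
        assert idx["RVI"].data[0, 0] == pytest.approx(1.0)

    def test_equal_visible_bands_zero_vdvi(self):
        idx, _ = compute_vegetation_indices(
            _bands({"B2": 0.2, "B3": 0.2, "B4": 0.2}))
        assert idx["VDVI"].data[0, 0] == pytest.approx(0.0)

    def test_golden_values_on_stated_formulas(self):
        b = {"B2": 0.05, "B3": 0.09, "B4": 0.12, "B5": 0.18, "B6": 0.24,
             "B8": 0.40, "B11": 0.22, "B12": 0.15}
        idx, _ = compute_vegetation_indices(_bands(b))
        v = {k: r.data[0, 0] for k, r in idx.items()}
        assert v["NDVI"] == pytest.approx((0.40 - 0.12) / (0.40 + 0.12))
        assert v["RENDVI"] == pytest.approx((0.24 - 0.18) / (0.24 + 0.18))
        assert v["NDWI"] == pytest.approx((0.09 - 0.40) / (0.09 + 0.40))
        assert v["EVI"] == pytest.approx(
            2.5 * (0.40 - 0.12) / (0.40 + 6 * 0.12 - 7.5 * 0.05 + 1))
        assert v["RVI"] == pytest.approx(0.40 / 0.12)
        assert v["DVI"] == pytest.approx(0.28)
        assert v["VDVI"] == pytest.approx(
            (2 * 0.09 - 0.12 - 0.05) / (2 * 0.09 + 0.12 + 0.05))
        assert v["SAVI"] == pytest.approx(
            1.5 * (0.40 - 0.12) / (0.40 + 0.12 + 0.5))
        assert v["MSAVI"] == pytest.approx(
            (2 * 0.40 + 1 - np.sqrt((2 * 0.40 + 1) ** 2
                                    - 8 * (0.40 - 0.12))) / 2)
        assert v["NBR"] == pytest.approx((0.40 - 0.15) / (0.40 + 0.15))
        assert v["NDMI"] == pytest.approx((0.40 - 0.22) / (0.40 + 0.22))

    def test_zero_denominator_becomes_missing_and_counted(self):
        idx, counts = compute_vegetation_indices(
            _bands({"B8": 0.0, "B4": 0.0}))
        assert np.isnan(idx["NDVI"].data).all()
        assert counts["NDVI"] == 9

    def test_missing_band_error_names_band_and_index(self):
        bands = _bands({})
        del bands["B8"]
        with pytest.raises(ValueError, match="B8"):
            compute_vegetation_indices(bands)

    def test_normalized_difference_indices_bounded(self, rng):
        vals = {n: rng.uniform(0.01, 1.0) for n in ALL_BAND_NAMES}
        idx, _ = compute_vegetation_indices(_bands(vals))
        for name in ("NDVI", "RENDVI", "NDWI", "NBR", "NDMI"):
            data = idx[name].data
            assert np.nanmin(data) >= -1.0 and np.nanmax(data) <= 1.0


class TestTasseledCap:
    def test_zero_bands_give_zero_components(self):
        tcb, tcg, tcw = tasseled_cap(_bands({n: 0.0 for n in ALL_BAND_NAMES}))
        assert (tcb.data == 0).all() and (tcg.data == 0).all() \
            and (tcw.data == 0).all()

    def test_all_ones_equals_coefficient_sums(self):
        tcb, tcg, tcw = tasseled_cap(_bands({n: 1.0 for n in ALL_BAND_NAMES}))
        for comp, r in zip(("TCB", "TCG", "TCW"), (tcb, tcg, tcw)):
            assert r.data[0, 0] == pytest.approx(
                sum(TASSELED_CAP_COEFFS[comp]), rel=1e-12)

    def test_linearity(self, rng):
        vals = {n: float(rng.uniform(0, 1)) for n in ALL_BAND_NAMES}
        doubled = {n: 2 * v for n, v in vals.items()}
        one = tasseled_cap(_bands(vals))
        two = tasseled_cap(_bands(doubled))
        for a, b in zip(one, two):
            np.testing.assert_allclose(b.data, 2 * a.data, rtol=1e-12)

    def test_missing_band_rejected(self):
        bands = _bands({})
        del bands["B10"]
        with pytest.raises(ValueError, match="B10"):
            tasseled_cap(bands)

    def test_custom_coefficients_override(self):
        coeffs = {"TCB": (1.0,) + (0.0,) * 12,
                  "TCG": (0.0, 1.0) + (0.0,) * 11,
                  "TCW": (0.0,) * 12 + (1.0,)}
        bands = _bands({"B1": 0.3, "B2": 0.6, "B8A": 0.9})
        tcb, tcg, tcw = tasseled_cap(bands, coeffs=coeffs)
        assert tcb.data[0, 0] == pytest.approx(0.3)
        assert tcg.data[0, 0] == pytest.approx(0.6)
        assert tcw.data[0, 0] == pytest.approx(0.9)


class TestTerrain:
    def test_flat_dem_zero_slope_sentinel_aspect(self):
        dem = Raster(np.full((4, 4), 250.0), GridSpec(0, 120, 30, 4, 4))
        _, slope, aspect = terrain_features(dem)
        assert (slope.data == 0).all()
        assert (aspect.data == -1.0).all()

    def test_plane_rising_east(self):
        xs = np.arange(5) * 30.0
        dem = Raster(np.tile(xs / 30.0, (5, 1)), GridSpec(0, 150, 30, 5, 5))
        _, slope, aspect = terrain_features(dem)
        inner = slice(1, -1)
        np.testing.assert_allclose(slope.data[inner, inner],
                                   np.degrees(np.arctan(1 / 30)), rtol=1e-9)
        np.testing.assert_allclose(aspect.data[inner, inner], 90.0,
                                   atol=1e-9)

    def test_flipping_plane_flips_aspect(self):
        xs = np.arange(5) * 30.0
        east = Raster(np.tile(xs / 30.0, (5, 1)), GridSpec(0, 150, 30, 5, 5))
        west = Raster(-east.data, east.grid)
        _, _, a_e = terrain_features(east)
        _, _, a_w = terrain_features(west)
        inner = slice(1, -1)
        np.testing.assert_allclose(
            (a_e.data[inner, inner] + 180.0) % 360.0,
            a_w.data[inner, inner], atol=1e-9)

    def test_tiny_dem_rejected(self):
        with pytest.raises(ValueError, match="3"):
            terrain_features(Raster(np.ones((2, 2)),
                                    GridSpec(0, 60, 30, 2, 2)))


class TestAssembleStack:
    def _inputs(self, rng):
        fine = GridSpec(0.0, 90.0, 10.0, 9, 9)
        bands = {n: Raster(rng.uniform(0.05, 0.6, (9, 9)), fine)
                 for n in ALL_BAND_NAMES}
        dem = Raster(rng.uniform(99, 101, (3, 3)), G3)
        return bands, dem

    def test_26_aligned_layers(self, rng):
        bands, dem = self._inputs(rng)
        stack = assemble_stack(bands, dem, target=G3)
        assert set(stack.layers) == set(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 26
        shapes = {r.shape for r in stack.layers.values()}
        assert shapes == {(3, 3)}

    def test_deterministic_assembly(self, rng):
        bands, dem = self._inputs(rng)
        s1 = assemble_stack(bands, dem, target=G3)
        s2 = assemble_stack(bands, dem, target=G3)
        for name in FEATURE_NAMES:
            np.testing.assert_array_equal(s1.layers[name].data,
                                          s2.layers[name].data)

    def test_dropping_b12_names_dependents(self, rng):
        bands, dem = self._inputs(rng)
        del bands["B12"]
        with pytest.raises(ValueError) as err:
            assemble_stack(bands, dem, target=G3)
        msg = str(err.value)
        for needed in ("NBR", "TCB", "TCG", "TCW", "B12"):
            assert needed in msg
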