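import numpy as np
import pytest

from asoanfis.features import (
    INDEX_REGISTRY,
    STACK_BAND_NAMES,
    MultispectralScene,
    PlotRecord,
    SarScene,
    build_feature_stack,
    compute_sar_combos,
    compute_spectral_indices,
    evaluate_formula,
    extract_plot_features,
)
from asoanfis.raster import Raster, resample_to_reference

from conftest import toy_raster


def _const_scene(b, g, r, n, shape=(4, 4)):
    mk = lambda v: toy_raster(np.full(shape, float(v)))
    return MultispectralScene(mk(b), mk(g), mk(r), mk(n))


class TestSarCombos:
    def test_hand_arithmetic(self):
        sar = SarScene(toy_raster(np.full((3, 3), -6.0)), toy_raster(np.full((3, 3), -12.0)))
        combos = compute_sar_combos(sar)
        assert np.allclose(combos["AVERAGE_vhvv"].data, -9.0)
        assert np.allclose(combos["DIFF_vvvh"].data, 6.0)
        assert np.allclose(combos["MULT_vhvv"].data, 72.0)
        assert np.allclose(combos["RATIO_vvvh"].data, 0.5)

    def test_identical_polarisations(self):
        sar = SarScene(toy_raster(np.full((3, 3), -8.0)), toy_raster(np.full((3, 3), -8.0)))
        combos = compute_sar_combos(sar)
        assert np.allclose(combos["DIFF_vvvh"].data, 0.0)
        assert np.allclose(combos["RATIO_vvvh"].data, 1.0)

    def test_zero_vh_masks_ratio_only(self):
        vh = np.full((2, 2), -10.0)
        vh[0, 0] = 0.0
        sar = SarScene(toy_raster(np.full((2, 2), -5.0)), toy_raster(vh))
        combos = compute_sar_combos(sar)
        assert np.isnan(combos["RATIO_vvvh"].data[0, 0])
        assert np.isfinite(combos["AVERAGE_vhvv"].data).all()
        assert np.isfinite(combos["MULT_vhvv"].data).all()


class TestSpectralIndices:
    def test_hand_evaluations(self):
        ms = _const_scene(b=0.05, g=0.2, r=0.1, n=0.4)
        idx = compute_spectral_indices(ms)
        assert np.allclose(idx["NDVI"].data, 0.6)
        assert np.allclose(idx["SAVI"].data, 1.5 * 0.3 / 1.0)
        assert np.allclose(idx["GI"].data, 2.0)
        assert np.allclose(idx["DVI"].data, 0.3)

    def test_nir_equals_red_symmetry(self):
        ms = _const_scene(b=0.05, g=0.2, r=0.3, n=0.3)
        idx = compute_spectral_indices(ms)
        for name in ("NDVI", "DVI", "RDVI"):
            assert np.allclose(idx[name].data, 0.0), name

    def test_constant_scene_gives_constant_indices(self):
        ms = _const_scene(b=0.04, g=0.12, r=0.09, n=0.35)
        for name, band in compute_spectral_indices(ms).items():
            vals = band.data[np.isfinite(band.data)]
            assert np.allclose(vals, vals.flat[0]), name

    def test_normalised_difference_indices_bounded(self, scene):
        ms, _, _ = scene
        idx = compute_spectral_indices(ms)
        for name in ("NDVI", "GNDVI", "RI", "PNDVI", "BWDRVI", "WDRVI", "GLI"):
            vals = idx[name].data[np.isfinite(idx[name].data)]
            assert vals.min() >= -1 - 1e-12 and vals.max() <= 1 + 1e-12, name

    def test_zero_denominator_masks_not_propagates(self):
        # G == B makes the IF shape-index denominator vanish
        ms = _const_scene(b=0.2, g=0.2, r=0.1, n=0.4)
        idx = compute_spectral_indices(ms)
        assert np.isnan(idx["IF"].data).all()
        assert np.isfinite(idx["NDVI"].data).all()

    def test_registry_formula_eval_matches_numpy(self, rng):
        B, G, R, N = (rng.uniform(0.05, 0.5, (5, 5)) for _ in range(4))
        got = evaluate_formula("(N - R) / (N + R)", B, G, R, N)
        assert np.allclose(got, (N - R) / (N + R))


class TestBuildStack:
    def test_exactly_42_unique_bands(self, feature_stack):
        assert len(feature_stack) == 42
        assert len(set(feature_stack)) == 42
        assert list(feature_stack) == STACK_BAND_NAMES
        shapes = {b.data.shape for b in feature_stack.values()}
        assert len(shapes) == 1

    def test_deterministic(self, scene):
        ms, sar, _ = scene
        s1 = build_feature_stack(ms, sar)
        s2 = build_feature_stack(ms, sar)
        for name in s1:
            np.testing.assert_array_equal(s1[name].data, s2[name].data)

    def test_missing_band_raises(self, scene):
        ms, sar, _ = scene
        with pytest.raises(ValueError, match="nir"):
            MultispectralScene(ms.blue, ms.green, ms.red, None)

    def test_misregistered_inputs_raise(self, scene):
        ms, _, _ = scene
        bad_vv = Raster(np.zeros(ms.nir.shape), (1.0, 2.0, 5.0, -5.0))
        bad = SarScene(bad_vv, bad_vv.copy_with(np.zeros(ms.nir.shape)))
        with pytest.raises(ValueError, match="co-registered"):
            build_feature_stack(ms, bad)


class TestResample:
    def test_constant_grid(self):
        src = toy_raster(np.full((8, 8), 3.5), cell=10.0)
        ref = toy_raster(np.zeros((12, 12)), cell=6.0)
        out = resample_to_reference(src, ref)
        vals = out.data[np.isfinite(out.data)]
        assert vals.size > 0 and np.allclose(vals, 3.5)

    def test_bilinear_closed_form_center(self):
        src = toy_raster(np.array([[0.0, 2.0], [2.0, 4.0]]), cell=10.0)
        # reference cell centred exactly between the four source centres
        ref = Raster(np.zeros((1, 1)), (5.0, 15.0, 10.0, -10.0))
        out = resample_to_reference(src, ref)
        assert out.data[0, 0] == pytest.approx(2.0)

    def test_nodata_propagates(self):
        data = np.ones((4, 4))
        data[1, 1] = np.nan
        src = toy_raster(data, cell=10.0)
        out = resample_to_reference(src, src)
        assert np.isnan(out.data[1, 1])

    def test_disjoint_extents_raise(self):
        src = toy_raster(np.ones((4, 4)), cell=10.0)
        ref = toy_raster(np.ones((4, 4)), cell=10.0, origin=(1000.0, 1000.0))
        with pytest.raises(ValueError, match="disjoint"):
            resample_to_reference(src, ref)


def brute_force_plot_mean(raster, x, y, side, supersample=400):
    """Oracle: dense regular sampling of the window (area-weighted limit)."""
    xs = np.linspace(x - side / 2, x + side / 2, supersample)
    ys = np.linspace(y - side / 2, y + side / 2, supersample)
    gx, gy = np.meshgrid(xs, ys)
    fr, fc = raster.world_to_rowcol(gx, gy)
    rr = np.clip(np.round(fr).astype(int), 0, raster.shape[0] - 1)
    cc = np.clip(np.round(fc).astype(int), 0, raster.shape[1] - 1)
    return float(np.mean(raster.data[rr, cc]))


class TestExtractPlots:
    def test_constant_band_any_plot_size(self):
        band = toy_raster(np.full((20, 20), 7.25))
        for area in (100.0, 1000.0):
            table = extract_plot_features(
                {"X": band}, [PlotRecord("a", 60.0, 60.0, area)]
            )
            assert table.loc["a", "X"] == pytest.approx(7.25)

    def test_matches_brute_force_overlap_average(self, rng):
        data = rng.random((30, 30))
        band = toy_raster(data)
        plots = [
            PlotRecord(f"p{i}", rng.uniform(40, 140), rng.uniform(40, 140), area)
            for i, area in enumerate([100.0, 1000.0, 400.0, 250.0])
        ]
        table = extract_plot_features({"B": band}, plots)
        for p in plots:
            oracle = brute_force_plot_mean(band, p.x, p.y, np.sqrt(p.area_m2))
            assert table.loc[p.id, "B"] == pytest.approx(oracle, abs=2e-3)

    def test_window_size_matters_on_curved_gradient(self):
        grad = toy_raster(np.tile(np.arange(40, dtype=float) ** 2, (40, 1)))
        plots = [
            PlotRecord("small", 120.0, 120.0, 100.0),
            PlotRecord("large", 120.0, 120.0, 1000.0),
        ]
        table = extract_plot_features({"G": grad}, plots)
        # a convex profile averages higher over the wider window
        assert table.loc["large", "G"] > table.loc["small", "G"] + 1.0

    def test_outside_plot_flagged_and_dropped(self):
        band = toy_raster(np.ones((10, 10)))
        plots = [
            PlotRecord("in", 30.0, 30.0, 100.0),
            PlotRecord("out", 1e6, 1e6, 100.0),
        ]
        with pytest.warns(UserWarning, match="out"):
            table = extract_plot_features({"B": band}, plots)
        assert list(table.index) == ["in"]

    def test_translation_invariance_on_tiled_scene(self):
        data = np.sin(np.arange(24))[None, :] * np.cos(np.arange(24))[:, None]
        single = toy_raster(data)
        tiled = Raster(np.tile(data, (2, 2)), single.transform)
        plot = [PlotRecord("p", 70.0, 70.0, 400.0)]
        t1 = extract_plot_features({"B": single}, plot)
        t2 = extract_plot_features({"B": tiled}, plot)
        assert t1.loc["p", "B"] == pytest.approx(t2.loc["p", "B"])
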