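"""Enrichment ratios, disc rasterization, and 10x10 heatmaps."""

import numpy as np
import pytest

from amisquant import (
    HeatmapMatrix,
    ProjectedImage,
    RegionMask,
    build_cell_heatmap,
    central_section_project,
    central_vs_surround_ratio,
    core_vs_cell_ratio,
    heatmap_central_level,
    interface_vs_matrix_intensity,
    stack_heatmaps,
)
from amisquant.errors import GeometryError, MaskError, UndefinedRatioError
from amisquant.regions import disc_mask
from amisquant.synthetic import SceneParams, generate_cluster_scene


def uniform_image(value, shape=(100, 100), px=0.2):
    return ProjectedImage(np.full(shape, float(value)), pixel_size_um=px, channel="par3")


def full_mask(shape=(100, 100), px=0.2, role="cluster"):
    return RegionMask(np.ones(shape, bool), px, role=role)


class TestCentralVsSurround:
    def test_uniform_image_ratio_one(self):
        res = central_vs_surround_ratio(uniform_image(5.0), full_mask(), (10.0, 10.0))
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_synthetic_cluster_matches_pixelwise_oracle(self):
        stack, truth = generate_cluster_scene(SceneParams(n_cells=4, par3_enrichment=3.0))
        img = central_section_project(stack, "par3")
        cm = truth.cluster_mask(img.pixels.shape)
        res = central_vs_surround_ratio(img, cm, truth.interface_midpoint_xy, 4.0)
        disc = disc_mask(img.pixels.shape, truth.interface_midpoint_xy, 4.0, 0.2)
        oracle_c = img.pixels[disc & cm.mask].mean()
        oracle_s = img.pixels[cm.mask & ~disc].mean()
        assert res.mean_central == pytest.approx(oracle_c, abs=1e-12)
        assert res.mean_surround == pytest.approx(oracle_s, abs=1e-12)
        assert res.ratio == pytest.approx(oracle_c / oracle_s, abs=1e-12)
        assert res.ratio > 1.0

    def test_zero_image_raises_undefined_ratio(self):
        with pytest.raises(UndefinedRatioError):
            central_vs_surround_ratio(uniform_image(0.0), full_mask(), (10.0, 10.0))

    def test_disc_outside_mask_raises(self):
        mask = np.zeros((100, 100), bool)
        mask[:20, :20] = True
        with pytest.raises(GeometryError):
            central_vs_surround_ratio(
                uniform_image(1.0), RegionMask(mask, 0.2), (15.0, 15.0)
            )

    def test_gain_invariance(self, rng):
        pixels = rng.random((80, 80)) + 0.5
        mask = full_mask((80, 80))
        a = central_vs_surround_ratio(
            ProjectedImage(pixels, 0.2), mask, (8.0, 8.0)
        ).ratio
        b = central_vs_surround_ratio(
            ProjectedImage(pixels * 37.0, 0.2), mask, (8.0, 8.0)
        ).ratio
        assert b == pytest.approx(a, rel=1e-12)


class TestCoreVsCell:
    def test_uniform_cell_ratio_one(self):
        res = core_vs_cell_ratio(uniform_image(2.0), full_mask(role="cell"),
                                 (10.0, 10.0), core_diameter_um=6.0)
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_core_diameter_is_mandatory(self):
        with pytest.raises(TypeError):
            core_vs_cell_ratio(uniform_image(2.0), full_mask(), (10.0, 10.0))

    def test_central_gaussian_core_matches_mask_oracle(self):
        px = 0.2
        yy, xx = np.mgrid[0:100, 0:100] * px
        pixels = 1.0 + 4.0 * np.exp(-(((xx - 10) ** 2 + (yy - 10) ** 2) / 8.0))
        img = ProjectedImage(pixels, px, channel="par3")
        cell = RegionMask(disc_mask((100, 100), (10.0, 10.0), 16.0, px), px, "cell")
        res = core_vs_cell_ratio(img, cell, (10.0, 10.0), core_diameter_um=6.0)
        core = disc_mask((100, 100), (10.0, 10.0), 6.0, px) & cell.mask
        assert res.ratio == pytest.approx(
            pixels[core].mean() / pixels[cell.mask].mean(), abs=1e-12
        )
        assert res.ratio > 1.0

    def test_core_outside_cell_raises(self):
        cell = RegionMask(disc_mask((100, 100), (5.0, 5.0), 6.0, 0.2), 0.2, "cell")
        with pytest.raises(GeometryError):
            core_vs_cell_ratio(uniform_image(1.0), cell, (18.0, 18.0), 2.0)


class TestInterfaceVsMatrix:
    def test_uniform_image_ratio_one(self):
        a = np.zeros((50, 50), bool); a[10:12, :] = True
        b = np.zeros((50, 50), bool); b[40:42, :] = True
        res = interface_vs_matrix_intensity(
            uniform_image(3.0, (50, 50)),
            RegionMask(a, 0.2, "interface band"),
            RegionMask(b, 0.2, "matrix band"),
        )
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_doublet_interface_twice_outer_membrane(self, null_doublet):
        # both cells contribute membrane at the shared interface
        stack, truth = null_doublet
        ref = truth.reference[1]  # noiseless cadherin
        img = ProjectedImage(ref[3], truth.pixel_size_um, channel="cadherin")
        p = truth.pixel_size_um
        mx, my, _ = truth.interface_midpoint
        band = np.zeros(img.pixels.shape, bool)
        iy, ix = int(round(my / p)), int(round(mx / p))
        band[iy - 5 : iy + 5, ix] = True  # on-chord interface band
        pole_x = int(round((truth.cell_centres[0][0] - truth.cell_radius_um) / p))
        matrix = np.zeros(img.pixels.shape, bool)
        matrix[iy - 5 : iy + 5, pole_x] = True  # outer membrane band
        res = interface_vs_matrix_intensity(
            img, RegionMask(band, p, "interface"), RegionMask(matrix, p, "matrix")
        )
        # curvature of the outer-membrane band relative to the shell ridge
        # biases the denominator by a few percent
        assert res.ratio == pytest.approx(2.0, rel=0.1)

    def test_overlapping_bands_raise(self):
        m = np.zeros((50, 50), bool); m[10:20, 10:20] = True
        with pytest.raises(MaskError):
            interface_vs_matrix_intensity(
                uniform_image(1.0, (50, 50)),
                RegionMask(m, 0.2), RegionMask(m.copy(), 0.2),
            )

    def test_empty_band_raises(self):
        with pytest.raises(MaskError):
            RegionMask(np.zeros((10, 10), bool), 0.2)


class TestDiscRasterization:
    @pytest.mark.parametrize("diameter", [2.0, 4.0, 6.0])
    def test_disc_area_close_to_analytic(self, diameter):
        px = 0.2
        mask = disc_mask((200, 200), (20.0, 20.0), diameter, px)
        analytic = np.pi * (diameter / 2) ** 2 / px**2
        # rasterization bound: within one pixel-row of the circumference
        assert abs(mask.sum() - analytic) <= np.pi * diameter / px


class TestHeatmaps:
    def test_uniform_roi_constant_units(self):
        hm = build_cell_heatmap(uniform_image(2.5, (60, 60)), (5, 5, 50))
        np.testing.assert_allclose(hm.units, 2.5, atol=1e-12)

    def test_linear_gradient_matches_block_mean_oracle(self):
        pixels = np.tile(np.arange(20.0), (20, 1))
        img = ProjectedImage(pixels, 0.2)
        hm = build_cell_heatmap(img, (0, 0, 20))
        expected = np.array(
            [[pixels[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].mean() for j in range(10)]
             for i in range(10)]
        )
        np.testing.assert_array_equal(hm.units, expected)
        assert np.all(np.diff(hm.units, axis=1) > 0)  # strictly increasing columns

    def test_indivisible_roi_matches_partition_oracle(self, rng):
        pixels = rng.random((40, 40))
        img = ProjectedImage(pixels, 0.2)
        hm = build_cell_heatmap(img, (1, 2, 37))
        from amisquant._util import partition_indices

        roi = pixels[1:38, 2:39]
        slices = partition_indices(37, 10)
        for i, rs in enumerate(slices):
            for j, cs in enumerate(slices):
                assert hm.units[i, j] == pytest.approx(roi[rs, cs].mean(), abs=1e-12)

    def test_small_roi_rejected(self):
        with pytest.raises(ValueError):
            build_cell_heatmap(uniform_image(1.0), (0, 0, 9))

    def test_stacking_identical_maps_is_identity(self, rng):
        hm = HeatmapMatrix(rng.random((10, 10)))
        out = stack_heatmaps([hm] * 5)
        np.testing.assert_allclose(out.units, hm.units, atol=1e-12)
        assert out.n_cells == 5

    def test_stacking_matches_elementwise_oracle(self, rng):
        maps = [HeatmapMatrix(rng.random((10, 10))) for _ in range(15)]
        out = stack_heatmaps(maps)
        np.testing.assert_allclose(
            out.units, np.stack([m.units for m in maps]).mean(axis=0), atol=1e-12
        )

    def test_central_level_uniform(self):
        assert heatmap_central_level(HeatmapMatrix(np.full((10, 10), 3.0))) == 3.0

    def test_central_level_single_unit(self):
        units = np.zeros((10, 10))
        units[4, 4] = 4.0  # unit (5,5) in 1-based numbering
        assert heatmap_central_level(HeatmapMatrix(units)) == pytest.approx(1.0)

    def test_central_level_matches_index_oracle(self, rng):
        units = rng.random((10, 10))
        expected = np.mean([units[4, 4], units[4, 5], units[5, 4], units[5, 5]])
        assert heatmap_central_level(HeatmapMatrix(units)) == pytest.approx(expected)
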