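"""Width-averaged line-scans, interface-end detection, and 20-bin
normalized profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amisquant import (
    InterfaceProfile,
    PolyLinePath,
    ProjectedImage,
    average_binned_profiles,
    bin_profile,
    centre_side_linescans,
    detect_interface_ends,
    sample_path_intensity,
)
from amisquant._util import partition_indices, perpendicular_offsets
from amisquant.errors import DetectionError, GeometryError


def make_profile(values, start=None, end=None, positions=None):
    values = np.asarray(values, float)
    if positions is None:
        positions = np.arange(len(values), dtype=float)
    return InterfaceProfile(
        positions, {"par3": values, "actin": values.copy()}, pixel_size_um=1.0,
        interface_start_idx=start, interface_end_idx=end,
    )


class TestSamplePathIntensity:
    def test_uniform_image_gives_constant_samples(self):
        img = ProjectedImage(np.full((40, 40), 7.5), pixel_size_um=0.2, channel="par3")
        path = PolyLinePath([[1.0, 1.0], [6.0, 5.0]], width_um=0.8)
        prof = sample_path_intensity(img, path)
        np.testing.assert_allclose(prof.values["par3"], 7.5, atol=1e-12)

    def test_straight_path_matches_columnwise_3pixel_means(self, rng):
        # axis-aligned path, width = 3 pixels: samples are 3-pixel column means
        pixels = rng.random((9, 30))
        img = ProjectedImage(pixels, pixel_size_um=1.0, channel="ch")
        row = 4
        path = PolyLinePath([[2.0, float(row)], [27.0, float(row)]], width_um=3.0)
        prof = sample_path_intensity(img, path)
        expected = pixels[row - 1 : row + 2, 2:28].mean(axis=0)
        np.testing.assert_allclose(prof.values["ch"], expected, atol=1e-12)

    def test_five_subsamples_for_standard_band(self):
        # the 0.8 um band at 0.2 um pixels averages 5 perpendicular sub-samples
        offs = perpendicular_offsets(0.8, 0.2)
        assert len(offs) == 5
        np.testing.assert_allclose(offs, [-0.4, -0.2, 0.0, 0.2, 0.4])

    def test_out_of_bounds_path_raises(self):
        img = ProjectedImage(np.zeros((10, 10)), pixel_size_um=1.0)
        with pytest.raises(GeometryError):
            sample_path_intensity(img, PolyLinePath([[0.0, 5.0], [20.0, 5.0]], 1.0))

    def test_one_sample_per_pixel_size(self):
        img = ProjectedImage(np.zeros((30, 30)), pixel_size_um=0.5)
        path = PolyLinePath([[2.0, 2.0], [10.0, 2.0]], width_um=1.0)
        prof = sample_path_intensity(img, path)
        assert np.all(np.diff(prof.arc_positions_um) == pytest.approx(0.5))


class TestDetectInterfaceEnds:
    def test_two_gaussian_peaks_found_exactly(self):
        x = np.arange(100, dtype=float)
        actin = np.exp(-((x - 10) ** 2) / 8.0) + np.exp(-((x - 90) ** 2) / 8.0)
        prof = make_profile(actin)
        assert detect_interface_ends(prof, "actin") == (10, 90)

    def test_mirror_symmetric_profile_gives_symmetric_ends(self):
        x = np.arange(101, dtype=float)
        actin = np.exp(-((x - 20) ** 2) / 5.0) + np.exp(-((x - 80) ** 2) / 5.0)
        s, e = detect_interface_ends(make_profile(actin), "actin")
        assert s + e == 100  # symmetric about the path midpoint

    def test_flat_profile_raises(self):
        with pytest.raises(DetectionError):
            detect_interface_ends(make_profile(np.ones(50)), "actin")

    def test_flat_half_raises(self):
        actin = np.zeros(60)
        actin[10] = 1.0  # only the first half has a peak
        with pytest.raises(DetectionError):
            detect_interface_ends(make_profile(actin), "actin")


class TestBinProfile:
    def test_constant_span_gives_constant_bins(self):
        prof = make_profile(np.full(80, 3.25), start=5, end=70)
        binned = bin_profile(prof, "par3")
        np.testing.assert_allclose(binned.bin_means, 3.25, atol=1e-12)

    def test_linear_ramp_worked_example(self):
        # 100-sample span of 1..100: bin i (1-based) = mean of 5(i-1)+1..5i
        prof = make_profile(np.arange(1.0, 101.0), start=0, end=99)
        binned = bin_profile(prof, "par3")
        assert binned.bin_means[0] == pytest.approx(3.0)
        assert binned.bin_means[-1] == pytest.approx(98.0)
        np.testing.assert_allclose(binned.bin_means, 3.0 + 5.0 * np.arange(20))

    def test_matches_index_range_oracle_on_random_profiles(self, rng):
        # remainder-to-earliest-bins convention against a direct oracle
        for _ in range(200):
            n = int(rng.integers(25, 300))
            vals = rng.random(n)
            start = int(rng.integers(0, n - 21))
            end = int(rng.integers(start + 20, n))
            prof = make_profile(vals, start=start, end=end)
            got = bin_profile(prof, "par3").bin_means
            span = vals[start : end + 1]
            expected = [span[sl].mean() for sl in partition_indices(len(span), 20)]
            np.testing.assert_array_equal(got, expected)

    def test_short_span_rejected(self):
        prof = make_profile(np.ones(30), start=5, end=15)
        with pytest.raises(ValueError, match="shorter"):
            bin_profile(prof, "par3")

    def test_unset_endpoints_rejected(self):
        with pytest.raises(ValueError, match="unset"):
            bin_profile(make_profile(np.ones(30)), "par3")

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance_of_shape(self, gain):
        vals = np.sin(np.linspace(0, 3, 64)) + 2.0
        base = bin_profile(make_profile(vals, 2, 60), "par3").bin_means
        scaled = bin_profile(make_profile(vals * gain, 2, 60), "par3").bin_means
        np.testing.assert_allclose(scaled, gain * base, rtol=1e-12)

    def test_conservation_when_20_divides_span(self, rng):
        vals = rng.random(200)
        prof = make_profile(vals, start=10, end=169)  # span of 160 = 20 * 8
        binned = bin_profile(prof, "par3")
        assert binned.bin_means.mean() == pytest.approx(vals[10:170].mean(), abs=1e-12)


class TestAverageBinnedProfiles:
    def test_single_profile_is_identity(self):
        b = bin_profile(make_profile(np.arange(40.0), 0, 39), "par3")
        mean, disp = average_binned_profiles([b])
        np.testing.assert_array_equal(mean.bin_means, b.bin_means)
        np.testing.assert_array_equal(disp, np.zeros(20))

    def test_two_profiles_average_elementwise(self):
        a = bin_profile(make_profile(np.full(40, 2.0), 0, 39), "par3")
        b = bin_profile(make_profile(np.full(40, 6.0), 0, 39), "par3")
        mean, _ = average_binned_profiles([a, b])
        np.testing.assert_allclose(mean.bin_means, 4.0)

    def test_many_profiles_match_elementwise_oracle(self, rng):
        profiles = [
            bin_profile(make_profile(rng.random(50), 0, 49), "par3") for _ in range(15)
        ]
        mean, disp = average_binned_profiles(profiles, dispersion="sd")
        stack = np.stack([p.bin_means for p in profiles])
        np.testing.assert_allclose(mean.bin_means, stack.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(disp, stack.std(axis=0, ddof=1), atol=1e-12)
        assert mean.n_profiles == 15

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_binned_profiles([])


class TestCentreSideLinescans:
    def test_uniform_image_equal_aucs(self):
        img = ProjectedImage(np.full((120, 120), 4.0), pixel_size_um=0.25, channel="cad")
        endpoints = np.array([[15.0, 8.0], [15.0, 22.0]])
        res = centre_side_linescans(img, endpoints, "cad")
        assert res.auc_centre == pytest.approx(res.auc_side, rel=1e-9)
        assert res.auc_ratio == pytest.approx(1.0, abs=1e-9)

    def test_null_doublet_auc_ratio_near_one(self, null_doublet):
        # uniform cadherin along the interface: centre/side AUC ~ 1
        stack, truth = null_doublet
        res = centre_side_linescans(
            stack, truth.interface_chord_endpoints[:, :2], "cadherin"
        )
        assert res.auc_ratio == pytest.approx(1.0, abs=0.05)

    def test_interface_too_short_raises(self):
        img = ProjectedImage(np.ones((100, 100)), pixel_size_um=0.25)
        endpoints = np.array([[10.0, 10.0], [10.0, 14.0]])  # 4 um < 3 * 3 um
        with pytest.raises(GeometryError):
            centre_side_linescans(img, endpoints, "ch0")

    def test_scan_regions_symmetric_about_midpoint(self, null_doublet):
        stack, truth = null_doublet
        res = centre_side_linescans(
            stack, truth.interface_chord_endpoints[:, :2], "par3"
        )
        # centre scan crosses the midpoint: its middle sample is the max
        # of the PAR-3 body plateau, identical to the side mean there
        mid_val = res.centre.values["par3"][len(res.centre.values["par3"]) // 2]
        side_mid = res.side.values["par3"][len(res.side.values["par3"]) // 2]
        assert mid_val == pytest.approx(side_mid, rel=0.02)
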