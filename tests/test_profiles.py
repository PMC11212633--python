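"""Image loading, preprocessing, profile extraction and ROI import."""

import math
import zipfile

import numpy as np
import pytest
import tifffile

import patternkit as pk
from patternkit.errors import (
    BoundsError,
    DegenerateProfileError,
    EmptyResultError,
    ParameterError,
)
from patternkit.profiles import normalize_channel

from conftest import (
    imagej_line_roi,
    imagej_polyline_roi,
    imagej_rect_roi,
    ladder_image,
    midline_selection,
)


class TestLoadImage:
    def test_identity_load_single_pixel(self, tmp_path):
        arr = np.zeros((64, 64), dtype=np.uint16)
        arr[10, 20] = 10
        p = tmp_path / "a.tif"
        tifffile.imwrite(p, arr)
        img = pk.load_image(p)
        assert img.n_frames == 1 and img.n_channels == 1
        assert img.pixel_array[0, 0].max() == 10
        assert img.pixel_array[0, 0, 10, 20] == 10

    def test_invert_swaps_extrema(self, tmp_path):
        arr = np.zeros((64, 64), dtype=np.uint16)
        arr[10, 20] = 10
        p = tmp_path / "a.tif"
        tifffile.imwrite(p, arr)
        img = pk.load_image(p, invert=True)
        assert img.pixel_array[0, 0, 10, 20] == 0
        assert img.pixel_array[0, 0, 0, 0] == 10

    def test_blur_conserves_sum_and_lowers_peak(self, tmp_path):
        img0, _ = ladder_image()
        p = tmp_path / "b.tif"
        tifffile.imwrite(p, img0.pixel_array[0, 0].astype(np.float32))
        blurred = pk.load_image(p, blur_sigma=2.0)
        a, b = img0.pixel_array, blurred.pixel_array
        assert b.max() < a.max()
        assert abs(b.sum() - a.sum()) / a.sum() < 1e-3

    def test_blur_matches_direct_convolution_oracle(self, tmp_path):
        # dense direct convolution with an explicit truncated kernel
        rng = np.random.default_rng(0)
        arr = rng.random((40, 40))
        p = tmp_path / "c.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        sigma = 1.5
        got = pk.load_image(p, blur_sigma=sigma).pixel_array[0, 0]
        r = int(4 * sigma)
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        k /= k.sum()
        pad = np.pad(arr, r, mode="symmetric")  # scipy's "reflect" convention
        expected = np.zeros_like(arr)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                patch = pad[i : i + 2 * r + 1, j : j + 2 * r + 1]
                expected[i, j] = k @ patch @ k
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_unreadable_file(self, tmp_path):
        p = tmp_path / "x.tif"
        p.write_text("not a tiff")
        with pytest.raises(OSError):
            pk.load_image(p)

    def test_multichannel_time_series_axes(self, tmp_path):
        arr = np.arange(3 * 2 * 8 * 9, dtype=np.uint16).reshape(3, 2, 8, 9)
        p = tmp_path / "tc.tif"
        tifffile.imwrite(p, arr, metadata={"axes": "TCYX"})
        img = pk.load_image(p)
        assert img.n_frames == 3 and img.n_channels == 2
        assert img.shape_yx == (8, 9)


class TestRollingBallBackground:
    def test_uniform_image_maps_to_zero(self):
        img = pk.ImageData(np.full((1, 1, 40, 60), 37.0))
        out = pk.subtract_background_em(img, radius=20)
        np.testing.assert_allclose(out.pixel_array, 0.0, atol=1e-9)

    def test_dark_bands_on_dark_gradient(self):
        # light background with a slow dark gradient and dark bands (EM-like)
        w = 300
        x = np.arange(w, dtype=float)
        gradient = 30.0 * x / w  # slowly varying darkening
        bands = np.zeros(w)
        for c in range(40, 280, 40):
            bands += 50.0 * np.exp(-0.5 * ((x - c) / 3.0) ** 2)
        row = 200.0 - gradient - bands  # dark features on light background
        img = pk.ImageData(np.tile(row, (30, 1))[None, None])
        out = pk.subtract_background_em(img, radius=50)
        prof = out.pixel_array[0, 0, 15]
        # band contrast preserved within 5%
        band_amp = prof[40::40][:6].mean() - np.median(prof)
        assert band_amp == pytest.approx(50.0, rel=0.05)
        # residual large-scale tilt reduced by >= 90%
        bg_cols = [20, 60, 100, 140, 180, 220, 260]
        residual = np.ptp(prof[bg_cols])
        original_tilt = np.ptp((200.0 - gradient)[bg_cols])
        assert residual <= 0.1 * original_tilt

    def test_invalid_radius(self):
        img = pk.ImageData(np.ones((1, 1, 10, 10)))
        with pytest.raises(ParameterError):
            pk.subtract_background_em(img, radius=0)


class TestExtractProfile:
    def test_linear_ramp_normalizes_to_identity(self):
        arr = np.tile(np.arange(50.0), (20, 1))
        img = pk.ImageData(arr[None, None])
        sel = pk.Selection([(0, 10), (25, 10), (49, 10)])
        prof = pk.extract_profile(img, sel)
        np.testing.assert_allclose(
            prof.intensities[0], prof.positions / prof.positions[-1], atol=1e-9
        )

    def test_linewidth_invariant_across_uniform_stripe(self):
        arr = np.zeros((30, 20))
        arr[14:16, :] = 5.0  # horizontal stripe
        img = pk.ImageData(arr[None, None])
        base = pk.extract_profile(img, pk.Selection([(10, 4), (10, 26)], linewidth=1))
        wide = pk.extract_profile(img, pk.Selection([(10, 4), (10, 26)], linewidth=7))
        np.testing.assert_allclose(base.intensities, wide.intensities, atol=1e-9)

    def test_rotated_selection_stretches_period_by_inverse_cosine(self):
        img, centers = ladder_image(n_bands=10, spacing=25.0, height=120)
        theta = math.radians(5.0)
        x0, x1 = centers[0] - 10, centers[-1] + 10
        length = x1 - x0
        y0 = 60 - length / 2 * math.tan(theta)
        sel = pk.Selection([(x0, y0), (x1, y0 + length * math.tan(theta))])
        prof = pk.extract_profile(img, sel)
        est = pk.estimate_period(prof, 0)
        assert est.period == pytest.approx(25.0 / math.cos(theta), abs=0.1)

    def test_constant_profile_is_degenerate(self):
        img = pk.ImageData(np.full((1, 1, 20, 20), 3.0))
        with pytest.raises(DegenerateProfileError):
            pk.extract_profile(img, pk.Selection([(2, 10), (17, 10)]))

    def test_out_of_bounds_selection(self):
        img = pk.ImageData(np.zeros((1, 1, 20, 20)))
        with pytest.raises(BoundsError):
            pk.extract_profile(img, pk.Selection([(2, 10), (30, 10)]))

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(3)
        v = rng.random(100)
        once, _ = normalize_channel(v)
        twice, _ = normalize_channel(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_linewidth_averaging_reduces_background_noise(self):
        # pooled over seeds: background variance falls as linewidth grows
        variances = []
        for lw in (1, 3, 7, 12):
            pooled = []
            for seed in range(20):
                img, _ = pk.simulate_image(pk.SimulationConfig(snr=2.0, seed=seed))
                prof = pk.extract_profile(
                    img, midline_selection(img, lw), normalize=False
                )
                pooled.append(prof.intensities[0][:12])  # margin: background
            variances.append(np.var(np.concatenate(pooled)))
        assert all(a > b for a, b in zip(variances, variances[1:]))


class TestAngularError:
    @pytest.mark.parametrize(
        "theta,expected,tol",
        [(0.0, 0.0, 1e-12), (5.0, 0.00382, 5e-5), (60.0, 1.0, 1e-12)],
    )
    def test_closed_form(self, theta, expected, tol):
        assert pk.angular_length_error(theta) == pytest.approx(expected, abs=tol)

    def test_domain(self):
        with pytest.raises(ParameterError):
            pk.angular_length_error(90.0)


class TestImageJRoiImport:
    def test_line_roi_roundtrip(self, tmp_path):
        p = tmp_path / "line.roi"
        p.write_bytes(imagej_line_roi(10, 10, 60, 10, stroke_width=7))
        (sel,) = pk.import_imagej_rois(p)
        assert sel.linewidth == 7
        np.testing.assert_allclose(sel.vertex_array(), [[10, 10], [60, 10]])

    def test_zip_of_polylines_in_order(self, tmp_path):
        p = tmp_path / "rois.zip"
        with zipfile.ZipFile(p, "w") as zf:
            for i in range(3):
                pts = [(5 + i, 5), (20 + i, 9), (40, 5 + i)]
                zf.writestr(f"roi_{i}.roi", imagej_polyline_roi(pts, stroke_width=3))
        sels = pk.import_imagej_rois(p)
        assert len(sels) == 3
        assert [s.vertex_array()[0, 0] for s in sels] == [5, 6, 7]
        assert all(s.linewidth == 3 for s in sels)

    def test_zip_of_rectangles_is_empty_result(self, tmp_path):
        p = tmp_path / "rects.zip"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("r.roi", imagej_rect_roi(1, 1, 10, 10))
        with pytest.raises(EmptyResultError):
            pk.import_imagej_rois(p)

    def test_missing_stroke_width_defaults_to_one(self, tmp_path):
        p = tmp_path / "line.roi"
        p.write_bytes(imagej_line_roi(0, 0, 9, 9, stroke_width=0))
        (sel,) = pk.import_imagej_rois(p)
        assert sel.linewidth == 1


def test_selection_json_roundtrip(tmp_path):
    sels = [
        pk.Selection([(1.5, 2.5), (10, 2.5)], linewidth=5, frame=3, label="a"),
        pk.Selection([(0, 0), (5, 5), (9, 2)], label="b"),
    ]
    path = tmp_path / "sel.json"
    pk.save_selections(sels, path)
    back = pk.load_selections(path)
    assert len(back) == 2
    assert back[0].linewidth == 5 and back[0].frame == 3 and back[0].label == "a"
    np.testing.assert_allclose(back[1].vertex_array(), sels[1].vertex_array())
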