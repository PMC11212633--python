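"""Subpixel fits for bands, block edges and the actin motif."""

import numpy as np
import pytest

import patternkit as pk
from patternkit.errors import ParameterError
from patternkit.features import (
    ChannelSpec,
    PatternSpec,
    canonicalize_pattern,
    choose_grouping,
    edge_position,
    fit_bands,
    fit_block,
    fit_block_with_middle_band,
)

from conftest import gaussian_bumps, midline_selection


def blurred_block(length, left, right, sigma=1.5, offset=0.05, boost=0.0, center=None):
    """Step plateau (optionally with a central band), lightly blurred."""
    from scipy.ndimage import gaussian_filter1d

    os_ = 20
    x = np.arange(length * os_) / os_
    v = np.where((x >= left) & (x <= right), 1.0, 0.0)
    if boost > 0:
        v += boost * np.exp(-0.5 * ((x - center) / 1.5) ** 2)
    v = gaussian_filter1d(v, sigma * os_)
    return v[::os_][:length] + offset  # sample index k sits at x = k


class TestFitBands:
    def test_single_noiseless_band_center(self):
        v = gaussian_bumps(25, [12.30])
        (f,) = fit_bands(v, 1)
        assert f.position_px == pytest.approx(12.30, abs=0.01)
        assert f.fit_params["sigma"] == pytest.approx(2.5, abs=0.05)

    def test_two_bands_recovered_sorted(self):
        v = gaussian_bumps(26, [8.0, 17.0], sigma=1.8)
        a, b = fit_bands(v, 2)
        assert a.position_px == pytest.approx(8.0, abs=0.05)
        assert b.position_px == pytest.approx(17.0, abs=0.05)

    def test_missing_band_returns_none(self):
        v = gaussian_bumps(25, [12.0])
        assert fit_bands(v, 3) is None

    def test_band_center_precision_on_simulator(self):
        # single-band localization error spread at SNR 3 stays subpixel
        errors = []
        for seed in range(100):
            cfg = pk.SimulationConfig(snr=3.0, seed=seed)
            img, truth = pk.simulate_image(cfg)
            prof = pk.extract_profile(img, midline_selection(img, 7))
            res = pk.extract_features(prof, PatternSpec([ChannelSpec("bands", 1)]))
            n_det, matches = pk.score_extraction(res.pattern_centers[0], truth)
            for ti, ei in matches:
                errors.append(
                    np.sort(res.pattern_centers[0])[ei] - truth.band_positions[ti]
                )
        assert np.std(errors) <= 0.25


class TestFitBlock:
    def test_ideal_plateau_edges(self):
        v = blurred_block(25, 6.5, 18.5)
        left, right = fit_block(v)
        assert left.position_px == pytest.approx(6.5, abs=0.05)
        assert right.position_px == pytest.approx(18.5, abs=0.05)

    def test_half_threshold_equals_midpoint_parameter(self):
        v = blurred_block(25, 6.5, 18.5)
        left, right = fit_block(v, edge_threshold=0.5)
        assert left.position_px == pytest.approx(left.fit_params["midpoint"], abs=1e-9)
        assert right.position_px == pytest.approx(right.fit_params["midpoint"], abs=1e-9)

    def test_other_thresholds_from_fit_parameters(self):
        params = dict(low=0.0, high=1.0, midpoint=10.0, slope=1.5)
        # 0.5 -> midpoint; thresholds symmetric around it
        assert edge_position(params, True, 0.5) == pytest.approx(10.0)
        up = edge_position(params, True, 0.9)
        down = edge_position(params, True, 0.1)
        assert up - 10.0 == pytest.approx(10.0 - down)

    def test_symmetric_block_midpoint_matches_center_of_mass(self):
        v = blurred_block(30, 9.0, 21.0)
        left, right = fit_block(v)
        mid = 0.5 * (left.position_px + right.position_px)
        x = np.arange(v.size)
        w = v - v.min()
        com = float(np.sum(x * w) / np.sum(w))
        assert mid == pytest.approx(com, abs=0.1)


class TestActinMotif:
    def test_block_with_central_band(self):
        v = blurred_block(50, 10.0, 40.0, boost=1.0, center=25.0)
        left, mid, right = fit_block_with_middle_band(v)
        assert mid.position_px == pytest.approx(25.0, abs=0.05)
        assert left.position_px == pytest.approx(10.0, abs=0.5)
        assert right.position_px == pytest.approx(40.0, abs=0.5)

    def test_translation_equivariance(self):
        a = fit_block_with_middle_band(blurred_block(50, 10.0, 40.0, boost=1.0, center=25.0))
        b = fit_block_with_middle_band(blurred_block(54, 13.7, 43.7, boost=1.0, center=28.7))
        for fa, fb in zip(a, b):
            assert fb.position_px - fa.position_px == pytest.approx(3.7, abs=0.05)

    def test_flat_window_fails_gracefully(self):
        assert fit_block_with_middle_band(np.full(40, 0.3)) is None


class TestCanonicalize:
    def test_band_pattern_center_is_mean(self):
        feats = fit_bands(gaussian_bumps(30, [10.0, 20.0], sigma=1.8), 2)
        center = canonicalize_pattern(feats, ChannelSpec("bands", 2))
        assert center == pytest.approx(15.0, abs=0.05)

    def test_actin_center_is_middle_band(self):
        v = blurred_block(50, 10.0, 40.0, boost=1.0, center=25.0)
        feats = list(fit_block_with_middle_band(v))
        center = canonicalize_pattern(feats, ChannelSpec("block_with_middle_band"))
        assert center == pytest.approx(25.0, abs=0.05)

    def test_doublet_grouping_matches_enumeration_oracle(self):
        # ladder  A·a····A·a····  with A brighter: each A pairs with the
        # following a; oracle enumerates both phases and picks min spread
        positions = [0.0, 4.0, 14.0, 18.0, 28.0, 32.0]
        intensities = [2.0, 1.0, 2.0, 1.0, 2.0, 1.0]
        groups = choose_grouping(positions, intensities, 2)
        # oracle: contiguous pairings, phase 0 or 1
        best, best_spread = None, np.inf
        for phase in (0, 1):
            idx = list(range(phase, len(positions)))
            pairs = [idx[i : i + 2] for i in range(0, len(idx) - 1, 2)]
            spread = sum(positions[p[1]] - positions[p[0]] for p in pairs)
            if spread < best_spread:
                best, best_spread = pairs, spread
        assert groups == best
        # pairs are the close ones (spread 4), not the far ones (spread 10)
        assert all(positions[b] - positions[a] == pytest.approx(4.0) for a, b in groups)


class TestExtractFeatures:
    def test_noiseless_ladder_lengths(self):
        cfg = pk.SimulationConfig(snr=float("inf"))
        img, truth = pk.simulate_image(cfg)
        prof = pk.extract_profile(img, midline_selection(img, 7))
        res = pk.extract_features(prof, PatternSpec.parse("bands:1"))
        n_det, matches = pk.score_extraction(res.pattern_centers[0], truth)
        assert n_det == 10
        matched = np.sort(res.pattern_centers[0][[e for _, e in matches]])
        np.testing.assert_allclose(np.diff(matched), 25.0, atol=0.02)

    def test_three_channel_sarcomere_shares_segments(self):
        specs = ["bands:1", "blocks:1", "actin"]
        kinds = ["bands", "blocks", "block_with_middle_band"]
        planes, truths = [], []
        for kind in kinds:
            cfg = pk.SimulationConfig(
                pattern_kind=kind, snr=float("inf"), block_width=14, seed=0
            )
            img, truth = pk.simulate_image(cfg)
            planes.append(img.pixel_array[0, 0])
            truths.append(truth)
        multi = pk.ImageData(np.stack(planes)[None])
        prof = pk.extract_profile(multi, midline_selection(multi, 7))
        res = pk.extract_features(prof, PatternSpec.parse(",".join(specs)))
        assert res.driving_channel == 2  # actin channel drives segmentation
        for c, truth in enumerate(truths):
            n_det, _ = pk.score_extraction(res.pattern_centers[c], truth)
            assert n_det >= 9

    def test_affine_intensity_invariance(self):
        cfg = pk.SimulationConfig(snr=8.0, seed=21)
        img, _ = pk.simulate_image(cfg)
        prof = pk.extract_profile(img, midline_selection(img, 7))
        res_a = pk.extract_features(prof, PatternSpec.parse("bands:1"))
        prof.intensities = prof.intensities * 3.0 + 0.7  # affine rescale
        res_b = pk.extract_features(prof, PatternSpec.parse("bands:1"))
        np.testing.assert_allclose(
            res_a.pattern_centers[0], res_b.pattern_centers[0], atol=1e-6
        )

    def test_feature_ordering_within_segments(self):
        cfg = pk.SimulationConfig(
            pattern_kind="block_with_middle_band", snr=float("inf"), block_width=16
        )
        img, _ = pk.simulate_image(cfg)
        prof = pk.extract_profile(img, midline_selection(img, 7))
        res = pk.extract_features(prof, PatternSpec.parse("actin"))
        by_seg = {}
        for f in res.table.rows:
            by_seg.setdefault(f.segment_index, {})[f.feature_kind] = f.position_px
        checked = 0
        for feats in by_seg.values():
            if len(feats) == 3:
                assert feats["block_left_edge"] < feats["middle_band"] < feats["block_right_edge"]
                checked += 1
        assert checked >= 8

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            ChannelSpec("rings", 1)
        with pytest.raises(ParameterError):
            ChannelSpec("bands", 0)
        with pytest.raises(ParameterError):
            ChannelSpec("bands", 1, edge_threshold=1.0)
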