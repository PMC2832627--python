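"""Image quantification: rotation, gridding, clustering, top-hat, profiles."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from seroarray import (
    ArrayImage,
    SimulationConfig,
    SpotMeasurement,
    adjust_spot_area,
    black_top_hat,
    build_profile,
    cluster_spot_pixels,
    correct_rotation,
    crop_edges,
    estimate_rotation,
    generate_layout,
    quantify_image,
    render_image,
    segment_grid,
    simulate_profiles,
)


# ---------------------------------------------------------------------------
# Rotation
# ---------------------------------------------------------------------------


class TestRotation:
    @pytest.mark.parametrize("angle", [0.0, 1.0, -1.5])
    def test_injected_angle_recovered_within_tolerance(self, angle, clean_config):
        cfg = SimulationConfig(
            **{**clean_config.__dict__, "rotation_deg": angle, "noise_sd": 5.0}
        )
        _, truth = simulate_profiles(cfg)
        depths = np.full(cfg.n_antigens, 80.0)
        img = render_image(depths, truth, cfg, seed=4)
        theta = estimate_rotation(img.pixels, max_angle=3.0)
        assert theta is not None
        assert abs(theta - angle) <= 0.2

    def test_constant_image_warns_and_passes_through(self, caplog):
        img = ArrayImage(np.full((50, 50), 128, dtype=np.uint8))
        with caplog.at_level(logging.WARNING, logger="seroarray"):
            out = correct_rotation(img)
        assert np.array_equal(out.pixels, img.pixels)
        assert any("no grid signal" in r.message for r in caplog.records)

    def test_correction_records_angle_in_metadata(self, clean_config):
        cfg = SimulationConfig(**{**clean_config.__dict__, "rotation_deg": 1.0})
        _, truth = simulate_profiles(cfg)
        img = render_image(np.full(cfg.n_antigens, 80.0), truth, cfg, seed=4)
        out = correct_rotation(img, max_angle=3.0)
        assert abs(out.rotation_corrected - 1.0) <= 0.2


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------


class TestCrop:
    def test_uniform_margin_arithmetic(self):
        img = ArrayImage(np.zeros((100, 100), dtype=np.uint8))
        out = crop_edges(img, 10)
        assert out.pixels.shape == (80, 80)
        assert out.crop_margins == (10, 10, 10, 10)

    def test_zero_margin_is_identity(self):
        img = ArrayImage(np.arange(100, dtype=np.uint8).reshape(10, 10))
        out = crop_edges(img, 0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_margin_consuming_the_image_errors(self):
        img = ArrayImage(np.zeros((100, 100), dtype=np.uint8))
        with pytest.raises(ValueError):
            crop_edges(img, 60)


# ---------------------------------------------------------------------------
# Grid segmentation
# ---------------------------------------------------------------------------


class TestSegmentGrid:
    def test_target_area_count(self):
        cfg = SimulationConfig(
            n_antigens=50, n_subgrid_rows=2, n_subgrid_cols=2,
            spots_per_subgrid=25, n_group1=2, n_group2=2,
        )
        layout = generate_layout(cfg)
        img = ArrayImage(np.zeros(layout.image_shape, dtype=np.uint8))
        rects = segment_grid(img, layout)
        assert len(rects) == 100

    def test_true_spot_centers_fall_inside_their_areas(self, clean_sim):
        matrix, truth = clean_sim
        layout = truth.layout
        img = ArrayImage(np.zeros(layout.image_shape, dtype=np.uint8))
        rects = segment_grid(img, layout)
        for s in np.flatnonzero(layout.occupied):
            cy, cx = layout.centers[s]
            y0, x0, y1, x1 = rects[s]
            assert y0 <= cy < y1 and x0 <= cx < x1

    def test_layout_exceeding_image_errors_naming_subgrids(self, clean_sim):
        _, truth = clean_sim
        small = ArrayImage(np.zeros((20, 20), dtype=np.uint8))
        with pytest.raises(ValueError, match="subgrid"):
            segment_grid(small, truth.layout)


# ---------------------------------------------------------------------------
# Foreground clustering (exact 1-D 2-means)
# ---------------------------------------------------------------------------


def brute_force_partition(values):
    """Oracle: exhaustively try every contiguous split of the sorted values
    and return the threshold of the SSE-minimal 2-partition."""
    s = np.sort(np.asarray(values, dtype=float))
    best, best_cut = np.inf, None
    for k in range(1, len(s)):
        if s[k - 1] == s[k]:
            continue
        lo, hi = s[:k], s[k:]
        sse = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        if sse < best - 1e-12:
            best, best_cut = sse, s[k - 1]
    return best, best_cut


class TestClusterSpotPixels:
    def test_bimodal_toy_area(self):
        area = np.array([[10, 10, 10], [200, 200, 10]])
        fg, empty = cluster_spot_pixels(area)
        assert not empty
        assert np.array_equal(fg, area == 10)

    def test_constant_area_flags_empty_foreground(self):
        fg, empty = cluster_spot_pixels(np.full((4, 4), 7))
        assert empty
        assert not fg.any()

    def test_rendered_disc_recovered_exactly(self, clean_sim):
        matrix, truth = clean_sim
        cfg_depth = 100
        depths = np.zeros(truth.layout.n_antigens)
        depths[2] = cfg_depth
        from seroarray import SimulationConfig

        cfg = SimulationConfig(
            n_antigens=30, n_subgrid_rows=2, n_subgrid_cols=2,
            spots_per_subgrid=16, n_group1=5, n_group2=5, noise_sd=0.0,
            rotation_deg=0.0, background_gradient=0.0, seed=101,
        )
        img = render_image(depths, truth, cfg)
        s = truth.layout.antigen_spots[2][0]
        y0, x0, y1, x1 = truth.layout.rects[s]
        area = img.pixels[y0:y1, x0:x1]
        fg, empty = cluster_spot_pixels(area)
        assert not empty
        assert np.array_equal(fg, area == 200 - cfg_depth)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=255), min_size=4, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_optimal_partition(self, values, _seed):
        area = np.array(values)
        fg, empty = cluster_spot_pixels(area)
        if area.min() == area.max():
            assert empty
            return
        sse_opt, cut = brute_force_partition(area)
        lo, hi = area[fg].astype(float), area[~fg].astype(float)
        sse = np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)
        assert sse == pytest.approx(sse_opt, abs=1e-9)

    def test_agrees_with_lloyd_kmeans_on_random_areas(self, rng):
        """Independent route: sklearn's Lloyd iterations with many restarts
        should find the same partition the exact solver returns."""
        from sklearn.cluster import KMeans

        for _ in range(20):
            v = rng.integers(0, 256, size=rng.integers(5, 40))
            if v.min() == v.max():
                continue
            fg, _ = cluster_spot_pixels(v)
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                v.reshape(-1, 1).astype(float)
            )
            dark = int(np.argmin(km.cluster_centers_.ravel()))
            assert np.array_equal(fg, km.labels_ == dark)


# ---------------------------------------------------------------------------
# Area adjustment
# ---------------------------------------------------------------------------


def _disc_image(h, w, cy, cx, r, depth, bg=200):
    img = np.full((h, w), bg, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = bg - depth
    return img.astype(np.uint8)


class TestAdjustSpotArea:
    def test_interior_disc_leaves_area_unchanged(self):
        img = _disc_image(30, 30, 15, 15, 3, 100)
        rect = (10, 10, 21, 21)
        fg, _ = cluster_spot_pixels(img[10:21, 10:21])
        new_rect, new_fg, adjusted, overlap = adjust_spot_area(img, rect, fg)
        assert new_rect == rect
        assert not adjusted and not overlap

    def test_straddling_disc_fully_captured(self):
        # disc overhangs the right border of its target area by 5 px
        img = _disc_image(30, 40, 15, 19, 4, 100)
        rect = (10, 8, 21, 19)  # disc straddles the x=19 border
        fg, _ = cluster_spot_pixels(img[rect[0]:rect[2], rect[1]:rect[3]])
        new_rect, new_fg, adjusted, overlap = adjust_spot_area(img, rect, fg)
        assert adjusted
        y0, x0, y1, x1 = new_rect
        captured = int((img[y0:y1, x0:x1][new_fg] == 100).sum())
        true_disc = int((img == 100).sum())
        assert captured >= 0.99 * true_disc

    def test_growth_toward_neighbor_spot_is_flagged_and_bounded(self):
        # two abutting discs; growth toward the neighbour must stop at its centre
        img = np.full((30, 40), 200, dtype=float)
        yy, xx = np.mgrid[0:30, 0:40]
        img[(yy - 15) ** 2 + (xx - 17) ** 2 <= 16] = 100  # our disc, overflows
        img[(yy - 15) ** 2 + (xx - 22) ** 2 <= 9] = 100  # neighbour disc
        img = img.astype(np.uint8)
        rect = (10, 8, 21, 19)
        fg, _ = cluster_spot_pixels(img[rect[0]:rect[2], rect[1]:rect[3]])
        new_rect, new_fg, adjusted, overlap = adjust_spot_area(
            img, rect, fg, blocked_centers=np.array([[15, 22]])
        )
        assert overlap
        assert new_rect[3] <= 22  # never contains the neighbour centre


# ---------------------------------------------------------------------------
# Black top-hat
# ---------------------------------------------------------------------------


class TestBlackTopHat:
    def test_constant_image_maps_to_zero(self):
        out = black_top_hat(np.full((20, 20), 77, dtype=np.uint8), 5)
        assert np.all(out == 0)

    def test_single_dark_pixel_hand_computed(self):
        # 5x5 raster, one dark pixel: closing restores the background, so
        # the top-hat equals the depth at that pixel and 0 elsewhere
        img = np.full((5, 5), 200, dtype=np.uint8)
        img[2, 2] = 100
        out = black_top_hat(img, 3)
        expected = np.zeros((5, 5))
        expected[2, 2] = 100
        assert np.array_equal(out, expected)

    def test_wide_dark_square_interior_is_preserved_hence_zero(self):
        img = np.full((20, 20), 200, dtype=np.uint8)
        img[5:15, 5:15] = 60  # 10x10 square, wider than the 5x5 element
        out = black_top_hat(img, 5)
        assert np.all(out[8:12, 8:12] == 0)

    def test_nonnegative_and_closing_extensive(self, rng):
        img = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        out = black_top_hat(img, 3)
        assert np.all(out >= 0)
        closing = out + img.astype(float)
        assert np.all(closing >= img)  # closing is extensive

    @pytest.mark.parametrize("side", [2, 4, 1, 0, -3])
    def test_invalid_structuring_element_rejected(self, side):
        with pytest.raises(ValueError):
            black_top_hat(np.zeros((10, 10), dtype=np.uint8), side)


# ---------------------------------------------------------------------------
# Spot intensity and duplicate averaging
# ---------------------------------------------------------------------------


class TestProfileAssembly:
    def test_spot_intensity_is_foreground_mean(self):
        from seroarray import spot_intensity

        processed = np.zeros((10, 10))
        processed[2:5, 2] = [10, 20, 30]
        fg = np.zeros((5, 5), dtype=bool)
        fg[2:5, 2] = True
        assert spot_intensity(processed, (0, 0, 5, 5), fg) == 20.0

    def test_empty_foreground_measures_zero(self):
        from seroarray import spot_intensity

        assert spot_intensity(np.ones((5, 5)), (0, 0, 5, 5),
                              np.zeros((5, 5), dtype=bool)) == 0.0

    @pytest.mark.parametrize(
        "a,b,expected", [(100.0, 110.0, 105), (100.0, 101.0, 101), (0.0, 0.0, 0)]
    )
    def test_duplicate_mean_rounds_half_up(self, a, b, expected, clean_sim):
        _, truth = clean_sim
        layout = truth.layout
        ms = []
        for ai in range(layout.n_antigens):
            for s in layout.antigen_spots[ai]:
                val = a if s == layout.antigen_spots[ai][0] else b
                ms.append(
                    SpotMeasurement(
                        antigen_id=layout.antigen_ids[ai], spot_index=int(s),
                        rect=(0, 0, 1, 1), n_foreground=1,
                        raw_mean=val, processed_mean=val,
                    )
                )
        profile = build_profile(ms, layout)
        assert profile.values[0] == expected

    def test_missing_replicate_uses_the_other_and_flags(self, clean_sim):
        _, truth = clean_sim
        layout = truth.layout
        ms = []
        for ai in range(layout.n_antigens):
            s0, s1 = layout.antigen_spots[ai]
            ms.append(SpotMeasurement(layout.antigen_ids[ai], int(s0),
                                      (0, 0, 1, 1), 1, 80.0, 80.0))
            # antigen 0: second replicate empty; antigen 1: missing entirely
            if ai == 0:
                ms.append(SpotMeasurement(layout.antigen_ids[ai], int(s1),
                                          (0, 0, 1, 1), 0, 0.0, 0.0, empty=True))
            elif ai > 1:
                ms.append(SpotMeasurement(layout.antigen_ids[ai], int(s1),
                                          (0, 0, 1, 1), 1, 80.0, 80.0))
        profile = build_profile(ms, layout)
        assert profile.values[0] == 80 and profile.flags[0]
        assert profile.values[1] == 80 and profile.flags[1]
        assert profile.values[2] == 80 and not profile.flags[2]


# ---------------------------------------------------------------------------
# End-to-end recovery
# ---------------------------------------------------------------------------


class TestEndToEnd:
    def test_noise_free_render_recovered_within_one_unit(self, clean_config, clean_sim):
        matrix, truth = clean_sim
        row = matrix.values.iloc[0].to_numpy()
        img = render_image(row, truth, clean_config, serum_id="s0")
        profile, _ = quantify_image(img, truth.layout, rotate=False)
        # depths above the background level clip to black at render time
        expected = np.minimum(row, int(clean_config.background_level))
        assert np.abs(profile.values - expected).max() <= 1

    def test_noisy_rotated_render_correlates_with_truth(self, noisy_config, noisy_sim):
        matrix, truth = noisy_sim
        row = matrix.values.iloc[3].to_numpy()
        img = render_image(row, truth, noisy_config, serum_id="s3")
        profile, _ = quantify_image(img, truth.layout)
        expected = np.minimum(row, int(noisy_config.background_level))
        r = np.corrcoef(profile.values, expected)[0, 1]
        assert r >= 0.95

    def test_profile_contract_length_and_range(self, clean_config, clean_sim):
        matrix, truth = clean_sim
        row = matrix.values.iloc[1].to_numpy()
        img = render_image(row, truth, clean_config, serum_id="s1")
        profile, measurements = quantify_image(img, truth.layout, rotate=False)
        assert len(profile.values) == clean_config.n_antigens
        assert profile.values.min() >= 0 and profile.values.max() <= 255
        assert len(measurements) == 2 * clean_config.n_antigens

    def test_profile_equivariant_under_antigen_relabeling(self, clean_config, clean_sim):
        from dataclasses import replace

        matrix, truth = clean_sim
        layout = truth.layout
        row = matrix.values.iloc[0].to_numpy()
        img = render_image(row, truth, clean_config, serum_id="s0")
        base, _ = quantify_image(img, layout, rotate=False)

        perm = np.random.default_rng(0).permutation(layout.n_antigens)
        spot_antigen = layout.spot_antigen.copy()
        occ = spot_antigen >= 0
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        spot_antigen[occ] = inv[spot_antigen[occ]]
        permuted = replace(
            layout,
            antigen_ids=[layout.antigen_ids[p] for p in perm],
            antigen_spots=layout.antigen_spots[perm],
            spot_antigen=spot_antigen,
        )
        shuffled, _ = quantify_image(img, permuted, rotate=False)
        assert np.array_equal(shuffled.values, base.values[perm])
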