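"""Radial segregation score: geometry, bands, ratios, batch summaries."""

import math

import numpy as np
import pytest

from mosaiq.imaging import BinaryMask, ColonyImage
from mosaiq.radial import (
    RadialConfig,
    RadialSegregation,
    ScoreConfig,
    colony_geometry,
    combined_segregation_score,
    population_radial_ratio,
    radial_band_masks,
    score_colony,
    summarize_scores,
)
from mosaiq.synthetic import ColonySpec, generate_colony_image


def _disk(radius, size=512, center=None):
    rr, cc = np.ogrid[:size, :size]
    if center is None:
        center = ((size - 1) / 2, (size - 1) / 2)
    return np.hypot(rr - center[0], cc - center[1]) <= radius


class TestColonyGeometry:
    def test_centered_disk(self, disk_mask):
        geom = colony_geometry(disk_mask)
        assert geom.centroid == pytest.approx((255.5, 255.5), abs=0.5)
        assert geom.radius == pytest.approx(200.0, rel=0.01)

    def test_two_disjoint_disks_pool_area(self):
        grid = _disk(50, center=(100, 100)) | _disk(50, center=(380, 380))
        geom = colony_geometry(BinaryMask(grid))
        area = grid.sum()
        assert geom.radius == pytest.approx(math.sqrt(area / math.pi), rel=1e-9)

    def test_single_pixel_mask_valid(self, caplog):
        grid = np.zeros((16, 16), dtype=bool)
        grid[5, 9] = True
        with caplog.at_level("WARNING"):
            geom = colony_geometry(BinaryMask(grid))
        assert geom.radius == pytest.approx(math.sqrt(1 / math.pi))
        assert "degenerate" in caplog.text

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no colony"):
            colony_geometry(BinaryMask(np.zeros((8, 8), dtype=bool)))


class TestRadialBands:
    def test_full_disk_band_areas_match_continuum(self, disk_mask):
        geom = colony_geometry(disk_mask)
        inner, outer = radial_band_masks(geom, disk_mask)
        r = geom.radius
        assert inner.area == pytest.approx(math.pi * (r / 4) ** 2, rel=0.03)
        assert outer.area == pytest.approx((7 / 16) * math.pi * r * r, rel=0.03)
        assert not np.any(inner.grid & outer.grid)

    def test_annular_mask_gives_empty_inner_band(self):
        grid = _disk(200) & ~_disk(120)
        mask = BinaryMask(grid)
        geom = colony_geometry(mask)
        inner, _ = radial_band_masks(geom, mask)
        assert inner.area == 0

    def test_degenerate_band_config_rejected(self):
        with pytest.raises(ValueError):
            RadialConfig(inner_frac=0.5, outer_frac=0.5)


class TestPopulationRatio:
    def test_uniform_population_hits_continuum_values(self, disk_mask):
        rng = np.random.default_rng(0)
        geom = colony_geometry(disk_mask)
        inner, outer = radial_band_masks(geom, disk_mask)
        pop = BinaryMask(disk_mask.grid & (rng.uniform(size=disk_mask.shape) < 0.3))
        assert pop.area >= 10_000
        literal = population_radial_ratio(pop, inner, outer, disk_mask,
                                          "literal_area")
        density = population_radial_ratio(pop, inner, outer, disk_mask,
                                          "density_normalized")
        assert literal == pytest.approx(1 / 7, rel=0.10)
        assert density == pytest.approx(1.0, rel=0.10)

    def test_population_equal_to_colony_scores_exactly_one(self, disk_mask):
        geom = colony_geometry(disk_mask)
        inner, outer = radial_band_masks(geom, disk_mask)
        assert population_radial_ratio(disk_mask, inner, outer, disk_mask,
                                       "density_normalized") == 1.0

    def test_inner_only_population_returns_infinity_sentinel(self, disk_mask):
        geom = colony_geometry(disk_mask)
        inner, outer = radial_band_masks(geom, disk_mask)
        pop = BinaryMask(_disk(20))
        assert population_radial_ratio(pop, inner, outer, disk_mask,
                                       "literal_area") == math.inf

    def test_empty_population_rejected(self, disk_mask):
        geom = colony_geometry(disk_mask)
        inner, outer = radial_band_masks(geom, disk_mask)
        empty = BinaryMask(np.zeros(disk_mask.shape, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            population_radial_ratio(empty, inner, outer, disk_mask,
                                    "literal_area")


class TestCombinedScore:
    @pytest.mark.parametrize("red,green,expected",
                             [(1.0, 1.0, 1.0), (0.5, 2.0, 0.5), (2.0, 0.5, 2.0)])
    def test_arithmetic(self, red, green, expected):
        assert combined_segregation_score(red, green) == pytest.approx(expected)

    @pytest.mark.parametrize("red,green", [(math.inf, 1.0), (1.0, 0.0),
                                           (math.nan, 1.0)])
    def test_degenerate_inputs_become_missing(self, red, green):
        assert math.isnan(combined_segregation_score(red, green))


class TestScoreColony:
    def test_channel_swap_swaps_population_ratios_exactly(self):
        img, _ = generate_colony_image(
            ColonySpec(mode="radial_edge", strength=0.5, n_cells=200, seed=2))
        orig = score_colony(img, ScoreConfig())
        swapped = score_colony(ColonyImage(channels=img.channels[[1, 0, 2]]),
                               ScoreConfig())
        assert swapped.ratio_red == orig.ratio_green
        assert swapped.ratio_green == orig.ratio_red

    def test_upsampling_leaves_density_ratios_nearly_unchanged(self):
        img, _ = generate_colony_image(ColonySpec(n_cells=200, seed=0))
        up = ColonyImage(channels=np.kron(img.channels, np.ones((1, 2, 2))))
        a = score_colony(img, ScoreConfig())
        b = score_colony(up, ScoreConfig())
        assert b.ratio_red == pytest.approx(a.ratio_red, rel=0.02)
        assert b.ratio_green == pytest.approx(a.ratio_green, rel=0.02)

    def test_edge_sorted_scores_below_matched_mixed(self):
        edge, mixed = [], []
        for seed in range(8):
            img_e, _ = generate_colony_image(
                ColonySpec(mode="radial_edge", strength=1.0, n_cells=200,
                           seed=seed))
            img_m, _ = generate_colony_image(
                ColonySpec(mode="mixed", n_cells=200, seed=seed))
            edge.append(score_colony(img_e, ScoreConfig()).combined)
            mixed.append(score_colony(img_m, ScoreConfig()).combined)
        assert np.nanmean(edge) < np.nanmean(mixed)

    def test_results_wrapper_reports_both_variants(self, mixed_colony):
        _, image, _ = mixed_colony
        res = RadialSegregation(image).fit()
        assert set(res.scores) == {"density_normalized", "literal_area"}
        assert res.combined == res.scores["density_normalized"].combined
        assert "Radial segregation" in res.summary()


class TestSummarizeScores:
    def test_identical_groups_give_p_one(self):
        out = summarize_scores({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out.test == "t-test"
        assert out.p_value == pytest.approx(1.0)

    def test_two_group_t_statistic_matches_hand_value(self):
        out = summarize_scores({"lo": [1.0, 2.0, 3.0], "hi": [4.0, 5.0, 6.0]})
        assert abs(out.statistic) == pytest.approx(3.674, abs=1e-3)

    def test_three_groups_use_anova_with_pairwise(self):
        out = summarize_scores({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0],
                                "c": [3.0, 4.0, 5.0]})
        assert out.test == "anova"
        assert out.statistic == pytest.approx(3.0)
        assert len(out.pairwise) == 3

    def test_nonfinite_scores_excluded_and_counted(self):
        out = summarize_scores({"a": [1.0, 2.0, math.nan],
                                "b": [4.0, 5.0, math.inf]})
        assert out.n_excluded == {"a": 1, "b": 1}
        assert list(out.group_stats["n"]) == [2, 2]

    def test_underpopulated_group_dropped(self):
        out = summarize_scores({"a": [1.0, 2.0], "b": [4.0, 5.0],
                                "c": [math.nan, 1.0]})
        assert set(out.group_stats["group"]) == {"a", "b"}
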