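import numpy as np
import pytest
from scipy import ndimage

from spatialfly import AnalysisConfig, RasterMask
from spatialfly.localization_stats import (
    build_tissue_mask,
    distance_summary,
    nearest_nucleus_distances,
    region_specificity,
)
from spatialfly.synthetic_data import exclusive_markers
from .conftest import make_spots


def morphology_oracle(img, config):
    """Independent recipe implementation using scipy's binary morphology
    (different code path from the separable filters in the package)."""
    from spatialfly.localization_stats import _blur_binarize

    out = _blur_binarize(img, config.blur_kernel, config.blur_sigma)
    for k in config.erosion_kernels:
        out = ndimage.binary_erosion(out, structure=np.ones((k, k), bool))
    struct = np.ones((config.dilation_kernel, config.dilation_kernel), bool)
    for _ in range(config.dilation_repeats):
        out = ndimage.binary_dilation(out, structure=struct)
    return _blur_binarize(out, config.final_blur_kernel, config.final_blur_sigma)


class TestBuildTissueMask:
    def test_no_spots_empty_mask(self):
        mask = build_tissue_mask(np.empty((0, 2)))
        assert mask.n_foreground == 0

    def test_single_spot_removed_by_erosions(self):
        # blur(5x5) grows one pixel to a 5x5 block; eroding 5x5 then 4x4
        # leaves nothing
        mask = build_tissue_mask(np.array([[10.0, 10.0]]))
        assert mask.n_foreground == 0

    def test_dense_block_covered_with_margin(self):
        # 50x50 µm block with >= 1 spot per pixel survives and gains a
        # 3 * floor(50/2) px dilation margin on each side
        config = AnalysisConfig()
        s = config.pixel_size
        n = int(50 / s)
        cols, rows = np.meshgrid(np.arange(n), np.arange(n))
        pts = np.column_stack([(cols.ravel() + 0.5) * s + 20.0,
                               (rows.ravel() + 0.5) * s + 20.0])
        mask = build_tissue_mask(pts, config)
        inside = mask.contains(pts[:, 0], pts[:, 1])
        assert inside.all()
        margin_um = 3 * (50 // 2) * s
        # sample points inside the expected dilation margin (minus a couple of
        # pixels for the erosion shrinkage and even-kernel anchor asymmetry)
        probe = margin_um - 6 * s
        edge_pts = np.array(
            [[20.0 - probe, 45.0], [20.0 + 50.0 + probe, 45.0],
             [45.0, 20.0 - probe], [45.0, 20.0 + 50.0 + probe]]
        )
        assert mask.contains(edge_pts[:, 0], edge_pts[:, 1]).all()

    def test_matches_independent_morphology_oracle(self):
        # pixel-exact equality with an independently coded recipe on a random
        # scene (small dilation kernel keeps the oracle fast)
        config = AnalysisConfig(dilation_kernel=8, dilation_repeats=3)
        rng = np.random.default_rng(0)
        pts = rng.uniform(5, 25, size=(400, 2))
        mask = build_tissue_mask(pts, config)
        img = np.zeros(mask.shape, bool)
        col = np.floor((pts[:, 0] - mask.origin_x) / config.pixel_size).astype(int)
        row = np.floor((pts[:, 1] - mask.origin_y) / config.pixel_size).astype(int)
        img[row, col] = True
        np.testing.assert_array_equal(mask.pixels, morphology_oracle(img, config))

    def test_matches_oracle_with_default_kernels(self):
        # same check with the published 5/4/50 kernels on a compact instance
        config = AnalysisConfig()
        rng = np.random.default_rng(1)
        pts = rng.uniform(10, 20, size=(600, 2))
        mask = build_tissue_mask(pts, config)
        img = np.zeros(mask.shape, bool)
        col = np.floor((pts[:, 0] - mask.origin_x) / config.pixel_size).astype(int)
        row = np.floor((pts[:, 1] - mask.origin_y) / config.pixel_size).astype(int)
        img[row, col] = True
        np.testing.assert_array_equal(mask.pixels, morphology_oracle(img, config))


def nucleus_mask_from_pixels(pixels, shape=(100, 100), pixel_size=1.0):
    raster = np.zeros(shape, bool)
    for r, c in pixels:
        raster[r, c] = True
    return RasterMask(raster, pixel_size=pixel_size)


class TestNearestNucleusDistances:
    def test_spot_on_nucleus_pixel_center(self):
        mask = nucleus_mask_from_pixels([(10, 10)])
        spots = make_spots(["g"] * 2, [10.5, 10.5], [10.5, 10.5])
        profiles = nearest_nucleus_distances(spots, mask, min_gene_spots=1)
        assert profiles["g"].distances.tolist() == [0.0, 0.0]

    def test_three_four_five_triangle(self):
        # nucleus pixel center at (0.5, 0.5); spot offset by (3, 4) -> 5 µm
        mask = nucleus_mask_from_pixels([(0, 0)])
        spots = make_spots(["g", "g"], [3.5, 0.5], [4.5, 0.5])
        profiles = nearest_nucleus_distances(spots, mask, min_gene_spots=1)
        assert profiles["g"].distances[0] == pytest.approx(5.0, abs=1e-12)

    def test_brute_force_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        pix = [tuple(p) for p in rng.integers(0, 100, size=(50, 2))]
        mask = nucleus_mask_from_pixels(pix)
        n = 1000
        xs, ys = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
        spots = make_spots(["g"] * n, xs, ys)
        profiles = nearest_nucleus_distances(spots, mask, min_gene_spots=1)
        centers = mask.foreground_centers()
        brute = np.sqrt(
            ((np.column_stack([xs, ys])[:, None] - centers[None]) ** 2).sum(-1)
        ).min(1)
        np.testing.assert_allclose(profiles["g"].distances, brute, atol=1e-9)

    def test_invariant_to_pixel_enumeration_order(self):
        rng = np.random.default_rng(3)
        pix = [tuple(p) for p in rng.integers(0, 50, size=(20, 2))]
        spots = make_spots(["g"] * 100, rng.uniform(0, 50, 100), rng.uniform(0, 50, 100))
        d1 = nearest_nucleus_distances(spots, nucleus_mask_from_pixels(pix),
                                       min_gene_spots=1)["g"].distances
        d2 = nearest_nucleus_distances(spots, nucleus_mask_from_pixels(pix[::-1]),
                                       min_gene_spots=1)["g"].distances
        np.testing.assert_array_equal(d1, d2)

    def test_min_gene_spots_filter(self):
        mask = nucleus_mask_from_pixels([(0, 0)])
        spots = make_spots(["g"] * 5, np.arange(5.0), np.arange(5.0))
        assert nearest_nucleus_distances(spots, mask, min_gene_spots=100) == {}
        assert "g" in nearest_nucleus_distances(spots, mask, min_gene_spots=5)

    def test_tissue_mask_prefilter(self):
        nuc = nucleus_mask_from_pixels([(0, 0)])
        tissue = RasterMask(np.zeros((100, 100), bool), pixel_size=1.0)
        tissue.pixels[:, :10] = True  # x < 10 only
        spots = make_spots(["g"] * 4, [5.0, 5.0, 50.0, 50.0], [5.0, 6.0, 5.0, 6.0])
        profiles = nearest_nucleus_distances(spots, nuc, tissue, min_gene_spots=1)
        assert profiles["g"].n_spots == 2

    def test_empty_nucleus_mask_is_error(self):
        mask = RasterMask(np.zeros((10, 10), bool), pixel_size=1.0)
        spots = make_spots(["g"], [1.0], [1.0])
        with pytest.raises(ValueError, match="no foreground"):
            nearest_nucleus_distances(spots, mask, min_gene_spots=1)

    def test_spot_inside_nucleus_small_distance(self):
        mask = nucleus_mask_from_pixels([(5, 5)], pixel_size=0.138)
        x = 5 * 0.138 + 0.01  # inside the pixel, off its center
        spots = make_spots(["g"], [x], [x])
        d = nearest_nucleus_distances(spots, mask, min_gene_spots=1)["g"].distances[0]
        assert d <= 0.138 * np.sqrt(2) / 2


class TestDistanceSummary:
    def test_median_of_three(self):
        median, _ = distance_summary(np.array([1.0, 2.0, 3.0]))
        assert median == 2.0

    def test_degenerate_constant_sample(self):
        median, peak = distance_summary(np.full(10, 4.2))
        assert median == 4.2 and peak == 4.2

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            distance_summary(np.array([1.0]))

    def test_rayleigh_mode_recovery(self):
        rng = np.random.default_rng(4)
        sigma = 2.0
        draws = sigma * np.sqrt(-2 * np.log(rng.uniform(size=10_000)))
        _, peak = distance_summary(draws)
        assert peak == pytest.approx(sigma, rel=0.05)  # Rayleigh mode == sigma

    def test_profile_median_is_empirical_percentile(self):
        rng = np.random.default_rng(5)
        mask = nucleus_mask_from_pixels([(10, 10), (40, 70)])
        spots = make_spots(["g"] * 200, rng.uniform(0, 100, 200), rng.uniform(0, 100, 200))
        prof = nearest_nucleus_distances(spots, mask, min_gene_spots=1)["g"]
        assert prof.median == np.percentile(prof.distances, 50)


class TestRegionSpecificity:
    def _mask(self):
        raster = np.zeros((100, 100), bool)
        raster[:, :50] = True  # x < 50 µm at 1 µm/px
        return RasterMask(raster, pixel_size=1.0)

    def test_all_inside(self):
        spots = make_spots(["g"] * 3, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        report = region_specificity(spots, self._mask())
        pooled = report[(report["gene"] == "g") & (report["sample"] == "pooled")]
        assert pooled["fraction"].iloc[0] == 1.0

    def test_one_of_four_inside(self):
        spots = make_spots(["g"] * 4, [10.0, 60.0, 70.0, 80.0], [5.0] * 4)
        report = region_specificity(spots, self._mask())
        pooled = report[report["sample"] == "pooled"]
        assert pooled["fraction"].iloc[0] == 0.25
        assert pooled["inside"].iloc[0] == 1 and pooled["total"].iloc[0] == 4

    def test_zero_spot_gene_undefined(self):
        from spatialfly import GenePanel, SpotTable
        import pandas as pd

        table = SpotTable(
            pd.DataFrame({"gene": ["g1"], "x": [1.0], "y": [1.0], "sample": ["s"]}),
            GenePanel(("g1", "g2")),
        )
        report = region_specificity(table, self._mask())
        g2 = report[(report["gene"] == "g2") & (report["sample"] == "pooled")]
        assert np.isnan(g2["fraction"].iloc[0])

    def test_upsampled_mask_invariance(self):
        rng = np.random.default_rng(6)
        spots = make_spots(["g"] * 500, rng.uniform(0, 100, 500), rng.uniform(0, 100, 500))
        coarse = self._mask()
        fine = RasterMask(np.kron(coarse.pixels, np.ones((4, 4), bool)), pixel_size=0.25)
        fa = region_specificity(spots, coarse)
        fb = region_specificity(spots, fine)
        a = fa[fa["sample"] == "pooled"]["fraction"].iloc[0]
        b = fb[fb["sample"] == "pooled"]["fraction"].iloc[0]
        assert a == b  # same geometry, boundary falls between sample points

    def test_synthetic_exclusive_gene_specificity(self, body_scene):
        gene = exclusive_markers(body_scene)["muscle"][0]
        report = region_specificity(
            body_scene.spots, body_scene.region_masks["muscle"], "muscle",
            genes=[gene],
        )
        pooled = report[report["sample"] == "pooled"]
        assert pooled["fraction"].iloc[0] >= 0.99


class TestBodySceneOrdering:
    def test_enriched_median_below_depleted(self, body_scene):
        profiles = nearest_nucleus_distances(
            body_scene.spots, body_scene.nucleus_mask, min_gene_spots=100,
            genes=["mus-nucin", "mus-nucout"],
        )
        assert profiles["mus-nucin"].median < profiles["mus-nucout"].median
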