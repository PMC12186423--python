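"""Core detection stack: components, radial threshold, chamfer, watershed."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from seedscreen import segmentation as seg
from seedscreen import synthetic as syn
from seedscreen.errors import NoMarkersError, NoRegionsError, ParameterError
from seedscreen.imaging import invert

from conftest import build_grid_scene


def _flood_fill_labels(mask):
    """Independent 8-connectivity labelling by explicit stack-based flood fill."""
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, int)
    nxt = 0
    H, W = mask.shape
    for si in range(H):
        for sj in range(W):
            if not mask[si, sj] or out[si, sj]:
                continue
            nxt += 1
            stack = [(si, sj)]
            out[si, sj] = nxt
            while stack:
                i, j = stack.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < H and 0 <= nj < W and mask[ni, nj] and not out[ni, nj]:
                            out[ni, nj] = nxt
                            stack.append((ni, nj))
    return out


def _canonical(labels):
    """Relabel by first occurrence so labelings compare up to renumbering."""
    out = np.zeros_like(labels)
    mapping = {}
    for v in labels.ravel():
        if v and v not in mapping:
            mapping[v] = len(mapping) + 1
    for old, new in mapping.items():
        out[labels == old] = new
    return out


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:7] = True
        mask[10:15, 10:15] = True
        labels, regions = seg.label_components(mask)
        assert len(regions) == 2
        assert sorted(r.area_px for r in regions) == [25, 25]
        assert regions[0].centroid == (4.0, 4.0)

    def test_diagonal_touch_is_one_region(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        mask[5:8, 5:8] = True  # touches only at the (4,4)-(5,5) diagonal
        _, regions = seg.label_components(mask)
        assert len(regions) == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            mask = rng.random((24, 24)) < 0.35
            labels, regions = seg.label_components(mask)
            oracle = _flood_fill_labels(mask)
            assert np.array_equal(_canonical(labels), _canonical(oracle))
            assert len(regions) == oracle.max()


class TestRadialThreshold:
    def _regions_with_median_radius(self, r_med):
        area = int(round(np.pi * r_med**2))
        return [seg.SeedRegion(i + 1, area, (0.0, 0.0)) for i in range(3)]

    @pytest.mark.parametrize("ratio,expected", [(0.45, 9.0), (0.50, 10.0)])
    def test_ratio_threshold_pairings(self, ratio, expected):
        # a median seed of equivalent radius 20 px makes both benchmark
        # (ratio, threshold) pairs come out of the same linear rule
        regions = self._regions_with_median_radius(20.0)
        assert seg.derive_radial_threshold(regions, ratio) == pytest.approx(
            expected, abs=0.01
        )

    def test_vanishes_with_ratio(self):
        regions = self._regions_with_median_radius(20.0)
        assert seg.derive_radial_threshold(regions, 1e-6) < 1e-4

    def test_empty_regions_guides_user(self):
        with pytest.raises(NoRegionsError, match="intensity threshold"):
            seg.derive_radial_threshold([], 0.4)

    def test_filter_noise_by_equivalent_radius(self):
        regions = [seg.SeedRegion(i + 1, a, (0.0, 0.0)) for i, a in enumerate([400, 50, 3])]
        kept = seg.filter_noise(regions, 9.0)
        assert [r.area_px for r in kept] == [400]
        assert seg.filter_noise(regions, 0.0) == regions
        for r in seg.filter_noise(regions, 3.5):
            assert np.sqrt(r.area_px / np.pi) >= 3.5


class TestMorphologicalClean:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not seg.morphological_clean(mask).any()

    def test_disk_nearly_preserved(self):
        yy, xx = np.mgrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        opened = seg.morphological_clean(disk)
        assert disk.sum() * 0.95 < opened.sum() <= disk.sum()

    def test_idempotent(self, rng):
        mask = rng.random((40, 40)) < 0.4
        once = seg.morphological_clean(mask)
        assert np.array_equal(seg.morphological_clean(once), once)


class TestChamferDistance:
    def test_background_zero_and_thin_line(self):
        mask = np.zeros((11, 11), bool)
        mask[5, 1:10] = True
        d = seg.chamfer_distance(mask)
        assert np.all(d[~mask] == 0)
        assert np.all(d[mask] == 1.0)

    def test_all_foreground_rejected(self):
        with pytest.raises(ParameterError):
            seg.chamfer_distance(np.ones((4, 4), bool))

    def test_within_8pct_of_euclidean(self, rng):
        for _ in range(10):
            mask = rng.random((48, 48)) < 0.6
            mask[0, 0] = False  # keep some background
            d = seg.chamfer_distance(mask)
            bg = np.argwhere(~mask)
            tree = cKDTree(bg)
            fg = np.argwhere(mask)
            exact, _ = tree.query(fg)
            got = d[mask]
            rel = np.abs(got - exact) / np.maximum(exact, 1e-9)
            assert rel.max() <= 0.08

    def test_boundary_pixels_near_one(self, rng):
        # foreground pixels 8-adjacent to background sit at <= sqrt(2)+tol
        mask = rng.random((32, 32)) < 0.5
        mask[0, 0] = False
        d = seg.chamfer_distance(mask)
        from scipy.ndimage import binary_dilation

        edge = mask & binary_dilation(~mask, np.ones((3, 3), bool))
        assert d[edge].max() <= np.sqrt(2) + 0.01


def _disk(center, r, shape):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


class TestMakeMarkers:
    def test_disk_core_is_concentric_level_set(self):
        mask = _disk((40, 40), 20, (80, 80))
        markers = seg.make_markers(mask, 9.0)
        assert markers.max() == 1
        core = markers == 1
        # level set of a radius-20 disk at distance 9 is a radius ~11 disk
        assert core.sum() == pytest.approx(np.pi * 11**2, rel=0.15)
        yy, xx = np.nonzero(core)
        assert (yy.mean(), xx.mean()) == pytest.approx((40, 40), abs=0.5)

    def test_zero_threshold_returns_components(self, rng):
        mask = rng.random((30, 30)) < 0.3
        mask[0, :] = False
        markers = seg.make_markers(mask, 0.0)
        labels, regions = seg.label_components(mask)
        assert markers.max() == len(regions)
        assert np.array_equal(markers > 0, mask)

    def test_touching_disks_give_two_markers(self):
        r = 20
        mask = _disk((40, 40), r, (80, 120)) | _disk((40, 40 + 1.8 * r), r, (80, 120))
        markers = seg.make_markers(mask, 0.45 * r)
        assert markers.max() == 2

    def test_excessive_threshold_raises(self):
        mask = _disk((20, 20), 8, (40, 40))
        with pytest.raises(NoMarkersError, match="radial threshold"):
            seg.make_markers(mask, 30.0)


class TestWatershedSplit:
    def test_single_marker_floods_whole_blob(self):
        mask = _disk((20, 20), 10, (40, 40))
        dist = seg.chamfer_distance(mask)
        markers = np.zeros(mask.shape, np.int32)
        markers[20, 20] = 1
        out = seg.watershed_split(-dist, mask, markers)
        assert np.array_equal(out > 0, mask)
        assert np.unique(out[out > 0]).tolist() == [1]

    def test_two_lobed_mask_partitions(self):
        r = 20
        c1, c2 = (40, 40), (40, 70)  # centres 1.5 radii apart
        mask = _disk(c1, r, (80, 110)) | _disk(c2, r, (80, 110))
        dist = seg.chamfer_distance(mask)
        markers = np.zeros(mask.shape, np.int32)
        markers[c1], markers[c2] = 1, 2
        out = seg.watershed_split(-dist, mask, markers)
        assert np.array_equal(out > 0, mask)  # exact partition of foreground
        assert out[c1] == 1 and out[c2] == 2
        assert np.unique(out[out > 0]).size == 2

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_n_markers_give_n_labels(self, n):
        shape = (40, 40 * n)
        mask = np.zeros(shape, bool)
        markers = np.zeros(shape, np.int32)
        for i in range(n):
            c = (20, 20 + 40 * i)
            mask |= _disk(c, 12, shape)
            markers[c] = i + 1
        out = seg.watershed_split(-seg.chamfer_distance(mask), mask, markers)
        assert np.unique(out[out > 0]).size == n

    def test_errors(self):
        mask = _disk((10, 10), 5, (20, 20))
        with pytest.raises(NoMarkersError):
            seg.watershed_split(-seg.chamfer_distance(mask), mask,
                                np.zeros(mask.shape, np.int32))
        bad = np.zeros(mask.shape, np.int32)
        bad[0, 0] = 1  # outside the mask
        with pytest.raises(ParameterError):
            seg.watershed_split(-seg.chamfer_distance(mask), mask, bad)


class TestExtractContours:
    def test_square_contour_encloses_its_area(self):
        labels = np.zeros((10, 10), np.int32)
        labels[3:6, 3:6] = 1
        (poly,) = seg.extract_contours(labels)
        assert np.array_equal(poly[0], poly[-1])  # closed
        shp = Polygon([(c, r) for r, c in poly])
        assert shp.area == pytest.approx(9.0, rel=0.35)
        for r, c in np.argwhere(labels == 1):
            assert shp.contains(Point(c, r))

    def test_one_polygon_per_label_and_pixel_membership(self, rng):
        for _ in range(20):
            mask = rng.random((24, 24)) < 0.3
            labels, regions = seg.label_components(seg.morphological_clean(mask))
            polys = seg.extract_contours(labels)
            assert len(polys) == len(regions)
            ids = np.unique(labels[labels > 0])
            for k, poly in zip(ids, polys):
                shp = Polygon([(c, r) for r, c in poly])
                inside = np.zeros(labels.shape, bool)
                for r, c in np.ndindex(labels.shape):
                    inside[r, c] = shp.intersects(Point(c, r))
                member = labels == k
                assert np.all(inside[member])  # every own pixel enclosed
                assert not np.any(inside & (labels > 0) & ~member)  # no foreign pixels


class TestSegmentSeeds:
    def test_recovers_nonoverlapping_scene(self):
        scene = syn.generate_scene(50, overlap_fraction=0.0, rng_seed=101)
        bf, _ = syn.render_fluorescence_pair(scene)
        _, regions = seg.segment_seeds(invert(bf))
        assert len(regions) == 50

    def test_blank_image_gives_zero_seeds(self):
        labels, regions = seg.segment_seeds(np.zeros((64, 64), np.uint8))
        assert regions == [] and labels.max() == 0

    def test_touching_pairs_resolved_at_default_ratio(self):
        # 28 singles plus 6 touching/slightly overlapping pairs -> 40 seeds.
        # A ratio-t level set splits a pair when the interpenetration depth
        # is below t^2/rho, so contacts at >= 97% of the contact distance
        # (seeds leaning on each other in a monolayer) must all resolve.
        scene = build_grid_scene(28, pair_contacts=(1.0, 0.995, 0.99, 0.985, 0.98, 0.97))
        bf, _ = syn.render_fluorescence_pair(scene, noise_sd=2.0)
        _, regions = seg.segment_seeds(invert(bf))
        assert len(regions) == 40

    def test_count_invariant_under_translation(self):
        # same layout shifted by an integer offset counts identically
        for k in range(6):
            scene = syn.generate_scene(12, overlap_fraction=0.0, rng_seed=300 + k,
                                       canvas=(360, 420))
            H, W = scene.canvas
            shifted = syn.SyntheticScene(
                tuple(
                    syn.SyntheticSeed((s.center[0] + 15, s.center[1] + 11),
                                      s.semi_major, s.semi_minor, s.orientation,
                                      s.seed_class, s.brightness)
                    for s in scene.seeds
                ),
                (H + 30, W + 30), scene.overlap_pairs, scene.rng_seed,
            )
            for sc in (scene, shifted):
                bf, _ = syn.render_fluorescence_pair(sc, noise_sd=0.0)
                _, regions = seg.segment_seeds(invert(bf))
                assert len(regions) == 12

    def test_params_validation(self):
        with pytest.raises(ParameterError):
            seg.SegmentationParams(radial_threshold=5.0, radial_threshold_ratio=0.4)
        with pytest.raises(ParameterError):
            seg.SegmentationParams(radial_threshold_ratio=1.5)
        assert seg.SegmentationParams().resolved_ratio == 0.4
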