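"""Bisecting k-means, ROI assembly and polygon masks."""

import itertools

import numpy as np
import pytest

from lipidmsi.phantom import generate_section, region_masks
from lipidmsi.segmentation import (
    ROIMask,
    accumulate_layers,
    bisecting_kmeans,
    border_labels,
    manual_polygon_roi,
    outer_cortex_selection,
    rank_segments_by_marker,
    roi_mean_abundance,
    segments_to_roi,
)


def _partition(labels):
    """Label-free view of a clustering: frozenset of index frozensets."""
    return frozenset(
        frozenset(np.flatnonzero(labels == lab)) for lab in np.unique(labels)
    )


def _exhaustive_two_partition_cost(X):
    """Minimum total within-cluster L1 cost over all 2-partitions."""
    n = len(X)
    best = np.inf
    best_part = None
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        for side in (mask, ~mask):
            pts = X[side]
            cost += np.abs(pts - np.median(pts, axis=0)).sum()
        if cost < best:
            best = cost
            best_part = mask
    return best, best_part


class TestBisectingKmeans:
    def test_separated_1d_clusters(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        seg = bisecting_kmeans(X, 2, seed=0)
        assert _partition(seg.labels) == _partition(np.array([0, 0, 0, 1, 1]))

    def test_single_segment_no_split(self, rng):
        X = rng.normal(size=(10, 3))
        seg = bisecting_kmeans(X, 1, seed=0)
        assert seg.n_segments == 1 and not seg.splits

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_two_partition(self, seed):
        r = np.random.default_rng(seed)
        centers = np.array([[0.0, 0.0], [4.0, 3.0]])
        X = np.concatenate([c + r.normal(scale=0.8, size=(3, 2)) for c in centers])
        seg = bisecting_kmeans(X, 2, seed=0)
        got_cost = sum(
            np.abs(X[seg.labels == lab] - np.median(X[seg.labels == lab], axis=0)).sum()
            for lab in range(2)
        )
        best_cost, _ = _exhaustive_two_partition_cost(X)
        assert got_cost == pytest.approx(best_cost)

    def test_total_cost_nonincreasing_in_segments(self, rng):
        X = rng.normal(size=(60, 4))
        costs = []
        for n in (1, 2, 3, 5, 8):
            seg = bisecting_kmeans(X, n, seed=7)
            costs.append(
                sum(
                    np.abs(X[seg.labels == lab] - np.median(X[seg.labels == lab], axis=0)).sum()
                    for lab in range(seg.n_segments)
                )
            )
        assert np.all(np.diff(costs) <= 1e-9)

    def test_each_split_never_increases_cost(self, rng):
        X = rng.normal(size=(80, 5))
        seg = bisecting_kmeans(X, 6, seed=3)
        for s in seg.splits:
            assert s["cost_after"] <= s["cost_before"] + 1e-9

    def test_permutation_invariant_partition(self, rng):
        X = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        a = bisecting_kmeans(X, 4, seed=5)
        b = bisecting_kmeans(X[perm], 4, seed=5)
        mapped = np.empty(40, dtype=int)
        mapped[perm] = b.labels
        assert _partition(a.labels) == _partition(mapped)

    def test_determinism(self, rng):
        X = rng.normal(size=(50, 3))
        a = bisecting_kmeans(X, 5, seed=9)
        b = bisecting_kmeans(X, 5, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_many_segments_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            bisecting_kmeans(rng.normal(size=(4, 2)), 5)

    def test_identical_points_stop_early(self):
        X = np.zeros((10, 2))
        X[5:] = 1.0
        seg = bisecting_kmeans(X, 5, seed=0)
        assert seg.n_segments == 2  # only two distinct molecular profiles


class TestSegmentsToRoi:
    def _toy_seg(self):
        # 4x4 grid, two vertical segments
        labels = np.array([0, 0, 1, 1] * 4)
        gi = np.array([(r, c) for r in range(4) for c in range(4)])
        from lipidmsi.segmentation import SegmentationResult

        return (
            SegmentationResult(labels, 2, np.bincount(labels)),
            gi,
            (4, 4),
        )

    def test_select_all_labels_full_mask(self):
        seg, gi, shape = self._toy_seg()
        roi = segments_to_roi(seg, gi, shape, "all", labels=[0, 1])
        assert roi.count == 16

    def test_single_label_count_preserved(self):
        seg, gi, shape = self._toy_seg()
        roi = segments_to_roi(seg, gi, shape, "left", labels=[0])
        assert roi.count == 8

    def test_empty_selection_fails(self):
        seg, gi, shape = self._toy_seg()
        with pytest.raises(ValueError, match="provide either"):
            segments_to_roi(seg, gi, shape, "none")

    def test_marker_rule_recovers_phantom_white_matter(self, clean_config):
        ds, truth = generate_section(clean_config, "sham", seed=0)
        from lipidmsi.preprocess import FeatureList, extract_feature_table, normalize_dataset

        marker_mz = clean_config.marker_mz("WM")
        feats = FeatureList(
            np.sort([p.mz for p in clean_config.panel]),
            np.full(len(clean_config.panel), 3.0),
        )
        norm = normalize_dataset(ds)
        tab = extract_feature_table(norm, feats)
        j = int(np.argmin(np.abs(feats.mz - marker_mz)))
        seg = bisecting_kmeans(tab, 8, seed=0)
        gi = ds.pixel_grid_index()
        border = border_labels(seg, gi, ds.shape)
        roi = segments_to_roi(
            seg, gi, ds.shape, "WM", marker_values=tab[:, j], exclude=border
        )
        true_wm = truth.masks["WM"].mask
        recall = (roi.mask & true_wm).sum() / true_wm.sum()
        assert recall >= 0.95

    def test_zero_noise_phantom_regions_recovered_exactly(self, clean_config):
        # with no noise each region is one molecular profile: segmentation
        # then marker selection must reproduce every truth mask exactly
        ds, truth = generate_section(clean_config, "sham", seed=0)
        from lipidmsi.preprocess import FeatureList, extract_feature_table, normalize_dataset

        feats = FeatureList(
            np.sort([p.mz for p in clean_config.panel]),
            np.full(len(clean_config.panel), 3.0),
        )
        tab = extract_feature_table(normalize_dataset(ds), feats)
        seg = bisecting_kmeans(tab, 8, seed=0)
        gi = ds.pixel_grid_index()
        border = border_labels(seg, gi, ds.shape)
        for region in ("GM", "WM", "HC", "OC", "CC"):
            j = int(np.argmin(np.abs(feats.mz - clean_config.marker_mz(region))))
            roi = segments_to_roi(
                seg, gi, ds.shape, region, marker_values=tab[:, j], exclude=border
            )
            np.testing.assert_array_equal(roi.mask, truth.masks[region].mask)


class TestOuterCortexRule:
    @pytest.mark.parametrize(
        "counts, expected_layers",
        [
            ([3000], 1),  # already in range
            ([3000, 500], 1),
            ([1200, 1600], 2),  # 2800 lands in range
            ([2400, 2400], 1),  # 2400 beats 4800
            ([1000, 1000, 1000], 3),
            ([600, 700, 2900], 3),  # 1300 (dist 1200) vs 4200 (dist 700) -> add
        ],
    )
    def test_layer_accumulation(self, counts, expected_layers):
        assert accumulate_layers(counts, (2500, 3500)) == expected_layers

    def test_rings_selected_outermost_first(self):
        # concentric square rings: ring index = distance to border
        from lipidmsi.segmentation import SegmentationResult

        shape = (20, 20)
        gi = np.array([(r, c) for r in range(20) for c in range(20)])
        ring = np.minimum.reduce(
            [gi[:, 0], gi[:, 1], 19 - gi[:, 0], 19 - gi[:, 1]]
        )
        labels = np.minimum(ring, 3)  # 4 nested layers
        seg = SegmentationResult(labels, 4, np.bincount(labels))
        tissue = np.ones(shape, dtype=bool)
        roi = outer_cortex_selection(
            seg, gi, shape, tissue, target_range=(140, 220)
        )
        # outermost ring has 76 px, next 68: rule stops at 144 in range
        assert roi.count == 76 + 68
        assert roi.mask[0, 0] and not roi.mask[10, 10]

    def test_undersized_region_returns_all_with_warning(self):
        from lipidmsi.segmentation import SegmentationResult

        shape = (4, 4)
        gi = np.array([(r, c) for r in range(4) for c in range(4)])
        labels = np.zeros(16, dtype=int)
        seg = SegmentationResult(labels, 1, np.bincount(labels))
        with pytest.warns(UserWarning, match="below target"):
            roi = outer_cortex_selection(seg, gi, shape, np.ones(shape, bool), (100, 200))
        assert roi.count == 16


class TestPolygonRoi:
    def test_rectangle_covers_block(self):
        roi = manual_polygon_roi(
            [(0.5, 0.5), (10.5, 0.5), (10.5, 10.5), (0.5, 10.5)], (20, 20)
        )
        assert roi.count == 100

    def test_two_vertices_rejected(self):
        with pytest.raises(ValueError):
            manual_polygon_roi([(0, 0), (5, 5)], (10, 10))

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            manual_polygon_roi([(0, 0), (4, 4), (4, 0), (0, 4)], (10, 10))

    def test_triangle_matches_ray_casting_oracle(self):
        verts = [(1.2, 1.1), (8.7, 2.3), (4.4, 9.6)]
        roi = manual_polygon_roi(verts, (12, 12))

        def inside(px, py):
            crossings = 0
            n = len(verts)
            for i in range(n):
                (x1, y1), (x2, y2) = verts[i], verts[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xc = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if xc > px:
                        crossings += 1
            return crossings % 2 == 1

        expected = np.array(
            [[inside(x, y) for x in range(1, 13)] for y in range(1, 13)]
        )
        np.testing.assert_array_equal(roi.mask, expected)


class TestRoiMean:
    def test_single_pixel_mask_returns_row(self):
        table = np.array([[1.0, 2.0], [3.0, 4.0]])
        gi = np.array([[0, 0], [0, 1]])
        mask = ROIMask("m", np.array([[False, True]]))
        np.testing.assert_allclose(roi_mean_abundance(table, mask, gi), [3.0, 4.0])

    def test_hand_mean(self):
        table = np.array([[1.0], [2.0], [6.0]])
        gi = np.array([[0, 0], [0, 1], [0, 2]])
        mask = ROIMask("m", np.ones((1, 3), bool))
        assert roi_mean_abundance(table, mask, gi)[0] == pytest.approx(3.0)

    def test_constant_feature_preserved(self):
        table = np.full((5, 2), 4.2)
        gi = np.array([[0, i] for i in range(5)])
        mask = ROIMask("m", np.ones((1, 5), bool))
        np.testing.assert_allclose(roi_mean_abundance(table, mask, gi), 4.2)

    def test_mask_png_and_coords_round_trip(self, tmp_path, rng):
        mask = ROIMask("m", rng.random((6, 9)) > 0.5)
        back = ROIMask.read_png(mask.write_png(tmp_path / "m.png"))
        np.testing.assert_array_equal(back.mask, mask.mask)
        rebuilt = ROIMask.from_coords(mask.to_coords(), mask.mask.shape, "m")
        np.testing.assert_array_equal(rebuilt.mask, mask.mask)

    def test_empty_mask_rejected(self):
        table = np.ones((2, 2))
        gi = np.array([[0, 0], [0, 1]])
        mask = ROIMask("m", np.zeros((1, 2), bool))
        with pytest.raises(ValueError, match="no pixels"):
            roi_mean_abundance(table, mask, gi)
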