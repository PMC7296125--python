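"""Region-merging segmentation: partition, cost threshold, determinism, ESP."""

import numpy as np
import pytest
from scipy import ndimage

from mossquad.segmentation import (EspCurve, SegmentationParams, detect_scale_peaks,
                                   esp_curve, multiresolution_segment)


def brute_force_stats(labels: np.ndarray, features: np.ndarray):
    """Recompute per-object area, perimeter, band means/stds and adjacency
    by a direct pixel pass (independent of the merge bookkeeping)."""
    h, w = labels.shape
    ids = np.unique(labels)
    stats = {}
    for oid in ids:
        sel = labels == oid
        vals = features[sel]
        # perimeter: pixel edges facing a different label or the image border
        perim = 0
        for r, c in zip(*np.nonzero(sel)):
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < h and 0 <= cc < w) or labels[rr, cc] != oid:
                    perim += 1
        stats[int(oid)] = dict(area=int(sel.sum()), perimeter=perim,
                               mean=vals.mean(axis=0), std=vals.std(axis=0))
    adj: dict[int, dict[int, int]] = {int(i): {} for i in ids}
    for r in range(h):
        for c in range(w):
            a = labels[r, c]
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr < h and cc < w and labels[rr, cc] != a:
                    b = labels[rr, cc]
                    adj[int(a)][int(b)] = adj[int(a)].get(int(b), 0) + 1
                    adj[int(b)][int(a)] = adj[int(b)].get(int(a), 0) + 1
    return stats, adj


class TestMultiresolutionSegment:
    def test_uniform_image_single_object(self):
        img = np.full((12, 12, 3), 77.0)
        seg = multiresolution_segment(img, SegmentationParams(scale=5))
        assert seg.n_objects == 1
        assert (seg.labels == 1).all()

    def test_two_homogeneous_halves_stay_separate(self):
        # halves differ by 100 in every band; the cheapest cross-boundary
        # merge (two single pixels) already costs 3 bands * n_m * sigma_m
        # = 3 * 2 * 50 = 300 > scale^2 = 25, and the cost only grows as the
        # halves coalesce, while within-half merges are free (color cost 0,
        # shape weight 0).
        img = np.empty((8, 8, 3))
        img[:, :4] = 50.0
        img[:, 4:] = 150.0
        seg = multiresolution_segment(img, SegmentationParams(5.0, 0.0, 0.5))
        assert seg.n_objects == 2
        assert len(np.unique(seg.labels[:, :4])) == 1
        assert len(np.unique(seg.labels[:, 4:])) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_object_count_nonincreasing_with_scale(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 60, (16, 16, 3)).astype(float)
        counts = [
            multiresolution_segment(img, SegmentationParams(s, 0.1, 0.5)).n_objects
            for s in (2.0, 5.0, 10.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_partition_and_stats_match_brute_force(self, rng):
        img = rng.integers(0, 40, (24, 24, 3)).astype(float)
        seg = multiresolution_segment(img, SegmentationParams(8.0, 0.2, 0.5))
        labels = seg.labels
        # partition: contiguous ids from 1, every pixel labeled
        assert labels.min() == 1 and labels.max() == seg.n_objects
        assert set(np.unique(labels)) == set(range(1, seg.n_objects + 1))
        # 4-connectivity of every object
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for oid in range(1, seg.n_objects + 1):
            _, n_comp = ndimage.label(labels == oid, structure=structure)
            assert n_comp == 1
        # stats and adjacency equal an independent pixel pass
        stats, adj = brute_force_stats(labels, img)
        for oid, st in stats.items():
            row = seg.object_stats.loc[oid]
            assert row["area_px"] == st["area"]
            assert row["perimeter"] == st["perimeter"]
            np.testing.assert_allclose(
                [row["mean_0"], row["mean_1"], row["mean_2"]], st["mean"], atol=1e-9)
            np.testing.assert_allclose(
                [row["std_0"], row["std_1"], row["std_2"]], st["std"], atol=1e-9)
        assert seg.adjacency == adj

    def test_adjacency_symmetric(self, rng):
        img = rng.integers(0, 80, (16, 16, 3)).astype(float)
        seg = multiresolution_segment(img, SegmentationParams(6.0))
        for a, nbrs in seg.adjacency.items():
            for b, length in nbrs.items():
                assert seg.adjacency[b][a] == length

    def test_masks_never_crossed(self, rng):
        img = rng.integers(90, 110, (16, 16, 3)).astype(float)  # near-uniform
        masks = np.zeros((16, 16), dtype=int)
        masks[:, 8:] = 1
        seg = multiresolution_segment(img, SegmentationParams(50.0), thematic_masks=masks)
        for oid in range(1, seg.n_objects + 1):
            assert len(np.unique(masks[seg.labels == oid])) == 1

    def test_deterministic(self, rng):
        img = rng.integers(0, 100, (20, 20, 3)).astype(float)
        a = multiresolution_segment(img, SegmentationParams(9.0, 0.1, 0.5))
        b = multiresolution_segment(img.copy(), SegmentationParams(9.0, 0.1, 0.5))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_extent_rejected(self):
        from mossquad.raster_io import GeometryError

        with pytest.raises(GeometryError):
            multiresolution_segment(np.empty((0, 0, 3)))

    def test_invalid_params_rejected(self):
        from mossquad.raster_io import ParameterError

        with pytest.raises(ParameterError):
            SegmentationParams(scale=-1)
        with pytest.raises(ParameterError):
            SegmentationParams(shape_weight=1.0)


class TestEspCurve:
    def test_uniform_image_zero_lv_everywhere(self):
        img = np.full((10, 10, 3), 42.0)
        curve = esp_curve(img, 2, 6, 2)
        assert curve.lv == [0.0, 0.0, 0.0]

    def test_patch_tiling_lv_jump_at_cross_patch_scale(self):
        # 4x4 tiling of 6x6 patches in a two-value checkerboard differing by
        # 16 per band. Once each patch is one object, merging two adjacent
        # patches costs dh_color = 3 bands * n_m * sigma_m = 3 * 72 * 8 =
        # 1728 (shape weight 0), so cross-patch merges first become
        # admissible for scale^2 > 1728, i.e. between scales 36 and 48 of
        # the sweep below. A +/-0.25 deterministic dither keeps LV positive
        # (and ROC defined) at fine scales.
        rng = np.random.default_rng(5)
        img = np.zeros((24, 24, 3))
        for pr in range(4):
            for pc in range(4):
                img[pr * 6:(pr + 1) * 6, pc * 6:(pc + 1) * 6] = 100 + 16 * ((pr + pc) % 2)
        img += (rng.integers(0, 2, (24, 24, 3)) - 0.5) * 0.5
        curve = esp_curve(img, 24, 60, 6, shape_weight=0.0)
        lv = dict(zip(curve.scales, curve.lv))
        assert lv[36] < 1.0         # only within-patch dither
        assert lv[48] > 4.0         # cross-patch objects mix the two colors
        peaks = detect_scale_peaks(curve)
        assert peaks and 36 < peaks[0] <= 48  # top ROC peak at the transition

    def test_step_refinement_preserves_values_at_shared_scales(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 50, (10, 10, 3)).astype(float)
        coarse = esp_curve(img, 2, 8, 2)
        fine = esp_curve(img, 2, 8, 1)
        fine_map = dict(zip(fine.scales, fine.lv))
        for s, v in zip(coarse.scales, coarse.lv):
            assert fine_map[s] == v


class TestDetectScalePeaks:
    def test_example_curve_two_peaks_ordered_by_roc(self):
        curve = EspCurve(scales=[10, 20, 30, 40, 50, 60],
                         lv=[1] * 6,
                         roc=[float("nan"), 1, 5, 2, 4, 1])
        assert detect_scale_peaks(curve) == [30, 50]

    def test_monotone_roc_no_peaks(self):
        curve = EspCurve(scales=[1, 2, 3, 4], lv=[1] * 4,
                         roc=[float("nan"), 1, 2, 3])
        assert detect_scale_peaks(curve) == []

    def test_plateau_reports_smallest_scale_once(self):
        curve = EspCurve(scales=[1, 2, 3, 4, 5], lv=[1] * 5,
                         roc=[float("nan"), 1, 4, 4, 1])
        assert detect_scale_peaks(curve) == [3]  # plateau 4,4 starts at scale 3

    def test_too_few_defined_entries_empty(self):
        curve = EspCurve(scales=[1, 2], lv=[1, 1], roc=[float("nan"), 2])
        assert detect_scale_peaks(curve) == []
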