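"""Rule engine: mask precedence, context refinement, cover extraction."""

import numpy as np
import pytest
from shapely.geometry import box

import mossquad.classify as cl
from mossquad.classify import (ClassMap, Condition, ConfigError, ContextRule, Rule,
                               apply_ruleset, default_ruleset, load_ruleset,
                               manual_correction, percent_cover, relative_border,
                               ruleset_to_dict)
from mossquad.raster_io import GeometryError, MaskSet, QuadratImage, rasterize_masks
from mossquad.schema import CLASS_CODE, PROVENANCE_CODE, SchemaError
from mossquad.segmentation import SegmentationParams, multiresolution_segment


def _segment_label_image(class_grid: np.ndarray, colors: dict[int, tuple]):
    """Build an image whose segmentation reproduces class_grid regions."""
    h, w = class_grid.shape
    img = np.zeros((h, w, 3))
    for code, rgb in colors.items():
        img[class_grid == code] = rgb
    seg = multiresolution_segment(img, SegmentationParams(5.0, 0.0, 0.5))
    return img, seg


class TestRelativeBorder:
    def test_fully_enclosed_object(self):
        grid = np.ones((6, 6), dtype=int)
        grid[2:4, 2:4] = 2
        img, seg = _segment_label_image(grid, {1: (80, 130, 45), 2: (25, 24, 26)})
        assert seg.n_objects == 2
        # object classes: map each object to its dominant color class
        obj_classes = np.array([CLASS_CODE["healthy_moss"], CLASS_CODE["shadow"]])
        inner = int(seg.labels[2, 2])
        frac = relative_border(seg, obj_classes, inner, "healthy_moss")
        assert frac == 1.0

    def test_corner_object_half_boundary(self):
        # 2x2 object in the image corner: 4 edges on the boundary, 4 edges
        # shared with the surrounding object -> fraction 4/8
        grid = np.ones((4, 4), dtype=int)
        grid[:2, :2] = 2
        img, seg = _segment_label_image(grid, {1: (80, 130, 45), 2: (25, 24, 26)})
        corner = int(seg.labels[0, 0])
        obj_classes = np.where(
            np.arange(1, seg.n_objects + 1) == corner,
            CLASS_CODE["shadow"], CLASS_CODE["healthy_moss"])
        assert relative_border(seg, obj_classes, corner, "healthy_moss") == 0.5

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_pixel_edge_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 200, (16, 16, 3)).astype(float)
        seg = multiresolution_segment(img, SegmentationParams(10.0))
        obj_classes = rng.integers(1, 4, seg.n_objects)
        labels = seg.labels
        h, w = labels.shape
        for oid in range(1, seg.n_objects + 1):
            target = 2
            shared = total = 0
            for r, c in zip(*np.nonzero(labels == oid)):
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if not (0 <= rr < h and 0 <= cc < w):
                        total += 1
                    elif labels[rr, cc] != oid:
                        total += 1
                        if obj_classes[labels[rr, cc] - 1] == target:
                            shared += 1
            expected = shared / total if total else 0.0
            assert np.isclose(relative_border(seg, obj_classes, oid, target), expected)


def _quadrat(pixels):
    pixels = np.asarray(pixels, dtype=np.uint8)
    return QuadratImage(pixels, 0.001, np.ones(pixels.shape[:2], bool))


class TestApplyRuleset:
    def test_mask_precedence_overrides_spectra(self):
        # healthy-colored pixels under a rock mask polygon classify as rock
        img = _quadrat(np.full((10, 10, 3), (80, 130, 45)))
        masks = MaskSet(layers={"rock": [box(0.0, 0.0, 0.005, 0.01)]})
        mask_raster = rasterize_masks(masks, img)
        seg = multiresolution_segment(img.pixels.astype(float),
                                      thematic_masks=mask_raster)
        cmap = apply_ruleset(seg, mask_raster=mask_raster)
        assert (cmap.labels[:, :5] == CLASS_CODE["rock"]).all()
        assert (cmap.provenance[:, :5] == PROVENANCE_CODE["mask"]).all()
        assert (cmap.labels[:, 5:] == CLASS_CODE["healthy_moss"]).all()

    def test_shadow_reassigned_when_majority_border_healthy(self):
        # a shadow object sharing > 50% of its border with healthy moss
        # becomes healthy moss after one context pass
        grid = np.ones((8, 8), dtype=int)
        grid[3:5, 3:5] = 2
        img, seg = _segment_label_image(grid, {1: (80, 130, 45), 2: (25, 24, 26)})
        cmap = apply_ruleset(seg)
        assert (cmap.labels == CLASS_CODE["healthy_moss"]).all()

    def test_small_bright_object_enclosed_by_healthy_becomes_rock(self):
        grid = np.ones((10, 10), dtype=int)
        grid[4:6, 4:6] = 2  # 4 px bright blob, below the 25-px ceiling
        img, seg = _segment_label_image(grid, {1: (80, 130, 45), 2: (250, 250, 250)})
        cmap = apply_ruleset(seg)
        assert (cmap.labels[4:6, 4:6] == CLASS_CODE["rock"]).all()
        assert (cmap.provenance[4:6, 4:6] == PROVENANCE_CODE["context_rule"]).all()

    def test_no_matching_rule_stays_unclassified(self):
        img = np.full((6, 6, 3), (255, 0, 255), dtype=float)  # magenta
        seg = multiresolution_segment(img)
        rules = [Rule("green", (Condition("pbr_g", ">=", 0.9),), "healthy_moss", 0)]
        cmap = apply_ruleset(seg, rules=rules, context_rules=[])
        assert (cmap.labels == CLASS_CODE["unclassified"]).all()

    def test_pixel_conservation_across_stages(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 255, (20, 20, 3)).astype(float)
        seg = multiresolution_segment(img)
        cmap = apply_ruleset(seg)
        assert cmap.labels.size == 400
        assert (cmap.labels != CLASS_CODE["outside_quadrat"]).all()

    def test_unknown_feature_in_rule_rejected_before_execution(self):
        with pytest.raises(ConfigError):
            Condition("ndvi", ">=", 0.5)

    def test_empty_ruleset_rejected(self):
        img = np.full((4, 4, 3), 100.0)
        seg = multiresolution_segment(img)
        with pytest.raises(ConfigError):
            apply_ruleset(seg, rules=[], context_rules=[])

    def test_context_iteration_propagates_through_nested_shadow(self):
        # shadow ring inside healthy flips first (2/3 of its border is
        # healthy); the enclosed shadow core then flips once the ring has
        # -- the reassignment cascades instead of stopping after one rule
        grid = np.ones((10, 10), dtype=int)
        grid[3:7, 3:7] = 2   # ring, 1 px thick after the core is cut out
        grid[4:6, 4:6] = 3   # core
        img, seg = _segment_label_image(
            grid, {1: (80, 130, 45), 2: (25, 24, 26), 3: (38, 37, 39)})
        assert seg.n_objects == 3
        cmap = apply_ruleset(seg, max_iter=10)
        assert (cmap.labels == CLASS_CODE["healthy_moss"]).all()


class TestPercentCover:
    def test_all_healthy_quadrat(self):
        labels = np.full((10, 10), CLASS_CODE["healthy_moss"], dtype=np.uint8)
        cover = percent_cover(labels, np.ones((10, 10), bool)).set_index("class")
        assert cover.loc["healthy_moss", "percent"] == 100.0
        assert (cover.drop("healthy_moss")["percent"] == 0.0).all()

    def test_equals_truth_counting_identity(self, rng):
        labels = rng.integers(1, 11, (30, 30)).astype(np.uint8)
        mask = rng.random((30, 30)) < 0.8
        cover = percent_cover(labels, mask).set_index("class")
        total = mask.sum()
        for cls, code in CLASS_CODE.items():
            if cls == "outside_quadrat":
                continue
            expected = 100.0 * np.sum(labels[mask] == code) / total
            assert np.isclose(cover.loc[cls, "percent"], expected)

    def test_percentages_sum_to_100(self, rng):
        labels = rng.integers(1, 11, (25, 25)).astype(np.uint8)
        cover = percent_cover(labels, np.ones((25, 25), bool))
        assert abs(cover["percent"].sum() - 100.0) < 0.01

    def test_empty_quadrat_mask_rejected(self):
        labels = np.ones((5, 5), dtype=np.uint8)
        with pytest.raises(GeometryError):
            percent_cover(labels, np.zeros((5, 5), bool))


class TestManualCorrection:
    def _classmap(self):
        labels = np.full((10, 10), CLASS_CODE["moribund_moss"], dtype=np.uint8)
        return ClassMap(labels, np.full((10, 10), PROVENANCE_CODE["rule"], np.uint8))

    def test_empty_polygon_set_identity(self):
        cmap = self._classmap()
        out = manual_correction(cmap, [], "wet_moss", 0.001)
        np.testing.assert_array_equal(out.labels, cmap.labels)
        assert out.correction_log == []

    def test_polygon_reassigns_with_provenance(self):
        cmap = self._classmap()
        poly = box(0.0, 0.0, 0.005, 0.005)
        out = manual_correction(cmap, [poly], "wet_moss", 0.001)
        assert (out.labels[:5, :5] == CLASS_CODE["wet_moss"]).all()
        assert (out.provenance[:5, :5] == PROVENANCE_CODE["manual_correction"]).all()
        assert (out.labels[5:, 5:] == CLASS_CODE["moribund_moss"]).all()
        assert out.correction_log[0]["n_pixels"] == 25

    def test_idempotent(self):
        cmap = self._classmap()
        poly = box(0.0, 0.0, 0.004, 0.004)
        once = manual_correction(cmap, [poly], "wet_moss", 0.001)
        twice = manual_correction(once, [poly], "wet_moss", 0.001)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_unknown_class_rejected(self):
        with pytest.raises(SchemaError):
            manual_correction(self._classmap(), [], "lava", 0.001)


class TestRulesetIO:
    def test_yaml_round_trip(self, tmp_path):
        import yaml

        rules, ctx = default_ruleset()
        path = tmp_path / "rules.yaml"
        path.write_text(yaml.safe_dump(ruleset_to_dict(rules, ctx)))
        rules2, ctx2 = load_ruleset(path)
        assert rules2 == rules
        assert ctx2 == ctx

    def test_single_condition_flat_form_accepted(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "rules:\n"
            "  - {name: r1, feature: stress, comparator: '>=', threshold: 1.5,\n"
            "     target_class: stressed_moss, stage: 0}\n")
        rules, ctx = load_ruleset(path)
        assert rules[0].conditions[0].feature == "stress"
        assert ctx == []

    def test_unknown_feature_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "rules:\n"
            "  - {feature: ndvi, comparator: '<', threshold: 1, target_class: rock}\n")
        with pytest.raises(ConfigError):
            load_ruleset(path)

    def test_context_rule_requires_exactly_one_condition_kind(self):
        with pytest.raises(ConfigError):
            ContextRule("c", "shadow", "healthy_moss",
                        relative_border_to="healthy_moss", min_fraction=0.5,
                        max_area=10, enclosed_by="rock")
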