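"""Threshold- and context-rule classification of segmented objects.

Objects inherit manually digitized mask classes unconditionally (mask
precedence is absolute); remaining objects run through threshold rules in
stage order on object-level spectral features, then context rules refine
classes by neighborhood and size (e.g. a shadow object sharing more than
half its border with healthy moss becomes healthy moss; a very small
bright object enclosed by healthy moss becomes a wind-blown rock).
Context rules iterate until no object changes class or ``max_iter`` is
reached. Objects matching no rule stay ``unclassified`` — a legal
terminal class that is reported, never silently redistributed.

The shipped default ruleset (:func:`default_ruleset`) follows the stage
order: moribund by high death index 1, residual moribund by low death
index 2, stressed by high stress index, healthy by low stress index and
high green ratio, shadow by low intensity, snow then wind-blown rock by
high intensity. Threshold values are calibrated between natural-breaks
categories of the synthetic generator's object features; real imagery is
expected to need recalibration (``mossquad calibrate``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry.base import BaseGeometry

from . import schema
from .features import (DEFAULT_JENKS_CLASSES, FEATURE_NAMES, FeatureStack,
                       jenks_breaks, object_features)
from .raster_io import GeometryError, rasterize_polygon
from .schema import (CLASS_CODE, CLASS_NAMES, MASK_LAYER_CLASS, MASK_LAYERS,
                     PROVENANCE_CODE, SchemaError)
from .segmentation import SegmentationResult


class ConfigError(ValueError):
    """Ruleset configuration is structurally invalid."""


#: Default relative-border fraction (strict "more than half the border").
DEFAULT_BORDER_FRACTION = 0.5

#: Default small-object area ceiling for the wind-blown-rock context rule,
#: in pixels (25 px at 0.0005 m pixels = 6.25 mm^2).
DEFAULT_MAX_AREA_PX = 25

DEFAULT_MAX_ITER = 10


@dataclass(frozen=True)
class Condition:
    feature: str
    comparator: str  # "<" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ConfigError(f"unknown feature {self.feature!r}")
        if self.comparator not in ("<", ">="):
            raise ConfigError(f"comparator must be '<' or '>=', got {self.comparator!r}")
        if not np.isfinite(self.threshold):
            raise ConfigError(f"threshold for {self.feature} must be finite")

    def holds(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            out = v < self.threshold if self.comparator == "<" else v >= self.threshold
        return out & ~np.isnan(v)  # undefined features never satisfy a rule


@dataclass(frozen=True)
class Rule:
    """A staged threshold rule; all conditions must hold (conjunction)."""

    name: str
    conditions: tuple[Condition, ...]
    target_class: str
    stage: int

    def __post_init__(self) -> None:
        if self.target_class not in CLASS_NAMES:
            raise SchemaError(f"unknown target class {self.target_class!r}")
        if self.stage < 0:
            raise ConfigError("stage must be >= 0")
        if not self.conditions:
            raise ConfigError(f"rule {self.name!r} has no conditions")


@dataclass(frozen=True)
class ContextRule:
    """Reassignment by neighborhood (relative border) or by size+enclosure."""

    name: str
    applies_to: str
    new_class: str
    relative_border_to: str | None = None
    min_fraction: float | None = None
    max_area: float | None = None       # in pixels
    enclosed_by: str | None = None

    def __post_init__(self) -> None:
        for c in (self.applies_to, self.new_class):
            if c not in CLASS_NAMES:
                raise SchemaError(f"unknown class {c!r}")
        border_mode = self.relative_border_to is not None
        size_mode = self.max_area is not None
        if border_mode == size_mode:
            raise ConfigError(
                f"context rule {self.name!r} must set exactly one of "
                "relative_border_to/min_fraction or max_area/enclosed_by"
            )
        if border_mode:
            if self.min_fraction is None or not (0 < self.min_fraction <= 1):
                raise ConfigError(f"context rule {self.name!r}: min_fraction must be in (0, 1]")
            if self.relative_border_to not in CLASS_NAMES:
                raise SchemaError(f"unknown class {self.relative_border_to!r}")
        else:
            if not self.max_area > 0:
                raise ConfigError(f"context rule {self.name!r}: max_area must be positive")
            if self.enclosed_by is None or self.enclosed_by not in CLASS_NAMES:
                raise SchemaError(f"context rule {self.name!r}: invalid enclosed_by class")


@dataclass
class ClassMap:
    """Per-pixel class raster with per-pixel provenance.

    ``labels`` holds :data:`mossquad.schema.CLASS_CODE` values;
    ``provenance`` holds :data:`mossquad.schema.PROVENANCE_CODE` values.
    """

    labels: np.ndarray
    provenance: np.ndarray
    correction_log: list[dict] = field(default_factory=list)

    def copy(self) -> "ClassMap":
        return ClassMap(self.labels.copy(), self.provenance.copy(), list(self.correction_log))


# ---------------------------------------------------------------------------
# Ruleset I/O
# ---------------------------------------------------------------------------

def _parse_rule(d: dict, idx: int) -> Rule:
    try:
        if "conditions" in d:
            conds = tuple(
                Condition(c["feature"], c["comparator"], float(c["threshold"]))
                for c in d["conditions"]
            )
        else:
            conds = (Condition(d["feature"], d["comparator"], float(d["threshold"])),)
        return Rule(name=d.get("name", f"rule_{idx}"), conditions=conds,
                    target_class=d["target_class"], stage=int(d.get("stage", idx)))
    except KeyError as exc:
        raise ConfigError(f"rules[{idx}]: missing key {exc}") from None


def _parse_context_rule(d: dict, idx: int) -> ContextRule:
    cond = d.get("condition", d)
    try:
        return ContextRule(
            name=d.get("name", f"context_{idx}"),
            applies_to=d["applies_to"],
            new_class=d["new_class"],
            relative_border_to=cond.get("relative_border_to"),
            min_fraction=cond.get("min_fraction"),
            max_area=cond.get("max_area"),
            enclosed_by=cond.get("enclosed_by"),
        )
    except KeyError as exc:
        raise ConfigError(f"context_rules[{idx}]: missing key {exc}") from None


def load_ruleset(path: str | Path) -> tuple[list[Rule], list[ContextRule]]:
    """Read a YAML/JSON ruleset with ``rules:`` and ``context_rules:`` lists."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'rules' list")
    rules = [_parse_rule(d, i) for i, d in enumerate(doc["rules"])]
    ctx = [_parse_context_rule(d, i) for i, d in enumerate(doc.get("context_rules", []))]
    return rules, ctx


def ruleset_to_dict(rules: list[Rule], context_rules: list[ContextRule]) -> dict:
    return {
        "rules": [
            {
                "name": r.name,
                "stage": r.stage,
                "target_class": r.target_class,
                "conditions": [
                    {"feature": c.feature, "comparator": c.comparator, "threshold": c.threshold}
                    for c in r.conditions
                ],
            }
            for r in rules
        ],
        "context_rules": [
            {
                "name": c.name,
                "applies_to": c.applies_to,
                "new_class": c.new_class,
                "condition": {
                    k: v
                    for k, v in (
                        ("relative_border_to", c.relative_border_to),
                        ("min_fraction", c.min_fraction),
                        ("max_area", c.max_area),
                        ("enclosed_by", c.enclosed_by),
                    )
                    if v is not None
                },
            }
            for c in context_rules
        ],
    }


def default_ruleset() -> tuple[list[Rule], list[ContextRule]]:
    """Shipped default rules, calibrated on the synthetic generator's colors.

    Stage order: moribund (high death1, mid intensity) -> residual moribund
    (low death2) -> stressed (high stress) -> healthy (low stress, green) ->
    shadow (dark) -> snow (very bright) -> wind-blown rock (bright).
    """
    c = Condition
    rules = [
        Rule("moribund_death1", (c("death1", ">=", 1.6), c("hsi_s", "<", 0.30),
                                 c("pbr_g", "<", 0.40), c("hsi_i", ">=", 0.16),
                                 c("hsi_i", "<", 0.50)), "moribund_moss", 0),
        Rule("moribund_death2", (c("death2", "<", 1.2), c("hsi_i", "<", 0.30)),
             "moribund_moss", 1),
        Rule("stressed_high_stress", (c("stress", ">=", 1.40),), "stressed_moss", 2),
        Rule("healthy_green", (c("stress", "<", 1.40), c("pbr_g", ">=", 0.40)),
             "healthy_moss", 3),
        Rule("shadow_dark", (c("hsi_i", "<", 0.16), c("luminance", "<", 0.45)), "shadow", 4),
        Rule("snow_bright", (c("hsi_i", ">=", 0.85),), "snow", 5),
        Rule("rock_bright", (c("hsi_i", ">=", 0.50),), "rock", 6),
    ]
    ctx = [
        ContextRule("shadow_to_healthy", "shadow", "healthy_moss",
                    relative_border_to="healthy_moss", min_fraction=DEFAULT_BORDER_FRACTION),
        ContextRule("shadow_to_stressed", "shadow", "stressed_moss",
                    relative_border_to="stressed_moss", min_fraction=DEFAULT_BORDER_FRACTION),
        ContextRule("shadow_to_moribund", "shadow", "moribund_moss",
                    relative_border_to="moribund_moss", min_fraction=DEFAULT_BORDER_FRACTION),
        # tiny white blobs inside healthy turf are wind-blown rocks, not snow
        ContextRule("small_rock_from_snow", "snow", "rock",
                    max_area=DEFAULT_MAX_AREA_PX, enclosed_by="healthy_moss"),
        ContextRule("small_rock_unclassified", "unclassified", "rock",
                    max_area=DEFAULT_MAX_AREA_PX, enclosed_by="healthy_moss"),
    ]
    return rules, ctx


# ---------------------------------------------------------------------------
# Relative border
# ---------------------------------------------------------------------------

def relative_border(
    seg: SegmentationResult,
    object_classes: np.ndarray,
    object_id: int,
    target_class: str,
) -> float:
    """Fraction of an object's border shared with objects of ``target_class``.

    The denominator is the object's full perimeter in pixel edges, so the
    image boundary counts as class "outside". ``object_classes`` maps
    object id - 1 to a class code.
    """
    if object_id not in seg.adjacency:
        raise KeyError(f"object {object_id} not in segmentation")
    target = CLASS_CODE[target_class] if isinstance(target_class, str) else int(target_class)
    perim = float(seg.object_stats.loc[object_id, "perimeter"])
    if perim == 0:
        return 0.0
    shared = sum(
        length for nbr, length in seg.adjacency[object_id].items()
        if object_classes[nbr - 1] == target
    )
    return shared / perim


# ---------------------------------------------------------------------------
# Ruleset application
# ---------------------------------------------------------------------------

def _object_mask_layers(seg: SegmentationResult, mask_raster: np.ndarray | None) -> np.ndarray:
    """Mask-layer index (0 = unmasked) per object, from the per-pixel raster.

    Segmentation respects mask boundaries, so each object is uniform in
    mask label; the label of the object's first pixel is used.
    """
    n = seg.n_objects
    out = np.zeros(n, dtype=int)
    if mask_raster is None:
        return out
    flat_lab = seg.labels.ravel()
    flat_mask = np.asarray(mask_raster).ravel()
    _, first = np.unique(flat_lab, return_index=True)
    out[flat_lab[first] - 1] = flat_mask[first]
    return out


def apply_ruleset(
    seg: SegmentationResult,
    features: FeatureStack | None = None,
    mask_raster: np.ndarray | None = None,
    rules: list[Rule] | None = None,
    context_rules: list[ContextRule] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    quadrat_mask: np.ndarray | None = None,
) -> ClassMap:
    """Assign every object a class; rasterize to a per-pixel ClassMap.

    ``features`` are object-level (index = object id - 1); when omitted
    they are computed from the segmentation's object mean bands (the first
    three stat bands are taken as R, G, B). Masked objects take their mask
    class unconditionally; threshold rules run in stage order with
    first-match-wins among currently unclassified objects; context rules
    then iterate to a fixpoint (bounded by ``max_iter``).
    """
    if rules is None and context_rules is None:
        rules, context_rules = default_ruleset()
    rules = rules or []
    context_rules = context_rules or []
    if not rules:
        raise ConfigError("rules must be non-empty")
    if features is None:
        stats = seg.object_stats
        features = object_features(
            stats["mean_0"].to_numpy(), stats["mean_1"].to_numpy(), stats["mean_2"].to_numpy()
        )

    n = seg.n_objects
    obj_class = np.full(n, CLASS_CODE["unclassified"], dtype=int)
    obj_prov = np.full(n, PROVENANCE_CODE["rule"], dtype=int)

    # 1. mask precedence (absolute)
    layer_idx = _object_mask_layers(seg, mask_raster)
    masked = layer_idx > 0
    for li in np.unique(layer_idx[masked]):
        cls = MASK_LAYER_CLASS[MASK_LAYERS[li - 1]]
        obj_class[layer_idx == li] = CLASS_CODE[cls]
    obj_prov[masked] = PROVENANCE_CODE["mask"]

    # 2. threshold rules in stage order, first match wins
    unassigned = ~masked
    for rule in sorted(rules, key=lambda r: r.stage):
        hit = unassigned.copy()
        for cond in rule.conditions:
            hit &= cond.holds(features[cond.feature])
        obj_class[hit] = CLASS_CODE[rule.target_class]
        unassigned &= ~hit

    # 3. context rules iterate to a fixpoint
    for _ in range(max_iter):
        changed = False
        for crule in context_rules:
            src = CLASS_CODE[crule.applies_to]
            dst = CLASS_CODE[crule.new_class]
            candidates = np.flatnonzero((obj_class == src) & ~masked)
            for oi in candidates:
                oid = int(oi) + 1
                if crule.relative_border_to is not None:
                    frac = relative_border(seg, obj_class, oid, crule.relative_border_to)
                    ok = frac > crule.min_fraction
                else:
                    area = float(seg.object_stats.loc[oid, "area_px"])
                    ok = area < crule.max_area and (
                        relative_border(seg, obj_class, oid, crule.enclosed_by)
                        > DEFAULT_BORDER_FRACTION
                    )
                if ok and obj_class[oi] != dst:
                    obj_class[oi] = dst
                    obj_prov[oi] = PROVENANCE_CODE["context_rule"]
                    changed = True
        if not changed:
            break

    # 4. rasterize
    labels = obj_class[seg.labels - 1].astype(np.uint8)
    prov = obj_prov[seg.labels - 1].astype(np.uint8)
    if quadrat_mask is not None:
        outside = ~np.asarray(quadrat_mask, dtype=bool)
        labels[outside] = CLASS_CODE[schema.OUTSIDE_QUADRAT]
        prov[outside] = PROVENANCE_CODE["mask"]
    return ClassMap(labels=labels, provenance=prov)


# ---------------------------------------------------------------------------
# Cover, corrections, calibration
# ---------------------------------------------------------------------------

def percent_cover(
    classmap: ClassMap | np.ndarray,
    quadrat_mask: np.ndarray,
    quadrat_id: str = "",
    year: int = 0,
) -> pd.DataFrame:
    """Percent cover of every schema class inside the quadrat.

    Returns a DataFrame with columns (quadrat_id, year, class, percent);
    all cover classes are reported, zeros included, and the percents sum
    to 100 within floating-point tolerance.
    """
    labels = classmap.labels if isinstance(classmap, ClassMap) else np.asarray(classmap)
    quadrat_mask = np.asarray(quadrat_mask, dtype=bool)
    if labels.shape != quadrat_mask.shape:
        raise GeometryError("classmap and quadrat mask shapes differ")
    inside = quadrat_mask & (labels != CLASS_CODE[schema.OUTSIDE_QUADRAT])
    total = int(inside.sum())
    if total == 0:
        raise GeometryError("quadrat mask selects no classified pixels")
    counts = np.bincount(labels[inside].ravel(), minlength=schema.N_CLASSES)
    rows = [
        (quadrat_id, year, cls, 100.0 * counts[CLASS_CODE[cls]] / total)
        for cls in schema.COVER_CLASSES
    ]
    return pd.DataFrame(rows, columns=["quadrat_id", "year", "class", "percent"])


def manual_correction(
    classmap: ClassMap,
    polygons: list[BaseGeometry],
    new_class: str,
    pixel_size: float,
) -> ClassMap:
    """Reassign pixels under the polygons to ``new_class`` (logged, idempotent)."""
    if new_class not in CLASS_NAMES:
        raise SchemaError(f"unknown class {new_class!r}")
    out = classmap.copy()
    n_pixels = 0
    for geom in polygons:
        hit = rasterize_polygon(geom, out.labels.shape, pixel_size)
        hit &= out.labels != CLASS_CODE[schema.OUTSIDE_QUADRAT]
        out.labels[hit] = CLASS_CODE[new_class]
        out.provenance[hit] = PROVENANCE_CODE["manual_correction"]
        n_pixels += int(hit.sum())
    if polygons:
        out.correction_log.append({"new_class": new_class, "n_polygons": len(polygons),
                                   "n_pixels": n_pixels})
    return out


def object_feature_table(seg: SegmentationResult) -> pd.DataFrame:
    """Per-object feature table (CSV-ready) from a 3-band segmentation."""
    stats = seg.object_stats
    fs = object_features(stats["mean_0"].to_numpy(), stats["mean_1"].to_numpy(),
                         stats["mean_2"].to_numpy())
    df = pd.DataFrame({
        "object_id": stats.index,
        "area_px": stats["area_px"].to_numpy(),
        "mean_r": stats["mean_0"].to_numpy(),
        "mean_g": stats["mean_1"].to_numpy(),
        "mean_b": stats["mean_2"].to_numpy(),
    })
    for name in FEATURE_NAMES:
        col = {"hsi_h": "h", "hsi_s": "s", "hsi_i": "i"}.get(name, name)
        df[col] = fs[name]
    return df


def calibrate_thresholds(
    feature_table: pd.DataFrame,
    n_classes: int = DEFAULT_JENKS_CLASSES,
    features: tuple[str, ...] = ("death1", "death2", "stress", "pbr_g", "i", "luminance"),
) -> dict[str, list[float]]:
    """Natural-breaks threshold candidates per feature (k classes).

    Mirrors the calibration procedure: each feature's object-level
    distribution is split into ``n_classes`` natural-breaks categories and
    the break values are proposed as candidate rule thresholds, to be
    chosen between visually.
    """
    out: dict[str, list[float]] = {}
    for feat in features:
        vals = feature_table[feat].dropna().to_numpy()
        if len(vals) < n_classes:
            continue
        out[feat] = jenks_breaks(vals, n_classes).breaks
    return out
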