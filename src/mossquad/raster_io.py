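"""Imagery, mask and table I/O, and the geometric frame used downstream.

Coordinate convention (used everywhere in the package): origin at the
top-left corner of the raster, x increasing rightward, y increasing
downward, both in meters. Pixels are square with side ``pixel_size``; the
pixel at row i, column j has its center at
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``. Rasterization
includes a pixel iff its center lies strictly inside the polygon
(boundary-touching centers are resolved by shapely's covers predicate).

There is no CRS: quadrat photographs live in a local meter frame anchored
to the quadrat corners, which removes any GIS dependency while preserving
the geometry contract (0.0005 m pixels, point grids, polygon masks).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .schema import MASK_LAYERS, SchemaError

logger = logging.getLogger("mossquad")

#: Default pixel size in meters for rectified quadrat photographs.
DEFAULT_PIXEL_SIZE = 0.0005

#: Default accuracy-assessment point-grid spacing in meters.
DEFAULT_GRID_SPACING = 0.005


class FormatError(ValueError):
    """Input file is not a 3-band 8-bit RGB raster (or cannot be decoded)."""


class GeometryError(ValueError):
    """A polygon or extent precondition failed."""


class ParameterError(ValueError):
    """A scalar parameter is out of its valid range."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class QuadratImage:
    """An RGB quadrat photograph in a local meter frame.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    pixel_size : meters per pixel (square pixels)
    quadrat_mask : (H, W) bool array, True inside the physical quadrat
    quadrat_id, year : provenance tags carried into cover tables
    """

    pixels: np.ndarray
    pixel_size: float
    quadrat_mask: np.ndarray
    quadrat_id: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.quadrat_mask = np.asarray(self.quadrat_mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"expected (H, W, 3) pixel array, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"expected uint8 bands, got {self.pixels.dtype}")
        if self.quadrat_mask.shape != self.pixels.shape[:2]:
            raise GeometryError("quadrat_mask shape does not match image bands")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size must be positive")
        if not self.quadrat_mask.any():
            raise GeometryError("quadrat_mask has no interior cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in meters."""
        h, w = self.shape
        return w * self.pixel_size, h * self.pixel_size


@dataclass
class MaskSet:
    """Manually digitized polygons for non-moss ground cover, per layer.

    ``layers`` maps a mask layer name (restricted to the fixed schema) to a
    list of shapely polygons in the image's meter frame.
    """

    layers: dict[str, list[BaseGeometry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.layers:
            if name not in MASK_LAYERS:
                raise SchemaError(
                    f"unknown mask layer {name!r}; valid layers: {', '.join(MASK_LAYERS)}"
                )


@dataclass
class PointGrid:
    """Regular lattice of sample points covering an image extent."""

    spacing: float
    points: np.ndarray  # (N, 2) array of (x, y) meter coordinates

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ParameterError("spacing must be positive")
        self.points = np.asarray(self.points, dtype=float)


# ---------------------------------------------------------------------------
# Loading and geometry
# ---------------------------------------------------------------------------

def _pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Meshgrid of pixel-center coordinates (x, y arrays of shape (H, W))."""
    h, w = shape
    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    return np.meshgrid(xs, ys)


def rasterize_polygon(geom: BaseGeometry, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean raster of pixels whose centers the polygon covers."""
    xx, yy = _pixel_centers(shape, pixel_size)
    # Strict center-in-polygon test: an axis-aligned square spanning whole
    # pixels rasterizes to exactly area / pixel_size**2 cells.
    return shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(shape)


def load_quadrat_image(
    path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    quadrat_polygon: BaseGeometry | None = None,
    quadrat_id: str = "",
    year: int = 0,
) -> QuadratImage:
    """Read a TIFF/PNG/JPEG photograph and rasterize the quadrat footprint.

    ``quadrat_polygon`` is the physical quadrat interior in the image's
    meter frame; if omitted the full extent is treated as in-quadrat.
    Band values are never transformed; >8-bit inputs are linearly rescaled
    to 0–255 with a warning.
    """
    if not pixel_size > 0:
        raise ParameterError("pixel_size must be positive")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            arr = np.asarray(tifffile.imread(path))  # preserves >8-bit depths
        else:
            with Image.open(path) as im:
                if im.mode == "RGBA":
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except FormatError:
        raise
    except Exception as exc:  # decoders raise a zoo of errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path} is not a 3-band RGB image (shape {arr.shape})")
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        top = info.max if info else float(arr.max() or 1)
        warnings.warn(f"{path}: {arr.dtype} bands rescaled linearly to 8-bit", stacklevel=2)
        arr = np.clip(np.round(arr.astype(float) * 255.0 / top), 0, 255).astype(np.uint8)

    shape = arr.shape[:2]
    if quadrat_polygon is None:
        mask = np.ones(shape, dtype=bool)
    else:
        if quadrat_polygon.is_empty or quadrat_polygon.area <= 0:
            raise GeometryError("quadrat polygon is degenerate")
        w_m = shape[1] * pixel_size
        h_m = shape[0] * pixel_size
        minx, miny, maxx, maxy = quadrat_polygon.bounds
        if maxx <= 0 or maxy <= 0 or minx >= w_m or miny >= h_m:
            raise GeometryError("quadrat polygon lies outside the image extent")
        mask = rasterize_polygon(quadrat_polygon, shape, pixel_size)
        if not mask.any():
            raise GeometryError("quadrat polygon covers no pixel centers")
    return QuadratImage(arr, pixel_size, mask, quadrat_id=quadrat_id, year=year)


def resample_nearest(image: QuadratImage, target_pixel_size: float) -> QuadratImage:
    """Nearest-neighbor resampling to a new pixel size (original values kept).

    Each output pixel takes the value of the input pixel containing its
    center, so output values are always a subset of input values and the
    meter extent is preserved to within one output pixel.
    """
    if not target_pixel_size > 0:
        raise ParameterError("target_pixel_size must be positive")
    if target_pixel_size == image.pixel_size:
        return QuadratImage(
            image.pixels.copy(), image.pixel_size, image.quadrat_mask.copy(),
            quadrat_id=image.quadrat_id, year=image.year,
        )
    h, w = image.shape
    w_m, h_m = image.extent
    out_h = max(1, int(round(h_m / target_pixel_size)))
    out_w = max(1, int(round(w_m / target_pixel_size)))
    rows = np.minimum(((np.arange(out_h) + 0.5) * target_pixel_size / image.pixel_size).astype(int), h - 1)
    cols = np.minimum(((np.arange(out_w) + 0.5) * target_pixel_size / image.pixel_size).astype(int), w - 1)
    pixels = image.pixels[np.ix_(rows, cols)]
    mask = image.quadrat_mask[np.ix_(rows, cols)]
    return QuadratImage(pixels, target_pixel_size, mask, quadrat_id=image.quadrat_id, year=image.year)


def rasterize_masks(masks: MaskSet, image: QuadratImage) -> np.ndarray:
    """Label raster of masked classes over the image extent.

    Returns an (H, W) array of small ints: 0 = unmasked, i >= 1 = the i-th
    layer of :data:`mossquad.schema.MASK_LAYERS`. Overlaps resolve by the
    fixed layer precedence (earlier layers win), applied by painting layers
    in reverse precedence order so higher-precedence layers overwrite.
    """
    out = np.zeros(image.shape, dtype=np.uint8)
    for idx in range(len(MASK_LAYERS) - 1, -1, -1):
        name = MASK_LAYERS[idx]
        for geom in masks.layers.get(name, []):
            hit = rasterize_polygon(geom, image.shape, image.pixel_size)
            out[hit] = idx + 1
    return out


def make_point_grid(image: QuadratImage, spacing: float = DEFAULT_GRID_SPACING) -> PointGrid:
    """Regular point grid at ``spacing`` meters covering the image extent.

    Points sit at the centers of spacing-sized cells, giving
    floor(width/spacing) x floor(height/spacing) points.
    """
    if spacing < image.pixel_size:
        raise ParameterError(
            f"grid spacing {spacing} m is finer than the pixel size {image.pixel_size} m"
        )
    w_m, h_m = image.extent
    nx = int(w_m / spacing + 1e-9)
    ny = int(h_m / spacing + 1e-9)
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return PointGrid(spacing=spacing, points=pts)


def sample_raster_at_points(raster: np.ndarray, pixel_size: float, grid: PointGrid) -> np.ndarray:
    """Value of the pixel containing each grid point (deterministic lookup)."""
    cols = np.clip((grid.points[:, 0] / pixel_size).astype(int), 0, raster.shape[1] - 1)
    rows = np.clip((grid.points[:, 1] / pixel_size).astype(int), 0, raster.shape[0] - 1)
    return raster[rows, cols]


# ---------------------------------------------------------------------------
# GeoJSON masks
# ---------------------------------------------------------------------------

def _geojson_features(doc: dict) -> list[dict]:
    if doc.get("type") == "FeatureCollection":
        return list(doc.get("features", []))
    if doc.get("type") == "Feature":
        return [doc]
    # bare geometry
    return [{"type": "Feature", "properties": {}, "geometry": doc}]


def load_masks_geojson(paths: dict[str, str | Path] | str | Path) -> MaskSet:
    """Read mask polygons from GeoJSON.

    Accepts either a mapping {layer_name: path} (one file per layer) or a
    single path whose features carry a ``layer`` property. Coordinates are
    in the image's meter frame.
    """
    layers: dict[str, list[BaseGeometry]] = {}
    if isinstance(paths, (str, Path)):
        doc = json.loads(Path(paths).read_text())
        for feat in _geojson_features(doc):
            name = (feat.get("properties") or {}).get("layer")
            if name is None:
                raise SchemaError("GeoJSON feature lacks a 'layer' property")
            if name not in MASK_LAYERS:
                raise SchemaError(f"unknown mask layer {name!r}")
            layers.setdefault(name, []).append(shapely_shape(feat["geometry"]))
    else:
        for name, p in paths.items():
            if name not in MASK_LAYERS:
                raise SchemaError(f"unknown mask layer {name!r}")
            doc = json.loads(Path(p).read_text())
            geoms = [shapely_shape(f["geometry"]) for f in _geojson_features(doc)]
            layers.setdefault(name, []).extend(geoms)
    return MaskSet(layers=layers)


def load_quadrat_polygon(path: str | Path) -> BaseGeometry:
    """Read the quadrat-interior polygon from a GeoJSON file (first feature)."""
    doc = json.loads(Path(path).read_text())
    feats = _geojson_features(doc)
    if not feats:
        raise GeometryError(f"{path}: no features")
    return shapely_shape(feats[0]["geometry"])


# ---------------------------------------------------------------------------
# Saving
# ---------------------------------------------------------------------------

def save_image_png(image: QuadratImage, path: str | Path) -> None:
    """Lossless PNG export of the RGB bands."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path), format="PNG")


#: Palette (RGB) used for paletted class-raster exports, one entry per class code.
CLASS_PALETTE = np.array(
    [
        (0, 0, 0),        # outside_quadrat
        (60, 170, 60),    # healthy_moss
        (190, 90, 40),    # stressed_moss
        (105, 100, 95),   # moribund_moss
        (225, 220, 170),  # lichen
        (170, 170, 170),  # rock
        (245, 245, 255),  # snow
        (50, 90, 180),    # water
        (30, 90, 50),     # wet_moss
        (35, 30, 45),     # shadow
        (255, 0, 255),    # unclassified
    ],
    dtype=np.uint8,
)


def save_class_raster(labels: np.ndarray, path: str | Path) -> None:
    """Write a class-code raster as paletted PNG or single-band TIFF by suffix."""
    path = Path(path)
    labels = np.asarray(labels, dtype=np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, labels)
    else:
        im = Image.fromarray(labels, mode="P")
        im.putpalette(CLASS_PALETTE.ravel().tolist())
        im.save(path, format="PNG")


def load_class_raster(path: str | Path) -> np.ndarray:
    """Read a class-code raster written by :func:`save_class_raster`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    with Image.open(path) as im:
        return np.asarray(im)
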