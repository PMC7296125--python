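"""Deterministic synthetic quadrat photographs with ground-truth labels.

The generator emulates the color structure the classifier assumes: moss
turf in three health/color states (bright green/olive healthy moss,
red/brown stressed moss, gray/black moribund moss) plus rock, snow,
shadow and the other schema classes, arranged as contiguous irregular
patches. Space is partitioned by seeded region growth (random-priority
multi-source flood fill), which produces the ragged turf-boundary shapes
segmentation must handle; patches are assigned to classes to hit the
requested cover fractions; pixel colors are drawn from per-class RGB
models with patch-level mean jitter and per-pixel noise; an optional
contiguous shadow region darkens the image, and small bright "wind-blown
rock" blobs can be inserted inside healthy patches.

All randomness flows from a single integer seed through numpy
SeedSequence spawning, so the same seed gives bit-identical output. It is
emphatically not photorealistic: no illumination field beyond the flat
shadow multiplier, no camera response, no mixed-class gradient pixels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import ClassMap
from .raster_io import DEFAULT_PIXEL_SIZE, QuadratImage
from .schema import CLASS_CODE, CLASS_NAMES, PROVENANCE_CODE, SchemaError


class GenerationError(ValueError):
    """Requested composition cannot be realized (with a diagnostic)."""


#: Default per-class color models: mean RGB and per-band standard deviation
#: of the patch means. Healthy moss is bright green/olive, stressed moss
#: red/brown, moribund moss gray/black; rock mid-gray, snow near-white,
#: shadow near-black, water dark blue, wet moss very dark green, lichen pale.
DEFAULT_COLOR_MODELS: dict[str, tuple[tuple[float, float, float], float]] = {
    "healthy_moss": ((80, 130, 45), 10.0),
    "stressed_moss": ((150, 75, 45), 10.0),
    "moribund_moss": ((95, 90, 85), 8.0),
    "lichen": ((205, 200, 185), 8.0),
    "rock": ((170, 168, 165), 8.0),
    "snow": ((240, 240, 245), 4.0),
    "water": ((40, 60, 90), 8.0),
    "wet_moss": ((35, 60, 30), 6.0),
    "shadow": ((25, 24, 26), 3.0),
}

#: Default cover composition: a three-state moss turf with some rock.
DEFAULT_COVER_FRACTIONS: dict[str, float] = {
    "healthy_moss": 0.45,
    "stressed_moss": 0.25,
    "moribund_moss": 0.25,
    "rock": 0.05,
}

#: Multiplier applied to RGB under the synthetic shadow region.
SHADOW_MULTIPLIER = 0.22


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic quadrat."""

    size_px: tuple[int, int] = (96, 96)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    cover_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVER_FRACTIONS))
    class_color_models: dict[str, tuple[tuple[float, float, float], float]] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_MODELS))
    patch_scale: int = 12          # characteristic patch diameter, pixels
    shadow_fraction: float = 0.0
    small_rock_count: int = 0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cover_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"cover fractions sum to {total}, expected 1")
        for cls, frac in self.cover_fractions.items():
            if cls not in CLASS_NAMES:
                raise SchemaError(f"unknown class {cls!r}")
            if frac < 0:
                raise GenerationError(f"negative fraction for {cls}")
        for cls, (mean, _sd) in self.class_color_models.items():
            if any(not (0 <= m <= 255) for m in mean):
                raise GenerationError(f"color mean for {cls} outside 0-255")
        if self.patch_scale < 2:
            raise GenerationError("patch_scale must be >= 2 pixels")
        if not (0 <= self.shadow_fraction < 1):
            raise GenerationError("shadow_fraction must be in [0, 1)")


@dataclass
class SyntheticQuadrat:
    image: QuadratImage
    truth: ClassMap
    realized_fractions: dict[str, float]


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

def _grow_patches(shape: tuple[int, int], n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Random-priority multi-source flood fill: (H, W) patch-id raster."""
    h, w = shape
    labels = np.full((h, w), -1, dtype=int)
    seeds = rng.choice(h * w, size=n_seeds, replace=False)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for pid, s in enumerate(seeds.tolist()):
        heapq.heappush(heap, (rng.random(), counter, s, pid))
        counter += 1
    n_assigned = 0
    while heap:
        _, _, pos, pid = heapq.heappop(heap)
        if labels.flat[pos] != -1:
            continue
        labels.flat[pos] = pid
        n_assigned += 1
        r, c = divmod(pos, w)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == -1:
                heapq.heappush(heap, (rng.random(), counter, rr * w + cc, pid))
                counter += 1
    assert n_assigned == h * w
    return labels


def _grow_single_region(shape: tuple[int, int], n_pixels: int,
                        rng: np.random.Generator) -> np.ndarray:
    """One contiguous random region of n_pixels (for the shadow)."""
    h, w = shape
    taken = np.zeros((h, w), dtype=bool)
    start = int(rng.integers(h * w))
    heap = [(0.0, 0, start)]
    counter = 1
    count = 0
    while heap and count < n_pixels:
        _, _, pos = heapq.heappop(heap)
        if taken.flat[pos]:
            continue
        taken.flat[pos] = True
        count += 1
        r, c = divmod(pos, w)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and not taken[rr, cc]:
                heapq.heappush(heap, (rng.random(), counter, rr * w + cc))
                counter += 1
    return taken


def _assign_patches(
    patch_sizes: np.ndarray,
    targets_px: dict[str, float],
    rng: np.random.Generator,
) -> list[str]:
    """Assign patches to classes to approach the target pixel counts.

    Greedy largest-patch-to-largest-deficit, then a local improvement
    sweep moving single patches wherever that reduces total |error|.
    """
    classes = list(targets_px)
    deficit = {c: float(targets_px[c]) for c in classes}
    order = np.argsort(-patch_sizes, kind="stable")
    assign: dict[int, str] = {}
    for p in order.tolist():
        best = max(classes, key=lambda c: deficit[c])
        assign[p] = best
        deficit[best] -= patch_sizes[p]
    # improvement sweeps
    err = {c: -deficit[c] for c in classes}  # realized - target
    for _ in range(10):
        improved = False
        for p in order.tolist():
            s = patch_sizes[p]
            c1 = assign[p]
            for c2 in classes:
                if c2 == c1:
                    continue
                delta = (abs(err[c1] - s) + abs(err[c2] + s)) - (abs(err[c1]) + abs(err[c2]))
                if delta < -1e-9:
                    assign[p] = c2
                    err[c1] -= s
                    err[c2] += s
                    c1 = c2
                    improved = True
        if not improved:
            break
    return [assign[p] for p in range(len(patch_sizes))]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _carve_to_targets(truth: np.ndarray, targets_px: dict[str, float],
                      rng: np.random.Generator, tol_frac: float = 0.005) -> None:
    """Move connected sub-regions between classes until realized cover is
    within ``tol_frac`` of every target (in place; contiguity preserved)."""
    from scipy import ndimage

    area = truth.size
    tol = tol_frac * area
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for _ in range(30):
        counts = np.bincount(truth.ravel(), minlength=len(CLASS_NAMES))
        err = {c: counts[CLASS_CODE[c]] - targets_px[c] for c in targets_px}
        c_over = max(err, key=err.get)
        c_under = min(err, key=err.get)
        if err[c_over] <= tol or err[c_under] >= -tol:
            return
        amount = int(round(min(err[c_over], -err[c_under])))
        comp, n_comp = ndimage.label(truth == CLASS_CODE[c_over], structure=structure)
        comp_sizes = np.bincount(comp.ravel())[1:]
        big = int(np.argmax(comp_sizes)) + 1
        sel = comp == big
        if n_comp == 1 and amount >= comp_sizes[big - 1]:
            amount = int(comp_sizes[big - 1]) - 1  # keep the class represented
        if comp_sizes[big - 1] <= amount:
            truth[sel] = CLASS_CODE[c_under]
            continue
        # grow a connected sub-region of `amount` pixels from a component edge
        h, w = truth.shape
        edge = sel & ~ndimage.binary_erosion(sel, structure=structure)
        starts = np.flatnonzero(edge.ravel())
        start = int(rng.choice(starts))
        taken = np.zeros((h, w), dtype=bool)
        heap = [(0.0, 0, start)]
        counter = 1
        count = 0
        while heap and count < amount:
            _, _, pos = heapq.heappop(heap)
            if taken.flat[pos] or not sel.flat[pos]:
                continue
            taken.flat[pos] = True
            count += 1
            r, c = divmod(pos, w)
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < h and 0 <= cc < w and sel[rr, cc] and not taken[rr, cc]:
                    heapq.heappush(heap, (rng.random(), counter, rr * w + cc))
                    counter += 1
        truth[taken] = CLASS_CODE[c_under]


def _render_colors(truth: np.ndarray, spec: GeneratorSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Float RGB raster: one mean draw per connected class region + noise."""
    from scipy import ndimage

    h, w = truth.shape
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    img = np.empty((h, w, 3), dtype=float)
    for code in np.unique(truth):
        cls = CLASS_NAMES[code]
        mean, sd = spec.class_color_models[cls]
        comp, n_comp = ndimage.label(truth == code, structure=structure)
        means = np.asarray(mean, dtype=float) + rng.normal(0.0, sd, size=(n_comp, 3))
        for ci in range(1, n_comp + 1):
            img[comp == ci] = means[ci - 1]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def _build_truth(spec: GeneratorSpec, rng_tess: np.random.Generator,
                 rng_assign: np.random.Generator) -> np.ndarray:
    """Tessellate, assign classes, and carve to the requested fractions."""
    h, w = spec.size_px
    area = h * w
    n_seeds = max(len([f for f in spec.cover_fractions.values() if f > 0]),
                  int(round(area / spec.patch_scale ** 2)))
    if n_seeds > area:
        raise GenerationError("patch_scale too small for the raster size")
    patches = _grow_patches((h, w), n_seeds, rng_tess)
    sizes = np.bincount(patches.ravel(), minlength=n_seeds)
    targets = {c: f * area for c, f in spec.cover_fractions.items() if f > 0}
    patch_class = _assign_patches(sizes, targets, rng_assign)
    truth = np.empty((h, w), dtype=np.uint8)
    for pid, cls in enumerate(patch_class):
        truth[patches == pid] = CLASS_CODE[cls]
    _carve_to_targets(truth, targets, rng_assign)
    for cls, frac in spec.cover_fractions.items():
        if frac > 0 and not np.any(truth == CLASS_CODE[cls]):
            raise GenerationError(
                f"class {cls} (fraction {frac:.3f}) received no patch; "
                f"decrease patch_scale (currently {spec.patch_scale}) or raise the fraction"
            )
    return truth


def generate_quadrat(spec: GeneratorSpec, quadrat_id: str = "SYN", year: int = 0
                     ) -> SyntheticQuadrat:
    """Render one synthetic quadrat (image + truth labels + realized cover)."""
    h, w = spec.size_px
    area = h * w
    ss = np.random.SeedSequence(spec.seed)
    rng_tess, rng_assign, rng_color, rng_extras = (
        np.random.default_rng(s) for s in ss.spawn(4))

    truth = _build_truth(spec, rng_tess, rng_assign)
    img = _render_colors(truth, spec, rng_color)

    # contiguous shadow region: darken and relabel
    if spec.shadow_fraction > 0:
        n_shadow = int(round(spec.shadow_fraction * area))
        region = _grow_single_region((h, w), n_shadow, rng_extras)
        img[region] *= SHADOW_MULTIPLIER
        truth[region] = CLASS_CODE["shadow"]

    # small wind-blown rocks inside healthy patches
    if spec.small_rock_count > 0:
        healthy = np.flatnonzero(truth.ravel() == CLASS_CODE["healthy_moss"])
        if len(healthy) == 0:
            raise GenerationError("small rocks requested but no healthy moss present")
        mean, sd = spec.class_color_models.get("rock", DEFAULT_COLOR_MODELS["rock"])
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(spec.small_rock_count):
            pos = int(rng_extras.choice(healthy))
            r, c = divmod(pos, w)
            radius = float(rng_extras.uniform(1.0, 2.2))  # area <= ~15 px
            blob = (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2
            blob &= truth == CLASS_CODE["healthy_moss"]
            img[blob] = np.asarray(mean, dtype=float) + rng_extras.normal(0, 2, 3)
            truth[blob] = CLASS_CODE["rock"]

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    qmask = np.ones((h, w), dtype=bool)
    image = QuadratImage(pixels, spec.pixel_size, qmask, quadrat_id=quadrat_id, year=year)
    classmap = ClassMap(labels=truth,
                        provenance=np.zeros((h, w), dtype=np.uint8))

    counts = np.bincount(truth.ravel(), minlength=len(CLASS_NAMES))
    realized = {cls: counts[CLASS_CODE[cls]] / area
                for cls in CLASS_NAMES if counts[CLASS_CODE[cls]] > 0}
    if spec.shadow_fraction == 0 and spec.small_rock_count == 0:
        for cls, frac in spec.cover_fractions.items():
            if frac >= 0.05 and abs(realized.get(cls, 0.0) - frac) > 0.02:
                raise GenerationError(
                    f"realized cover of {cls} ({realized.get(cls, 0.0):.3f}) misses the "
                    f"request ({frac:.3f}) by more than 2 points; decrease patch_scale"
                )
    return SyntheticQuadrat(image=image, truth=classmap, realized_fractions=realized)


def _shift_fractions(base: dict[str, float], effects: dict[str, float]) -> dict[str, float]:
    out = dict(base)
    for cls, delta in effects.items():
        out[cls] = out.get(cls, 0.0) + delta
        if out[cls] < -1e-12:
            raise GenerationError(f"year effect drives {cls} cover negative ({out[cls]:.3f})")
        out[cls] = max(out[cls], 0.0)
    total = sum(out.values())
    return {c: f / total for c, f in out.items()}


def generate_time_series(
    base_spec: GeneratorSpec,
    year_effects: dict[int, dict[str, float]],
    n_quadrats: int,
    seed: int = 0,
    render_images: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, int], SyntheticQuadrat]]:
    """Independent synthetic quadrats per (quadrat, year) plus a cover table.

    ``year_effects`` maps each year to per-class cover-fraction shifts
    (renormalized after shifting). The returned long-format table holds
    the truth cover percentages. With ``render_images`` false only truth
    tessellations are produced (colors skipped), which is what the change
    statistics consume.
    """
    rows = []
    quadrats: dict[tuple[str, int], SyntheticQuadrat] = {}
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(n_quadrats * len(year_effects) * 2, dtype=np.uint32))
    for qi in range(n_quadrats):
        qid = f"Q{qi + 1:02d}"
        for year in sorted(year_effects):
            fractions = _shift_fractions(base_spec.cover_fractions, year_effects[year])
            sub_seed = int(next(child))
            next(child)  # reserve one state per cell for future use
            spec = replace(base_spec, cover_fractions=fractions, seed=sub_seed)
            if render_images:
                sq = generate_quadrat(spec, quadrat_id=qid, year=year)
                quadrats[(qid, year)] = sq
                realized = sq.realized_fractions
            else:
                realized = _truth_fractions_only(spec)
            for cls, frac in realized.items():
                rows.append((qid, year, cls, 100.0 * frac))
    table = pd.DataFrame(rows, columns=["quadrat_id", "year", "class", "percent"])
    return table, quadrats


def _truth_fractions_only(spec: GeneratorSpec) -> dict[str, float]:
    """Realized truth fractions without color rendering (fast path).

    Uses the same tessellation and assignment streams as
    :func:`generate_quadrat`, so fractions match a rendered quadrat with
    the same spec (shadow/rock extras excluded).
    """
    area = spec.size_px[0] * spec.size_px[1]
    ss = np.random.SeedSequence(spec.seed)
    rng_tess, rng_assign = (np.random.default_rng(s) for s in ss.spawn(4)[:2])
    truth = _build_truth(spec, rng_tess, rng_assign)
    counts = np.bincount(truth.ravel(), minlength=len(CLASS_NAMES))
    return {cls: counts[CLASS_CODE[cls]] / area
            for cls in CLASS_NAMES if counts[CLASS_CODE[cls]] > 0}
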