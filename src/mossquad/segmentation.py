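"""Multiresolution region-merging segmentation and scale selection.

Bottom-up segmentation in the Baatz–Schäpe family: starting from
single-pixel objects, adjacent objects merge while the increase in
weighted heterogeneity stays below a squared scale threshold:

    f = (1 - shape_weight) * dh_color + shape_weight * dh_shape  <  scale**2

    dh_color = sum_bands w_b * (n_m * sigma_m - n_1 * sigma_1 - n_2 * sigma_2)
    dh_shape = compactness_weight * dh_cmpct + (1 - compactness_weight) * dh_smooth
    dh_cmpct = l_m * sqrt(n_m) - l_1 * sqrt(n_1) - l_2 * sqrt(n_2)
    dh_smooth = n_m * l_m / b_m - n_1 * l_1 / b_1 - n_2 * l_2 / b_2

with n the object area in pixels, sigma the per-band standard deviation,
l the perimeter in pixel edges, b the bounding-box perimeter, and equal
band weights w_b = 1. Merging uses local mutual best fitting: A merges
with B only when B is A's lowest-cost neighbor and vice versa, with ties
broken toward the smaller object id and objects treated in ascending-id
sweeps — the procedure is fully deterministic. 4-connectivity throughout;
merges never cross a thematic-mask boundary.

Scale selection follows the estimation-of-scale-parameter idea: segment
across a range of scales, record the local variance LV (mean over objects
of the within-object standard deviation of the brightness band) and its
rate of change ROC; peaks in ROC mark candidate scales. LV is computed
per object level (the definition that yields a scale-indexed curve),
not as a fixed moving-window statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster_io import GeometryError, ParameterError

#: Segmentation parameter defaults used throughout the pipeline
#: (scale 27, shape 0.1, compactness 0.5).
DEFAULT_SCALE = 27.0
DEFAULT_SHAPE_WEIGHT = 0.1
DEFAULT_COMPACTNESS_WEIGHT = 0.5


@dataclass(frozen=True)
class SegmentationParams:
    scale: float = DEFAULT_SCALE
    shape_weight: float = DEFAULT_SHAPE_WEIGHT
    compactness_weight: float = DEFAULT_COMPACTNESS_WEIGHT

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ParameterError("scale must be positive")
        if not (0 <= self.shape_weight < 1):
            raise ParameterError("shape_weight must be in [0, 1)")
        if not (0 <= self.compactness_weight <= 1):
            raise ParameterError("compactness_weight must be in [0, 1]")


@dataclass
class SegmentationResult:
    """Label raster plus region-adjacency and per-object statistics.

    ``labels`` holds contiguous object ids from 1; ``adjacency[a][b]`` is
    the shared border length in pixel edges (symmetric); ``object_stats``
    is a DataFrame indexed by object id with per-band mean/std, area_px
    and perimeter (pixel edges, image border included).
    """

    labels: np.ndarray
    n_objects: int
    adjacency: dict[int, dict[int, int]]
    object_stats: pd.DataFrame
    params: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass
class EspCurve:
    scales: list[float]
    lv: list[float]
    roc: list[float]  # roc[0] is NaN (undefined); NaN where LV_{l-1} == 0


# ---------------------------------------------------------------------------
# Core merging engine
# ---------------------------------------------------------------------------

class _Regions:
    """Mutable region bookkeeping over a (H, W, B) feature raster."""

    def __init__(self, features: np.ndarray, mask_labels: np.ndarray | None):
        h, w, nb = features.shape
        n = h * w
        self.h, self.w, self.nb = h, w, nb
        flat = features.reshape(n, nb).astype(float)
        self.n = np.ones(n, dtype=np.int64)
        self.sum = flat.copy()
        self.sumsq = flat ** 2
        self.perim = np.full(n, 4, dtype=np.int64)
        rows, cols = np.divmod(np.arange(n), w)
        self.minr = rows.copy()
        self.maxr = rows.copy()
        self.minc = cols.copy()
        self.maxc = cols.copy()
        self.alive = np.ones(n, dtype=bool)
        self.parent = np.arange(n)
        if mask_labels is None:
            self.mask = np.zeros(n, dtype=np.int64)
        else:
            self.mask = np.asarray(mask_labels).reshape(n).astype(np.int64)
        # adjacency as dict-of-dicts, border length in pixel edges
        self.adj: list[dict[int, int]] = [dict() for _ in range(n)]
        idx = np.arange(n).reshape(h, w)
        for a, b in zip(idx[:, :-1].ravel(), idx[:, 1:].ravel()):
            self.adj[a][b] = 1
            self.adj[b][a] = 1
        for a, b in zip(idx[:-1, :].ravel(), idx[1:, :].ravel()):
            self.adj[a][b] = 1
            self.adj[b][a] = 1

    # -- cost ---------------------------------------------------------------

    def _sigma_n(self, ids: np.ndarray) -> np.ndarray:
        """n * sigma summed over bands for the given object ids."""
        n = self.n[ids, None]
        var = np.maximum(self.sumsq[ids] / n - (self.sum[ids] / n) ** 2, 0.0)
        return (n.ravel()[:, None] * np.sqrt(var)).sum(axis=1)

    def merge_costs(self, a: np.ndarray, b: np.ndarray, border: np.ndarray,
                    params: SegmentationParams) -> np.ndarray:
        """Vectorized fusion cost for candidate pairs (a, b)."""
        na = self.n[a].astype(float)
        nbm = self.n[b].astype(float)
        nm = na + nbm
        sum_m = self.sum[a] + self.sum[b]
        sumsq_m = self.sumsq[a] + self.sumsq[b]
        var_m = np.maximum(sumsq_m / nm[:, None] - (sum_m / nm[:, None]) ** 2, 0.0)
        h_color_m = (nm[:, None] * np.sqrt(var_m)).sum(axis=1)
        dh_color = h_color_m - self._sigma_n(a) - self._sigma_n(b)

        cost = (1.0 - params.shape_weight) * dh_color
        if params.shape_weight > 0:
            la = self.perim[a].astype(float)
            lb = self.perim[b].astype(float)
            lm = la + lb - 2.0 * border
            bb_a = 2.0 * ((self.maxr[a] - self.minr[a] + 1) + (self.maxc[a] - self.minc[a] + 1))
            bb_b = 2.0 * ((self.maxr[b] - self.minr[b] + 1) + (self.maxc[b] - self.minc[b] + 1))
            minr = np.minimum(self.minr[a], self.minr[b])
            maxr = np.maximum(self.maxr[a], self.maxr[b])
            minc = np.minimum(self.minc[a], self.minc[b])
            maxc = np.maximum(self.maxc[a], self.maxc[b])
            bb_m = 2.0 * ((maxr - minr + 1) + (maxc - minc + 1))
            dh_cmpct = lm * np.sqrt(nm) - la * np.sqrt(na) - lb * np.sqrt(nbm)
            dh_smooth = nm * lm / bb_m - na * la / bb_a - nbm * lb / bb_b
            dh_shape = (params.compactness_weight * dh_cmpct
                        + (1.0 - params.compactness_weight) * dh_smooth)
            cost = cost + params.shape_weight * dh_shape
        return cost

    # -- merging ------------------------------------------------------------

    def merge(self, a: int, b: int) -> None:
        """Merge object b into a (a < b); updates stats and adjacency."""
        border = self.adj[a].pop(b)
        self.adj[b].pop(a)
        self.n[a] += self.n[b]
        self.sum[a] += self.sum[b]
        self.sumsq[a] += self.sumsq[b]
        self.perim[a] += self.perim[b] - 2 * border
        self.minr[a] = min(self.minr[a], self.minr[b])
        self.maxr[a] = max(self.maxr[a], self.maxr[b])
        self.minc[a] = min(self.minc[a], self.minc[b])
        self.maxc[a] = max(self.maxc[a], self.maxc[b])
        for nb, length in self.adj[b].items():
            self.adj[a][nb] = self.adj[a].get(nb, 0) + length
            del self.adj[nb][b]
            self.adj[nb][a] = self.adj[nb].get(a, 0) + length
        self.adj[b].clear()
        self.alive[b] = False
        self.parent[b] = a

    def sweep(self, params: SegmentationParams) -> int:
        """One local-mutual-best-fitting pass; returns number of merges."""
        alive_ids = np.flatnonzero(self.alive)
        ea, eb, ebord = [], [], []
        for a in alive_ids:
            mask_a = self.mask[a]
            for b, length in self.adj[a].items():
                if b > a and self.mask[b] == mask_a:
                    ea.append(a)
                    eb.append(b)
                    ebord.append(length)
        if not ea:
            return 0
        ea = np.asarray(ea)
        eb = np.asarray(eb)
        ebord = np.asarray(ebord, dtype=float)
        cost = self.merge_costs(ea, eb, ebord, params)

        # best neighbor per object: min cost, tie -> smaller neighbor id
        obj = np.concatenate([ea, eb])
        nbr = np.concatenate([eb, ea])
        cc = np.concatenate([cost, cost])
        order = np.lexsort((nbr, cc, obj))
        obj_s, nbr_s, cc_s = obj[order], nbr[order], cc[order]
        first = np.ones(len(obj_s), dtype=bool)
        first[1:] = obj_s[1:] != obj_s[:-1]
        best_of = dict(zip(obj_s[first].tolist(), nbr_s[first].tolist()))
        best_cost = dict(zip(obj_s[first].tolist(), cc_s[first].tolist()))

        threshold = params.scale ** 2
        merges = 0
        for a in alive_ids:
            if not self.alive[a]:
                continue
            b = best_of.get(int(a))
            if b is None or not self.alive[b]:
                continue
            if best_of.get(b) != int(a):
                continue
            if best_cost[int(a)] >= threshold:
                continue
            lo, hi = (int(a), b) if a < b else (b, int(a))
            self.merge(lo, hi)
            merges += 1
        return merges

    # -- output -------------------------------------------------------------

    def root(self) -> np.ndarray:
        parent = self.parent
        # path compression by repeated indexing (parent pointers form a DAG
        # of bounded depth but iterate to the fixpoint to be safe)
        r = parent.copy()
        while True:
            rr = parent[r]
            if np.array_equal(rr, r):
                return r
            r = rr


def multiresolution_segment(
    features: np.ndarray,
    params: SegmentationParams | None = None,
    thematic_masks: np.ndarray | None = None,
    max_sweeps: int = 10_000,
) -> SegmentationResult:
    """Segment a multi-band raster into homogeneous objects.

    Parameters
    ----------
    features : (H, W, B) or (H, W) float-compatible array
    params : scale / shape / compactness weights
    thematic_masks : optional (H, W) integer raster; merges are confined
        to cells sharing a mask label, so mask boundaries are object
        boundaries in the result.
    """
    params = params or SegmentationParams()
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[:, :, None]
    if features.ndim != 3 or features.size == 0:
        raise GeometryError("features must be a non-empty (H, W, B) raster")
    if thematic_masks is not None and np.asarray(thematic_masks).shape != features.shape[:2]:
        raise GeometryError("thematic_masks shape does not match features")

    reg = _Regions(features, thematic_masks)
    for _ in range(max_sweeps):
        if reg.sweep(params) == 0:
            break

    roots = reg.root().reshape(reg.h, reg.w)
    # contiguous ids from 1, ordered by first (row-major) occurrence
    _, first_pos, inverse = np.unique(roots, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    labels = (order[inverse] + 1).reshape(reg.h, reg.w)

    alive_ids = np.flatnonzero(reg.alive)
    # internal root id -> output label, via first occurrence in the raster
    id_of: dict[int, int] = {}
    flat_roots = roots.ravel()
    flat_labels = labels.ravel()
    for rt, lb in zip(flat_roots.tolist(), flat_labels.tolist()):
        if rt not in id_of:
            id_of[rt] = lb

    adjacency: dict[int, dict[int, int]] = {id_of[int(a)]: {} for a in alive_ids}
    for a in alive_ids:
        la = id_of[int(a)]
        for b, length in reg.adj[int(a)].items():
            adjacency[la][id_of[int(b)]] = int(length)

    nb = reg.nb
    rows = []
    for a in alive_ids:
        n = int(reg.n[a])
        mean = reg.sum[a] / n
        var = np.maximum(reg.sumsq[a] / n - mean ** 2, 0.0)
        rows.append((id_of[int(a)], n, int(reg.perim[a]), *mean, *np.sqrt(var)))
    cols = (["object_id", "area_px", "perimeter"]
            + [f"mean_{i}" for i in range(nb)] + [f"std_{i}" for i in range(nb)])
    stats = pd.DataFrame(rows, columns=cols).set_index("object_id").sort_index()

    return SegmentationResult(
        labels=labels, n_objects=int(labels.max()), adjacency=adjacency,
        object_stats=stats, params=params,
    )


# ---------------------------------------------------------------------------
# Scale selection
# ---------------------------------------------------------------------------

def esp_curve(
    features: np.ndarray,
    scale_min: float,
    scale_max: float,
    step: float,
    shape_weight: float = DEFAULT_SHAPE_WEIGHT,
    compactness_weight: float = DEFAULT_COMPACTNESS_WEIGHT,
    thematic_masks: np.ndarray | None = None,
) -> EspCurve:
    """Local variance and its rate of change across a range of scales.

    LV at a scale is the mean over objects of the within-object standard
    deviation of the brightness band (mean of all bands); ROC is the
    percent change of LV from the previous scale (NaN for the first entry
    and wherever the previous LV is zero).
    """
    if not (scale_min < scale_max):
        raise ParameterError("scale_min must be < scale_max")
    if not step > 0:
        raise ParameterError("step must be positive")
    features = np.asarray(features, dtype=float)
    if features.ndim == 2:
        features = features[:, :, None]
    brightness = features.mean(axis=2)

    scales = []
    s = scale_min
    while s <= scale_max + 1e-9:
        scales.append(round(s, 10))
        s += step
    lv: list[float] = []
    for sc in scales:
        seg = multiresolution_segment(
            features, SegmentationParams(sc, shape_weight, compactness_weight), thematic_masks
        )
        lab = seg.labels.ravel()
        br = brightness.ravel()
        cnt = np.bincount(lab)[1:]
        ssum = np.bincount(lab, weights=br)[1:]
        ssq = np.bincount(lab, weights=br ** 2)[1:]
        var = np.maximum(ssq / cnt - (ssum / cnt) ** 2, 0.0)
        lv.append(float(np.mean(np.sqrt(var))))
    roc = [float("nan")]
    for k in range(1, len(lv)):
        prev = lv[k - 1]
        roc.append(100.0 * (lv[k] - prev) / prev if prev != 0 else float("nan"))
    return EspCurve(scales=scales, lv=lv, roc=roc)


def detect_scale_peaks(curve: EspCurve) -> list[float]:
    """Scales at strict local maxima of ROC, ordered by descending ROC.

    A plateau of equal adjacent maxima reports its smallest scale once.
    Returns an empty list when fewer than three ROC values are defined or
    ROC is monotone.
    """
    roc = np.asarray(curve.roc, dtype=float)
    scales = np.asarray(curve.scales, dtype=float)
    defined = ~np.isnan(roc)
    if defined.sum() < 3:
        return []
    idx = np.flatnonzero(defined)
    r = roc[idx]
    peaks = []
    k = 1
    while k < len(r) - 1:
        if r[k] > r[k - 1]:
            # extend over a plateau
            j = k
            while j + 1 < len(r) and r[j + 1] == r[k]:
                j += 1
            if j < len(r) - 1 and r[j + 1] < r[k]:
                peaks.append((float(r[k]), float(scales[idx[k]])))
                k = j + 1
                continue
            k = j + 1
        else:
            k += 1
    peaks.sort(key=lambda t: (-t[0], t[1]))
    return [s for _, s in peaks]
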