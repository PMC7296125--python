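"""Per-pixel and per-object spectral features for moss-health classification.

The classifier works on brightness-invariant color descriptors rather than
raw band values, because quadrat photographs span different cameras and
lighting:

* pixel-based band ratios PbR = band / (R + G + B);
* HSI channels (arccos hue, saturation 1 - min/I, intensity (R+G+B)/3);
* a death index  PbR_B / (PbR_G * PbR_R)      — high for gray/black moribund moss;
* a second death index  I / (S * PbR_R * PbR_G) — low for dark saturated moribund moss;
* a stress index  PbR_R / PbR_G               — high for reddened stressed moss;
* a luminance  0.2126*PbR_R + 0.7152*PbR_G + 0.0722*PbR_B (Rec. 709 weights)
  used with intensity to find shadows (both low) and small bright rocks
  (both high).

Thresholds between classes are chosen between Jenks natural-breaks
categories of a feature's object-level distribution; the exact
Fisher–Jenks dynamic program lives here too.

Undefined values (black pixels, achromatic pixels for the saturation-based
index) are returned as NaN and excluded from the rules that use them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Luminance weights (Rec. 709) applied to the band ratios.
LUMINANCE_WEIGHTS = (0.2126, 0.7152, 0.0722)

#: Saturation guard below which the saturation-based death index is undefined.
SATURATION_EPS = 1e-6

#: Number of natural-breaks categories used when proposing rule thresholds.
DEFAULT_JENKS_CLASSES = 15

#: Largest input size for which the exact Fisher–Jenks DP runs; above this,
#: values are deterministically subsampled to this many order statistics.
JENKS_EXACT_LIMIT = 20_000

FEATURE_NAMES = (
    "pbr_r", "pbr_g", "pbr_b", "hsi_h", "hsi_s", "hsi_i",
    "death1", "death2", "stress", "luminance",
)


# ---------------------------------------------------------------------------
# Band ratios and HSI
# ---------------------------------------------------------------------------

def band_ratios(r, g, b):
    """Pixel-based band ratios (PbR): each band over the band sum.

    Returns three arrays summing to 1 wherever the band sum is positive;
    black pixels (R+G+B == 0) yield NaN in all three ratios.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(r < 0) or np.any(g < 0) or np.any(b < 0):
        raise ValueError("band values must be non-negative")
    total = r + g + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, np.stack([r, g, b]) / total, np.nan)
    return out[0], out[1], out[2]


def rgb_to_hsi(r, g, b):
    """Standard arccos/bi-conic HSI transform.

    Bands are rescaled to [0, 1] internally (8-bit inputs divided by 255).
    Returns hue in degrees [0, 360), saturation in [0, 1], intensity in
    [0, 1]. Achromatic pixels (R=G=B, including black) get h=0, s=0.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if max(r.max(initial=0.0), g.max(initial=0.0), b.max(initial=0.0)) > 1.0:
        r, g, b = r / 255.0, g / 255.0, b / 255.0
    i = (r + g + b) / 3.0
    minband = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(i > 0, 1.0 - minband / np.where(i > 0, i, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    h = np.where(b > g, 360.0 - theta, theta)
    achromatic = den == 0
    h = np.where(achromatic, 0.0, h)
    h = np.where(h >= 360.0, h - 360.0, h)
    s = np.where(s < 1e-12, 0.0, s)  # exact zero on the achromatic axis
    return h, np.clip(s, 0.0, 1.0), i


def hsi_to_rgb(h, s, i):
    """Inverse of :func:`rgb_to_hsi` (sector formulation), for round-trip checks."""
    h = np.asarray(h, dtype=float) % 360.0
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    h, s, i = np.broadcast_arrays(h, s, i)
    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)

    def sector(hh):
        hr = np.radians(hh)
        first = i * (1 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
        third = i * (1 - s)
        return first, third

    m0 = h < 120.0
    m1 = (h >= 120.0) & (h < 240.0)
    m2 = h >= 240.0
    f, t = sector(h)
    r[m0], b[m0] = f[m0], t[m0]
    g[m0] = 3 * i[m0] - r[m0] - b[m0]
    f, t = sector(h - 120.0)
    g[m1], r[m1] = f[m1], t[m1]
    b[m1] = 3 * i[m1] - r[m1] - g[m1]
    f, t = sector(h - 240.0)
    b[m2], g[m2] = f[m2], t[m2]
    r[m2] = 3 * i[m2] - g[m2] - b[m2]
    return r, g, b


# ---------------------------------------------------------------------------
# Health indices
# ---------------------------------------------------------------------------

def death_index1(pbr_r, pbr_g, pbr_b):
    """PbR_B / (PbR_G * PbR_R); high values indicate moribund (gray/black) moss."""
    pbr_r = np.asarray(pbr_r, dtype=float)
    pbr_g = np.asarray(pbr_g, dtype=float)
    pbr_b = np.asarray(pbr_b, dtype=float)
    den = pbr_g * pbr_r
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, pbr_b / np.where(den > 0, den, 1.0), np.nan)


def death_index2(hsi_i, hsi_s, pbr_r, pbr_g, eps: float = SATURATION_EPS):
    """I / (S * PbR_R * PbR_G); low values indicate moribund moss.

    Undefined (NaN) wherever saturation <= eps — near-achromatic objects
    are routed to the shadow/rock intensity rules instead.
    """
    hsi_i = np.asarray(hsi_i, dtype=float)
    hsi_s = np.asarray(hsi_s, dtype=float)
    pbr_r = np.asarray(pbr_r, dtype=float)
    pbr_g = np.asarray(pbr_g, dtype=float)
    den = hsi_s * pbr_r * pbr_g
    ok = (hsi_s > eps) & (den > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, hsi_i / np.where(ok, den, 1.0), np.nan)


def stress_index(pbr_r, pbr_g):
    """PbR_R / PbR_G; high values indicate reddened, stressed moss."""
    pbr_r = np.asarray(pbr_r, dtype=float)
    pbr_g = np.asarray(pbr_g, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(pbr_g > 0, pbr_r / np.where(pbr_g > 0, pbr_g, 1.0), np.nan)


def luminance(pbr_r, pbr_g, pbr_b):
    """Rec. 709 weighted sum of the band ratios."""
    wr, wg, wb = LUMINANCE_WEIGHTS
    return wr * np.asarray(pbr_r, float) + wg * np.asarray(pbr_g, float) + wb * np.asarray(pbr_b, float)


# ---------------------------------------------------------------------------
# Feature stacks
# ---------------------------------------------------------------------------

@dataclass
class FeatureStack:
    """All per-pixel (or per-object) features as same-shaped float arrays."""

    pbr_r: np.ndarray
    pbr_g: np.ndarray
    pbr_b: np.ndarray
    hsi_h: np.ndarray
    hsi_s: np.ndarray
    hsi_i: np.ndarray
    death1: np.ndarray
    death2: np.ndarray
    stress: np.ndarray
    luminance: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def compute_features(r, g, b) -> FeatureStack:
    """Full feature stack from band values (any shape; 8-bit or [0,1])."""
    pr, pg, pb = band_ratios(r, g, b)
    h, s, i = rgb_to_hsi(r, g, b)
    return FeatureStack(
        pbr_r=pr, pbr_g=pg, pbr_b=pb,
        hsi_h=h, hsi_s=s, hsi_i=i,
        death1=death_index1(pr, pg, pb),
        death2=death_index2(i, s, pr, pg),
        stress=stress_index(pr, pg),
        luminance=luminance(pr, pg, pb),
    )


def object_features(mean_r, mean_g, mean_b) -> FeatureStack:
    """Object-level features from object *mean* band values.

    Ratios and indices are computed from the means (OBIA convention),
    not averaged over per-pixel indices — the two orders differ.
    """
    return compute_features(mean_r, mean_g, mean_b)


# ---------------------------------------------------------------------------
# Jenks natural breaks (exact Fisher dynamic program)
# ---------------------------------------------------------------------------

@dataclass
class BreaksResult:
    """Natural-breaks classification of a 1-D feature distribution.

    ``breaks`` holds the upper data value of each class except the last
    (len = n_classes - 1, strictly ascending); ``gvf`` is the
    goodness-of-variance fit 1 - SSD_within / SSD_total.
    """

    breaks: list[float]
    n_classes: int
    gvf: float
    empty_classes: int = 0


def _jenks_dp(values: np.ndarray, k: int) -> list[int]:
    """Exact Fisher–Jenks DP on sorted values; returns class end indices.

    Minimizes total within-class sum of squared deviations over all
    partitions of the sorted array into k contiguous classes. Ties are
    broken toward the smaller end index (lower break value).
    O(k n^2) time, O(k n) memory.
    """
    n = len(values)
    pref = np.concatenate([[0.0], np.cumsum(values)])
    pref2 = np.concatenate([[0.0], np.cumsum(values ** 2)])

    def ssd(i: int, j: int) -> np.ndarray:
        """Within-class SSD of values[i:j] for vector j (exclusive)."""
        cnt = j - i
        s = pref[j] - pref[i]
        s2 = pref2[j] - pref2[i]
        return s2 - s * s / np.maximum(cnt, 1)

    # cost[m][j] = optimal SSD of the first j values in m classes
    INF = np.inf
    cost = np.full(n + 1, INF)
    cost[0] = 0.0
    # first class: values[0:j]
    j_idx = np.arange(1, n + 1)
    cost[1:] = ssd(0, j_idx)
    back: list[np.ndarray] = [np.zeros(n + 1, dtype=int)]
    for m in range(2, k + 1):
        new = np.full(n + 1, INF)
        bk = np.zeros(n + 1, dtype=int)
        for j in range(m, n + 1):
            i_idx = np.arange(m - 1, j)  # last class is values[i:j]
            cand = cost[i_idx] + ssd(i_idx, j)
            best = int(np.argmin(cand))  # argmin returns first min: lower break
            new[j] = cand[best]
            bk[j] = i_idx[best]
        cost = new
        back.append(bk)
    # backtrack
    ends = []
    j = n
    for m in range(k, 1, -1):
        i = int(back[m - 1][j])
        ends.append(j)
        j = i
    ends.append(j)
    ends.reverse()  # ends[m] = exclusive end of class m (last entry == n)
    return ends


def jenks_breaks(values, n_classes: int) -> BreaksResult:
    """Optimal 1-D natural-breaks classification (exact Fisher–Jenks).

    ``values`` need not be sorted. With fewer distinct values than classes,
    each distinct value forms its own class and the shortfall is reported
    via ``empty_classes``. Inputs longer than :data:`JENKS_EXACT_LIMIT` are
    reduced to that many evenly spaced order statistics before the exact DP
    (deterministic).
    """
    vals = np.sort(np.asarray(values, dtype=float).ravel())
    vals = vals[~np.isnan(vals)]
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if len(vals) < n_classes:
        raise ValueError(f"need at least {n_classes} values, got {len(vals)}")
    total_ssd = float(np.sum((vals - vals.mean()) ** 2))

    distinct = np.unique(vals)
    empty = 0
    k = n_classes
    if len(distinct) < n_classes:
        empty = n_classes - len(distinct)
        k = len(distinct)
    if len(vals) > JENKS_EXACT_LIMIT:
        idx = np.linspace(0, len(vals) - 1, JENKS_EXACT_LIMIT).round().astype(int)
        work = vals[idx]
    else:
        work = vals
    if k == 1:
        return BreaksResult(breaks=[], n_classes=n_classes, gvf=0.0 if total_ssd > 0 else 0.0,
                            empty_classes=empty)
    ends = _jenks_dp(work, k)
    breaks = [float(work[e - 1]) for e in ends[:-1]]
    if work is vals:
        # exact: within-class SSD straight from the DP partition
        within = 0.0
        start = 0
        for e in ends:
            grp = vals[start:e]
            if len(grp):
                within += float(np.sum((grp - grp.mean()) ** 2))
            start = e
    else:
        # subsampled: evaluate the chosen breaks on the full data
        assign = np.searchsorted(np.asarray(breaks), vals, side="left")
        within = 0.0
        for c in range(k):
            grp = vals[assign == c]
            if len(grp):
                within += float(np.sum((grp - grp.mean()) ** 2))
    gvf = 1.0 - within / total_ssd if total_ssd > 0 else 0.0
    return BreaksResult(breaks=breaks, n_classes=n_classes, gvf=gvf, empty_classes=empty)
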