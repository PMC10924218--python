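"""Chromatin-density and nucleus-segmentation image analyses.

The imaging arm quantifies confocal images of transplanted nuclei stained
with a DNA dye (density / area) and HP1α (heterochromatin occupancy):

* :func:`huang_threshold` — fuzzy-entropy binarization of the DNA channel;
* :func:`recursive_watershed` — splits touching nuclei by marker-based
  watershed on the Euclidean distance map, recursing into oversized
  fragments with a decreasing h-maxima tolerance;
* :func:`iterative_otsu` — multi-level chromatin-density classification
  where each Otsu threshold is computed on the histogram restricted to
  values ≥ the previous threshold, yielding background / loose / middle /
  dense classes;
* :func:`hp1a_occupancy` — fraction of each density class covered by
  HP1α-positive signal;
* :func:`measure_chromatin_area` / :func:`compare_chromatin_areas` —
  per-cell chromatin areas and two-group comparison (fold change +
  Student's t-test).

All operations are deterministic: no randomized steps, ties resolved to
the lowest candidate threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

BACKGROUND, LOOSE, MIDDLE, DENSE = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", LOOSE: "loose", MIDDLE: "middle", DENSE: "dense"}


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def _as_histogram(image_or_hist, mask=None, n_levels: int = 256) -> np.ndarray:
    arr = np.asarray(image_or_hist)
    if arr.ndim == 1:  # already a histogram of counts per gray level
        return arr.astype(np.int64)
    values = arr[mask] if mask is not None else arr.ravel()
    return np.bincount(values.astype(np.intp).ravel(), minlength=n_levels)


def huang_threshold(image, mask=None) -> int:
    """Huang's fuzzy threshold of an 8-bit image (or histogram).

    For every candidate threshold t the image is split into a low class
    (levels ≤ t) and a high class (> t); each level's fuzzy membership to
    its class mean μ is u = 1 / (1 + |g − μ| / C) with C the gray-level
    range, and the candidate minimizing the total Shannon entropy
    −u·ln u − (1−u)·ln(1−u) weighted by the histogram wins. Ties resolve
    to the lowest level. Foreground is ``image > t``.
    """
    hist = _as_histogram(image, mask)
    levels = np.flatnonzero(hist)
    if levels.size < 2:
        raise ValueError("constant image: Huang threshold undefined")
    gmin, gmax = levels[0], levels[-1]
    c = float(gmax - gmin)
    g = np.arange(hist.size, dtype=float)
    w = hist.astype(float)
    cum_n = np.cumsum(w)
    cum_s = np.cumsum(w * g)
    total_n, total_s = cum_n[-1], cum_s[-1]

    best_t, best_s = None, np.inf
    for t in range(gmin, gmax):  # both classes non-empty
        n0 = cum_n[t]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = cum_s[t] / n0
        mu1 = (total_s - cum_s[t]) / n1
        mu = np.where(g <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(g - mu) / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        ent[~np.isfinite(ent)] = 0.0  # u == 1 contributes zero entropy
        s = float(np.dot(w, ent))
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return int(best_t)


def otsu_threshold(hist: np.ndarray, lower: int = 0) -> int:
    """Otsu split of a histogram restricted to levels ≥ ``lower``.

    Returns the smallest level T maximizing the between-class variance of
    the split {levels < T} vs {levels ≥ T} within the restricted
    histogram; pixels ≥ T form the upper class. Ties resolve to the
    lowest T.
    """
    h = np.asarray(hist, dtype=float).copy()
    h[:lower] = 0
    levels = np.flatnonzero(h)
    if levels.size < 2:
        raise ValueError("histogram has fewer than 2 occupied levels")
    g = np.arange(h.size, dtype=float)
    total_n = h.sum()
    total_s = float(np.dot(h, g))
    cum_n = np.cumsum(h)
    cum_s = np.cumsum(h * g)
    # candidate split points T: low class = levels < T (non-empty both sides)
    cand = np.arange(levels[0] + 1, levels[-1] + 1)
    n0 = cum_n[cand - 1]
    s0 = cum_s[cand - 1]
    n1 = total_n - n0
    valid = (n0 > 0) & (n1 > 0)
    mu0 = np.where(n0 > 0, s0 / np.maximum(n0, 1e-300), 0.0)
    mu1 = np.where(n1 > 0, (total_s - s0) / np.maximum(n1, 1e-300), 0.0)
    sigma_b = n0 * n1 * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    return int(cand[int(np.argmax(sigma_b))])


@dataclass
class DensityPartition:
    """Ordered intensity thresholds and the resulting density class map.

    ``thresholds`` = (t_bg, t_mid, t_dense), strictly increasing; pixels
    < t_bg are background, [t_bg, t_mid) loose, [t_mid, t_dense) middle,
    ≥ t_dense dense. Pixels outside the analysis mask are background.
    """

    thresholds: tuple[int, int, int]
    class_map: np.ndarray

    def class_areas(self) -> dict[int, int]:
        return {cls: int((self.class_map == cls).sum()) for cls in CLASS_NAMES}


def iterative_otsu(image, mask=None, n_classes: int = 3) -> DensityPartition:
    """Multi-level Otsu with iteratively restricted histograms.

    The first threshold is plain Otsu on the (masked) histogram; each
    subsequent threshold is Otsu on the histogram limited to values ≥ the
    previous threshold. With ``n_classes=3`` this yields a background cut
    plus two chromatin cuts, i.e. the three density classes loose /
    middle / dense.
    """
    image = np.asarray(image)
    hist = _as_histogram(image, mask)
    thresholds: list[int] = []
    lower = 0
    for _ in range(n_classes):
        t = otsu_threshold(hist, lower=lower)
        thresholds.append(t)
        lower = t  # restrict to values >= previous threshold (inclusive)
    if image.ndim == 1:
        class_map = None
    else:
        class_map = np.zeros(image.shape, dtype=np.int8)
        for t in thresholds:
            class_map[image >= t] += 1
        if mask is not None:
            class_map[~np.asarray(mask, dtype=bool)] = BACKGROUND
    return DensityPartition(thresholds=tuple(thresholds), class_map=class_map)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class WatershedParams:
    """Controls of the recursive distance-map watershed.

    ``tolerance_start=None`` starts each component at half its maximum
    distance-transform value (a conservative first split); the tolerance
    is multiplied by ``tolerance_decay`` at each recursion level down to
    ``tolerance_floor``. The size gate [min_area, max_area] decides what
    counts as an individual nucleus.
    """

    min_area: int = 600
    max_area: int = 1550
    tolerance_start: float | None = None
    tolerance_decay: float = 0.7
    tolerance_floor: float = 1.0
    max_depth: int = 8

    def validate(self) -> None:
        if not 0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if not 0 < self.tolerance_decay < 1:
            raise ValueError("tolerance_decay must be in (0,1)")
        if self.tolerance_floor <= 0:
            raise ValueError("tolerance_floor must be > 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class NucleusSegment:
    """One segmented nucleus."""

    label: int
    mask: np.ndarray
    area_px: int
    extraction_depth: int

    def area_um2(self, pixel_size_um: float) -> float:
        return self.area_px * pixel_size_um**2


@dataclass
class WatershedResult:
    """Segments plus the conservation bookkeeping of the recursion."""

    segments: list[NucleusSegment]
    unresolved: list[np.ndarray] = field(default_factory=list)
    discarded_small_px: int = 0
    foreground_px: int = 0

    def label_image(self, shape=None) -> np.ndarray:
        shape = shape if shape is not None else self.segments[0].mask.shape
        out = np.zeros(shape, dtype=np.uint16)
        for seg in self.segments:
            out[seg.mask] = seg.label
        return out

    @property
    def areas(self) -> list[int]:
        return [s.area_px for s in self.segments]


def _split_once(comp_mask: np.ndarray, tolerance: float) -> list[np.ndarray]:
    """One marker-based watershed pass; [] when no split is possible."""
    edt = ndimage.distance_transform_edt(comp_mask)
    markers_mask = h_maxima(edt, tolerance)
    markers, n_markers = ndimage.label(markers_mask)
    if n_markers < 2:
        return []
    labels = watershed(-edt, markers=markers, mask=comp_mask)
    return [labels == i for i in range(1, n_markers + 1)]


def recursive_watershed(mask: np.ndarray, params: WatershedParams | None = None) -> WatershedResult:
    """Segment a binary nucleus mask into individual nuclei.

    Connected components within the size gate are emitted at depth 0.
    Each oversized component is split by watershed on its Euclidean
    distance transform with markers from the h-maxima of the map at the
    current tolerance; fragments inside the gate are emitted, oversized
    fragments recurse with tolerance × decay, and whatever is still
    oversized when the tolerance floor or depth limit is reached is
    reported as unresolved (never silently dropped). Fragments below
    ``min_area`` are discarded and tallied.
    """
    params = params or WatershedParams()
    params.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    result = WatershedResult(segments=[], foreground_px=int(mask.sum()))

    def process(comp_mask: np.ndarray, depth: int, tolerance: float | None) -> None:
        area = int(comp_mask.sum())
        if area < params.min_area:
            result.discarded_small_px += area
            return
        if area <= params.max_area:
            result.segments.append(
                NucleusSegment(
                    label=len(result.segments) + 1,
                    mask=comp_mask,
                    area_px=area,
                    extraction_depth=depth,
                )
            )
            return
        if tolerance is None:
            edt_max = float(ndimage.distance_transform_edt(comp_mask).max())
            tolerance = max(edt_max / 2.0, params.tolerance_floor)
        if depth >= params.max_depth or tolerance < params.tolerance_floor:
            result.unresolved.append(comp_mask)
            return
        pieces = _split_once(comp_mask, tolerance)
        if not pieces:
            # no markers separate at this tolerance: decay and retry
            process(comp_mask, depth + 1, tolerance * params.tolerance_decay)
            return
        for piece in pieces:
            process(piece, depth + 1, tolerance * params.tolerance_decay)

    labeled, n_comp = ndimage.label(mask)
    for i in range(1, n_comp + 1):
        process(labeled == i, 0, params.tolerance_start)
    return result


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def measure_chromatin_area(
    segments: list[NucleusSegment] | WatershedResult,
    class_map: np.ndarray,
    pixel_size_um: float = 1.0,
) -> list[float]:
    """Per-cell chromatin area: non-background class pixels in each segment."""
    if isinstance(segments, WatershedResult):
        segments = segments.segments
    chromatin = np.asarray(class_map) > BACKGROUND
    return [float((chromatin & seg.mask).sum() * pixel_size_um**2) for seg in segments]


def compare_chromatin_areas(group_a: list[float], group_b: list[float]) -> dict[str, float]:
    """Two-group area comparison: means ± SD, fold change, Student's t.

    Uses the equal-variance two-sample t-test. Two degenerate zero-variance
    groups return p = 1.0 when the means agree (no difference) and 0.0
    when they differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    fold = float(b.mean() / a.mean()) if a.mean() != 0 else float("inf")
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        t_stat, p = 0.0, (1.0 if a.mean() == b.mean() else 0.0)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
        "fold_change": fold,
        "t_stat": t_stat,
        "p_value": p,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


@dataclass
class OccupancyProfile:
    """HP1α occupancy per chromatin-density class."""

    class_area: dict[int, int]
    positive_area: dict[int, int]
    occupancy: dict[int, float]  # NaN where the class has zero area
    threshold: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.occupancy[LOOSE], self.occupancy[MIDDLE], self.occupancy[DENSE])


def hp1a_occupancy(
    class_map: np.ndarray,
    hp1_channel: np.ndarray,
    threshold: float | None = None,
) -> OccupancyProfile:
    """Fraction of each density class occupied by HP1α-positive pixels.

    ``threshold=None`` derives the positivity cutoff by Otsu on the HP1α
    intensities within chromatin (non-background) pixels; a fixed value
    can be supplied instead. A pixel is positive when ≥ the cutoff.
    """
    class_map = np.asarray(class_map)
    hp1 = np.asarray(hp1_channel)
    if class_map.shape != hp1.shape:
        raise ValueError("class_map and HP1α channel shapes differ")
    chromatin = class_map > BACKGROUND
    if threshold is None:
        if not chromatin.any():
            raise ValueError("no chromatin pixels to derive an HP1α threshold from")
        hist = np.bincount(hp1[chromatin].astype(np.intp).ravel(), minlength=256)
        threshold = float(otsu_threshold(hist))
    positive = hp1 >= threshold
    class_area, positive_area, occupancy = {}, {}, {}
    for cls in (LOOSE, MIDDLE, DENSE):
        sel = class_map == cls
        class_area[cls] = int(sel.sum())
        positive_area[cls] = int((sel & positive).sum())
        occupancy[cls] = (
            positive_area[cls] / class_area[cls] if class_area[cls] > 0 else float("nan")
        )
    return OccupancyProfile(
        class_area=class_area,
        positive_area=positive_area,
        occupancy=occupancy,
        threshold=float(threshold),
    )
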