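"""Simulation of two-channel confocal-like images of transplanted nuclei.

Channel 1 emulates a DNA stain (TO-PRO-1): each elliptical nucleus is
partitioned radially into three chromatin-density zones — dense core,
middle shell, loose rim — with strictly increasing mean intensities over a
near-zero background. Channel 2 emulates HP1α immunofluorescence: each
chromatin pixel is positive with a class-dependent probability that rises
with density, reproducing the observation that condensed chromatin carries
more HP1α.

Cluster placement produces partially overlapping nuclei (center spacing
below the sum of semi-axes) so that downstream watershed segmentation has
merged objects to split. A paired "post-NT" image set can be generated in
which nucleus areas are scaled by ``dispersal_factor`` and HP1α occupancy
is reduced, emulating chromatin dispersion and HP1α loss after transfer.

Pixel areas are exact by construction: a nucleus mask is the first *A*
pixels in elliptical-radius order, so scaling *A* by the dispersal factor
changes the measured area by exactly that factor (no rasterization drift).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BACKGROUND, LOOSE, MIDDLE, DENSE = 0, 1, 2, 3


@dataclass
class ImgSimConfig:
    """Parameters of the image simulation.

    ``cluster_spec`` lists touching-cluster sizes (e.g. ``(2, 2)`` = two
    clusters of two overlapping nuclei); remaining nuclei are isolated.
    ``density_fractions`` are per-nucleus area fractions of
    loose / middle / dense chromatin, ``class_intensity_means`` the
    corresponding DNA-channel means (strictly increasing, 8-bit range),
    ``hp1_occupancy`` the per-class probability that a chromatin pixel is
    HP1α-positive (non-decreasing with density). ``dispersal_factor``
    scales nucleus areas and ``hp1_reduction`` scales occupancies in the
    paired post-NT image set.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 20
    cluster_spec: tuple[int, ...] = (2, 2, 2)
    radius_range: tuple[float, float] = (18.0, 22.0)
    density_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    class_intensity_means: tuple[float, float, float] = (80.0, 140.0, 200.0)
    hp1_occupancy: tuple[float, float, float] = (0.2, 0.5, 0.8)
    hp1_positive_intensity: float = 200.0
    hp1_negative_intensity: float = 30.0
    noise_sd: float = 4.0
    dispersal_factor: float = 2.0
    hp1_reduction: float = 0.5
    seed: int = 0
    max_place_tries: int = 2000

    def validate(self) -> None:
        m = self.class_intensity_means
        if not (0 < m[0] < m[1] < m[2] <= 255):
            raise ValueError("class_intensity_means must be strictly increasing in (0,255]")
        o = self.hp1_occupancy
        if not (0 <= o[0] <= o[1] <= o[2] <= 1):
            raise ValueError("hp1_occupancy must be non-decreasing in [0,1]")
        if abs(sum(self.density_fractions) - 1.0) > 1e-9:
            raise ValueError("density_fractions must sum to 1")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if sum(self.cluster_spec) > self.n_nuclei:
            raise ValueError("cluster_spec exceeds n_nuclei")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid radius_range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dispersal_factor <= 0:
            raise ValueError("dispersal_factor must be > 0")


@dataclass
class NucleusTruth:
    """Geometry and mask of one simulated nucleus."""

    label: int
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float
    mask: np.ndarray  # bool, image-shaped
    area_px: int


@dataclass
class ImgTruth:
    """Per-image ground truth: nuclei plus per-pixel class and HP1α maps."""

    nuclei: list[NucleusTruth]
    class_map: np.ndarray  # int8: 0 bg, 1 loose, 2 middle, 3 dense
    hp1_map: np.ndarray  # bool

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def occupancy_by_class(self) -> dict[int, float]:
        out = {}
        for cls in (LOOSE, MIDDLE, DENSE):
            sel = self.class_map == cls
            out[cls] = float(self.hp1_map[sel].mean()) if sel.any() else float("nan")
        return out

    def summary_json(self, path: str | Path) -> None:
        payload = {
            "n_nuclei": self.n_nuclei,
            "areas_px": [n.area_px for n in self.nuclei],
            "occupancy_by_class": {str(k): v for k, v in self.occupancy_by_class().items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _elliptical_radius(shape, center, semi_axes, orientation):
    """Normalized elliptical radius u (u<=1 inside) over the pixel grid."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    cos, sin = np.cos(orientation), np.sin(orientation)
    major = dy * cos + dx * sin
    minor = -dy * sin + dx * cos
    a, b = semi_axes
    return np.sqrt((major / a) ** 2 + (minor / b) ** 2)


def _nucleus_pixels(shape, center, semi_axes, orientation, area_scale=1.0):
    """Pixels of one nucleus, ordered inside-out, with exact scaled area.

    The base area is the count of pixels with u <= 1; the returned mask is
    the first round(area_scale * base_area) pixels in u-order, so areas
    scale exactly with ``area_scale``.
    """
    u = _elliptical_radius(shape, center, semi_axes, orientation)
    base_area = int((u <= 1.0).sum())
    target = int(round(area_scale * base_area))
    flat = np.argsort(u, axis=None, kind="stable")[:target]
    return flat, target


def _place_nuclei(config: ImgSimConfig, rng: np.random.Generator, margin_scale: float):
    """Centers/axes/orientations for singles and touching clusters.

    ``margin_scale`` pads the border margin so the same geometry also fits
    after area scaling by ``dispersal_factor``.
    """
    h, w = config.image_shape
    lo, hi = config.radius_range
    placed: list[tuple[float, float, float]] = []  # y, x, clearance radius
    out = []

    def far_enough(y, x, r):
        return all((y - py) ** 2 + (x - px) ** 2 >= (r + pr) ** 2 for py, px, pr in placed)

    def sample_axes():
        # mild eccentricity keeps single-nucleus areas well separated
        # from the area of any touching pair (watershed size gate)
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.85, 1.0)
        return a, b

    def place_one(extra=()):
        # extra: additional nuclei at fixed offsets (cluster partners)
        for _ in range(config.max_place_tries):
            a, b = sample_axes()
            r = a * margin_scale
            group = [(a, b, 0.0, 0.0)]
            span = r
            for off in extra:
                a2, b2 = sample_axes()
                group.append((a2, b2, off[0], off[1]))
                span = max(span, np.hypot(*off) + a2 * margin_scale)
            y = rng.uniform(span + 1, h - span - 1)
            x = rng.uniform(span + 1, w - span - 1)
            if far_enough(y, x, span + 2):
                placed.append((y, x, span + 2))
                theta = rng.uniform(0, np.pi)
                for a2, b2, oy, ox in group:
                    out.append(((y + oy, x + ox), (a2, b2), theta))
                return
        raise RuntimeError("could not place nuclei without exceeding the frame")

    n_clustered = sum(config.cluster_spec)
    for size in config.cluster_spec:
        # partners offset at 1.5×mean radius: < sum of semi-axes → overlap
        offsets = []
        for i in range(1, size):
            d = 1.5 * (lo + hi) / 2
            ang = rng.uniform(0, 2 * np.pi)
            offsets.append((i * d * np.sin(ang), i * d * np.cos(ang)))
        place_one(extra=offsets)
    for _ in range(config.n_nuclei - n_clustered):
        place_one()
    return out


def _render(config: ImgSimConfig, rng: np.random.Generator, geometry, area_scale, occupancy):
    """Rasterize one image pair (DNA, HP1α) plus truth for a geometry."""
    shape = config.image_shape
    class_map = np.zeros(shape, dtype=np.int8)
    hp1_map = np.zeros(shape, dtype=bool)
    nuclei = []
    f_loose, f_mid, f_dense = config.density_fractions
    for label, (center, axes, theta) in enumerate(geometry, start=1):
        flat, area = _nucleus_pixels(shape, center, axes, theta, area_scale)
        mask = np.zeros(shape, dtype=bool)
        mask.flat[flat] = True
        # inside-out order: dense core, then middle shell, then loose rim
        n_dense = int(round(f_dense * area))
        n_mid = int(round(f_mid * area))
        cm_flat = class_map.reshape(-1)
        cm_flat[flat[:n_dense]] = DENSE
        cm_flat[flat[n_dense : n_dense + n_mid]] = MIDDLE
        cm_flat[flat[n_dense + n_mid :]] = LOOSE
        nuclei.append(
            NucleusTruth(
                label=label,
                center=tuple(float(c) for c in center),
                semi_axes=tuple(float(a) for a in axes),
                orientation=float(theta),
                mask=mask,
                area_px=area,
            )
        )
    # HP1α positivity per chromatin pixel, probability by density class
    occ = {LOOSE: occupancy[0], MIDDLE: occupancy[1], DENSE: occupancy[2]}
    u = rng.random(shape)
    for cls, p in occ.items():
        sel = class_map == cls
        hp1_map[sel] = u[sel] < p

    means = np.array([0.0, *config.class_intensity_means])
    dna = means[class_map]
    hp1 = np.where(
        hp1_map,
        config.hp1_positive_intensity,
        np.where(class_map > 0, config.hp1_negative_intensity, 0.0),
    )
    if config.noise_sd > 0:
        dna = dna + rng.normal(0, config.noise_sd, shape)
        hp1 = hp1 + rng.normal(0, config.noise_sd, shape)
    dna = np.clip(np.rint(dna), 0, 255).astype(np.uint8)
    hp1 = np.clip(np.rint(hp1), 0, 255).astype(np.uint8)
    return np.stack([dna, hp1]), ImgTruth(nuclei=nuclei, class_map=class_map, hp1_map=hp1_map)


def simulate_images(
    config: ImgSimConfig, n_images: int = 1
) -> tuple[list[np.ndarray], list[ImgTruth]]:
    """Simulate two-channel images of (possibly clustered) nuclei.

    Returns ``n_images`` arrays of shape (2, H, W) — channel 0 DNA,
    channel 1 HP1α — with matching :class:`ImgTruth`. Deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    images, truths = [], []
    for _ in range(n_images):
        geometry = _place_nuclei(config, rng, margin_scale=1.05)
        img, truth = _render(config, rng, geometry, 1.0, config.hp1_occupancy)
        images.append(img)
        truths.append(truth)
    return images, truths


def simulate_image_pair(
    config: ImgSimConfig, n_images: int = 1
) -> dict[str, tuple[list[np.ndarray], list[ImgTruth]]]:
    """Simulate paired pre-NT ("0h") and post-NT ("24h") image sets.

    The 24 h set shares nucleus geometry with the 0 h set but scales each
    nucleus pixel area by exactly ``dispersal_factor`` and multiplies HP1α
    occupancies by ``hp1_reduction`` (chromatin dispersion + HP1α loss).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    margin = 1.05 * np.sqrt(max(config.dispersal_factor, 1.0))
    out = {"0h": ([], []), "24h": ([], [])}
    occ24 = tuple(o * config.hp1_reduction for o in config.hp1_occupancy)
    for _ in range(n_images):
        geometry = _place_nuclei(config, rng, margin_scale=margin)
        img0, tr0 = _render(config, rng, geometry, 1.0, config.hp1_occupancy)
        img1, tr1 = _render(config, rng, geometry, config.dispersal_factor, occ24)
        out["0h"][0].append(img0)
        out["0h"][1].append(tr0)
        out["24h"][0].append(img1)
        out["24h"][1].append(tr1)
    return out
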