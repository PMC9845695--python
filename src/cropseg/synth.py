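"""Synthetic Sentinel-2-like parcel scenes.

Real crop-type scenes in the study area are mosaics of irregular field
parcels: each parcel grows one crop, parcels are separated by narrow roads
and field margins, class areas are strongly imbalanced (the background
"other" class covers ~64% of pixels), and the four 10 m bands (R, G, B, NIR)
show class-dependent reflectance with sensor noise and smooth scene-level
illumination variation.  This module emulates exactly those properties so
the whole pipeline is testable without the (private) labelled imagery:

* parcels are Voronoi cells of uniformly seeded points, which produces the
  irregular, sometimes long-and-narrow field shapes the refinement branch
  targets;
* each parcel draws its crop class from the configured class probabilities
  (defaults match the study area's pixel-count imbalance);
* pixels within ``gap_width`` of a parcel boundary become background,
  emulating roads and margins;
* band values are a per-class mean reflectance modulated by a low-order
  polynomial illumination surface and i.i.d. Gaussian noise;
* optional random rectangles are masked out, as done for unlabelled areas.

It does NOT model radiative transfer, texture within parcels, mixed border
pixels, or temporal dynamics — a classifier score on these scenes bounds
plumbing correctness and learnability, not real-world accuracy.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .scene import Scene, apply_mask

# Pixel counts of (other, rice, maize, soybean) in the study-area label
# raster; the normalised shares are the default class probabilities.
STUDY_AREA_PIXELS = (15_116_388, 4_685_724, 2_833_795, 925_493)
DEFAULT_CLASS_PROBS = tuple(c / sum(STUDY_AREA_PIXELS) for c in STUDY_AREA_PIXELS)

# Per-class mean reflectance for (R, G, B, NIR).  Chosen once so pairwise
# class separation is ~2-3 default noise SDs: separable but overlapping.
DEFAULT_BAND_MEANS = np.array([
    [0.32, 0.30, 0.28, 0.38],   # other: soil / built-up / water mix
    [0.15, 0.24, 0.12, 0.52],   # rice
    [0.22, 0.30, 0.16, 0.62],   # maize
    [0.12, 0.18, 0.10, 0.44],   # soybean
])


@dataclasses.dataclass
class SynthConfig:
    height: int = 512
    width: int = 512
    n_parcels: int = 150
    class_probs: tuple = DEFAULT_CLASS_PROBS
    band_means: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_BAND_MEANS.copy())
    noise_sd: float = 0.05
    illum_amplitude: float = 0.08
    gap_width: int = 2
    mask_rects: int = 2
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.class_probs, dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.noise_sd < 0 or self.illum_amplitude < 0 or self.gap_width < 0:
            raise ValueError("noise_sd, illum_amplitude and gap_width must be >= 0")
        self.band_means = np.asarray(self.band_means, dtype=float)
        if self.band_means.shape != (len(probs), 4):
            raise ValueError("band_means must be [n_classes, 4]")

    def _rngs(self) -> list[np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(3)]


def generate_parcels(cfg: SynthConfig, rng: np.random.Generator | None = None,
                     return_parcels: bool = False):
    """Voronoi-tessellated crop-class map [H, W] (uint8).

    Each cell of the tessellation of ``n_parcels`` seeded points is assigned
    a class drawn from ``class_probs``; pixels within ``gap_width`` of a cell
    boundary become the background class 0.
    """
    if cfg.n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    if cfg.n_parcels > cfg.height * cfg.width:
        raise ValueError("more parcels than pixels")
    rng = rng if rng is not None else cfg._rngs()[0]
    pts = rng.uniform(0, [cfg.height, cfg.width], size=(cfg.n_parcels, 2))
    rr, cc = np.mgrid[0:cfg.height, 0:cfg.width]
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    _, parcel = cKDTree(pts).query(grid, workers=1)
    parcel = parcel.reshape(cfg.height, cfg.width)
    classes = rng.choice(len(cfg.class_probs), size=cfg.n_parcels,
                         p=np.asarray(cfg.class_probs, dtype=float))
    labels = classes[parcel].astype(np.uint8)
    if cfg.gap_width > 0 and cfg.n_parcels > 1:
        boundary = np.zeros_like(parcel, dtype=bool)
        boundary[:, :-1] |= parcel[:, :-1] != parcel[:, 1:]
        boundary[:-1, :] |= parcel[:-1, :] != parcel[1:, :]
        dist = ndimage.distance_transform_edt(~boundary)
        labels[dist < cfg.gap_width] = 0
    if return_parcels:
        return labels, parcel
    return labels


def render_bands(labels: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render a [4, H, W] float32 reflectance tensor for a class map.

    value = band_mean[class] * (1 + illumination) + N(0, noise_sd), where the
    illumination field is a random quadratic surface rescaled to peak
    amplitude ``illum_amplitude``.
    """
    if labels.max(initial=0) >= cfg.band_means.shape[0]:
        raise ValueError("label values exceed configured classes")
    rng = rng if rng is not None else cfg._rngs()[1]
    h, w = labels.shape
    base = cfg.band_means[labels].transpose(2, 0, 1)  # [4, H, W]
    if cfg.illum_amplitude > 0:
        u = np.linspace(-1, 1, h)[:, None]
        v = np.linspace(-1, 1, w)[None, :]
        coef = rng.uniform(-1, 1, size=6)
        field = (coef[0] + coef[1] * u + coef[2] * v + coef[3] * u * v
                 + coef[4] * u ** 2 + coef[5] * v ** 2)
        peak = np.abs(field).max()
        if peak > 0:
            field = cfg.illum_amplitude * field / peak
        base = base * (1.0 + field)
    else:
        rng.uniform(-1, 1, size=6)  # keep the stream aligned across configs
    noise = rng.normal(0.0, cfg.noise_sd, size=base.shape) if cfg.noise_sd > 0 else 0.0
    return (base + noise).astype(np.float32)


def random_mask_rects(cfg: SynthConfig, rng: np.random.Generator):
    """Random rectangles covering roughly 10-25% of each dimension."""
    rects = []
    for _ in range(cfg.mask_rects):
        rh = int(rng.uniform(0.10, 0.25) * cfg.height)
        rw = int(rng.uniform(0.10, 0.25) * cfg.width)
        r0 = int(rng.integers(0, cfg.height - rh + 1))
        c0 = int(rng.integers(0, cfg.width - rw + 1))
        rects.append((r0, c0, r0 + rh, c0 + rw))
    return rects


def generate_scene(cfg: SynthConfig) -> Scene:
    """Full synthetic scene: parcels -> bands -> random rectangular masks."""
    rng_parcel, rng_band, rng_mask = cfg._rngs()
    labels = generate_parcels(cfg, rng=rng_parcel)
    image = render_bands(labels, cfg, rng=rng_band)
    scene = Scene(image, labels, np.ones_like(labels, dtype=bool))
    if cfg.mask_rects > 0:
        scene = apply_mask(scene, random_mask_rects(cfg, rng_mask))
    return scene
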