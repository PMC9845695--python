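"""Scene containers and the patch-preparation pipeline.

A labelled scene is a co-registered pair of a 4-band reflectance raster and an
integer crop-class raster, plus a validity mask.  Pixels without a trustworthy
label (uninsured parcels, manually masked rectangles) carry the ignore value
and are excluded from every loss and metric downstream.

The preparation protocol is: mask rectangles -> cut into fixed-size tiles with
a non-overlapping sliding window (stride = tile size, so the train/val/test
tiles share no pixels) -> discard tiles whose masked fraction exceeds a
threshold (default 15%) -> seeded random 8:1:1 split.

All coordinates are 0-based and rectangles are half-open.  Raster I/O uses
plain multiband TIFF via :mod:`tifffile`; patch provenance (origin, masked
fraction, split) lives in a manifest CSV next to the patch files.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
import tifffile

IGNORE = 255
CLASS_NAMES = ("other", "rice", "maize", "soybean")


@dataclasses.dataclass
class Scene:
    """Aligned image [4,H,W], label map [H,W] and validity mask [H,W]."""

    image: np.ndarray
    labels: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.image.ndim != 3:
            raise ValueError("image must be [bands, H, W]")
        if self.image.shape[1:] != self.labels.shape or self.labels.shape != self.valid.shape:
            raise ValueError(
                f"misaligned rasters: image {self.image.shape[1:]}, labels "
                f"{self.labels.shape}, valid {self.valid.shape}")
        # invalid pixels always carry the ignore value
        self.labels = self.labels.copy()
        self.labels[~self.valid] = IGNORE
        self.valid = self.valid & (self.labels != IGNORE)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclasses.dataclass
class Patch:
    """One square tile of a scene, with provenance."""

    image: np.ndarray              # [4, S, S]
    labels: np.ndarray             # [S, S]; masked pixels = IGNORE
    origin: tuple[int, int]        # (row, col) offset in the source scene
    masked_fraction: float

    @property
    def size(self) -> int:
        return self.labels.shape[0]


@dataclasses.dataclass
class SplitSpec:
    """Ratios and seed of a random train/val/test split."""

    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    seed: int = 0

    def counts(self, n: int) -> tuple[int, int, int]:
        """Counts with val/test rounded down and the remainder in train.

        For 8:1:1 this is n_val = n_test = floor(n/10); with 177 retained
        patches it yields the 143/17/17 split of the study protocol.
        """
        total = sum(self.ratios)
        n_val = int(np.floor(n * self.ratios[1] / total))
        n_test = int(np.floor(n * self.ratios[2] / total))
        return n - n_val - n_test, n_val, n_test


def apply_mask(scene: Scene, rectangles) -> Scene:
    """Invalidate half-open rectangles (row0, col0, row1, col1) in a scene."""
    h, w = scene.shape
    labels = scene.labels.copy()
    valid = scene.valid.copy()
    for rect in rectangles:
        r0, c0, r1, c1 = (int(v) for v in rect)
        if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
            raise ValueError(f"mask rectangle {tuple(rect)} outside scene bounds {h}x{w}")
        labels[r0:r1, c0:c1] = IGNORE
        valid[r0:r1, c0:c1] = False
    return Scene(scene.image, labels, valid)


def tile(scene: Scene, size: int = 256, stride: int = 256) -> list[Patch]:
    """Cut a scene into square patches in row-major offset order.

    Only tiles fully inside the scene are produced; partial edge tiles are
    dropped rather than padded, so a 5505x4280 scene yields 21*16 tiles of
    size 256.
    """
    h, w = scene.shape
    if size > min(h, w):
        raise ValueError(f"tile size {size} exceeds scene extent {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    patches = []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            labels = scene.labels[r:r + size, c:c + size].copy()
            frac = float(np.mean(labels == IGNORE))
            patches.append(Patch(
                image=scene.image[:, r:r + size, c:c + size].copy(),
                labels=labels,
                origin=(r, c),
                masked_fraction=frac,
            ))
    return patches


def filter_masked(patches: list[Patch], threshold: float = 0.15) -> list[Patch]:
    """Keep patches whose masked fraction does not exceed ``threshold``.

    The cut is strict on the far side: a patch at exactly the threshold is
    retained (only fractions *higher* than the threshold are discarded).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return [p for p in patches if p.masked_fraction <= threshold]


def split(patches, spec: SplitSpec | None = None):
    """Seeded random partition into (train, val, test) index arrays."""
    spec = spec or SplitSpec()
    n = patches if isinstance(patches, int) else len(patches)
    if n < 3:
        raise ValueError(f"need at least 3 patches to split, got {n}")
    n_train, n_val, n_test = spec.counts(n)
    perm = np.random.default_rng(spec.seed).permutation(n)
    val = np.sort(perm[:n_val])
    test = np.sort(perm[n_val:n_val + n_test])
    train = np.sort(perm[n_val + n_test:])
    assert len(train) == n_train
    return train, val, test


def band_stats(patches: list[Patch], indices) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean/SD over the valid pixels of the given (training) patches."""
    vals = [p.image[:, p.labels != IGNORE] for p in (patches[i] for i in indices)]
    allv = np.concatenate(vals, axis=1)
    return allv.mean(axis=1), allv.std(axis=1)


def normalize_patches(patches: list[Patch], mean: np.ndarray, sd: np.ndarray) -> list[Patch]:
    """Z-score each band with training-split statistics."""
    sd = np.where(sd > 0, sd, 1.0)
    return [dataclasses.replace(
        p, image=(p.image - mean[:, None, None]) / sd[:, None, None]) for p in patches]


# -- file I/O ---------------------------------------------------------------

def save_scene(outdir, scene: Scene, prefix: str = "scene") -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{prefix}_image.tif", scene.image,
                     photometric="minisblack", planarconfig="separate")
    tifffile.imwrite(outdir / f"{prefix}_labels.tif", scene.labels)


def load_scene(image_path, labels_path) -> Scene:
    image = np.asarray(tifffile.imread(image_path), dtype=np.float32)
    if image.ndim == 3 and image.shape[0] not in (1, 2, 3, 4) and image.shape[-1] <= 8:
        image = image.transpose(2, 0, 1)  # accept band-last TIFFs
    labels = np.asarray(tifffile.imread(labels_path))
    if labels.ndim != 2:
        raise ValueError("label raster must be single-band")
    labels = labels.astype(np.uint8)
    return Scene(image, labels, labels != IGNORE)


def read_mask_csv(path) -> list[tuple[int, int, int, int]]:
    """Rectangles as row0,col0,row1,col1 lines; blank lines and '#' comments ok."""
    rects = []
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line or line.startswith("row"):
            continue
        parts = [int(v) for v in line.split(",")]
        if len(parts) != 4:
            raise ValueError(f"bad mask line: {line!r}")
        rects.append(tuple(parts))
    return rects


def save_patches(outdir, patches: list[Patch], splits=None) -> pd.DataFrame:
    """Write patch TIFF pairs into per-split directories plus a manifest CSV."""
    outdir = pathlib.Path(outdir)
    names = np.full(len(patches), "all", dtype=object)
    if splits is not None:
        for name, idx in zip(("train", "val", "test"), splits):
            names[np.asarray(idx, dtype=int)] = name
    rows = []
    for i, p in enumerate(patches):
        sub = outdir / str(names[i])
        sub.mkdir(parents=True, exist_ok=True)
        pid = f"patch_{p.origin[0]:05d}_{p.origin[1]:05d}"
        tifffile.imwrite(sub / f"{pid}_image.tif", p.image,
                         photometric="minisblack", planarconfig="separate")
        tifffile.imwrite(sub / f"{pid}_labels.tif", p.labels)
        rows.append({"patch_id": pid, "row": p.origin[0], "col": p.origin[1],
                     "masked_fraction": p.masked_fraction, "split": names[i]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_patch_dir(directory) -> list[Patch]:
    directory = pathlib.Path(directory)
    patches = []
    for img_path in sorted(directory.glob("*_image.tif")):
        lbl_path = img_path.with_name(img_path.name.replace("_image.tif", "_labels.tif"))
        if not lbl_path.exists():
            raise FileNotFoundError(f"no label raster for {img_path.name}")
        image = np.asarray(tifffile.imread(img_path), dtype=np.float32)
        labels = np.asarray(tifffile.imread(lbl_path), dtype=np.uint8)
        stem = img_path.name.replace("_image.tif", "")
        _, r, c = stem.rsplit("_", 2)
        patches.append(Patch(image, labels, (int(r), int(c)),
                             float(np.mean(labels == IGNORE))))
    if not patches:
        raise FileNotFoundError(f"no patches found in {directory}")
    return patches
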