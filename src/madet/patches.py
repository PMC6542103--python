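"""Labeled patch extraction, class balancing and dihedral augmentation.

Both classifiers are trained on fixed-size square windows cut from
shade-corrected fundus images; a patch is labeled by the class of its
central pixel (microaneurysm / background).  Because lesion pixels are a
tiny fraction of the retina, the raw pool is heavily imbalanced; stage-1
training draws an equal number of patches per class from it.

Coordinates are 0-based ``(row, col)`` pixel positions.  Windows that
overhang the image border are filled by mirror reflection, which preserves
local intensity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import FundusImage

__all__ = [
    "MA",
    "NON_MA",
    "GroundTruth",
    "PatchRecord",
    "SamplerConfig",
    "extract_patch",
    "label_for_center",
    "build_patch_pool",
    "balanced_sample",
    "materialize",
    "augment",
]

MA = 1
NON_MA = 0


@dataclass
class GroundTruth:
    """Per-image lesion annotation: centroids and, optionally, a mask.

    ``centroids`` is an ``(n, 2)`` integer array of 0-based ``(row, col)``
    lesion centres.  ``mask`` (if given) is a boolean grid with True on
    lesion pixels; every centroid must then lie on a True pixel.
    """

    image_id: str
    centroids: np.ndarray
    mask: np.ndarray | None = None
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.int64).reshape(-1, 2)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.shape is None:
                self.shape = self.mask.shape
        if self.shape is not None:
            h, w = self.shape
            if self.centroids.size and (
                self.centroids.min() < 0
                or self.centroids[:, 0].max() >= h
                or self.centroids[:, 1].max() >= w
            ):
                raise ValueError("centroid outside image bounds")
        if self.mask is not None and self.centroids.size:
            if not self.mask[self.centroids[:, 0], self.centroids[:, 1]].all():
                raise ValueError("centroid not on a positive mask pixel")

    @property
    def n_lesions(self) -> int:
        return len(self.centroids)


@dataclass
class PatchRecord:
    """One training sample: a window, its label and its provenance.

    ``pixels`` may be ``None`` for a lazily-defined record (centre and label
    known, window not yet cut); :func:`materialize` fills it in.
    """

    center: tuple[int, int]
    label: int
    image_id: str = ""
    pixels: np.ndarray | None = None


@dataclass
class SamplerConfig:
    """Patch-sampling parameters.

    ``patch_side`` defaults to 101 pixels (odd sides keep the centre pixel
    well defined; the engine accepts any side >= 3).  ``lesion_radius`` is
    the closed-ball radius (pixels) within which a centre counts as
    lesion-positive when only centroids are annotated.  ``neg_ratio`` sets
    how many background centres are drawn per lesion centre when building
    the raw pool.  ``seed`` makes sampling reproducible.
    """

    patch_side: int = 101
    border_policy: str = "reflect"
    lesion_radius: float = 3.0
    neg_ratio: float = 9.0
    balance_ratio: float = 1.0
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_side < 1:
            raise ValueError("patch_side must be >= 1")
        if self.border_policy != "reflect":
            raise ValueError("only reflect border policy is supported")
        if self.neg_ratio <= 0 or self.balance_ratio <= 0:
            raise ValueError("ratios must be positive")


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Map integer indices onto [0, n) by symmetric (mirror) reflection."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - 1 - idx, idx)


def extract_patch(
    img: FundusImage, center: tuple[int, int], cfg: SamplerConfig | None = None
) -> np.ndarray:
    """Cut the ``patch_side`` square window centred at *center*.

    Out-of-bounds pixels are filled by mirror reflection, so the result
    always has shape ``(patch_side, patch_side, 3)``.
    """
    cfg = cfg or SamplerConfig()
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < img.height and 0 <= c < img.width):
        raise ValueError(f"center {center} outside image {img.pixels.shape[:2]}")
    half = cfg.patch_side // 2
    rows = _reflect_indices(np.arange(r - half, r - half + cfg.patch_side), img.height)
    cols = _reflect_indices(np.arange(c - half, c - half + cfg.patch_side), img.width)
    return img.pixels[np.ix_(rows, cols)]


def label_for_center(
    gt: GroundTruth, center: tuple[int, int], lesion_radius: float = 3.0
) -> int:
    """Class of the pixel at *center*: MA iff it is a lesion pixel.

    With a mask, that is the mask value; with centroid-only annotation, a
    centre within ``lesion_radius`` (closed ball) of any centroid is MA.
    """
    r, c = int(center[0]), int(center[1])
    if gt.mask is not None:
        return MA if gt.mask[r, c] else NON_MA
    if gt.centroids.size == 0:
        return NON_MA
    d2 = (gt.centroids[:, 0] - r) ** 2 + (gt.centroids[:, 1] - c) ** 2
    return MA if d2.min() <= lesion_radius**2 else NON_MA


def _positive_centers(gt: GroundTruth, lesion_radius: float) -> np.ndarray:
    """All lesion-positive pixel centres of one image, as an (n, 2) array."""
    if gt.mask is not None:
        return np.argwhere(gt.mask)
    if gt.shape is None:
        raise ValueError("centroid-only ground truth needs an image shape")
    h, w = gt.shape
    pts = []
    rad = int(np.floor(lesion_radius))
    for cr, cc in gt.centroids:
        rr, cc2 = np.mgrid[
            max(0, cr - rad) : min(h, cr + rad + 1),
            max(0, cc - rad) : min(w, cc + rad + 1),
        ]
        keep = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= lesion_radius**2
        pts.append(np.stack([rr[keep], cc2[keep]], axis=1))
    if not pts:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.concatenate(pts, axis=0), axis=0)


def build_patch_pool(
    images: list[FundusImage],
    gts: dict[str, GroundTruth],
    cfg: SamplerConfig | None = None,
    materialize_pixels: bool = False,
) -> list[PatchRecord]:
    """Raw training pool: every lesion pixel plus sampled background centres.

    MA centres are all lesion-positive pixels of each image; non-MA centres
    are drawn uniformly over FOV pixels farther than ``lesion_radius`` from
    any lesion, ``neg_ratio`` per positive.  Pixels are cut immediately only
    when ``materialize_pixels`` is set; otherwise records stay lazy so a
    later :func:`balanced_sample` can cut only the patches it keeps.
    """
    cfg = cfg or SamplerConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[PatchRecord] = []
    for img in images:
        if img.image_id not in gts:
            raise ValueError(f"no ground truth for image {img.image_id!r}")
        gt = gts[img.image_id]
        pos = _positive_centers(gt, cfg.lesion_radius)
        fov = (
            img.fov_mask
            if img.fov_mask is not None
            else np.ones(img.pixels.shape[:2], dtype=bool)
        )
        negmask = fov.copy()
        if gt.mask is not None:
            # exclude a small guard band around lesions from the negatives
            from scipy import ndimage as _ndi

            rad = int(np.ceil(cfg.lesion_radius))
            dil = _ndi.binary_dilation(gt.mask, iterations=max(rad, 1))
            negmask &= ~dil
        elif pos.size:
            negmask[pos[:, 0], pos[:, 1]] = False
        neg_all = np.argwhere(negmask)
        n_neg = min(int(round(cfg.neg_ratio * max(len(pos), 1))), len(neg_all))
        neg = neg_all[rng.choice(len(neg_all), size=n_neg, replace=False)]
        for r, c in pos:
            records.append(PatchRecord((int(r), int(c)), MA, img.image_id))
        for r, c in neg:
            records.append(PatchRecord((int(r), int(c)), NON_MA, img.image_id))
    if materialize_pixels:
        records = materialize(records, images, cfg)
    return records


def materialize(
    records: list[PatchRecord],
    images: list[FundusImage],
    cfg: SamplerConfig | None = None,
) -> list[PatchRecord]:
    """Fill in the pixel windows of lazy patch records."""
    cfg = cfg or SamplerConfig()
    by_id = {img.image_id: img for img in images}
    out = []
    for rec in records:
        if rec.pixels is not None:
            out.append(rec)
        else:
            px = extract_patch(by_id[rec.image_id], rec.center, cfg)
            out.append(replace(rec, pixels=px))
    return out


def balanced_sample(
    pool: list[PatchRecord],
    cfg: SamplerConfig | None = None,
    seed: int | None = None,
) -> list[PatchRecord]:
    """Equal-per-class subsample of the pool, without replacement.

    Both classes are truncated to the minority count (scaled by
    ``balance_ratio`` for the negatives), drawn uniformly and
    reproducibly from ``seed`` (defaults to ``cfg.seed``).
    """
    cfg = cfg or SamplerConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pos = [r for r in pool if r.label == MA]
    neg = [r for r in pool if r.label == NON_MA]
    if not pos or not neg:
        raise ValueError("balanced_sample needs both classes in the pool")
    n_pos = min(len(pos), len(neg))
    n_neg = min(int(round(n_pos * cfg.balance_ratio)), len(neg))
    keep_pos = rng.choice(len(pos), size=n_pos, replace=False)
    keep_neg = rng.choice(len(neg), size=n_neg, replace=False)
    out = [pos[i] for i in sorted(keep_pos)] + [neg[i] for i in sorted(keep_neg)]
    return out


def augment(patch: PatchRecord) -> list[PatchRecord]:
    """The 8 dihedral variants of a square patch (4 rotations x mirror).

    Rotations are multiples of 90 degrees so no interpolation occurs and the
    label transfers exactly; the original patch is variant 0.
    """
    if patch.pixels is None:
        raise ValueError("augment needs a materialized patch")
    if patch.pixels.shape[0] != patch.pixels.shape[1]:
        raise ValueError("augment needs a square patch")
    out = []
    for mirrored in (False, True):
        base = patch.pixels[:, ::-1] if mirrored else patch.pixels
        for k in range(4):
            out.append(replace(patch, pixels=np.ascontiguousarray(np.rot90(base, k))))
    return out
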