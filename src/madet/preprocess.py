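"""Illumination normalisation for fundus images.

Retinal photographs are non-uniformly illuminated: a bright centre fades
towards the field-of-view (FOV) rim, and slow shading gradients dominate the
raw intensity range.  Microaneurysms are tiny (a few pixels) low-contrast
dips, so the detector works on a shade-corrected image obtained by
estimating the background with a large median filter and subtracting it.

The default kernel is 30x30 pixels.  An even-sided median window has no
canonical centre; here the window anchor is at ``floor(side / 2)`` and, for
an even number of samples, the upper-middle order statistic is taken (the
convention of :func:`scipy.ndimage.median_filter`).  Borders are handled by
symmetric reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FundusImage",
    "PreprocessConfig",
    "estimate_background",
    "subtract_background",
    "preprocess",
]


@dataclass
class FundusImage:
    """An RGB retinal photograph plus its circular field-of-view mask.

    Parameters
    ----------
    pixels:
        ``(height, width, 3)`` float array with intensities in
        ``[0, range_max]``.
    image_id:
        Opaque identifier used to join images with ground truth and
        candidate lists.
    fov_mask:
        Optional ``(height, width)`` boolean array, True inside the retinal
        field of view.  Pixels outside the FOV carry no retinal content.
    range_max:
        Upper bound of the recorded intensity range (255 for 8-bit input,
        1.0 for normalised input).
    """

    pixels: np.ndarray
    image_id: str = ""
    fov_mask: np.ndarray | None = None
    range_max: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be (H, W, 3), got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > self.range_max:
            raise ValueError(
                "pixel intensities outside the recorded range "
                f"[0, {self.range_max}]"
            )
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise ValueError("fov_mask shape must match pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PreprocessConfig:
    """Background-subtraction parameters.

    ``offset`` is added back after subtraction so the result stays
    representable; ``None`` means "per-channel mean of the original image",
    which keeps the overall brightness of the input.  ``per_channel``
    estimates and removes the background separately on R, G and B (colour
    normalisation); turning it off estimates a single background from the
    channel mean.
    """

    kernel_side: int = 30
    offset: float | None = None
    per_channel: bool = True

    def __post_init__(self) -> None:
        if self.kernel_side < 1:
            raise ValueError("kernel_side must be >= 1")
        if self.offset is not None and not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


def estimate_background(
    img: FundusImage, cfg: PreprocessConfig | None = None
) -> FundusImage:
    """Median-filter background estimate of *img*.

    Each output pixel is the median of the ``kernel_side`` x ``kernel_side``
    window anchored at ``floor(side/2)``, borders reflected.  Returns a new
    :class:`FundusImage` of identical shape.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.kernel_side > 2 * max(img.height, img.width):
        raise ValueError(
            f"kernel_side {cfg.kernel_side} larger than twice the image "
            f"extent {max(img.height, img.width)}"
        )
    if cfg.per_channel:
        bg = np.stack(
            [
                ndimage.median_filter(
                    img.pixels[..., c], size=cfg.kernel_side, mode="reflect"
                )
                for c in range(3)
            ],
            axis=-1,
        )
    else:
        shared = ndimage.median_filter(
            img.pixels.mean(axis=-1), size=cfg.kernel_side, mode="reflect"
        )
        bg = np.repeat(shared[..., None], 3, axis=-1)
    return FundusImage(
        bg.astype(np.float32),
        image_id=img.image_id,
        fov_mask=img.fov_mask,
        range_max=img.range_max,
    )


def subtract_background(
    img: FundusImage, bg: FundusImage, cfg: PreprocessConfig | None = None
) -> FundusImage:
    """``img - bg + offset``, clipped to the recorded intensity range.

    The FOV mask of *img* is propagated unchanged.
    """
    cfg = cfg or PreprocessConfig()
    if bg.pixels.shape != img.pixels.shape:
        raise ValueError("image and background shapes differ")
    if cfg.offset is None:
        offset = img.pixels.reshape(-1, 3).mean(axis=0)
    else:
        offset = np.full(3, cfg.offset, dtype=np.float32)
    out = img.pixels - bg.pixels + offset[None, None, :]
    np.clip(out, 0.0, img.range_max, out=out)
    return FundusImage(
        out.astype(np.float32),
        image_id=img.image_id,
        fov_mask=img.fov_mask,
        range_max=img.range_max,
    )


def preprocess(
    img: FundusImage, cfg: PreprocessConfig | None = None
) -> FundusImage:
    """Shade-correct *img*: estimate the median background and subtract it.

    Deterministic: identical input and configuration give byte-identical
    output.
    """
    cfg = cfg or PreprocessConfig()
    return subtract_background(img, estimate_background(img, cfg), cfg)
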