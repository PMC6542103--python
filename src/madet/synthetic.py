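"""Seeded synthetic fundus scenes with exact lesion ground truth.

The generator emulates the three image properties the detector has to
cope with: a smooth non-uniform illumination field inside a circular
field of view, dark curvilinear vessel structures, and small dark
circular lesions (microaneurysms are capillary outpouchings under
~125 um across, i.e. a handful of pixels at typical fundus resolution
— the default lesion radii are 2-5 px).  Lesions are rendered with an
approximately Gaussian intensity dip, strongest in the green channel,
matching how reddish lesions photograph on an RGB sensor.

Scenes are fully determined by their seed, so every pipeline stage has a
reproducible, download-free test surface.  This is deliberately not a
photorealistic retina: there is no optic disc, no exudates or
haemorrhages, no texture, and vessels are random smooth walks rather
than a vascular tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .patches import GroundTruth
from .preprocess import FundusImage

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "generate_dataset"]

# base colour of the simulated retina (R, G, B) on a 0-255 scale
_BASE_COLOR = np.array([165.0, 95.0, 40.0])
# relative strength of the lesion/vessel dip per channel (green hit hardest)
_DIP_WEIGHT = np.array([0.55, 1.0, 0.35])


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``lesion_contrast`` is the fractional intensity dip at a lesion centre
    (0.35 = 35% darker than the local background); ``illumination_amplitude``
    is the fractional peak-to-peak strength of the smooth shading field;
    ``noise_sd`` is additive Gaussian noise on the 0-255 scale.
    """

    height: int = 256
    width: int = 256
    n_lesions: int = 8
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)
    lesion_contrast: float = 0.35
    n_vessels: int = 6
    vessel_width_range: tuple[float, float] = (2.0, 5.0)
    illumination_amplitude: float = 0.25
    noise_sd: float = 3.0
    hard_mode: bool = False  # place a fraction of lesions against vessels
    hard_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not lo < hi:
            raise ValueError("lesion_radius_range must satisfy min < max")
        for v in (self.lesion_contrast, self.illumination_amplitude, self.noise_sd):
            if not np.isfinite(v) or v < 0:
                raise ValueError("scene scalars must be finite and non-negative")
        if self.n_lesions < 0 or self.n_vessels < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SyntheticScene:
    """A rendered scene: image, ground truth and full provenance."""

    image: FundusImage
    ground_truth: GroundTruth
    config: SceneConfig


def _fov_mask(h: int, w: int) -> np.ndarray:
    r = 0.48 * min(h, w)
    yy, xx = np.mgrid[:h, :w]
    return (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r**2


def _illumination(h: int, w: int, amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative shading: tilted plane + off-centre vignette."""
    yy, xx = np.mgrid[:h, :w]
    yn, xn = yy / h - 0.5, xx / w - 0.5
    theta = rng.uniform(0, 2 * np.pi)
    plane = np.cos(theta) * yn + np.sin(theta) * xn
    cy, cx = rng.uniform(-0.25, 0.25, size=2)
    vign = np.exp(-((yn - cy) ** 2 + (xn - cx) ** 2) / (2 * 0.35**2))
    fld = 0.5 * plane + 0.5 * (vign - vign.mean())
    span = fld.max() - fld.min()
    if span > 0:
        fld = (fld - fld.min()) / span - 0.5
    return 1.0 + amplitude * fld


def _vessels(h: int, w: int, cfg: SceneConfig, rng) -> np.ndarray:
    """Dip field of dark smooth random curves; also used as a vessel mask."""
    field = np.zeros((h, w))
    yy, xx = np.mgrid[:h, :w]
    for _ in range(cfg.n_vessels):
        width = rng.uniform(*cfg.vessel_width_range)
        # random smooth walk across the FOV
        r = np.array([rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)])
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(1.2 * max(h, w))
        pts = []
        for _ in range(n_steps):
            ang += rng.normal(0, 0.08)
            r = r + np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= r[0] < h and 0 <= r[1] < w):
                break
            pts.append(r.copy())
        sigma = width / 2.0
        for p in pts[:: max(1, int(sigma))]:
            dy = yy[
                max(0, int(p[0] - 3 * sigma)) : int(p[0] + 3 * sigma) + 1,
                max(0, int(p[1] - 3 * sigma)) : int(p[1] + 3 * sigma) + 1,
            ] - p[0]
            dx = xx[
                max(0, int(p[0] - 3 * sigma)) : int(p[0] + 3 * sigma) + 1,
                max(0, int(p[1] - 3 * sigma)) : int(p[1] + 3 * sigma) + 1,
            ] - p[1]
            g = np.exp(-(dy**2 + dx**2) / (2 * sigma**2))
            sl = (
                slice(max(0, int(p[0] - 3 * sigma)), int(p[0] + 3 * sigma) + 1),
                slice(max(0, int(p[1] - 3 * sigma)), int(p[1] + 3 * sigma) + 1),
            )
            field[sl] = np.maximum(field[sl], g)
    return field


def _place_lesions(
    cfg: SceneConfig, fov: np.ndarray, vessel_field: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample lesion centres and radii.

    Centres stay >= 2*max_radius apart and, unless ``hard_mode`` marks them
    as vessel-adjacent, clear of vessels.  Raises after a bounded number of
    retries when the requested count cannot be placed.
    """
    h, w = fov.shape
    rmin, rmax = cfg.lesion_radius_range
    margin = int(np.ceil(rmax)) + 2
    # lesions must fit inside the FOV with room for their full profile;
    # an eroded FOV keeps them off the rim where contrast is undefined
    from scipy import ndimage as _ndi

    fov = _ndi.binary_erosion(fov, iterations=margin + 2)
    vessel_mask = vessel_field > 0.2
    centers: list[tuple[int, int]] = []
    radii: list[float] = []
    n_hard = int(round(cfg.hard_fraction * cfg.n_lesions)) if cfg.hard_mode else 0
    tries = 0
    while len(centers) < cfg.n_lesions:
        tries += 1
        if tries > 1000 * max(cfg.n_lesions, 1):
            raise RuntimeError(
                f"could not place {cfg.n_lesions} lesions after {tries} tries"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if not fov[r, c]:
            continue
        hard = len(centers) < n_hard
        near_vessel = vessel_mask[
            max(0, r - 2 * margin) : r + 2 * margin,
            max(0, c - 2 * margin) : c + 2 * margin,
        ].any()
        if hard and not near_vessel:
            continue
        if not hard and vessel_mask[
            max(0, r - margin) : r + margin, max(0, c - margin) : c + margin
        ].any():
            continue
        if any((r - rr) ** 2 + (c - cc) ** 2 < (2 * rmax) ** 2 for rr, cc in centers):
            continue
        centers.append((r, c))
        radii.append(float(rng.uniform(rmin, rmax)))
    return np.array(centers, dtype=np.int64).reshape(-1, 2), np.array(radii)


def generate_scene(cfg: SceneConfig | None = None) -> SyntheticScene:
    """Render one scene; byte-identical for identical config (incl. seed)."""
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    fov = _fov_mask(h, w)
    illum = _illumination(h, w, cfg.illumination_amplitude, rng)
    vessel_field = _vessels(h, w, cfg, rng)
    centers, radii = _place_lesions(cfg, fov, vessel_field, rng)

    yy, xx = np.mgrid[:h, :w]
    lesion_field = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for (r, c), rad in zip(centers, radii):
        sigma = rad / 2.0
        ext = int(np.ceil(3 * sigma)) + 1
        sl = (slice(max(0, r - ext), r + ext + 1), slice(max(0, c - ext), c + ext + 1))
        dy, dx = yy[sl] - r, xx[sl] - c
        g = np.exp(-(dy**2 + dx**2) / (2 * sigma**2))
        lesion_field[sl] = np.maximum(lesion_field[sl], g)
        mask[sl] |= dy**2 + dx**2 <= rad**2

    dip = np.clip(
        0.5 * vessel_field + cfg.lesion_contrast * lesion_field, 0.0, 0.95
    )
    img = (
        _BASE_COLOR[None, None, :]
        * illum[..., None]
        * (1.0 - dip[..., None] * _DIP_WEIGHT[None, None, :])
    )
    img[~fov] = 0.0
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    # keep renders reproducible across BLAS/libm builds: freeze to 8-bit
    img = np.round(img).astype(np.uint8).astype(np.float32)

    image_id = f"synth-{cfg.seed:010d}"
    image = FundusImage(img, image_id=image_id, fov_mask=fov)
    gt = GroundTruth(image_id=image_id, centroids=centers, mask=mask)
    return SyntheticScene(image=image, ground_truth=gt, config=cfg)


def generate_dataset(
    n_images: int, cfg: SceneConfig | None = None, seed: int = 0
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Generate *n_images* scenes with distinct child seeds plus a manifest.

    Child seeds are derived deterministically from *seed* via
    :class:`numpy.random.SeedSequence`, so the dataset is reproducible from
    the master seed alone.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cfg = cfg or SceneConfig()
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_images)
    ]
    scenes = []
    rows = []
    for i, child in enumerate(child_seeds):
        scene_cfg = SceneConfig(**{**asdict(cfg), "seed": child})
        scene = generate_scene(scene_cfg)
        # disambiguate in the unlikely event of a child-seed collision
        scene.image.image_id = f"synth-{i:03d}-{child:010d}"
        scene.ground_truth.image_id = scene.image.image_id
        scenes.append(scene)
        rows.append(
            {
                "image_id": scene.image.image_id,
                "seed": child,
                "n_lesions": scene.ground_truth.n_lesions,
            }
        )
    return scenes, pd.DataFrame(rows)
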