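"""Two-stage training: balanced screening net, then a hard-example net.

Lesion pixels are outnumbered roughly ten-to-one (or worse) by background
in the raw patch pool, and the overwhelming majority of background patches
are trivially easy.  The strategy here attacks that imbalance in two
stages:

1. the *basic* net is trained on an exactly class-balanced sample of the
   pool, then scanned over every training image to produce a per-pixel
   microaneurysm probability map;
2. pixels whose probability exceeds a threshold ``T`` (default 0.6) —
   i.e. the false positives the balanced net could not reject, plus the
   true lesions — become the training set of the deeper *final* net.

The selection shrinks the negative class to its informative fraction, so
the stage-2 training set is far less imbalanced than the raw pool while
containing exactly the examples that are hard to classify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nets import NetworkSpec, TrainConfig, TrainedNet, predict_proba, train
from .patches import (
    MA,
    GroundTruth,
    PatchRecord,
    SamplerConfig,
    balanced_sample,
    build_patch_pool,
    label_for_center,
    materialize,
    _positive_centers,
    _reflect_indices,
)
from .preprocess import FundusImage

__all__ = [
    "ProbabilityMap",
    "StageConfig",
    "TwoStageConfig",
    "TwoStageReport",
    "infer_probability_map",
    "infer_cascade_map",
    "select_candidates",
    "run_two_stage",
]


@dataclass
class ProbabilityMap:
    """Per-pixel lesion probability aligned to a fundus image.

    When inference ran on a stride > 1 grid, skipped positions carry the
    value of their nearest evaluated neighbour; off-FOV pixels are 0.
    """

    values: np.ndarray
    image_id: str = ""
    generating_net: str = ""
    stride: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class StageConfig:
    """Hard-example selection settings.

    ``threshold`` is the probability above which (strictly) a pixel is kept
    as a stage-2 training centre; ``inference_stride`` trades probability-map
    resolution for speed; ``include_positives`` forces every ground-truth
    lesion pixel into the stage-2 set even if the basic net missed it.
    """

    threshold: float = 0.6
    inference_stride: int = 1
    include_positives: bool = True
    batch_size: int = 512

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.inference_stride < 1:
            raise ValueError("inference_stride must be >= 1")


def _eval_at_centers(
    net: TrainedNet, img: FundusImage, centers: np.ndarray, batch_size: int
) -> np.ndarray:
    """Net probability at each (row, col) centre, border-reflected windows."""
    side = net.spec.patch_side
    h, w = img.height, img.width
    half = side // 2
    pad = half + 1
    rows = _reflect_indices(np.arange(-pad, h + pad), h)
    cols = _reflect_indices(np.arange(-pad, w + pad), w)
    padded = img.pixels[np.ix_(rows, cols)]
    win = np.lib.stride_tricks.sliding_window_view(
        padded, (side, side), axis=(0, 1)
    )  # indexed by the window's top-left corner in padded coordinates
    out = np.empty(len(centers), dtype=np.float64)
    for start in range(0, len(centers), batch_size):
        chunk = centers[start : start + batch_size]
        batch = win[chunk[:, 0] - half + pad, chunk[:, 1] - half + pad]
        batch = np.ascontiguousarray(np.moveaxis(batch, 1, -1))  # to HWC
        out[start : start + len(chunk)] = predict_proba(
            net, batch, batch_size=batch_size
        )
    return out


def infer_probability_map(
    net: TrainedNet, img: FundusImage, cfg: StageConfig | None = None
) -> ProbabilityMap:
    """Scan *net* over *img* and return the per-pixel MA probability map.

    Patches are evaluated at every ``inference_stride``-th FOV pixel
    (mirror-reflected at borders); skipped positions take the value of the
    nearest evaluated grid point, off-FOV pixels are exactly 0.
    """
    cfg = cfg or StageConfig()
    if not isinstance(net, TrainedNet):
        raise ValueError("infer_probability_map needs a trained net")
    h, w = img.height, img.width
    fov = (
        img.fov_mask if img.fov_mask is not None else np.ones((h, w), dtype=bool)
    )
    s = cfg.inference_stride
    grid_fov = fov[::s, ::s]
    gh, gw = grid_fov.shape
    coarse = np.zeros((gh, gw), dtype=np.float32)
    centers = np.argwhere(grid_fov) * s  # image coordinates of grid points
    if len(centers):
        probs = _eval_at_centers(net, img, centers, cfg.batch_size)
        coarse[centers[:, 0] // s, centers[:, 1] // s] = probs

    # nearest-grid-point upsampling back to full resolution
    ridx = np.clip(np.round(np.arange(h) / s).astype(int), 0, gh - 1)
    cidx = np.clip(np.round(np.arange(w) / s).astype(int), 0, gw - 1)
    full = coarse[np.ix_(ridx, cidx)]
    full[~fov] = 0.0
    return ProbabilityMap(
        values=full, image_id=img.image_id, generating_net=net.spec.name, stride=s
    )


def infer_cascade_map(
    basic: TrainedNet,
    final: TrainedNet,
    img: FundusImage,
    cfg: StageConfig | None = None,
) -> ProbabilityMap:
    """Full detector map: final-net probability on basic-net candidates.

    The cheap basic net screens the whole image; the final net is then
    evaluated only at pixels whose screening probability exceeds the
    selection threshold, exactly mirroring how its training set was
    selected.  All other pixels are 0.  This keeps the deep classifier on
    the example distribution it was trained on and makes whole-image
    inference cheap.
    """
    cfg = cfg or StageConfig()
    bmap = infer_probability_map(basic, img, cfg)
    sel = np.argwhere(bmap.values > cfg.threshold)
    values = np.zeros_like(bmap.values)
    if len(sel):
        values[sel[:, 0], sel[:, 1]] = _eval_at_centers(
            final, img, sel, cfg.batch_size
        )
    return ProbabilityMap(
        values=values, image_id=img.image_id, generating_net="cascade", stride=cfg.inference_stride
    )


def select_candidates(
    pmap: ProbabilityMap,
    gt: GroundTruth,
    cfg: StageConfig | None = None,
    lesion_radius: float = 3.0,
) -> list[tuple[tuple[int, int], int]]:
    """Stage-2 training centres: pixels with probability > T, labeled.

    Each selected centre is labeled by the ground truth at that pixel.
    With ``include_positives`` every ground-truth lesion pixel is appended
    (deduplicated), so stage 2 always sees the full positive class.
    """
    cfg = cfg or StageConfig()
    sel = np.argwhere(pmap.values > cfg.threshold)
    out: list[tuple[tuple[int, int], int]] = []
    seen = set()
    for r, c in sel:
        center = (int(r), int(c))
        out.append((center, label_for_center(gt, center, lesion_radius)))
        seen.add(center)
    if cfg.include_positives:
        for r, c in _positive_centers(gt, lesion_radius):
            center = (int(r), int(c))
            if center not in seen:
                out.append((center, MA))
                seen.add(center)
    return out


@dataclass
class TwoStageConfig:
    """Bundle of everything :func:`run_two_stage` needs."""

    basic_spec: NetworkSpec
    final_spec: NetworkSpec
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    stage: StageConfig = field(default_factory=StageConfig)
    train_basic: TrainConfig = field(default_factory=TrainConfig)
    train_final: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class TwoStageReport:
    """Pool sizes before/after hard-example selection."""

    pool_n_ma: int
    pool_n_nonma: int
    stage2_n_ma: int
    stage2_n_nonma: int

    @property
    def pool_imbalance(self) -> float:
        return self.pool_n_nonma / max(self.pool_n_ma, 1)

    @property
    def stage2_imbalance(self) -> float:
        return self.stage2_n_nonma / max(self.stage2_n_ma, 1)

    @property
    def nonma_reduction(self) -> float:
        """Factor by which selection shrank the negative class."""
        return self.pool_n_nonma / max(self.stage2_n_nonma, 1)


def run_two_stage(
    images: list[FundusImage],
    gts: dict[str, GroundTruth],
    cfg: TwoStageConfig,
    seed: int = 0,
) -> tuple[TrainedNet, TrainedNet, TwoStageReport]:
    """Train both classifiers on (preprocessed) *images*.

    Stage 1 trains the basic net on an exactly balanced sample of the raw
    pool; its probability maps over the training images select the hard
    negatives (plus all lesion pixels) that train the final net.  Fully
    deterministic given *seed* and the configs.
    """
    if not images:
        raise ValueError("no training images")
    if not any(gts[i.image_id].n_lesions for i in images):
        raise ValueError("training images contain no lesions")
    ss = np.random.SeedSequence(seed)
    s_pool, s_bal, s_basic, s_final = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )

    sampler = SamplerConfig(**{**vars(cfg.sampler), "seed": s_pool})
    pool = build_patch_pool(images, gts, sampler)
    pool_n_ma = sum(1 for r in pool if r.label == MA)
    pool_n_nonma = len(pool) - pool_n_ma

    stage1 = materialize(balanced_sample(pool, sampler, seed=s_bal), images, sampler)
    basic = train(
        cfg.basic_spec,
        stage1,
        TrainConfig(**{**vars(cfg.train_basic), "seed": s_basic}),
    )

    stage2: list[PatchRecord] = []
    for img in images:
        pmap = infer_probability_map(basic, img, cfg.stage)
        for center, label in select_candidates(
            pmap, gts[img.image_id], cfg.stage, sampler.lesion_radius
        ):
            stage2.append(PatchRecord(center, label, img.image_id))
    stage2_n_ma = sum(1 for r in stage2 if r.label == MA)
    stage2_n_nonma = len(stage2) - stage2_n_ma
    stage2 = materialize(stage2, images, sampler)
    final = train(
        cfg.final_spec,
        stage2,
        TrainConfig(**{**vars(cfg.train_final), "seed": s_final}),
    )
    report = TwoStageReport(
        pool_n_ma=pool_n_ma,
        pool_n_nonma=pool_n_nonma,
        stage2_n_ma=stage2_n_ma,
        stage2_n_nonma=stage2_n_nonma,
    )
    return basic, final, report
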