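"""End-to-end experiment driver on synthetic scenes.

Wires the whole detector together at desk scale: generate seeded training
and test scenes, shade-correct them, run the two training stages, scan the
test images with the final net, post-process the probability maps into
candidates and score them at lesion level.  This is the reference recipe
for the worked example in the README and for reproducibility scripts.

Default problem sizes are deliberately modest — 20 training plus 10 test
scenes of 256x256 pixels with 8 lesions each, 25-pixel patches, 5 epochs
per stage, inference stride 2 — small enough to run on one CPU core in a
few minutes while leaving the detection task non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .froc import (
    CPM_FPI_POINTS,
    FROCCurve,
    cpm,
    froc_curve,
    partial_fauc,
    sensitivity_at_fpi,
)
from .nets import TrainConfig, TrainedNet, build_basic_cnn, build_final_cnn
from .patches import SamplerConfig
from .postprocess import Candidate, find_candidates, smooth_map
from .preprocess import PreprocessConfig, preprocess
from .synthetic import SceneConfig, generate_dataset
from .twostage import (
    StageConfig,
    TwoStageConfig,
    TwoStageReport,
    infer_cascade_map,
    run_two_stage,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_synthetic_experiment"]


@dataclass
class ExperimentConfig:
    """Scaled-down study conditions for the synthetic end-to-end run."""

    n_train: int = 20
    n_test: int = 10
    scene: SceneConfig = field(default_factory=SceneConfig)
    patch_side: int = 25
    epochs: int = 5
    inference_stride: int = 2
    disk_radius: int = 5
    match_radius: float = 5.0
    kernel_side: int = 30


@dataclass
class ExperimentResult:
    """Everything the end-to-end run produced."""

    basic: TrainedNet
    final: TrainedNet
    report: TwoStageReport
    candidates: dict[str, list[Candidate]]
    lesions: dict[str, np.ndarray]
    curve: FROCCurve

    @property
    def sensitivity_at(self) -> dict[float, float]:
        return {f: sensitivity_at_fpi(self.curve, f) for f in CPM_FPI_POINTS}

    @property
    def cpm(self) -> float:
        return cpm(list(self.sensitivity_at.values()))

    @property
    def partial_fauc(self) -> float:
        return partial_fauc(self.curve)


def run_synthetic_experiment(
    seed: int = 0, cfg: ExperimentConfig | None = None
) -> ExperimentResult:
    """Generate data, train both stages, detect on held-out scenes, score.

    All randomness (scene content, pool sampling, weight init, dropout,
    batch order) derives from *seed*, so two calls with the same seed give
    identical candidates and scores.
    """
    cfg = cfg or ExperimentConfig()
    ss = np.random.SeedSequence(seed)
    seed_train, seed_test, seed_fit = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    train_scenes, _ = generate_dataset(cfg.n_train, cfg.scene, seed=seed_train)
    test_scenes, _ = generate_dataset(cfg.n_test, cfg.scene, seed=seed_test)

    pre_cfg = PreprocessConfig(kernel_side=cfg.kernel_side)
    train_imgs = [preprocess(s.image, pre_cfg) for s in train_scenes]
    test_imgs = [preprocess(s.image, pre_cfg) for s in test_scenes]
    gts = {s.image.image_id: s.ground_truth for s in train_scenes}

    two_cfg = TwoStageConfig(
        basic_spec=build_basic_cnn(cfg.patch_side),
        final_spec=build_final_cnn(cfg.patch_side),
        sampler=SamplerConfig(patch_side=cfg.patch_side),
        stage=StageConfig(inference_stride=cfg.inference_stride),
        train_basic=TrainConfig(epochs=cfg.epochs),
        train_final=TrainConfig(epochs=cfg.epochs),
    )
    basic, final, report = run_two_stage(train_imgs, gts, two_cfg, seed=seed_fit)

    stage = StageConfig(inference_stride=cfg.inference_stride)
    candidates: dict[str, list[Candidate]] = {}
    lesions: dict[str, np.ndarray] = {}
    for scene, img in zip(test_scenes, test_imgs):
        pmap = infer_cascade_map(basic, final, img, stage)
        # drop the all-zero background plateau from the maxima scan
        candidates[img.image_id] = find_candidates(
            smooth_map(pmap, cfg.disk_radius),
            min_distance=cfg.disk_radius,
            min_confidence=1e-6,
        )
        lesions[img.image_id] = scene.ground_truth.centroids
    curve = froc_curve(candidates, lesions, radius=cfg.match_radius)
    return ExperimentResult(
        basic=basic,
        final=final,
        report=report,
        candidates=candidates,
        lesions=lesions,
        curve=curve,
    )
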