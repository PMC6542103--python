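"""Lesion-level evaluation: matching, sensitivity, FROC, CPM, partial AUC.

A candidate counts as a true positive when a ground-truth lesion centroid
lies within a 5-pixel radius (closed ball); matching is one-to-one,
greedy in descending candidate confidence, each candidate taking the
nearest still-unmatched lesion.  Sensitivity is TP / (TP + FN), pooled
over all lesions of the evaluation set.

A free-response ROC (FROC) curve sweeps a threshold over the candidate
confidences and plots pooled per-lesion sensitivity against the mean
number of false positives per image (FPI).  Two scalar summaries are
standard for microaneurysm detection:

* CPM — the mean sensitivity at FPI = 1/8, 1/4, 1/2, 1, 2, 4 and 8;
* partial F_AUC — the area under sensitivity as a function of log2(FPI)
  over FPI in [1/8, 8], normalised by the interval width (6) so a
  perfect detector scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .postprocess import Candidate

__all__ = [
    "CPM_FPI_POINTS",
    "MatchingResult",
    "FROCCurve",
    "match_candidates",
    "sensitivity",
    "froc_curve",
    "sensitivity_at_fpi",
    "cpm",
    "curve_cpm",
    "partial_fauc",
    "kfold_split",
]

CPM_FPI_POINTS = (1 / 8, 1 / 4, 1 / 2, 1, 2, 4, 8)


@dataclass
class MatchingResult:
    """Counts and matched pairs of one candidate-vs-lesion comparison."""

    tp: int
    fp: int
    fn: int
    tn: int = 0  # nominal; lesion-level scoring has no meaningful TN
    pairs: list[tuple[Candidate, tuple[int, int], float]] = field(
        default_factory=list
    )


def match_candidates(
    cands: list[Candidate], lesions: np.ndarray, radius: float = 5.0
) -> MatchingResult:
    """One-to-one greedy matching of candidates to lesion centroids.

    Candidates are processed in descending confidence (ties: smaller
    coordinate first); each takes the nearest unmatched lesion within
    *radius* (closed ball, Euclidean).  Unmatched candidates are false
    positives, unmatched lesions false negatives.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    lesions = np.asarray(lesions, dtype=np.float64).reshape(-1, 2)
    order = sorted(cands, key=lambda c: (-c.confidence, c.center))
    taken = np.zeros(len(lesions), dtype=bool)
    pairs = []
    fp = 0
    for cand in order:
        if len(lesions) == 0:
            fp += 1
            continue
        d = np.hypot(
            lesions[:, 0] - cand.center[0], lesions[:, 1] - cand.center[1]
        )
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= radius:
            taken[j] = True
            pairs.append((cand, (int(lesions[j, 0]), int(lesions[j, 1])), float(d[j])))
        else:
            fp += 1
    tp = int(taken.sum())
    return MatchingResult(tp=tp, fp=fp, fn=len(lesions) - tp, pairs=pairs)


def sensitivity(m: MatchingResult) -> float:
    """Per-lesion sensitivity TP / (TP + FN)."""
    if m.tp + m.fn == 0:
        raise ValueError("sensitivity undefined: no lesions")
    return m.tp / (m.tp + m.fn)


@dataclass
class FROCCurve:
    """Operating points (threshold, fpi, sensitivity) of a detector.

    Points are ordered by descending threshold, so fpi and sensitivity are
    non-decreasing along the list.
    """

    points: list[tuple[float, float, float]]
    n_images: int
    n_lesions: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["threshold", "fpi", "sensitivity"]
        )


def froc_curve(
    cands_by_image: dict[str, list[Candidate]],
    lesions_by_image: dict[str, np.ndarray],
    radius: float = 5.0,
) -> FROCCurve:
    """FROC curve over every distinct confidence threshold.

    For each threshold (the sorted unique candidate confidences,
    descending), candidates with confidence >= threshold are matched per
    image; TP and FN are pooled over images for the sensitivity, and fpi
    is total FP divided by the number of images.  Images with no
    candidates still count in the fpi denominator.
    """
    if not lesions_by_image:
        raise ValueError("no images to evaluate")
    n_images = len(lesions_by_image)
    n_lesions = sum(
        len(np.asarray(l).reshape(-1, 2)) for l in lesions_by_image.values()
    )
    if n_lesions == 0:
        raise ValueError("no lesions anywhere: FROC undefined")
    confs = sorted(
        {c.confidence for cands in cands_by_image.values() for c in cands},
        reverse=True,
    )
    points = []
    for thr in confs:
        tp_total = fp_total = fn_total = 0
        for image_id, lesions in lesions_by_image.items():
            kept = [
                c
                for c in cands_by_image.get(image_id, [])
                if c.confidence >= thr
            ]
            m = match_candidates(kept, lesions, radius)
            tp_total += m.tp
            fp_total += m.fp
            fn_total += m.fn
        points.append(
            (float(thr), fp_total / n_images, tp_total / (tp_total + fn_total))
        )
    return FROCCurve(points=points, n_images=n_images, n_lesions=n_lesions)


def sensitivity_at_fpi(curve: FROCCurve, fpi_target: float) -> float:
    """Step-interpolated sensitivity at a false-positive-per-image budget.

    The best (maximum) sensitivity over operating points with
    fpi <= target; 0 when no point fits the budget.
    """
    if fpi_target < 0:
        raise ValueError("fpi target must be non-negative")
    fits = [s for _, fpi, s in curve.points if fpi <= fpi_target]
    return max(fits, default=0.0)


def cpm(sens_at: "list[float] | np.ndarray") -> float:
    """Competition Performance Measure: the mean of the seven sensitivities
    at FPI = 1/8, 1/4, 1/2, 1, 2, 4 and 8."""
    sens_at = np.asarray(sens_at, dtype=np.float64)
    if sens_at.shape != (7,):
        raise ValueError("cpm needs exactly 7 sensitivities")
    if sens_at.min() < 0 or sens_at.max() > 1:
        raise ValueError("sensitivities must lie in [0, 1]")
    return float(sens_at.mean())


def curve_cpm(curve: FROCCurve) -> float:
    """CPM evaluated on a FROC curve at the seven standard FPI points."""
    return cpm([sensitivity_at_fpi(curve, f) for f in CPM_FPI_POINTS])


def partial_fauc(
    curve: FROCCurve, lo: float = 1 / 8, hi: float = 8.0
) -> float:
    """Normalised area under the FROC over FPI in [lo, hi], log2 axis.

    Operating points are joined linearly in (log2 fpi, sensitivity) and
    extended flat (step extension) beyond the first/last point; the
    trapezoidal integral is divided by log2(hi/lo) so the result lies in
    [0, 1].
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if lo <= 0:
        raise ValueError("lo must be positive")
    pts = sorted((fpi, s) for _, fpi, s in curve.points)
    # collapse duplicate fpi values to their best sensitivity
    by_fpi: dict[float, float] = {}
    for fpi, s in pts:
        by_fpi[fpi] = max(by_fpi.get(fpi, 0.0), s)
    fpis = np.array(sorted(by_fpi))
    sens = np.array([by_fpi[f] for f in fpis])
    if len(fpis) == 0:
        return 0.0
    # a zero-fpi point sits at -inf on the log axis; pin it just below lo
    x = np.log2(np.maximum(fpis, lo / 4.0))
    xlo, xhi = np.log2(lo), np.log2(hi)
    xs = np.unique(np.concatenate([[xlo, xhi], x[(x > xlo) & (x < xhi)]]))
    ys = np.interp(xs, x, sens)  # flat extension beyond both ends
    return float(np.trapezoid(ys, xs) / (xhi - xlo))


def kfold_split(
    image_ids: list[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Seeded k-fold split by image: list of (train_ids, test_ids)."""
    if k < 2 or k > len(image_ids):
        raise ValueError("k must lie in [2, n_images]")
    rng = np.random.default_rng(seed)
    ids = list(image_ids)
    rng.shuffle(ids)
    folds = [list(f) for f in np.array_split(ids, k)]
    return [
        (sorted(x for j, f in enumerate(folds) if j != i for x in f), sorted(folds[i]))
        for i in range(k)
    ]
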