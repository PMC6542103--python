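"""From noisy probability maps to scored point candidates.

The final classifier's probability map is noisy: one lesion can appear
as several nearby high-probability pixels, and two close lesions can
merge.  Convolving the map with a normalised disk kernel (default radius
5 px, the scale of a microaneurysm plus localisation slack) turns each
detection into a smooth bump whose local maximum sits at the lesion
centroid; the maxima, with the smoothed value as confidence, are the
candidate list the FROC evaluation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .twostage import ProbabilityMap

__all__ = ["Candidate", "disk_kernel", "smooth_map", "find_candidates"]


@dataclass
class Candidate:
    """A scored point detection."""

    center: tuple[int, int]
    confidence: float
    image_id: str = ""


def disk_kernel(radius: int) -> np.ndarray:
    """Binary disk { (dr,dc) : dr^2 + dc^2 <= radius^2 } normalised to sum 1."""
    radius = int(radius)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (rr**2 + cc**2 <= radius**2).astype(np.float64)
    return disk / disk.sum()


def smooth_map(pmap: ProbabilityMap, radius: int = 5) -> ProbabilityMap:
    """Convolve the map with the normalised disk (reflected borders).

    A convex combination of probabilities, so values stay in [0, 1] and
    the global maximum never increases.
    """
    kernel = disk_kernel(radius)
    smoothed = ndimage.convolve(
        pmap.values.astype(np.float64), kernel, mode="reflect"
    )
    return ProbabilityMap(
        values=np.clip(smoothed, 0.0, 1.0),
        image_id=pmap.image_id,
        generating_net=pmap.generating_net,
        stride=pmap.stride,
    )


def find_candidates(
    smoothed: ProbabilityMap,
    min_distance: int = 5,
    min_confidence: float = 0.0,
) -> list[Candidate]:
    """Local maxima of the smoothed map, as scored candidates.

    A pixel is a candidate iff its value is >= every value in its
    ``(2*min_distance+1)`` square neighbourhood, is >= ``min_confidence``,
    and it is the lexicographically smallest pixel attaining that value in
    the neighbourhood (deterministic plateau tie-break).  Candidates are
    returned sorted by descending confidence, ties broken by coordinate.
    """
    v = smoothed.values
    size = 2 * int(min_distance) + 1
    maxf = ndimage.maximum_filter(v, size=size, mode="constant", cval=-np.inf)
    peaks = np.argwhere((v >= maxf) & (v >= min_confidence))
    out: list[Candidate] = []
    h, w = v.shape
    m = int(min_distance)
    for r, c in peaks:
        val = v[r, c]
        nb = v[max(0, r - m) : r + m + 1, max(0, c - m) : c + m + 1]
        ties = np.argwhere(nb == val)
        ties[:, 0] += max(0, r - m)
        ties[:, 1] += max(0, c - m)
        first = ties[np.lexsort((ties[:, 1], ties[:, 0]))][0]
        if first[0] == r and first[1] == c:
            out.append(
                Candidate((int(r), int(c)), float(val), smoothed.image_id)
            )
    out.sort(key=lambda cand: (-cand.confidence, cand.center))
    return out
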