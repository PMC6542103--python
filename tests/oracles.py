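"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain loops over the mathematical
definitions, deliberately sharing no code with the package, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_windowed_median(channel: np.ndarray, side: int) -> np.ndarray:
    """Per-window median with anchor floor(side/2), symmetric reflection.

    For an even number of samples the upper-middle order statistic is
    taken (the package's documented convention).
    """
    h, w = channel.shape
    a = side // 2
    padded = np.pad(channel, side, mode="symmetric")
    out = np.empty_like(channel, dtype=np.float64)
    for r in range(h):
        for c in range(w):
            win = padded[
                r + side - a : r + 2 * side - a, c + side - a : c + 2 * side - a
            ]
            out[r, c] = np.sort(win.ravel())[side * side // 2]
    return out


def brute_convolve_reflect(grid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 2-D convolution with symmetric-reflection borders."""
    kh, kw = kernel.shape
    ah, aw = kh // 2, kw // 2
    padded = np.pad(grid.astype(np.float64), max(kh, kw), mode="symmetric")
    out = np.empty_like(grid, dtype=np.float64)
    h, w = grid.shape
    kflip = kernel[::-1, ::-1]
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    acc += (
                        kflip[i, j]
                        * padded[r + max(kh, kw) - ah + i, c + max(kh, kw) - aw + j]
                    )
            out[r, c] = acc
    return out


def brute_local_maxima(
    grid: np.ndarray, min_distance: int, min_confidence: float
) -> list[tuple[int, int]]:
    """All pixels that are >= every value in their square neighbourhood,
    >= min_confidence, and lexicographically first among equal-valued
    neighbourhood pixels."""
    h, w = grid.shape
    m = min_distance
    peaks = []
    for r in range(h):
        for c in range(w):
            v = grid[r, c]
            if v < min_confidence:
                continue
            nb = grid[max(0, r - m) : r + m + 1, max(0, c - m) : c + m + 1]
            if v < nb.max():
                continue
            tie_found = False
            for rr in range(max(0, r - m), r + m + 1):
                if rr >= h or tie_found:
                    break
                for cc in range(max(0, c - m), min(w, c + m + 1)):
                    if grid[rr, cc] == v and (rr, cc) < (r, c):
                        tie_found = True
                        break
            if not tie_found:
                peaks.append((r, c))
    return peaks


def brute_select_above_threshold(values: np.ndarray, thr: float) -> set:
    """All (row, col) with value strictly above the threshold."""
    out = set()
    h, w = values.shape
    for r in range(h):
        for c in range(w):
            if values[r, c] > thr:
                out.add((r, c))
    return out


def brute_match(cands, lesions: np.ndarray, radius: float):
    """Greedy confidence-descending one-to-one matching; returns tp, fp, fn."""
    lesions = np.asarray(lesions, dtype=float).reshape(-1, 2)
    used = [False] * len(lesions)
    order = sorted(cands, key=lambda c: (-c.confidence, c.center))
    tp = fp = 0
    for cand in order:
        best, best_d = None, None
        for j in range(len(lesions)):
            if used[j]:
                continue
            d = (
                (lesions[j, 0] - cand.center[0]) ** 2
                + (lesions[j, 1] - cand.center[1]) ** 2
            ) ** 0.5
            if d <= radius and (best_d is None or d < best_d):
                best, best_d = j, d
        if best is None:
            fp += 1
        else:
            used[best] = True
            tp += 1
    return tp, fp, len(lesions) - tp


def brute_froc(cands_by_image, lesions_by_image, radius: float):
    """All-thresholds enumeration of (threshold, fpi, sensitivity)."""
    thrs = sorted(
        {c.confidence for cs in cands_by_image.values() for c in cs}, reverse=True
    )
    n_img = len(lesions_by_image)
    points = []
    for thr in thrs:
        tp = fp = fn = 0
        for iid, lesions in lesions_by_image.items():
            kept = [c for c in cands_by_image.get(iid, []) if c.confidence >= thr]
            a, b, d = brute_match(kept, lesions, radius)
            tp, fp, fn = tp + a, fp + b, fn + d
        points.append((thr, fp / n_img, tp / (tp + fn)))
    return points


def reflect_index(i: int, n: int) -> int:
    """Mirror (symmetric) boundary index mapping onto [0, n)."""
    if n == 1:
        return 0
    period = 2 * n
    i = i % period
    return period - 1 - i if i >= n else i
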