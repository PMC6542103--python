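"""File formats: PNG images and masks, lesion/candidate CSVs, probability maps.

Conventions shared by the CLI and the evaluator:

* lesion CSV — one row per lesion, columns ``image_id,row,col`` (0-based);
* candidate CSV — one row per detection, ``image_id,row,col,confidence``;
* masks — single-channel PNG, 0 background / 255 lesion;
* probability maps — 16-bit single-channel PNG with
  ``value = round(p * 65535)`` plus a JSON sidecar recording provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .postprocess import Candidate
from .preprocess import FundusImage
from .twostage import ProbabilityMap

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "read_lesions_csv",
    "write_lesions_csv",
    "read_candidates_csv",
    "write_candidates_csv",
    "save_probability_map",
    "load_probability_map",
]


def load_image(path: str | Path, image_id: str | None = None) -> FundusImage:
    """Read a PNG/JPEG fundus image; image_id defaults to the file stem."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[..., None], 3, axis=-1)
    arr = arr[..., :3].astype(np.float32)
    return FundusImage(arr, image_id=image_id or path.stem)


def save_image(img: FundusImage, path: str | Path) -> None:
    scale = 255.0 / img.range_max
    iio.imwrite(
        Path(path), np.clip(img.pixels * scale, 0, 255).astype(np.uint8)
    )


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def read_lesions_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Lesion centroids per image_id from the standard CSV."""
    df = pd.read_csv(path)
    return {
        str(image_id): grp[["row", "col"]].to_numpy(dtype=np.int64)
        for image_id, grp in df.groupby("image_id", sort=True)
    }


def write_lesions_csv(
    lesions_by_image: dict[str, np.ndarray], path: str | Path
) -> None:
    rows = [
        {"image_id": image_id, "row": int(r), "col": int(c)}
        for image_id, arr in lesions_by_image.items()
        for r, c in np.asarray(arr).reshape(-1, 2)
    ]
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(
        path, index=False
    )


def read_candidates_csv(path: str | Path) -> dict[str, list[Candidate]]:
    df = pd.read_csv(path)
    out: dict[str, list[Candidate]] = {}
    for image_id, grp in df.groupby("image_id", sort=True):
        out[str(image_id)] = [
            Candidate((int(r.row), int(r.col)), float(r.confidence), str(image_id))
            for r in grp.itertuples()
        ]
    return out


def write_candidates_csv(
    cands_by_image: dict[str, list[Candidate]], path: str | Path
) -> None:
    rows = [
        {
            "image_id": image_id,
            "row": c.center[0],
            "col": c.center[1],
            "confidence": f"{c.confidence:.6f}",
        }
        for image_id in sorted(cands_by_image)
        for c in cands_by_image[image_id]
    ]
    pd.DataFrame(
        rows, columns=["image_id", "row", "col", "confidence"]
    ).to_csv(path, index=False)


def save_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(
        path.with_suffix(".png"),
        np.round(pmap.values.astype(np.float64) * 65535).astype(np.uint16),
    )
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "image_id": pmap.image_id,
                "generating_net": pmap.generating_net,
                "stride": pmap.stride,
            }
        )
    )


def load_probability_map(path: str | Path) -> ProbabilityMap:
    path = Path(path)
    values = np.asarray(iio.imread(path.with_suffix(".png"))).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ProbabilityMap(values=(values / 65535.0).astype(np.float32), **meta)
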