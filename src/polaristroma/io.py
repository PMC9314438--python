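"""File formats: multi-page TIFF stacks with JSON sidecars, ROI and
cohort CSVs, parametric-image TIFFs.

A stack is stored as an 18-page grayscale TIFF in ascending-angle page
order plus a ``<name>.json`` sidecar holding the angles and pixel size.
Ground truth, when saved, goes into ``<name>_truth.tif`` (orientation,
amplitude, gain pages) with the fiber mask recoverable as
``amplitude > 0``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .features import RoiRect
from .phantom import GroundTruth
from .polarimetry import PolarimetricStack

ROI_CSV_COLUMNS = ("patient_id", "roi_id", "x", "y", "width", "height")


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_stack(
    path: str | Path,
    stack: PolarimetricStack,
    truth: GroundTruth | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "angles_deg": [float(a) for a in stack.angles],
        "pixel_size_um": float(stack.pixel_size),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    if truth is not None:
        truth_path = path.with_name(path.stem + "_truth.tif")
        pages = np.stack(
            [
                np.nan_to_num(truth.orientation_map, nan=-1.0),
                truth.amplitude_map,
                truth.gain_map,
            ]
        ).astype(np.float32)
        tifffile.imwrite(truth_path, pages, photometric="minisblack")


def read_stack(path: str | Path) -> PolarimetricStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return PolarimetricStack(
        frames=frames,
        angles=np.asarray(meta["angles_deg"], dtype=float),
        pixel_size=float(meta["pixel_size_um"]),
    )


def read_truth(path: str | Path) -> GroundTruth:
    pages = tifffile.imread(path).astype(float)
    orientation = pages[0].copy()
    orientation[orientation < 0] = np.nan
    amplitude = pages[1]
    return GroundTruth(
        orientation_map=orientation,
        amplitude_map=amplitude,
        fiber_mask=amplitude > 0,
        gain_map=pages[2],
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image).astype(np.float32), photometric="minisblack")


def read_rois(path: str | Path) -> pd.DataFrame:
    """Read an ROI rectangle table (0-based, half-open pixel intervals)."""
    df = pd.read_csv(path)
    missing = set(ROI_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    return df


def roi_rects(df: pd.DataFrame) -> list[tuple[object, object, RoiRect]]:
    return [
        (row.patient_id, row.roi_id,
         RoiRect(int(row.x), int(row.y), int(row.width), int(row.height)))
        for row in df.itertuples()
    ]


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
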