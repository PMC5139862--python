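"""Reading and writing the pipeline's file formats.

Cohorts are RFC-4180 CSV with a fixed header; images and masks are 8-bit
PNG/TIFF; structured results are JSON.  Reads are schema-validated and
failures name the offending row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DomainError
from .segmentation import RGBImage
from .simulate import COHORT_COLUMNS, GroundTruth

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(value, row: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise DomainError(f"row {row}, column {column!r}: {value!r} is not a boolean")
    return _BOOL_MAP[key]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Required columns are the synthetic-cohort schema (``mvd_mean`` and
    ``mvd_group`` are optional, filled downstream).  Raises
    :class:`DomainError` naming the first bad row and column.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"cohort CSV is missing columns: {missing}")
    for col in ("death_event", "metastasis"):
        df[col] = [
            _parse_bool(v, i, col) for i, v in zip(df.index, df[col])
        ]
    for i, v in zip(df.index, df["followup_years"]):
        if not np.isfinite(v) or v < 0:
            raise DomainError(f"row {i}, column 'followup_years': {v!r} must be >= 0")
    for i, v in zip(df.index, df["size_cm"]):
        if not np.isfinite(v) or v <= 0:
            raise DomainError(f"row {i}, column 'size_cm': {v!r} must be > 0")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise DomainError(f"duplicate patient_id {dup!r}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, lineterminator="\r\n")


def read_image(path: str | Path, um_per_px: float) -> RGBImage:
    """Load a PNG/TIFF image as 8-bit RGB with the given pixel size."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return RGBImage(pixels=arr, um_per_px=um_per_px)


def write_image(image: RGBImage, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Save a binary raster as an 8-bit PNG (0 background, 255 foreground)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar with ellipse parameters and hot-spot centers."""
    payload = {
        "hotspot_centers": [list(c) for c in truth.hotspot_centers],
        "vessel_shapes": [
            {
                "center_xy": list(s.center_xy),
                "axes_px": list(s.axes_px),
                "angle_rad": s.angle_rad,
            }
            for s in truth.vessel_shapes
        ],
    }
    write_json(payload, path)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
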