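"""On-disk formats for slices, masks and dataset manifests.

Images are stored as 16-bit grayscale PNG holding ``HU + 1024`` (so the CT
range [-1024, 3071] maps to [0, 4095]); DICOM files are read through
pydicom with RescaleSlope/RescaleIntercept honored.  Masks are one 8-bit
PNG per tissue with values {0, 255}.  A manifest CSV ties them together
with columns ``id, plane, image_path, tissue, mask_path, seed``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

HU_OFFSET = 1024
MANIFEST_COLUMNS = ["id", "plane", "image_path", "tissue", "mask_path", "seed"]

__all__ = [
    "HU_OFFSET", "MANIFEST_COLUMNS",
    "write_image_png", "read_image_png", "read_dicom", "read_image",
    "write_mask_png", "read_mask_png",
    "write_manifest", "read_manifest",
]


def write_image_png(path, hu: np.ndarray) -> None:
    hu = np.asarray(hu)
    lo, hi = int(hu.min()), int(hu.max())
    if lo < -HU_OFFSET or hi > 3071:
        raise ValueError(f"HU values [{lo}, {hi}] outside [-1024, 3071]")
    raw = (hu.astype(np.int32) + HU_OFFSET).astype(np.uint16)
    Image.fromarray(raw).save(path)  # uint16 -> 16-bit grayscale PNG


def read_image_png(path) -> np.ndarray:
    raw = np.asarray(Image.open(path), dtype=np.int32)
    return (raw - HU_OFFSET).astype(np.int16)


def read_dicom(path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float32)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return np.rint(arr * slope + intercept).astype(np.int16)


def read_image(path) -> np.ndarray:
    """Dispatch on extension: .dcm/.dicom -> DICOM, otherwise 16-bit PNG."""
    suffix = Path(path).suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return read_dicom(path)
    return read_image_png(path)


def write_mask_png(path, mask: np.ndarray) -> None:
    m = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(m, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    raw = np.asarray(Image.open(path).convert("L"))
    return raw >= 128


def write_manifest(rows: list[dict], path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df
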