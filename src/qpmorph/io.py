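"""File formats: TIFF images, ImageJ-dialect bounding-box CSVs, feature tables.

Height maps travel as 32-bit float TIFF with a JSON calibration sidecar;
masks as 8-bit (0/255) PNG or TIFF.  Bounding boxes use the ImageJ
"Measure" CSV dialect: a leading unnamed index column and columns Label,
BX, BY, Width, Height and optionally Slice (1-based frame).  Coordinates
are converted to the package convention on import: 0-based, row-major,
half-open [x, x+w) x [y, y+h).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .morphometry import FEATURE_NAMES, FEATURE_UNITS
from .phase import HeightMap
from .segmentation import BoundingBox

__all__ = [
    "read_tiff",
    "write_tiff",
    "read_height_map",
    "write_height_map",
    "read_boxes_csv",
    "write_boxes_csv",
    "read_features_csv",
    "write_features_csv",
    "read_mask",
    "write_mask",
]


def read_tiff(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as float array."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr, dtype=float)


def write_tiff(path: str | Path, array: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32),
                     photometric="minisblack")


def write_height_map(path: str | Path, hm: HeightMap) -> None:
    """Write a height map as float32 TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    write_tiff(path, hm.height_um)
    sidecar = {
        "pixel_size_um": hm.pixel_size_um,
        "wavelength_um": hm.wavelength_um,
        "delta_n": hm.delta_n,
        "pass_factor": hm.pass_factor,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_height_map(path: str | Path) -> HeightMap:
    path = Path(path)
    arr = read_tiff(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return HeightMap(height_um=arr, **meta)


def read_boxes_csv(path: str | Path) -> list[BoundingBox]:
    """Read bounding boxes from an ImageJ "Measure" CSV."""
    df = pd.read_csv(path)
    required = {"BX", "BY", "Width", "Height"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected ImageJ Measure columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    boxes = []
    for i, row in df.iterrows():
        frame = str(int(row["Slice"])) if "Slice" in df.columns else "1"
        label = str(row["Label"]) if "Label" in df.columns else f"cell{i:04d}"
        boxes.append(BoundingBox(
            frame_id=frame,
            cell_id=label,
            x=int(round(row["BX"])),
            y=int(round(row["BY"])),
            width=int(round(row["Width"])),
            height=int(round(row["Height"])),
        ))
    return boxes


def write_boxes_csv(path: str | Path, boxes: Iterable[BoundingBox]) -> None:
    rows = [
        {" ": i + 1, "Label": b.cell_id, "BX": b.x, "BY": b.y,
         "Width": b.width, "Height": b.height, "Slice": int(b.frame_id)}
        for i, b in enumerate(boxes)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_features_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Write a tidy feature table with a units metadata comment line."""
    units = ",".join(
        f"{name}[{FEATURE_UNITS[name]}]" for name in FEATURE_NAMES if name in table.columns
    )
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        table.to_csv(fh, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_mask(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))
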