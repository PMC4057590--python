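"""File formats: multi-page TIFF cines with JSON sidecars, masks, tables.

On-disk conventions:

* cine loops — multi-page 8-bit grayscale TIFF plus a JSON sidecar
  holding ``frame_rate_hz``, ``clips``, flash timing, the compression
  law and the pixel size (frame timestamps are reconstructed from the
  clips and frame rate);
* masks — single-page 8-bit TIFF, 0/255;
* strain acquisitions — multi-page float32 TIFF (one page per
  replicate);
* cohort tables — CSV with header
  ``animal_id,group,day,height_mm,width_mm,thickness_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import CineLoop, clip_times
from .errors import ParameterError

__all__ = [
    "write_cine",
    "read_cine",
    "write_mask",
    "read_mask",
    "write_strain",
    "read_strain",
    "write_cohort_csv",
    "read_cohort_csv",
]

COHORT_COLUMNS = ["animal_id", "group", "day", "height_mm", "width_mm", "thickness_mm"]


def _sidecar_path(cine_path: Path) -> Path:
    return cine_path.with_suffix(".json")


def write_cine(path, cine: CineLoop) -> None:
    path = Path(path)
    tifffile.imwrite(path, cine.frames, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(cine.meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cine(path, meta_path=None) -> CineLoop:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta_path = Path(meta_path) if meta_path else _sidecar_path(path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    times = clip_times(meta["clips"], meta["frame_rate_hz"])
    if len(times) != len(frames):
        raise ParameterError(
            f"sidecar clips imply {len(times)} frames but the TIFF holds {len(frames)}"
        )
    return CineLoop(frames, times, meta)


def write_mask(path, mask: np.ndarray) -> None:
    m = np.asarray(mask).astype(bool)
    tifffile.imwrite(Path(path), (m * np.uint8(255)), photometric="minisblack")


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_strain(path, strains: np.ndarray) -> None:
    tifffile.imwrite(
        Path(path), np.asarray(strains, dtype=np.float32), photometric="minisblack"
    )


def read_strain(path) -> np.ndarray:
    s = tifffile.imread(Path(path))
    return s[None] if s.ndim == 2 else s


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"cohort table lacks columns: {sorted(missing)}")
    table[COHORT_COLUMNS].to_csv(Path(path), index=False, float_format="%.6f")


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ParameterError(f"cohort table lacks columns: {sorted(missing)}")
    return table
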