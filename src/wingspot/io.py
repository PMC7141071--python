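"""File formats: grayscale images, landmark CSVs, measurement tables, JSON.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.
Files written by the pipeline carry provenance (config hash, seed) as
``# key=value`` comment lines, which every reader here skips.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthgen import MEASUREMENT_COLUMNS, LandmarkPair, WingImage


def read_image(path, scale_um_per_px: float | None = None) -> WingImage:
    """Load a PNG/TIFF as a single-channel image (RGB is averaged)."""
    px = iio.imread(path)
    if px.ndim == 3:
        px = px[..., :3].mean(axis=2).astype(px.dtype)
    return WingImage(px, scale_um_per_px=scale_um_per_px, source=Path(path).stem)


def write_image(path, image: WingImage) -> None:
    iio.imwrite(path, image.pixels)


def read_landmarks(path) -> LandmarkPair:
    """Two-row CSV with x,y header (pixel coordinates, origin top-left)."""
    df = pd.read_csv(path, comment="#")
    if len(df) != 2 or not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{path}: landmark file must have columns x,y and 2 rows")
    return LandmarkPair((float(df.x[0]), float(df.y[0])),
                        (float(df.x[1]), float(df.y[1])))


def write_landmarks(path, landmarks: LandmarkPair, header: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        _write_header(fh, header)
        fh.write("x,y\n")
        for x, y in (landmarks.p1, landmarks.p2):
            fh.write(f"{x:g},{y:g}\n")


def _write_header(fh, header: dict | None) -> None:
    for k, v in (header or {}).items():
        fh.write(f"# {k}={v}\n")


def write_table(path, table: pd.DataFrame, header: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, header)
        table.to_csv(fh, index=False)


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing measurement columns {sorted(missing)}")
    return df


def read_individual_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
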