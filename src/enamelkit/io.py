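"""File I/O: float32 TIFF rasters with JSON sidecars, CSV tables, transects.

Raster convention: pixel centers, 0-based row-major, pixel size in µm
recorded in the sidecar metadata (``<name>.json`` next to ``<name>.tif``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import TransectProfile
from .sxrf import ElementMap

__all__ = [
    "write_element_map",
    "read_element_map",
    "read_transect_csv",
    "write_transect_csv",
    "extract_transect",
]


def write_element_map(emap: ElementMap, path: str | Path,
                      extra_meta: dict | None = None) -> Path:
    """Write a float32 TIFF plus a JSON sidecar with units and pixel size."""
    path = Path(path)
    tifffile.imwrite(path, emap.grid.astype(np.float32))
    meta = {
        "element": emap.element,
        "pixel_size_um": emap.pixel_size_um,
        "units_state": emap.units_state,
        **(extra_meta or {}),
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    if emap.phase_mask is not None:
        tifffile.imwrite(path.with_name(path.stem + "_mask.tif"),
                         emap.phase_mask.astype(np.uint8))
    return path


def read_element_map(path: str | Path) -> ElementMap:
    path = Path(path)
    grid = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask_path = path.with_name(path.stem + "_mask.tif")
    mask = np.asarray(tifffile.imread(mask_path)) if mask_path.exists() else None
    return ElementMap(element=meta["element"], grid=grid,
                      pixel_size_um=meta["pixel_size_um"],
                      units_state=meta["units_state"], phase_mask=mask)


def read_transect_csv(path: str | Path) -> TransectProfile:
    """Read a `position_um,value_ppm` transect table."""
    df = pd.read_csv(path)
    missing = {"position_um", "value_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"transect CSV missing columns {sorted(missing)}")
    return TransectProfile(df["position_um"].to_numpy(),
                           df["value_ppm"].to_numpy())


def write_transect_csv(profile: TransectProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"position_um": profile.positions_um,
                  "value_ppm": profile.values_ppm}).to_csv(path, index=False)
    return path


def extract_transect(emap: ElementMap,
                     polyline_um: list[tuple[float, float]],
                     step_um: float | None = None) -> TransectProfile:
    """Sample a raster along a polyline of (x, y) vertices in µm.

    Bilinear interpolation at pixel centers; cumulative arc length becomes
    the transect position axis (starting at 0).
    """
    from scipy.ndimage import map_coordinates

    if len(polyline_um) < 2:
        raise ValueError("polyline needs at least two vertices")
    step = step_um if step_um is not None else emap.pixel_size_um
    pts = np.asarray(polyline_um, dtype=float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, total + step / 2, step)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    # µm -> pixel-center index coordinates (row, col)
    rows = y / emap.pixel_size_um - 0.5
    cols = x / emap.pixel_size_um - 0.5
    vals = map_coordinates(emap.grid, [rows, cols], order=1, mode="nearest")
    return TransectProfile(s, np.clip(vals, 0.0, None))
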