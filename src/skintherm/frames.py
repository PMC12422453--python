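"""Frame containers and file I/O.

Thermal frames are 2-D temperature grids in °C, stored on disk either as
32-bit float TIFF or as a plain CSV grid. Optical frames are RGB rasters
(PNG/TIFF). ROI definitions round-trip through JSON sidecar files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .roi import EllipseROI

__all__ = [
    "ThermalFrame",
    "OpticalFrame",
    "read_thermal",
    "write_thermal",
    "read_optical",
    "write_optical",
    "read_roi_json",
    "write_roi_json",
]

MIN_FRAME_SIDE = 16


@dataclass
class ThermalFrame:
    """H x W temperature grid (°C) with acquisition metadata.

    Pixel coordinates are 0-based and row-major: x = column, y = row.
    """

    grid: np.ndarray
    camera_id: str = "E8XT"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 2 or min(g.shape) < MIN_FRAME_SIDE:
            raise ValueError(f"thermal grid must be 2-D with sides >= {MIN_FRAME_SIDE}")
        if not np.all(np.isfinite(g)):
            raise ValueError("thermal grid contains non-finite temperatures")
        self.grid = g

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class OpticalFrame:
    """RGB raster with labeled fiducial corner points (x, y), >= 3, non-collinear."""

    raster: np.ndarray
    fiducials: np.ndarray

    def __post_init__(self) -> None:
        self.fiducials = np.atleast_2d(np.asarray(self.fiducials, dtype=float))
        if len(self.fiducials) < 3:
            raise ValueError("at least 3 fiducial points are required")


def write_thermal(frame: ThermalFrame | np.ndarray, path) -> None:
    path = Path(path)
    grid = frame.grid if isinstance(frame, ThermalFrame) else np.asarray(frame, dtype=float)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, grid.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, grid, delimiter=",", fmt="%.4f")
    else:
        raise ValueError(f"unsupported thermal format: {path.suffix}")


def read_thermal(path, camera_id: str = "E8XT") -> ThermalFrame:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        grid = tifffile.imread(path).astype(float)
    elif path.suffix.lower() == ".csv":
        grid = np.loadtxt(path, delimiter=",", dtype=float)
    else:
        raise ValueError(f"unsupported thermal format: {path.suffix}")
    return ThermalFrame(grid=grid, camera_id=camera_id)


def write_optical(raster: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(raster, dtype=np.uint8)).save(Path(path))


def read_optical(path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("RGB"))


def write_roi_json(path, frame_id: str, **rois: EllipseROI) -> None:
    payload = {"frame_id": frame_id}
    payload.update({name: roi.to_dict() for name, roi in rois.items()})
    Path(path).write_text(json.dumps(payload, indent=2))


def read_roi_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        k: (EllipseROI.from_dict(v) if isinstance(v, dict) else v)
        for k, v in payload.items()
    }
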