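"""Minimal raster I/O: TIFF arrays with a JSON sidecar for georeferencing.

Rasters are plain numpy arrays written as (multi-band) TIFF via tifffile;
the GDAL-style geotransform (origin_x, pixel_w, 0, origin_y, 0, pixel_h)
and the nodata sentinel travel in a `<name>.aux.json` sidecar.  All grids
in a pipeline must share shape and transform exactly; no resampling is
performed here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["DEFAULT_TRANSFORM", "write_raster", "read_raster", "check_aligned"]

# 250 m pixels at an arbitrary projected origin
DEFAULT_TRANSFORM = (0.0, 250.0, 0.0, 0.0, 0.0, -250.0)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def write_raster(path, data, transform=DEFAULT_TRANSFORM, nodata=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(data))
    meta = {"transform": list(transform), "nodata": nodata}
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_raster(path):
    """Return (array, transform, nodata); transform defaults if no sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    transform, nodata = DEFAULT_TRANSFORM, None
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        transform = tuple(meta.get("transform", DEFAULT_TRANSFORM))
        nodata = meta.get("nodata")
    return data, transform, nodata


def check_aligned(shape_a, transform_a, shape_b, transform_b) -> None:
    if tuple(shape_a) != tuple(shape_b) or tuple(transform_a) != tuple(transform_b):
        raise ValueError(
            f"grids not aligned: shape/transform {shape_a}/{transform_a} "
            f"vs {shape_b}/{transform_b}"
        )
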