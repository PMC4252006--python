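"""File I/O: images, region annotations, measurement tables.

Conventions (stated in every output header): pixel coordinates are 0-based;
masks and rectangles are (row, col); polygon vertices are (x, y) = (col, row)
to match common annotation tools; a pixel belongs to a region when its center
(col + 0.5, row + 0.5) lies inside the polygon under the even-odd rule, so a
rectangle [x0, x1) x [y0, y1) with integer corners covers exactly
(x1 - x0) * (y1 - y0) pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ValidationError

__all__ = [
    "read_image",
    "write_image",
    "RegionAnnotationSet",
    "load_regions",
    "rasterize_regions",
    "write_measurements",
    "read_measurements",
]

_COORD_NOTE = (
    "coordinates 0-based; rows/cols from top-left; polygon vertices are (x=col, y=row)"
)


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB PNG or TIFF as an HxWx3 uint8 array.

    Greyscale, paletted, 16-bit and alpha-carrying images are rejected with a
    message naming the problem; convert upstream if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValidationError(f"unsupported image format {suffix!r} (use PNG or TIFF)")
    if arr.dtype != np.uint8:
        raise ValidationError(
            f"{path.name}: expected 8-bit channels, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        raise ValidationError(f"{path.name}: greyscale image; an RGB image is required")
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValidationError(
            f"{path.name}: expected exactly 3 channels, got shape {arr.shape}"
        )
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write an image as PNG or TIFF based on the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    elif suffix == ".png":
        Image.fromarray(image).save(path)
    else:
        raise ValidationError(f"unsupported image format {suffix!r}")


@dataclass(frozen=True)
class RegionAnnotationSet:
    """Polygon annotations: (region id, vertex list in (x, y) pixel coords, label)."""

    regions: tuple[tuple[int, np.ndarray, str | None], ...]

    def __post_init__(self):
        checked = []
        for rid, verts, label in self.regions:
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValidationError(
                    f"region {rid}: polygon needs >= 3 (x, y) vertices, got shape {v.shape}"
                )
            checked.append((int(rid), v, label))
        object.__setattr__(self, "regions", tuple(checked))

    def __len__(self) -> int:
        return len(self.regions)


def load_regions(path) -> RegionAnnotationSet:
    """Read a GeoJSON-like annotation file.

    Accepts either a FeatureCollection of Polygon features or a simple
    ``{"regions": [{"id": .., "vertices": [[x, y], ...], "label": ..}, ...]}``.
    """
    with open(path) as fh:
        data = json.load(fh)
    regions = []
    if data.get("type") == "FeatureCollection":
        for i, feat in enumerate(data.get("features", []), start=1):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                raise ValidationError(f"feature {i}: only Polygon geometry is supported")
            ring = geom["coordinates"][0]
            props = feat.get("properties") or {}
            regions.append((props.get("id", i), ring, props.get("label")))
    elif "regions" in data:
        for i, reg in enumerate(data["regions"], start=1):
            regions.append((reg.get("id", i), reg["vertices"], reg.get("label")))
    else:
        raise ValidationError("unrecognized annotation file structure")
    return RegionAnnotationSet(tuple(regions))


def _polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd polygon fill over pixel centers (vectorized ray crossing)."""
    h, w = shape
    px = np.arange(w) + 0.5
    py = np.arange(h) + 0.5
    cx = np.broadcast_to(px[None, :], (h, w))
    cy = np.broadcast_to(py[:, None], (h, w))
    inside = np.zeros(shape, dtype=bool)
    n = vertices.shape[0]
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        if y0 == y1:
            continue
        crosses = (y0 > cy) != (y1 > cy)
        xint = x0 + (cy - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (cx < xint)
    return inside


def rasterize_regions(
    annotations: RegionAnnotationSet, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize polygon annotations to an integer label mask.

    A pixel gets the id of the *first* region (file order) whose polygon
    contains the pixel center under the even-odd rule.  Vertices outside the
    image are clipped with a warning.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=np.int32)
    for rid, verts, _label in annotations.regions:
        v = verts.copy()
        oob = (v[:, 0] < 0) | (v[:, 0] > w) | (v[:, 1] < 0) | (v[:, 1] > h)
        if oob.any():
            warnings.warn(
                f"region {rid}: {int(oob.sum())} vertex/vertices outside the "
                f"{h}x{w} image were clipped",
                stacklevel=2,
            )
            v[:, 0] = np.clip(v[:, 0], 0, w)
            v[:, 1] = np.clip(v[:, 1], 0, h)
        poly = _polygon_mask(v, shape)
        mask[poly & (mask == 0)] = rid
    return mask


def write_measurements(
    measurements: pd.DataFrame, path, metadata: dict | None = None
) -> None:
    """Write a region-measurement table as CSV.

    Columns follow the stable order of ``quantify.MEASUREMENT_COLUMNS`` (any
    extra columns are appended); floats are rounded to 4 decimals; rows are
    sorted by region id.  Provenance (resolved configuration, package
    version) is embedded as '#'-prefixed header comments.
    """
    from . import __version__
    from .quantify import MEASUREMENT_COLUMNS

    df = measurements.copy()
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in MEASUREMENT_COLUMNS
    ]
    df = df[cols]
    if "region" in df.columns:
        df = df.sort_values("region").reset_index(drop=True)
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].round(4)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ihc-catscore {__version__}\n")
        fh.write(f"# {_COORD_NOTE}\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {json.dumps(val, default=str)}\n")
        df.to_csv(fh, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read back a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path, comment="#")
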