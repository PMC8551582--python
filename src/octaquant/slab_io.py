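"""Reading, writing and scaling conventions for enface OCTA slab images.

An enface slab is a 2-D projection of the OCTA volume between two segmented
retinal boundaries, exported by the device as a grayscale raster.  Everything
downstream (ROI geometry, densities, flow-void areas) is expressed in physical
units, so the slab carries its field of view and the derived pixel pitch.

Grid convention: row-major, origin at the top-left pixel, 0-based
``(row, col)`` indexing; physical x runs along columns, y along rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "Layer",
    "LandmarkSet",
    "EnfaceSlab",
    "to_8bit",
    "read_slab",
    "write_slab",
]

#: Rec.601 luminance weights used to collapse RGB exports to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_MIN_DIM = 64


class Layer(str, Enum):
    """Retinal vascular slab identity.

    SVP: superficial vascular plexus (ILM to outer IPL boundary).
    DVP: deep vascular plexus (outer IPL to outer OPL boundary).
    CC:  choriocapillaris (thin slab just below the RPE).
    """

    SVP = "SVP"
    DVP = "DVP"
    CC = "CC"


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical landmarks on the slab grid, in (row, col) pixels.

    ``label_box_px`` is an optional half-open rectangle
    (row0, col0, row1, col1) masking a burnt-in image label.
    """

    fovea_px: Tuple[int, int]
    onh_px: Tuple[int, int]
    label_box_px: Optional[Tuple[int, int, int, int]] = None

    def validate(self, shape: Tuple[int, int]) -> None:
        nr, nc = shape
        for name, (r, c) in (("fovea", self.fovea_px), ("onh", self.onh_px)):
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"{name} landmark {(r, c)} outside {nr}x{nc} grid")
        if tuple(self.fovea_px) == tuple(self.onh_px):
            raise ValueError("fovea and ONH landmarks coincide")
        if self.label_box_px is not None:
            r0, c0, r1, c1 = self.label_box_px
            if not (r0 < r1 and c0 < c1):
                raise ValueError("label box must have positive extent")


@dataclass
class EnfaceSlab:
    """A single-layer 8-bit enface angiogram with physical metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Intensity grid after 8-bit conversion.
    layer : Layer
        Which vascular slab the image represents.
    fov_mm : (float, float)
        Physical field of view as (width_x, height_y) in mm; the study
        default is the 15 x 9 mm widefield scan.
    eye_id, laterality : str
        Identifiers carried through to output tables. Laterality is
        "OD" (right) or "OS" (left).
    landmarks : LandmarkSet, optional
    """

    pixels: np.ndarray
    layer: Layer
    fov_mm: Tuple[float, float] = (15.0, 9.0)
    eye_id: str = ""
    laterality: str = "OD"
    landmarks: Optional[LandmarkSet] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError("slab pixels must be a non-empty 2-D grid")
        if min(self.pixels.shape) < _MIN_DIM:
            raise ValueError(f"slab dimensions must both be >= {_MIN_DIM}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("slab pixels must be uint8; use to_8bit() first")
        w, h = self.fov_mm
        if w <= 0 or h <= 0:
            raise ValueError("field of view must be positive")
        self.layer = Layer(self.layer)
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.landmarks is not None:
            self.landmarks.validate(self.shape)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_pitch_um(self) -> Tuple[float, float]:
        """(x, y) microns per pixel, derived from FOV and grid size."""
        nr, nc = self.pixels.shape
        return (self.fov_mm[0] * 1000.0 / nc, self.fov_mm[1] * 1000.0 / nr)

    @property
    def pixel_area_um2(self) -> float:
        px, py = self.pixel_pitch_um
        return px * py

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_area_um2 / 1e6


def to_8bit(pixels: np.ndarray) -> np.ndarray:
    """Convert an intensity grid of any bit depth to 8-bit.

    uint8 input is returned unchanged (conversion is a no-op, as in ImageJ).
    Anything else is linearly min-max rescaled to [0, 255] and rounded
    half-up; a constant grid maps to all zeros.
    """
    a = np.asarray(pixels)
    if a.size == 0:
        raise ValueError("empty intensity grid")
    if a.dtype == np.uint8:
        return a.copy()
    a = a.astype(np.float64)
    lo, hi = a.min(), a.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("non-finite intensities")
    if hi == lo:
        return np.zeros_like(a, dtype=np.uint8)
    scaled = (a - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def _load_raster(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        return np.asarray(Image.open(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the file named
        raise IOError(f"cannot read slab image {path!r}: {exc}") from exc


def read_slab(
    path: str,
    layer: Layer | str,
    fov_mm: Tuple[float, float] = (15.0, 9.0),
    landmarks: Optional[LandmarkSet] = None,
    eye_id: str = "",
    laterality: str = "OD",
) -> EnfaceSlab:
    """Read a TIFF/PNG enface slab and attach physical metadata.

    RGB(A) rasters are collapsed to Rec.601 luminance before 8-bit
    conversion; higher bit depths are min-max rescaled.
    """
    arr = _load_raster(path)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path!r}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path!r}")
    return EnfaceSlab(
        pixels=to_8bit(arr),
        layer=Layer(layer),
        fov_mm=tuple(fov_mm),  # type: ignore[arg-type]
        eye_id=eye_id,
        laterality=laterality,
        landmarks=landmarks,
    )


def write_slab(slab: EnfaceSlab, path: str) -> None:
    """Write the 8-bit pixel grid losslessly (TIFF or PNG by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, slab.pixels)
    elif ext == ".png":
        Image.fromarray(slab.pixels, mode="L").save(path)
    else:
        raise ValueError(f"unsupported output format {ext!r} (use .tif/.tiff/.png)")
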