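"""Perfusion density, length density, and FAZ shape metrics.

Vascular perfusion density (VPD) is the fraction of an ROI covered by
binarized vessel signal; vascular length density (VLD) is skeletonized
vessel length per unit ROI area in mm^-1.  The foveal avascular zone (FAZ)
is an input polygon (outlined manually in practice); its acircularity index
AI = perimeter / perimeter of the equal-area circle is 1 for a perfect
circle and grows with boundary irregularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from shapely.geometry import Polygon
from skimage.morphology import skeletonize as _skimage_skeletonize

from .roi_geometry import RegionMask
from .thresholding import BinaryMap

__all__ = [
    "VesselMaps",
    "FazShape",
    "skeletonize",
    "vpd",
    "vld",
    "skeleton_length_mm",
    "faz_metrics",
]

#: Neighbor offsets that enumerate each 8-connected skeleton edge once.
_EDGE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _mask_of(b: Union[BinaryMap, np.ndarray]) -> np.ndarray:
    return b.mask if isinstance(b, BinaryMap) else np.asarray(b, dtype=bool)


def skeletonize(binary: Union[BinaryMap, np.ndarray]) -> np.ndarray:
    """Topology-preserving thinning to 8-connected unit-width centerlines."""
    return _skimage_skeletonize(_mask_of(binary))


@dataclass
class VesselMaps:
    """Binary vessel map, its skeleton, and the ROI they are measured over."""

    binary: BinaryMap
    skeleton: np.ndarray
    roi: RegionMask

    @classmethod
    def from_binary(cls, binary: BinaryMap, roi: RegionMask) -> "VesselMaps":
        return cls(binary=binary, skeleton=skeletonize(binary), roi=roi)


def vpd(binary: Union[BinaryMap, np.ndarray], roi: RegionMask) -> float:
    """Perfusion density: foreground fraction of the ROI, in [0, 1].

    Reported as percent (x100) in output tables.
    """
    fg = _mask_of(binary)
    if fg.shape != roi.mask.shape:
        raise ValueError("binary map and ROI shapes differ")
    n_roi = roi.n_pixels
    if n_roi == 0:
        raise ValueError("empty ROI")
    return float((fg & roi.mask).sum()) / n_roi


def skeleton_length_mm(
    skeleton: np.ndarray,
    roi_mask: Optional[np.ndarray],
    pitch_um: Tuple[float, float],
    length_rule: str = "steps",
) -> float:
    """Total centerline length inside the ROI, in mm.

    ``length_rule='steps'`` sums 8-neighbor adjacency steps: orthogonal
    steps contribute one pitch, diagonal steps the diagonal pitch
    (pitch * sqrt(2) on an isotropic grid).  Branches crossing the ROI
    boundary contribute only steps with both endpoints inside.
    ``length_rule='pixel_count'`` is the coarser pixel-count x mean-pitch
    accounting some tools use.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if roi_mask is not None:
        sk = sk & np.asarray(roi_mask, dtype=bool)
    px, py = (p / 1000.0 for p in pitch_um)  # mm per pixel
    if length_rule == "pixel_count":
        return float(sk.sum()) * (px + py) / 2.0
    if length_rule != "steps":
        raise ValueError("length_rule must be 'steps' or 'pixel_count'")
    total = 0.0
    nr, nc = sk.shape
    for dr, dc in _EDGE_OFFSETS:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        pairs = sk[r0:r1, c0:c1] & sk[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        step = float(np.hypot(dc * px, dr * py))
        total += step * int(pairs.sum())
    return total


def vld(
    maps: VesselMaps,
    pitch_um: Tuple[float, float],
    length_rule: str = "steps",
) -> float:
    """Vascular length density: skeleton length per ROI area, mm^-1."""
    area = maps.roi.area_mm2
    if area <= 0:
        raise ValueError("empty ROI")
    return skeleton_length_mm(maps.skeleton, maps.roi.mask, pitch_um, length_rule) / area


@dataclass(frozen=True)
class FazShape:
    """FAZ boundary polygon with its derived shape metrics (mm units)."""

    boundary_mm: np.ndarray
    area_mm2: float
    perimeter_mm: float
    ai: float


def faz_metrics(
    boundary: np.ndarray,
    pitch_um: Optional[Tuple[float, float]] = None,
) -> FazShape:
    """Area, perimeter and acircularity index of a FAZ boundary polygon.

    ``boundary`` is an (N, 2) vertex array.  With ``pitch_um`` given the
    vertices are (row, col) pixel coordinates and are converted to mm;
    otherwise they are taken as (x, y) in mm.  The polygon must be simple
    (non-self-intersecting) with at least 3 vertices.

    Area comes from the shoelace formula, the perimeter from summed
    vertex-to-vertex Euclidean lengths, and AI = P / (2 * sqrt(pi * A)).
    """
    verts = np.asarray(boundary, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("boundary must be an (N >= 3, 2) vertex array")
    if pitch_um is not None:
        px, py = pitch_um
        verts = np.column_stack([verts[:, 1] * px / 1000.0, verts[:, 0] * py / 1000.0])
    poly = Polygon(verts)
    if not poly.is_valid or not poly.is_simple or poly.area <= 0:
        raise ValueError("FAZ boundary must be a simple, non-degenerate polygon")
    area = float(poly.area)
    perim = float(poly.exterior.length)
    return FazShape(
        boundary_mm=verts,
        area_mm2=area,
        perimeter_mm=perim,
        ai=perim / (2.0 * np.sqrt(np.pi * area)),
    )
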