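"""Analysis regions as boolean masks with exact physical areas.

The study quantifies each slab over fixed anatomical regions: a 6 mm disk at
the fovea (macular), a 0.5 mm-wide annulus of 2--3 mm diameter at the optic
nerve head (peripapillary), the whole field of view with the 3 mm papilla
disk and any burnt-in label removed, and -- for choriocapillaris flow voids
-- three 3 mm disks flanking the macular disk (peripheral).

Pixel-in-region rule: a pixel belongs to a disk when its *center* lies
strictly within the radius (half-open disk), which makes boundary handling
deterministic.  Masks are pure geometry: they depend on the grid, the pitch
and the landmarks, never on intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .slab_io import EnfaceSlab

__all__ = [
    "RegionMask",
    "macular_mask",
    "peripapillary_mask",
    "whole_fov_mask",
    "peripheral_circles_mask",
    "default_peripheral_centers",
]

# Defaults in mm, per the widefield protocol.
MACULAR_DIAMETER_MM = 6.0
PERIPAP_INNER_MM = 2.0
PERIPAP_OUTER_MM = 3.0
ONH_EXCLUSION_MM = 3.0
PERIPHERAL_DIAMETER_MM = 3.0
#: Fovea-to-center distance of the default peripheral circles (tangent to the
#: macular disk) and their angles from horizontal, chosen so all three disks
#: stay inside the 9 mm image height.
PERIPHERAL_RADIUS_FROM_FOVEA_MM = 4.5
PERIPHERAL_ANGLES_DEG = (-40.0, 0.0, 40.0)


@dataclass
class RegionMask:
    """A named boolean ROI congruent with its slab grid."""

    name: str
    mask: np.ndarray
    pixel_area_mm2: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_mm2(self) -> float:
        """Physical area of the region (true-pixel count x pixel area)."""
        return float(self.mask.sum()) * self.pixel_area_mm2

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _center_distances_mm(slab: EnfaceSlab, center_px: Tuple[float, float]) -> np.ndarray:
    """Distance in mm from every pixel center to the given pixel's center."""
    px, py = (p / 1000.0 for p in slab.pixel_pitch_um)
    nr, nc = slab.shape
    r0, c0 = center_px
    dy = (np.arange(nr) - r0)[:, None] * py
    dx = (np.arange(nc) - c0)[None, :] * px
    return np.hypot(dy, dx)


def _center_mm(slab: EnfaceSlab, center_px: Tuple[float, float]) -> Tuple[float, float]:
    """Physical (x, y) of a pixel center, origin at the top-left image corner."""
    px, py = (p / 1000.0 for p in slab.pixel_pitch_um)
    r, c = center_px
    return ((c + 0.5) * px, (r + 0.5) * py)


def _require_disk_inside(slab: EnfaceSlab, center_px, radius_mm: float, what: str) -> None:
    x, y = _center_mm(slab, center_px)
    w, h = slab.fov_mm
    if x - radius_mm < 0 or x + radius_mm > w or y - radius_mm < 0 or y + radius_mm > h:
        raise ValueError(
            f"{what}: disk of radius {radius_mm} mm at ({x:.2f}, {y:.2f}) mm "
            f"exceeds the {w} x {h} mm field of view"
        )


def macular_mask(
    slab: EnfaceSlab,
    fovea_px: Tuple[float, float],
    diameter_mm: float = MACULAR_DIAMETER_MM,
) -> RegionMask:
    """Disk of the given diameter (default 6 mm) centered at the fovea."""
    r = diameter_mm / 2.0
    _require_disk_inside(slab, fovea_px, r, "macular region")
    mask = _center_distances_mm(slab, fovea_px) < r
    return RegionMask("macular", mask, slab.pixel_area_mm2)


def peripapillary_mask(
    slab: EnfaceSlab,
    onh_px: Tuple[float, float],
    inner_diameter_mm: float = PERIPAP_INNER_MM,
    outer_diameter_mm: float = PERIPAP_OUTER_MM,
) -> RegionMask:
    """500 um-wide annulus (2 mm inner, 3 mm outer diameter) at the ONH."""
    ri, ro = inner_diameter_mm / 2.0, outer_diameter_mm / 2.0
    if not 0 < ri < ro:
        raise ValueError("need 0 < inner radius < outer radius")
    _require_disk_inside(slab, onh_px, ro, "peripapillary region")
    d = _center_distances_mm(slab, onh_px)
    return RegionMask("peripapillary", (d >= ri) & (d < ro), slab.pixel_area_mm2)


def whole_fov_mask(
    slab: EnfaceSlab,
    onh_px: Tuple[float, float],
    label_box_px: Optional[Tuple[int, int, int, int]] = None,
    onh_exclusion_mm: float = ONH_EXCLUSION_MM,
) -> RegionMask:
    """Whole field of view minus the optic papilla disk and any label box."""
    mask = np.ones(slab.shape, dtype=bool)
    mask &= _center_distances_mm(slab, onh_px) >= onh_exclusion_mm / 2.0
    if label_box_px is not None:
        r0, c0, r1, c1 = label_box_px
        mask[max(r0, 0) : r1, max(c0, 0) : c1] = False
    return RegionMask("whole_fov", mask, slab.pixel_area_mm2)


def default_peripheral_centers(
    slab: EnfaceSlab,
    fovea_px: Tuple[float, float],
    onh_px: Tuple[float, float],
    distance_mm: float = PERIPHERAL_RADIUS_FROM_FOVEA_MM,
    angles_deg: Sequence[float] = PERIPHERAL_ANGLES_DEG,
) -> List[Tuple[float, float]]:
    """Default peripheral flow-void circle centers, in (row, col) pixels.

    Three centers at ``distance_mm`` from the fovea (tangent to the 6 mm
    macular disk) fanned at ``angles_deg`` from horizontal on the side of
    the fovea *away* from the optic nerve head.
    """
    px, py = (p / 1000.0 for p in slab.pixel_pitch_um)
    direction = 1.0 if onh_px[1] <= fovea_px[1] else -1.0
    centers = []
    for a in angles_deg:
        th = np.deg2rad(a)
        dx_mm = direction * distance_mm * np.cos(th)
        dy_mm = distance_mm * np.sin(th)
        centers.append((fovea_px[0] + dy_mm / py, fovea_px[1] + dx_mm / px))
    return centers


def peripheral_circles_mask(
    slab: EnfaceSlab,
    fovea_px: Tuple[float, float],
    centers_px: Sequence[Tuple[float, float]],
    diameter_mm: float = PERIPHERAL_DIAMETER_MM,
    macular_diameter_mm: float = MACULAR_DIAMETER_MM,
) -> RegionMask:
    """Union of three 3 mm disks flanking (not intersecting) the macular disk."""
    r = diameter_mm / 2.0
    rm = macular_diameter_mm / 2.0
    fx, fy = _center_mm(slab, fovea_px)
    mask = np.zeros(slab.shape, dtype=bool)
    for i, ctr in enumerate(centers_px):
        _require_disk_inside(slab, ctr, r, f"peripheral circle {i}")
        cx, cy = _center_mm(slab, ctr)
        if np.hypot(cx - fx, cy - fy) < rm + r - 1e-9:
            raise ValueError(f"peripheral circle {i} intersects the macular disk")
        mask |= _center_distances_mm(slab, ctr) < r
    return RegionMask("peripheral_circles", mask, slab.pixel_area_mm2)
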