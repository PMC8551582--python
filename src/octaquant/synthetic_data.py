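"""Synthetic angiograms and cohort tables with known ground truth.

Every pipeline stage is testable without any image download: the generators
emit, alongside each image, the exact planted vessel mask / lesion label map
/ metric parameters, so recovered quantities can be checked against what was
planted rather than against eyeballed output.

``generate_svp`` draws a stochastic branching bright-vessel tree over a
granular capillary bed (emulating superficial/deep plexus slabs),
``generate_cc`` a quasi-uniform bright choriocapillaris texture with dark
hypoperfusion lesions and multiplicative speckle, and ``generate_cohort``
per-eye metric tables with group means/SDs taken from the study's printed
summary statistics.  All generators are pure functions of their spec,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .slab_io import EnfaceSlab, Layer

__all__ = [
    "VesselTreeSpec",
    "CcFieldSpec",
    "GroupSpec",
    "CohortSpec",
    "generate_svp",
    "generate_cc",
    "generate_cohort",
    "random_lesions",
    "COHORT_PRESETS",
    "cohort_preset",
]

#: Default synthetic grid: 834 x 500 px for the 15 x 9 mm field (~18 um/px).
DEFAULT_GRID_PX = (500, 834)
DEFAULT_FOV_MM = (15.0, 9.0)


# ------------------------------------------------------------------ SVP / DVP


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of the branching-tree angiogram generator.

    ``branching_prob`` is per mm of vessel growth; widths start at
    ``width_root_um`` and shrink by ``width_decay`` at each branching.
    ``capillary_fill_target`` is the total planted foreground fraction
    (tree plus capillary bed) over the whole image.
    """

    seed: int = 0
    n_roots: int = 5
    branching_prob: float = 0.5
    width_root_um: float = 60.0
    width_decay: float = 0.75
    capillary_fill_target: float = 0.45
    fov_mm: Tuple[float, float] = DEFAULT_FOV_MM
    grid_px: Tuple[int, int] = DEFAULT_GRID_PX
    layer: Layer = Layer.SVP
    min_width_um: float = 16.0
    step_mm: float = 0.25
    vessel_gray: Tuple[int, int] = (150, 245)  # capillary..artery brightness
    capillary_gray: int = 110
    background_gray: int = 25
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.capillary_fill_target < 1.0:
            raise ValueError("fill target must be in (0, 1)")
        if self.width_root_um <= 0 or self.width_decay <= 0 or self.width_decay > 1:
            raise ValueError("widths must be positive and non-increasing along branches")


def _grow_tree(spec: VesselTreeSpec, rng: np.random.Generator):
    """Random branching polylines in mm coordinates: (p0, p1, width_um) list."""
    w_mm, h_mm = spec.fov_mm
    segments: List[Tuple[np.ndarray, np.ndarray, float]] = []
    # roots enter from the left/right edges heading inward
    stack = []
    for i in range(spec.n_roots):
        x0 = 0.0 if i % 2 == 0 else w_mm
        y0 = rng.uniform(0.1 * h_mm, 0.9 * h_mm)
        heading = 0.0 if i % 2 == 0 else np.pi
        stack.append((np.array([x0, y0]), heading, spec.width_root_um))
    while stack:
        pos, heading, width = stack.pop()
        while width >= spec.min_width_um:
            heading += rng.normal(0.0, 0.35)
            new = pos + spec.step_mm * np.array([np.cos(heading), np.sin(heading)])
            new[0] = np.clip(new[0], 0.0, w_mm)
            new[1] = np.clip(new[1], 0.0, h_mm)
            if np.allclose(new, pos):
                break
            segments.append((pos.copy(), new.copy(), width))
            pos = new
            on_edge = new[0] in (0.0, w_mm) or new[1] in (0.0, h_mm)
            if on_edge:
                break
            if rng.random() < spec.branching_prob * spec.step_mm:
                child_w = width * spec.width_decay
                if child_w >= spec.min_width_um:
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    stack.append((pos.copy(), heading + side * rng.uniform(0.5, 1.1), child_w))
                    width = child_w  # parent narrows past the bifurcation
    return segments


def _rasterize_segments(segments, spec: VesselTreeSpec):
    """Distance-to-segment rasterization; returns (mask, width_map_um)."""
    nr, nc = spec.grid_px
    px = spec.fov_mm[0] / nc
    py = spec.fov_mm[1] / nr
    mask = np.zeros((nr, nc), dtype=bool)
    width_map = np.zeros((nr, nc), dtype=np.float32)
    for p0, p1, w_um in segments:
        r_mm = w_um / 2000.0
        x_lo = min(p0[0], p1[0]) - r_mm
        x_hi = max(p0[0], p1[0]) + r_mm
        y_lo = min(p0[1], p1[1]) - r_mm
        y_hi = max(p0[1], p1[1]) + r_mm
        c0 = max(int(x_lo / px) - 1, 0)
        c1 = min(int(x_hi / px) + 2, nc)
        r0 = max(int(y_lo / py) - 1, 0)
        r1 = min(int(y_hi / py) + 2, nr)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = (np.arange(c0, c1) + 0.5) * px
        ys = (np.arange(r0, r1) + 0.5) * py
        X, Y = np.meshgrid(xs, ys)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.hypot(X - p0[0], Y - p0[1])
        else:
            t = np.clip(((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / L2, 0.0, 1.0)
            dist = np.hypot(X - (p0[0] + t * d[0]), Y - (p0[1] + t * d[1]))
        hit = dist <= r_mm
        mask[r0:r1, c0:c1] |= hit
        sub = width_map[r0:r1, c0:c1]
        np.maximum(sub, np.where(hit, w_um, 0.0), out=sub)
    return mask, width_map


def _smooth_noise(shape, rng: np.random.Generator, sigma_px: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_svp(spec: VesselTreeSpec) -> Tuple[EnfaceSlab, np.ndarray, float]:
    """Generate a plexus slab: (slab, planted vessel mask, tree centerline mm).

    The capillary bed is added by thresholding smoothed noise at the exact
    quantile that brings the total planted foreground fraction to
    ``capillary_fill_target`` (the tree alone never reaches it).  The
    returned centerline length is the analytic summed length of the tree
    segments; the capillary bed has no meaningful centerline ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_roots == 0:
        blank = np.full(spec.grid_px, spec.background_gray, dtype=np.uint8)
        slab = EnfaceSlab(blank, spec.layer, spec.fov_mm, eye_id=f"syn{spec.seed}")
        return slab, np.zeros(spec.grid_px, dtype=bool), 0.0
    segments = _grow_tree(spec, rng)
    tree_mask, width_map = _rasterize_segments(segments, spec)
    centerline_mm = float(sum(np.hypot(*(p1 - p0)) for p0, p1, _ in segments))

    fill_now = tree_mask.mean()
    target = spec.capillary_fill_target
    cap_mask = np.zeros_like(tree_mask)
    if fill_now > target + 0.02:
        raise ValueError(
            f"fill target {target} unsatisfiable: tree alone covers {fill_now:.3f}"
        )
    if fill_now < target:
        # capillary bed: correlated noise thresholded at the quantile that
        # tops the union up to the target exactly (up to ties)
        noise = _smooth_noise(spec.grid_px, rng, sigma_px=1.2)
        free = ~tree_mask
        need = target - fill_now
        q = 1.0 - need / free.mean()
        cut = np.quantile(noise[free], q)
        cap_mask = free & (noise > cut)
    planted = tree_mask | cap_mask

    img = np.full(spec.grid_px, float(spec.background_gray))
    img += 12.0 * _smooth_noise(spec.grid_px, rng, 8.0)  # slow illumination drift
    lo, hi = spec.vessel_gray
    rel = np.clip(width_map / spec.width_root_um, 0.0, 1.0)
    img[tree_mask] = lo + (hi - lo) * rel[tree_mask]
    img[cap_mask] = spec.capillary_gray
    img += rng.normal(0.0, spec.noise_sd, spec.grid_px)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    slab = EnfaceSlab(pixels, spec.layer, spec.fov_mm, eye_id=f"syn{spec.seed}")
    return slab, planted, centerline_mm


# ------------------------------------------------------------------------- CC


@dataclass(frozen=True)
class CcFieldSpec:
    """Parameters of the choriocapillaris texture generator.

    ``lesions`` is a list of (center_mm (x, y), area_um2, contrast) planted
    dark flow-void disks; contrast is the fractional intensity drop.
    ``projection_mask`` optionally darkens pixels under large superficial
    vessels to emulate the projection artifact that the large-vessel mask
    removes.
    """

    seed: int = 0
    fov_mm: Tuple[float, float] = DEFAULT_FOV_MM
    grid_px: Tuple[int, int] = DEFAULT_GRID_PX
    base_gray: float = 180.0
    texture_amplitude: float = 8.0
    texture_sigma_px: float = 2.0
    lesions: Tuple[Tuple[Tuple[float, float], float, float], ...] = ()
    speckle_sigma: float = 0.03
    projection_mask: Optional[np.ndarray] = None
    projection_contrast: float = 0.35

    def __post_init__(self) -> None:
        w, h = self.fov_mm
        for (cx, cy), area, contrast in self.lesions:
            if area <= 0:
                raise ValueError("lesion areas must be positive")
            r_mm = np.sqrt(area / np.pi) / 1000.0
            if not (r_mm <= cx <= w - r_mm and r_mm <= cy <= h - r_mm):
                raise ValueError(f"lesion at ({cx}, {cy}) mm not inside the FOV")
            if not 0 < contrast <= 1:
                raise ValueError("lesion contrast must be in (0, 1]")


def generate_cc(spec: CcFieldSpec) -> Tuple[EnfaceSlab, np.ndarray]:
    """Generate a CC slab: (slab, lesion label map).

    The label map assigns each planted lesion a positive integer id; its
    pixel counts are the rasterized ground-truth areas (which is what a
    perfect particle analysis should recover).  Overlapping or touching
    lesions are rejected so planted components stay distinct.
    """
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.grid_px
    px = spec.fov_mm[0] / nc
    py = spec.fov_mm[1] / nr
    img = spec.base_gray + spec.texture_amplitude * _smooth_noise(
        spec.grid_px, rng, spec.texture_sigma_px
    )
    labels = np.zeros(spec.grid_px, dtype=np.int32)
    xs = (np.arange(nc) + 0.5) * px
    ys = (np.arange(nr) + 0.5) * py
    X, Y = np.meshgrid(xs, ys)
    for i, ((cx, cy), area_um2, contrast) in enumerate(spec.lesions, start=1):
        r_mm = np.sqrt(area_um2 / np.pi) / 1000.0
        hit = (X - cx) ** 2 + (Y - cy) ** 2 < r_mm**2
        if not hit.any():
            raise ValueError(f"lesion {i} smaller than one pixel at this pitch")
        grown = ndimage.binary_dilation(hit, structure=np.ones((3, 3), dtype=bool))
        if (labels[grown] != 0).any():
            raise ValueError(f"lesion {i} overlaps or touches an earlier lesion")
        labels[hit] = i
        img[hit] *= 1.0 - contrast
    if spec.projection_mask is not None:
        pm = np.asarray(spec.projection_mask, dtype=bool)
        if pm.shape != tuple(spec.grid_px):
            raise ValueError("projection mask shape differs from the grid")
        img[pm] *= 1.0 - spec.projection_contrast
    if spec.speckle_sigma > 0:
        # multiplicative gamma speckle, mean 1, sd = speckle_sigma
        shape_k = 1.0 / spec.speckle_sigma**2
        img *= rng.gamma(shape_k, 1.0 / shape_k, spec.grid_px)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    slab = EnfaceSlab(pixels, Layer.CC, spec.fov_mm, eye_id=f"syn{spec.seed}")
    return slab, labels


def random_lesions(
    rng: np.random.Generator,
    n: int,
    fov_mm: Tuple[float, float] = DEFAULT_FOV_MM,
    area_um2_range: Tuple[float, float] = (1500.0, 8000.0),
    contrast: float = 0.55,
    margin_mm: float = 0.5,
    min_sep_mm: float = 0.35,
    region_mm: Optional[Tuple[float, float, float, float]] = None,
    max_tries: int = 10000,
) -> Tuple[Tuple[Tuple[float, float], float, float], ...]:
    """Draw n non-overlapping lesion tuples for a CcFieldSpec by rejection.

    ``region_mm`` optionally restricts centers to (x_lo, x_hi, y_lo, y_hi).
    """
    w, h = fov_mm
    x_lo, x_hi, y_lo, y_hi = region_mm or (margin_mm, w - margin_mm, margin_mm, h - margin_mm)
    placed: List[Tuple[float, float, float]] = []  # x, y, radius_mm
    lesions = []
    tries = 0
    while len(lesions) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {n} disjoint lesions in {max_tries} tries")
        area = float(rng.uniform(*area_um2_range))
        r_mm = float(np.sqrt(area / np.pi) / 1000.0)
        x = float(rng.uniform(x_lo, x_hi))
        y = float(rng.uniform(y_lo, y_hi))
        if any(np.hypot(x - px_, y - py_) < r_mm + pr + min_sep_mm for px_, py_, pr in placed):
            continue
        placed.append((x, y, r_mm))
        lesions.append(((x, y), area, contrast))
    return tuple(lesions)


# ---------------------------------------------------------------- cohort tables


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: sample size, metric means/SDs, and BCVA parameters."""

    n_eyes: int
    metric_means: Dict[str, float]
    metric_sds: Dict[str, float]
    bcva_mean: Optional[float] = None
    bcva_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_eyes < 3:
            raise ValueError("each group needs n >= 3 eyes")
        for name, sd in self.metric_sds.items():
            if sd <= 0:
                raise ValueError(f"SD of {name!r} must be positive")
        if self.bcva_sd is not None and self.bcva_sd <= 0:
            raise ValueError("BCVA SD must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Three-arm cohort with an optional metric-BCVA correlation target.

    ``corr_metric``/``corr_r`` plant a Pearson correlation between the named
    metric and BCVA within each arm that has BCVA, via the bivariate-normal
    construction bcva = mu + sd * (r z1 + sqrt(1-r^2) z2).
    """

    groups: Dict[str, GroupSpec]
    seed: int = 0
    corr_metric: Optional[str] = None
    corr_r: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 < self.corr_r < 1.0:
            raise ValueError("target correlation must satisfy |r| < 1")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-eye cohort table from group-wise normal distributions."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gname, g in spec.groups.items():
        z_corr = rng.standard_normal(g.n_eyes)
        for i in range(g.n_eyes):
            row: Dict[str, object] = {"eye_id": f"{gname}_{i:03d}", "group": gname}
            for m, mu in g.metric_means.items():
                sd = g.metric_sds[m]
                if m == spec.corr_metric:
                    row[m] = mu + sd * z_corr[i]
                else:
                    row[m] = mu + sd * rng.standard_normal()
            if g.bcva_mean is None:
                row["bcva_logmar"] = np.nan
            else:
                z2 = rng.standard_normal()
                if spec.corr_metric is not None and spec.corr_metric in g.metric_means:
                    z = spec.corr_r * z_corr[i] + np.sqrt(1 - spec.corr_r**2) * z2
                else:
                    z = z2
                row["bcva_logmar"] = g.bcva_mean + g.bcva_sd * z
            rows.append(row)
    return pd.DataFrame(rows)


def _three_arm(name: str, hc, acute, conv, bcva=None) -> Dict[str, GroupSpec]:
    """(mean, sd, n) triplets per arm -> GroupSpec dict for one metric."""
    bcva = bcva or {"acute": (0.60, 0.35), "convalescent": (0.42, 0.28)}
    out = {}
    for gname, (mu, sd, n) in (("HC", hc), ("acute", acute), ("convalescent", conv)):
        b = bcva.get(gname)
        out[gname] = GroupSpec(
            n_eyes=n,
            metric_means={name: mu},
            metric_sds={name: sd},
            bcva_mean=None if b is None else b[0],
            bcva_sd=None if b is None else b[1],
        )
    return out


def _iqr_normal(median: float, p25: float, p75: float) -> Tuple[float, float]:
    """Normal (mean, sd) matching a printed median and quartiles."""
    return median, (p75 - p25) / 1.349


#: Printed group summary statistics (mean, SD, n per arm) used as simulator
#: presets.  VPD/FV-area values are percent, VLD mm^-1, FAZ mm^2, FV sizes
#: um^2; count/size presets are normal-matched from median (P25-P75).
COHORT_PRESETS: Dict[str, Dict[str, GroupSpec]] = {
    "faz_area": _three_arm("faz_area", (0.409, 0.090, 30), (0.334, 0.116, 20), (0.347, 0.110, 30)),
    "faz_ai": _three_arm("faz_ai", (1.133, 0.048, 30), (1.122, 0.047, 20), (1.133, 0.034, 30)),
    "macular_svp_vpd": _three_arm(
        "macular_svp_vpd", (49.41, 2.55, 30), (42.70, 5.14, 20), (49.24, 2.39, 30)
    ),
    "wholefov_svp_vpd": _three_arm(
        "wholefov_svp_vpd", (50.95, 3.52, 30), (44.41, 4.48, 20), (50.46, 3.98, 30)
    ),
    "peripap_svp_vpd": _three_arm(
        "peripap_svp_vpd", (49.04, 2.53, 30), (41.15, 5.73, 20), (47.72, 2.60, 30)
    ),
    "macular_dvp_vpd": _three_arm(
        "macular_dvp_vpd", (50.93, 2.24, 30), (49.63, 2.38, 20), (51.17, 2.96, 30)
    ),
    "wholefov_dvp_vpd": _three_arm(
        "wholefov_dvp_vpd", (53.10, 3.59, 30), (51.52, 3.38, 20), (54.25, 4.32, 30)
    ),
    "macular_cc_vpd": _three_arm(
        "macular_cc_vpd", (68.23, 2.67, 30), (63.53, 2.83, 20), (69.30, 4.34, 30)
    ),
    "wholefov_cc_vpd": _three_arm(
        "wholefov_cc_vpd", (67.59, 2.62, 30), (62.42, 3.01, 20), (68.61, 4.61, 30)
    ),
    "macular_svp_vld": _three_arm(
        "macular_svp_vld", (24.07, 1.91, 30), (21.88, 2.54, 20), (24.69, 2.04, 30)
    ),
    "wholefov_svp_vld": _three_arm(
        "wholefov_svp_vld", (23.15, 1.88, 30), (20.07, 1.91, 20), (23.54, 1.54, 30)
    ),
    "peripap_svp_vld": _three_arm(
        "peripap_svp_vld", (22.79, 1.37, 30), (19.21, 2.94, 20), (22.84, 1.35, 30)
    ),
    "macular_dvp_vld": _three_arm(
        "macular_dvp_vld", (27.29, 1.13, 30), (27.16, 1.30, 20), (27.86, 1.68, 30)
    ),
    "wholefov_dvp_vld": _three_arm(
        "wholefov_dvp_vld", (27.60, 1.01, 30), (27.05, 1.35, 20), (27.77, 1.71, 30)
    ),
    "macular_fv_area": _three_arm(
        "macular_fv_area", (14.80, 3.84, 30), (21.61, 3.80, 20), (14.86, 5.87, 30)
    ),
    "peripheral_fv_area": _three_arm(
        "peripheral_fv_area", (15.04, 4.03, 30), (22.49, 4.49, 20), (14.04, 5.98, 30)
    ),
    "macular_fv1000_count": _three_arm(
        "macular_fv1000_count",
        (*_iqr_normal(1182.0, 1140.25, 1246.25), 30),
        (*_iqr_normal(1285.0, 1204.0, 1335.0), 20),
        (*_iqr_normal(1211.5, 973.5, 1273.25), 30),
    ),
    "macular_fv1000_size": _three_arm(
        "macular_fv1000_size",
        (*_iqr_normal(3332.5, 2911.75, 3687.25), 30),
        (*_iqr_normal(4901.5, 3998.0, 5332.5), 20),
        (*_iqr_normal(3316.0, 2466.5, 3940.0), 30),
    ),
}


def cohort_preset(
    name: str, seed: int = 0, corr_r: float = 0.0, corr_metric: Optional[str] = None
) -> CohortSpec:
    """CohortSpec for a named printed-table preset (see COHORT_PRESETS)."""
    if name not in COHORT_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choices: {sorted(COHORT_PRESETS)}")
    groups = COHORT_PRESETS[name]
    if corr_metric is None and corr_r != 0.0:
        corr_metric = name
    return CohortSpec(groups=groups, seed=seed, corr_metric=corr_metric, corr_r=corr_r)
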