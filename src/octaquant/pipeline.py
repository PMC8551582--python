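"""End-to-end per-eye processing and study-level report generation.

``run_eye`` turns one eye's slab set into a tidy metric table; ``run_study``
maps it over a manifest and feeds the pooled per-eye table to the statistics
stage (group comparisons, BCVA correlations, stepwise BCVA model).  The
statistics stage consumes only the per-eye table, so it can be re-run
standalone on a saved metrics CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .cc_metrics import (
    WAND_MIN_COMPONENT_AREA_UM2,
    cc_binarize_masked,
    flow_void_metrics,
    large_vessel_mask,
)
from .cohort_stats import group_compare, pearson_with_p, stepwise_regression
from .retina_metrics import VesselMaps, faz_metrics, vld, vpd
from .roi_geometry import (
    default_peripheral_centers,
    macular_mask,
    peripapillary_mask,
    peripheral_circles_mask,
    whole_fov_mask,
)
from .slab_io import EnfaceSlab, LandmarkSet, Layer, read_slab
from .thresholding import PHANSALKAR_RADIUS_PX, huang_binarize

log = logging.getLogger("octaquant")

__all__ = ["EyeInput", "RunConfig", "run_eye", "run_study"]

#: Metrics emitted for a complete eye (plus faz_area/faz_perimeter/faz_ai).
FULL_METRIC_SET = (
    "macular_svp_vpd", "wholefov_svp_vpd", "peripap_svp_vpd",
    "macular_svp_vld", "wholefov_svp_vld", "peripap_svp_vld",
    "macular_dvp_vpd", "wholefov_dvp_vpd",
    "macular_dvp_vld", "wholefov_dvp_vld",
    "macular_cc_vpd", "wholefov_cc_vpd",
    "macular_fv_area", "macular_fv1000_count", "macular_fv1000_size",
    "peripheral_fv_area", "peripheral_fv1000_count", "peripheral_fv1000_size",
)


@dataclass
class EyeInput:
    """Manifest entry: one eye's slabs, landmarks and clinical columns."""

    eye_id: str
    group: str
    fovea_px: Tuple[int, int]
    onh_px: Tuple[int, int]
    svp: Optional[EnfaceSlab] = None
    dvp: Optional[EnfaceSlab] = None
    cc: Optional[EnfaceSlab] = None
    svp_path: Optional[str] = None
    dvp_path: Optional[str] = None
    cc_path: Optional[str] = None
    bcva_logmar: Optional[float] = None
    laterality: str = "OD"
    faz_polygon_px: Optional[np.ndarray] = None
    label_box_px: Optional[Tuple[int, int, int, int]] = None


@dataclass
class RunConfig:
    """Pipeline parameters; every value is logged into the output rows."""

    eyes: List[EyeInput] = field(default_factory=list)
    fov_mm: Tuple[float, float] = (15.0, 9.0)
    vld_length_rule: str = "steps"
    phansalkar_radius_px: int = PHANSALKAR_RADIUS_PX
    lv_min_component_area_um2: float = WAND_MIN_COMPONENT_AREA_UM2
    fv_min_area_um2: float = 1000.0
    peripheral_centers_px: Optional[Sequence[Tuple[float, float]]] = None

    def param_hash(self) -> str:
        payload = {
            "fov_mm": self.fov_mm,
            "vld_length_rule": self.vld_length_rule,
            "phansalkar_radius_px": self.phansalkar_radius_px,
            "lv_min_component_area_um2": self.lv_min_component_area_um2,
            "fv_min_area_um2": self.fv_min_area_um2,
            "version": __version__,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _resolve_slab(eye: EyeInput, which: str, cfg: RunConfig) -> Optional[EnfaceSlab]:
    slab = getattr(eye, which)
    if slab is not None:
        return slab
    path = getattr(eye, f"{which}_path")
    if path is None:
        return None
    landmarks = LandmarkSet(eye.fovea_px, eye.onh_px, eye.label_box_px)
    return read_slab(path, Layer(which.upper()), cfg.fov_mm, landmarks,
                     eye_id=eye.eye_id, laterality=eye.laterality)


def run_eye(cfg: RunConfig, eye: EyeInput) -> Dict[str, float]:
    """Compute every applicable metric for one eye.

    The SVP slab is mandatory (it defines the large-vessel mask and carries
    the peripapillary metrics); DVP and CC slabs, and the FAZ polygon, are
    optional and simply skip their metrics when absent.
    """
    svp = _resolve_slab(eye, "svp", cfg)
    if svp is None:
        raise ValueError(f"eye {eye.eye_id!r}: SVP slab is mandatory")
    dvp = _resolve_slab(eye, "dvp", cfg)
    cc = _resolve_slab(eye, "cc", cfg)
    pitch = svp.pixel_pitch_um

    mac = macular_mask(svp, eye.fovea_px)
    peripap = peripapillary_mask(svp, eye.onh_px)
    whole = whole_fov_mask(svp, eye.onh_px, eye.label_box_px)
    out: Dict[str, float] = {}

    for layer_name, slab, rois in (
        ("svp", svp, (("macular", mac), ("wholefov", whole), ("peripap", peripap))),
        ("dvp", dvp, (("macular", mac), ("wholefov", whole))),
    ):
        if slab is None:
            log.warning("eye %s: %s slab missing, skipping its metrics",
                        eye.eye_id, layer_name.upper())
            continue
        binary = huang_binarize(slab)
        log.debug("eye %s %s: Huang threshold %d", eye.eye_id, layer_name,
                  binary.params["threshold"])
        for roi_name, roi in rois:
            maps = VesselMaps.from_binary(binary, roi)
            out[f"{roi_name}_{layer_name}_vpd"] = 100.0 * vpd(binary, roi)
            out[f"{roi_name}_{layer_name}_vld"] = vld(maps, pitch, cfg.vld_length_rule)

    if cc is not None:
        lv = large_vessel_mask(svp, cfg.lv_min_component_area_um2)
        log.debug("eye %s: Default threshold %s for large-vessel mask",
                  eye.eye_id, lv.threshold)
        for roi_name, roi in (("macular", mac), ("wholefov", whole)):
            ccbin, analyzed = cc_binarize_masked(cc, lv, roi, cfg.phansalkar_radius_px)
            out[f"{roi_name}_cc_vpd"] = 100.0 * vpd(ccbin, analyzed)
        centers = cfg.peripheral_centers_px or default_peripheral_centers(
            svp, eye.fovea_px, eye.onh_px
        )
        periph = peripheral_circles_mask(svp, eye.fovea_px, centers)
        for roi_name, roi in (("macular", mac), ("peripheral", periph)):
            ccbin, analyzed = cc_binarize_masked(cc, lv, roi, cfg.phansalkar_radius_px)
            fv = flow_void_metrics(ccbin, analyzed, cc.pixel_area_um2, cfg.fv_min_area_um2)
            out[f"{roi_name}_fv_area"] = fv.void_area_percent
            out[f"{roi_name}_fv1000_count"] = float(fv.fv1000_count)
            out[f"{roi_name}_fv1000_size"] = fv.fv1000_mean_area_um2
    else:
        log.warning("eye %s: CC slab missing, skipping CC metrics", eye.eye_id)

    if eye.faz_polygon_px is not None:
        faz = faz_metrics(eye.faz_polygon_px, pitch)
        out["faz_area"] = faz.area_mm2
        out["faz_perimeter"] = faz.perimeter_mm
        out["faz_ai"] = faz.ai
    return out


# Candidate predictors offered to the stepwise BCVA model (macular and
# whole-FOV densities, as in the study's correlation table).
STEPWISE_CANDIDATES = (
    "macular_svp_vpd", "wholefov_svp_vpd", "macular_svp_vld", "wholefov_svp_vld",
    "macular_dvp_vpd", "wholefov_dvp_vpd", "macular_dvp_vld", "wholefov_dvp_vld",
    "macular_cc_vpd", "wholefov_cc_vpd", "macular_fv_area", "peripheral_fv_area",
)


def run_study(cfg: RunConfig) -> Dict[str, pd.DataFrame]:
    """Process every eye, then run the cohort statistics stage.

    Returns a bundle of tidy tables: ``metrics`` (per eye),
    ``comparisons`` (per-metric three-group tests), ``correlations``
    (metric vs BCVA Pearson r/p within each patient arm), and
    ``stepwise`` (selected BCVA predictors per patient arm).  Deterministic
    given the config and inputs.
    """
    rows = []
    for eye in cfg.eyes:
        metrics = run_eye(cfg, eye)
        rows.append(
            {"eye_id": eye.eye_id, "group": eye.group,
             "bcva_logmar": eye.bcva_logmar, **metrics}
        )
    metrics_df = pd.DataFrame(rows)
    metrics_df["version"] = __version__
    metrics_df["param_hash"] = cfg.param_hash()
    bundle = {"metrics": metrics_df}
    bundle.update(stats_stage(metrics_df))
    return bundle


def stats_stage(metrics_df: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Statistics over a per-eye metric table (standalone re-runnable)."""
    out: Dict[str, pd.DataFrame] = {}
    metric_cols = [c for c in metrics_df.columns
                   if c not in ("eye_id", "group", "bcva_logmar", "version", "param_hash")]
    groups = metrics_df["group"].unique()

    comp_rows = []
    if len(groups) >= 2:
        for m in metric_cols:
            sub = metrics_df.dropna(subset=[m])
            if sub.groupby("group")[m].count().min() < 3 or sub["group"].nunique() < 2:
                continue
            try:
                c = group_compare(sub, m)
            except ValueError as exc:
                log.warning("comparison skipped for %s: %s", m, exc)
                continue
            row = {"metric": m, "test": c.test_used, "global_p": c.global_p,
                   "levene_p": c.levene_p}
            for (g1, g2), p in c.pairwise_p.items():
                row[f"p_{g1}_vs_{g2}"] = p
            comp_rows.append(row)
    else:
        log.info("single-group input: comparison stage skipped")
    out["comparisons"] = pd.DataFrame(comp_rows)

    # correlations with BCVA only where BCVA exists (not available for HCs)
    corr_rows = []
    for g, sub in metrics_df.groupby("group"):
        sub = sub.dropna(subset=["bcva_logmar"])
        if len(sub) < 3:
            continue
        for m in metric_cols:
            vals = sub.dropna(subset=[m])
            if len(vals) < 3 or np.ptp(vals[m].to_numpy(float)) == 0:
                continue
            r, p = pearson_with_p(vals[m], vals["bcva_logmar"])
            corr_rows.append({"group": g, "metric": m, "r": r, "p": p, "n": len(vals)})
    out["correlations"] = pd.DataFrame(corr_rows)

    step_rows = []
    for g, sub in metrics_df.groupby("group"):
        sub = sub.dropna(subset=["bcva_logmar"])
        if len(sub) < 6:
            continue
        cand = [c for c in STEPWISE_CANDIDATES if c in sub.columns
                and sub[c].notna().all() and np.ptp(sub[c].to_numpy(float)) > 0]
        if not cand:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stepwise_regression(sub["bcva_logmar"].to_numpy(float), sub[cand])
        for name in res.coef.index:
            step_rows.append(
                {"group": g, "variable": name,
                 "B": res.coef.loc[name, "B"], "SE": res.coef.loc[name, "SE"],
                 "beta": res.coef.loc[name, "beta"], "p": res.coef.loc[name, "p"],
                 "r2": res.r2, "adj_r2": res.adj_r2, "model_p": res.model_p,
                 "n": res.n}
            )
    out["stepwise"] = pd.DataFrame(step_rows)
    return out
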