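#!/usr/bin/env python
"""Simulate a three-arm widefield OCTA imaging study.

Generates SVP/DVP/CC slabs for healthy-control, acute and convalescent eyes
with arm-specific vascular fill and flow-void load (acute eyes: sparser
plexus, heavier choriocapillaris lesion burden), writes the images and a
JSON manifest under scratch/images/, and records the planted ground truth.
Run from the repository root; images are large binaries and stay in scratch/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from octaquant.cc_metrics import large_vessel_mask
from octaquant.slab_io import write_slab
from octaquant.synthetic_data import (
    CcFieldSpec,
    VesselTreeSpec,
    generate_cc,
    generate_svp,
    random_lesions,
)

OUT = Path("scratch/images")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42

# arm -> (n eyes, SVP fill, CC lesion count, lesion contrast, BCVA mean)
ARMS = {
    "HC": (4, 0.47, 18, 0.50, None),
    "acute": (4, 0.40, 45, 0.60, 0.60),
    "convalescent": (4, 0.465, 20, 0.50, 0.42),
}
FOVEA, ONH = (250, 417), (250, 150)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    manifest = {"options": {"fov_mm": [15.0, 9.0]}, "eyes": []}
    truth = {}
    eye_no = 0
    for arm, (n, fill, n_lesions, contrast, bcva_mu) in ARMS.items():
        for i in range(n):
            eye_no += 1
            eid = f"{arm}_{i:02d}"
            s = SEED + 100 * eye_no
            svp, svp_mask, _ = generate_svp(
                VesselTreeSpec(seed=s, capillary_fill_target=fill)
            )
            dvp, _, _ = generate_svp(
                VesselTreeSpec(seed=s + 1, layer="DVP", width_root_um=40,
                               capillary_fill_target=fill + 0.05)
            )
            lv = large_vessel_mask(svp)
            lesions = random_lesions(
                np.random.default_rng(s + 2), n_lesions, area_um2_range=(1200, 9000),
                contrast=contrast,
            )
            cc, labels = generate_cc(
                CcFieldSpec(seed=s + 3, lesions=lesions,
                            projection_mask=lv.mask, projection_contrast=0.3)
            )
            for slab, tag in ((svp, "svp"), (dvp, "dvp"), (cc, "cc")):
                write_slab(slab, str(OUT / f"{eid}_{tag}.tif"))
            th = np.linspace(0, 2 * np.pi, 49)[:-1]
            r_px = rng.uniform(12, 18)
            faz = np.column_stack(
                [FOVEA[0] + r_px * np.sin(th), FOVEA[1] + r_px * np.cos(th)]
            ).tolist()
            bcva = None if bcva_mu is None else float(rng.normal(bcva_mu, 0.1))
            manifest["eyes"].append(
                {"eye_id": eid, "group": arm, "bcva_logmar": bcva,
                 "svp": f"{eid}_svp.tif", "dvp": f"{eid}_dvp.tif",
                 "cc": f"{eid}_cc.tif", "fovea_px": FOVEA, "onh_px": ONH,
                 "faz_polygon_px": faz}
            )
            truth[eid] = {
                "planted_svp_fill": float(svp_mask.mean()),
                "planted_lesions_gt_1000um2": int(
                    (np.bincount(labels.ravel())[1:] * cc.pixel_area_um2 > 1000).sum()
                ),
            }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    print(f"simulated {eye_no} eyes across {len(ARMS)} arms -> {OUT}/")
    print("planted SVP fill by arm:",
          {a: round(np.mean([t['planted_svp_fill'] for e, t in truth.items()
                             if e.startswith(a)]), 3) for a in ARMS})


if __name__ == "__main__":
    main()
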