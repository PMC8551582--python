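# octaquant

Quantification of retinal and choriocapillaris microvasculature on widefield
swept-source OCT angiography (OCTA), with the cohort statistics used in
uveitis imaging studies of Vogt–Koyanagi–Harada (VKH) disease.

OCTA renders blood flow as bright signal in enface slabs of the superficial
vascular plexus (SVP), deep vascular plexus (DVP) and choriocapillaris (CC).
`octaquant` turns those slabs into the standard microvascular biomarkers:

- **VPD** (vascular perfusion density): the fraction of a region of interest
  covered by binarized vessel signal, `VPD = |vessel ∧ ROI| / |ROI|`,
  reported in percent. SVP/DVP slabs are binarized with **Huang's
  fuzzy-entropy** global threshold; the CC slab with the **Phansalkar local
  threshold** (radius 15 px).
- **VLD** (vascular length density): skeletonized vessel length per unit ROI
  area in mm⁻¹, with 8-neighbor step accounting (orthogonal steps count one
  pixel pitch, diagonal steps pitch·√2).
- **FAZ shape**: area A, perimeter P of the foveal avascular zone polygon and
  its acircularity index `AI = P / (2√(πA))` (1 for a perfect circle).
- **CC flow voids**: 8-connected dark components of the binarized CC slab;
  total void-area fraction, plus count and mean size of voids larger than
  1,000 µm² (FV1,000). Large superficial vessels are segmented on the SVP
  slab (isodata "Default" threshold + component-area cutoff) and excluded
  from the analyzed CC area to suppress projection artifacts.

Metrics are evaluated over the study's anatomical regions on the
15 × 9 mm field: a 6 mm macular disk at the fovea, a 2–3 mm peripapillary
annulus at the optic nerve head, the whole field of view minus the 3 mm
papilla disk, and three 3 mm peripheral disks for flow voids.

The cohort stage mirrors the study's SPSS workflow: Shapiro–Wilk and Levene
gates route each metric to one-way ANOVA or Kruskal–Wallis with Bonferroni
post-hocs, Pearson correlation with t-based p-values
(`t = r√(n−2)/√(1−r²)`), and SPSS-style stepwise linear regression
(entry p < 0.05, removal p > 0.10) for predicting logMAR visual acuity.

A synthetic-data module generates branching-tree plexus slabs, granular CC
textures with planted hypoperfusion lesions, and cohort tables drawn from
the published group summary statistics — every generator emits its exact
ground truth, so the whole pipeline is testable without patient data.

## Worked example

```python
import numpy as np
import octaquant as oq

# synthetic SVP slab (834 x 500 px over 15 x 9 mm, ~18 um/px)
slab, planted_mask, tree_mm = oq.generate_svp(
    oq.VesselTreeSpec(seed=3, capillary_fill_target=0.427))

mac = oq.macular_mask(slab, fovea_px=(250, 417))
print(round(mac.area_mm2, 2))            # 28.27  (6 mm disk, pi*9 mm^2)

binary = oq.huang_binarize(slab)
print(binary.params["threshold"])        # 42     (fuzzy-entropy level)
print(round(100 * oq.vpd(binary, mac), 1))   # 48.5 % macular SVP-VPD

maps = oq.VesselMaps.from_binary(binary, mac)
print(round(oq.vld(maps, slab.pixel_pitch_um), 1))  # 16.5 mm^-1
```

The planted vessel mask covers 42.7% of the image by construction; the
measured Huang-binarized perfusion (48.5%) sits a few points above it
because the global threshold (level 42) also admits the brightest tail of
the noisy background and illumination drift.

A full synthetic study runs from the command line:

```bash
python analysis/01_simulate_study.py     # writes scratch/images/ + manifest
python analysis/02_quantify_eyes.py      # per-eye metrics + group stats
python analysis/03_cohort_statistics.py  # published-preset cohort comparisons
python analysis/04_bcva_models.py        # BCVA correlation + stepwise model
```

`02_quantify_eyes.py` prints, for the 12-eye demo, macular SVP-VPD of
52.1 ± 1.9 % (healthy), 45.6 ± 0.8 % (acute) and 51.5 ± 1.7 %
(convalescent), with a three-arm ANOVA p ≈ 3·10⁻⁴ — the acute-phase
perfusion deficit the metrics are designed to detect.  Equivalent processing
of user images goes through `octa-quant run --manifest manifest.json`.

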