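# Methods

## Coordinate and scaling conventions

Slabs are row-major 8-bit grids, origin at the top-left pixel, 0-based
(row, col) indexing; physical x runs along columns. Pixel pitch is derived
from the stated field of view (default 15 × 9 mm) and the grid dimensions.
Devices do not generally document their export pixel dimensions, so the
synthetic default — 834 × 500 px, i.e. ~18 µm/px — is configurable metadata,
not an assumption baked into any metric. Bit-depth conversion is a linear
min–max rescale to [0, 255] with round-half-up; 8-bit input passes through
unchanged and a constant image maps to zero (degenerate but harmless
downstream). RGB exports are collapsed by Rec.601 luminance first.

## Regions of interest

All ROIs are pure geometry over pixel centers, with a half-open disk rule
(center strictly within the radius) so boundary membership is
deterministic. The macular disk (6 mm), peripapillary annulus (2 mm inner /
3 mm outer diameter) and whole-field mask (minus the 3 mm papilla disk and
any burnt-in label rectangle) follow the widefield protocol directly. The
three 3 mm peripheral flow-void circles are not given coordinates in the
protocol beyond "next to the macular region"; the default places their
centers 4.5 mm from the fovea — tangent to the macular disk — on the side
away from the optic nerve head. The fan angles are 0° and ±40° from
horizontal: ±60° would push a 3 mm circle past the 9 mm image height at
the 4.5 mm radius (4.5·sin 60° + 1.5 = 5.4 > 4.5 mm of available half
height), while ±40° keeps all three disks inside the field and mutually
disjoint (center separation 2·4.5·sin 20° ≈ 3.08 mm > 3 mm). Centers are
overridable per eye. A region constructed at a landmark whose disk would
leave the field raises an error rather than clipping silently, since a
clipped ROI would bias the density denominators.

## Binarization

Three algorithms reproduce the ImageJ commands named in the protocol;
foreground is always `value > t`.

**Huang fuzzy entropy** (SVP/DVP). For each candidate level t the image
splits into classes below/above t with means m₀, m₁; gray level g gets
membership μ = 1/(1 + |g − m|/C) to its own class with C the occupied
intensity range, and t minimizes Σ h(g)·S(μ) with the Shannon pair function
S(μ) = −μ ln μ − (1−μ) ln(1−μ). The search is an explicit scan over all
levels with both classes non-empty; ties break toward the lower level
(first minimum wins, as in the ImageJ scan order). A two-level histogram
has zero entropy at every candidate, so the tie-break returns the lower
occupied level and the upper level alone is foreground.

**Isodata "Default"** (large-vessel mask). From the midpoint of the
occupied range, iterate t ← ⌊(mean_below(t) + mean_above(t))/2⌋ to a fixed
point (floor keeps the balanced {0, 255} histogram at the conventional 127;
a two-cycle, possible with integer maps, settles on the lower level; the
iteration is capped at 1000 steps, far beyond what 256 bins need).

**Phansalkar local threshold** (CC). Intensities are normalized to [0, 1]
(8-bit values / 255; float input is taken as already normalized) and each
pixel is compared with t(x) = μ(x)·(1 + p·e^(−q·μ(x)) + k·(σ(x)/r − 1))
over a circular window of radius 15 px with mirror-reflected edges, σ being
the population SD. The protocol states only the radius; k = 0.25, r = 0.5,
p = 2, q = 10 are the ImageJ plugin defaults and all four are exposed. The
radius is in pixels, as in ImageJ — at 18 µm/px it spans ~270 µm, which
matters when the pitch differs. Window means are computed by FFT
convolution on a reflect-padded image; agreement with the literal
per-pixel formula is re-verified against a naive oracle in the tests and
the acceptance script.

## Densities and FAZ shape

VPD is a pixel-count ratio inside the ROI, reported in percent. For VLD the
binary map of the whole slab is thresholded first and then restricted to
the ROI (select-then-measure order), skeletonized by topology-preserving
morphological thinning to 8-connected unit-width centerlines, and measured
by neighbor steps: orthogonal steps contribute one pitch, diagonal steps
the diagonal pitch. Step accounting tracks true geometric length more
closely than pixel-count × pitch (a 45° line would otherwise be ~41% short);
the coarser pixel-count rule remains available (`length_rule="pixel_count"`)
because some published pipelines use it and the choice is otherwise
invisible in the outputs. Skeleton steps crossing the ROI boundary count
only when both endpoints are inside.

The FAZ boundary is an input polygon — in practice graders outline it
manually — validated as simple and non-degenerate; area comes from the
shoelace formula, perimeter from summed vertex distances, and
AI = P/(2√(πA)) ≥ 1 up to discretization by the isoperimetric inequality.
There is no automatic FAZ segmentation.

## Choriocapillaris stage

The interactive wand selection of large superficial vessels is replaced by
a deterministic surrogate: isodata-threshold the SVP slab, take 8-connected
components, and keep those of at least 5,000 µm² (configurable; an optional
dilation margin widens the exclusion). Large-vessel pixels are removed from
the analyzed CC area — from the denominator, not filled as voids — because
the masking intent is to discard unmeasurable pixels, not to assert absent
flow beneath vessels. A blank SVP slab yields an empty mask rather than an
error so partially-degenerate inputs still process.

Flow voids are 8-connected dark components (ImageJ Analyze Particles
default connectivity) of the Phansalkar-binarized CC inside the analyzed
region. Void-area percent uses all dark pixels; FV1,000 count and mean size
use components strictly above 1,000 µm². Because voids and perfusion are
complements of one binary map over one region, void-area % + CC-VPD % = 100
exactly — asserted as an invariant. The published prose defines the area
fraction as "ROI area divided by total flow void area", which is inverted
relative to the ~15–22% values it reports; the implementation uses
total-void-area / ROI-area × 100.

## Cohort statistics

Per-metric three-arm comparisons use the gate: Shapiro–Wilk p > 0.05 in
every arm *and* Levene (mean-centered) p > 0.05 → one-way ANOVA with
Bonferroni-adjusted pairwise t-tests on the pooled within-group MSE
(df = N − k), otherwise Kruskal–Wallis with Dunn's rank z-tests
(tie-corrected) × the number of comparisons, capped at 1. The source
protocol names the tests but not the gate logic; this is the conventional
reading. Pearson p-values come from t = r√(n−2)/√(1−r²) on n−2 df,
two-sided. Stepwise regression uses SPSS defaults (α-enter 0.05, α-remove
0.10): each step adds the candidate with the smallest entry p if it
qualifies, then removes the worst included variable while its p exceeds the
removal bound; collinear candidates are skipped with a warning; reported
are B, SE, standardized Beta = B·sd(x)/sd(y), R², adjusted R² and the model
F-test. Eyes are treated as independent observations, as the published
sample sizes imply (both eyes of some patients included); inter-eye
correlation is a known limitation, not modeled.

## Synthetic data

The generators emulate the features the metrics consume, not device
physics. Plexus slabs are stochastic branching trees (roots entering from
the lateral edges, per-mm branching, widths decaying geometrically from
60 µm, brightness increasing with width) rasterized by distance-to-segment,
over a capillary bed obtained by thresholding correlated noise at exactly
the quantile that brings total planted foreground to the requested fill —
so the planted fraction is accurate by construction (default 0.45, in the
range implied by published perfusion densities of ~43–53%). CC slabs are a
bright granular texture (base 180, smooth amplitude 8) with dark disk
lesions of specified area and contrast, optional projection-artifact
darkening under a supplied vessel mask, and multiplicative gamma speckle
(sd 0.03). Cohort tables draw per-arm normals with the published means/SDs
(sample sizes 30/20/30); medians with quartile ranges are normal-matched
via sd = IQR/1.349; a designated metric–BCVA correlation is planted by the
bivariate construction b = μ + σ(r·z₁ + √(1−r²)·z₂). Every generator is a
pure function of its spec including the seed, and always returns its ground
truth (mask, label map, or parameters).

What passing tests on these fixtures do **not** show: robustness to real
segmentation error, motion artifact, media opacity, signal attenuation
under exudative detachments, or vessel morphology beyond a branching-tree
caricature. They do show that the measurement chain — thresholds, ROIs,
skeleton accounting, particle analysis, statistics — is numerically
faithful to its definitions.

## Problem sizes and numerical choices

Simulation-based checks use: 200 random 64 × 64 images for
threshold–oracle equivalence, 20 full-size (834 × 500) CC fields for
planted-lesion recovery, 2000 null cohorts for type-I calibration, 500
cohorts for power under the published effect sizes, and 200 runs at n = 200
for stepwise support recovery. These sizes give Monte-Carlo standard errors
well inside the asserted bands (e.g. ±0.5 points on a 5% rejection rate at
2000 seeds) while keeping the whole suite around a minute of CPU.

Degenerate inputs are handled explicitly: constant images error in global
thresholding (no threshold exists) but produce an empty large-vessel mask;
empty ROIs and empty analyzed regions raise; an FV1,000 mean over zero
voids is reported as missing (NaN) rather than zero. The FV1,000 cutoff is
applied in µm² as a strict inequality, so components strictly above the
cutoff are never dropped by pixel quantization.

## Known limitations

- No device-side concerns: layer segmentation, projection-artifact removal
  inside the instrument, eye tracking and signal-strength normalization are
  upstream of this package.
- The wand-tool surrogate (area cutoff) matches the intent, not the exact
  pixels, of an interactive selection; its cutoff is a free parameter.
- FAZ and landmark placement are inputs; no detection is attempted.
- Statistical routines assume independent eyes and complete cases.
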