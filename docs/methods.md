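# Methods

This note documents the models, parameter choices and numerical
conventions behind `cnvquant`, in the spirit of a methods appendix: what
is computed, why the defaults are what they are, and what the synthetic
validation does and does not demonstrate.

## Measurement model

All images are 2-D en-face angiograms held as floats min-max normalized
to [0, 1] (no bit depth is assumed); pixel coordinates are row-major,
origin top-left, 0-based. Physical pixel size is deliberately not
modeled: every quantity is a pixel-fraction percentage, so results are
comparable across devices only modulo field-of-view.

**Vessel density** is an exact pixel count: `100 * |mask ∩ ROI| / |ROI|`.
The ROI is explicit and configurable (default: the corneal disk inside
the limbal circle, radius 0.46 × the short canvas side, matching the
simulator's geometry; `roi: full` uses the whole frame). The ROI pixel
count is recorded with every measurement so any other convention can be
reproduced.

**Vessel growth density** between consecutive visits is the density
difference of the two binarized images on their *common overlay region*:
the later visit is warped into the earlier visit's frame and only pixels
valid in both (and inside both ROIs) are counted. Binary masks are
warped nearest-neighbour — fractional vessel pixels are undefined — and
the scalar equals, to machine precision, the identity
`density(later | common) − density(earlier | common)`. The pixelwise
grown/regressed/persistent/empty partition of the common region is kept
as a diagnostic change map. Growth is always measured week *t* → *t*+1
with week *t* as the fixed registration frame.

**Repeatability error** is the signed density difference between two
same-session scans. Replicates are assumed pre-aligned (one sitting, no
repositioning); a config flag can force registration of replicates for
robustness checks. Signed differences are the primitive; absolute-value
summaries are reported alongside.

## Registration

Between sessions the eye is repositioned; at this field size the motion
is well approximated as rigid, so the transform family is translation +
rotation about the image centre with scale fixed at 1 (same device, same
optics). The estimate is deterministic and derivative-free:

1. coarse rotation grid, ±10° in 0.5° steps; for each candidate angle
   the translation is resolved by subpixel phase correlation
   (cross-correlation form, upsampling ×10) and scored by normalized
   cross-correlation (NCC) on the valid overlap;
2. golden-section refinement of the rotation in the ±0.5° bracket around
   the best grid node (translation re-estimated at ×50 upsampling each
   evaluation, terminating at 0.02°), then a final translation pass at
   ×100.

Registration always runs on preprocessed *intensity* images, never on
binary masks, so segmentation error cannot propagate into alignment.
A result below the NCC acceptance floor (default 0.2) raises a
registration failure; the orchestrator logs it and excludes the pair
from downstream statistics rather than aborting the study. Measured on
synthetic pairs with known poses (shifts up to 10% of the canvas,
rotations up to 5°, default noise), recovery is within 0.5 px and 0.5°
in ≥ 95% of cases.

OCTA and ICGA time series are registered each within itself; the two
modalities are compared through their measurement values, never fused
pixel-to-pixel.

## Preprocessing

The chain is motion-line repair → median denoise → (optional) background
flattening → (optional) unsharp sharpening; every step can be disabled,
and the all-disabled chain is the identity.

*Motion-line repair* (OCTA default: on). Motion artefacts follow the
fast-scan axis and appear as bright full-width lines. A row is flagged
when the robust z-score (median/MAD) of its mean intensity exceeds a
threshold (default 3.5) either globally or after subtracting a running
median (window 11) of the row-mean profile — the local test matters on
densely vascularized frames, where central rows legitimately cross more
vessels than peripheral ones and the inflated MAD would otherwise hide
true artefact lines. A flagged row must additionally be a large impulse
(≥ 0.18 above the local baseline; artefact lines raise the row mean by
≥ ~0.25, geometric fluctuations stay below ~0.16). Flagged rows are
replaced by the average of the nearest clean rows above and below; all
other pixels are untouched. If more than 30% of rows are flagged the
frame is declared unusable.

*Median denoise* (default radius 1) suppresses speckle while preserving
vessel edges.

*Background flattening* subtracts a large-radius (default 20 px) rank
median of an 8-bit quantization of the frame and re-normalizes. It is
implemented and tested, but ships **disabled** even for ICGA: measured
on synthetic data, a median background estimate is biased wherever the
plexus covers more than half of the kernel footprint (it then "explains
away" vessel signal), and the local-mean segmentation threshold already
adapts to smooth fluorescence gradients. Density error was strictly
worse with flattening enabled (error SD 1.2 vs 0.9 points, with signal
erasure in dense regions). It remains available for strongly vignetted
inputs.

*Sharpening* (ICGA default: amount 0.8, sigma 1.0) is a mild unsharp
mask compensating the wider ICGA point-spread function before
thresholding; output is clipped, not re-normalized, so absolute
threshold offsets keep their meaning.

## Segmentation

The default chain thresholds the preprocessed **intensity** raster —
global Otsu within the ROI for OCTA, local mean (window 31, offset
−0.04) for ICGA — then closes 1-px gaps, drops 8-connected components
below 20 px, and finally applies a *tubularity gate*: components that
contain no seed from the Otsu-thresholded multiscale Hessian (Sato)
vesselness response are discarded as non-vascular. Threshold ties go to
foreground; connectivity is 8-connected everywhere.

Thresholding the vesselness response itself was evaluated and rejected
for density work: ridge filters are centreline-peaked, so any threshold
on them under-recovers vessel width systematically (Dice against ground
truth saturated near 0.85 on dense plexuses, densities biased −6 to −8
points). The division of labour is therefore: the Hessian response
decides *whether* a structure is a vessel, the intensity threshold
decides *how wide* it is. With the defaults, synthetic OCTA frames
recover ground-truth density to within 0.8 points (max) and ICGA frames
to within ~2 points across the 10-39% density range.

## Statistics

Bland-Altman limits of agreement use the conventional 1.96 multiplier on
the sample SD (n−1) of paired differences; the CI of the mean difference
uses Student's t with n−1 df. The paired nonparametric comparison is the
Wilcoxon signed-rank test: zero differences dropped, average ranks for
ties, exact tie-aware null distribution by generating-function
convolution for n ≤ 25, tie-corrected normal approximation (no
continuity correction) above; the all-ties case raises a no-information
error rather than fabricating a p-value. The unpaired test is Welch's t
(small, unequal groups; no variance-homogeneity assumption). A
Mann-Whitney U is provided for completeness where an unpaired
nonparametric comparison is wanted. Quantiles (IQR) use linear
interpolation between order statistics. Degenerate edge conventions are
pinned in code and tests: all-zero differences → t = 0, p = 1; zero-SD
nonzero-mean differences → p = 0.

## The synthetic study generator

The simulator emulates a suture-induced vascularization study with
anti-VEGF treatment arms. Its purpose is *verifiability*: every frame
comes with an exact ground-truth mask, density, pose and growth value.

**Geometry and growth.** Vessels sprout from 20 roots placed on a
limbal circle (radius 0.46 × canvas, full 360° span, canvas 256²) and
advance centripetally toward four concentric suture-row arcs (radii
0.78/0.62/0.46/0.30 of the limbal radius; row 4 innermost). Growth is a
biased branching random walk: per 4-px step the direction blends
persistence with the inward radial, plus Gaussian angular noise
(SD 0.28 rad); tips branch with probability 0.09 per step at ±0.6 rad;
radii taper from 2.2 px (roots) to a 1.3 px floor. The thinnest
capillaries are deliberately kept at or above the simulated device
resolution (PSF ~1 px): sub-resolution vessels would be unquantifiable
by any intensity-based pipeline and are not what these devices resolve.
Week 1 grows to row 2, week 2 to row 4 ("reaching the central cornea"),
yielding pre-treatment densities of ~20-31% of the corneal disk, the
range reported for this model class. This is not a physiological
angiogenesis model — no VEGF fields, no hemodynamics — just controllable
plausible geometry.

**Treatment schedules** (from week 3, per arm × route): saline keeps
growing (5 new roots/week, grown to row 4); the aflibercept-like arm
prunes distal-first (sub-conjunctival 48% then 18% more; topical 62%
then 45% more — sustained regression); the ranibizumab-like arm prunes
(55% / 68%) and then *regrows* at week 4 (to row 4 after injection —
full rebound; to row 3 topically — partial rebound). Pruning removes the
latest-born fraction of non-root segments (children are always born
after parents, so the pruned set is closed under descent), reproducing
the observed row-by-row regression pattern. The resulting weekly
density ratios match the reported arm trajectories to within a few
percent of pre-treatment density.

**Rendering.** Both modalities render the *same* mask per visit. OCTA:
vessel level 0.82, background 0.12, unit-mean log-normal speckle
(σ = 0.35), PSF 0.5 px, Poisson(4) bright motion lines (+0.5).
ICGA: vessel 0.62, background 0.22, speckle σ = 0.12, PSF 1.0 px, a
random smooth background fluorescence gradient (amplitude 0.22) and
additive noise (σ = 0.03). With all noise off and levels (1, 0) the
render equals the mask exactly — the noiseless oracle used in tests.

**Poses and replicates.** Week 1 defines the canonical frame; each later
visit gets a random rigid pose (translations uniform within ±10% of the
canvas per axis, rotations within ±5°), applied to the tree *coordinates*
(no resampling), and the pair transforms are recorded. Ground-truth
density is computed in each visit's own posed frame against the fixed
ROI — exactly what a pipeline that cannot see the pose should recover.
Same-session replicates share the mask and pose and differ only in
rendering noise. Everything is deterministic under a fixed seed
(per-animal seed streams spawned from the master seed).

**What passing does and does not show.** The simulator exercises the
failure modes the pipeline claims to handle — speckle, artefact lines,
contrast and PSF differences between modalities, background gradients,
inter-visit rigid motion, growth and regression — under known truth. It
does not emulate non-rigid deformation, depth-projection artefacts,
focus loss, dye leakage, vessel-calibre changes without length changes,
or operator framing variability; agreement numbers on real data will be
worse than the synthetic ones, and the synthetic results validate the
*software*, not any clinical claim.

## Problem sizes used in validation

The standard validation study is 6 animals (one per arm × route) × 4
weeks × 2 modalities × 2 replicates on a 256² canvas — 96 frames, 36
registered intervals — which keeps the full suite and the acceptance
script within a few minutes on one CPU while leaving every statistic
with ≥ 18 matched pairs. The simulator's default design (3 animals per
drug arm, 2 controls per route, 16 animals) is used when study-level
group statistics are the object of interest.

## Known limitations

* Rigid-only registration; deformable motion is out of scope.
* Cross-modality (OCTA↔ICGA) spatial registration is not implemented;
  modalities are compared by measurement value only.
* The ICGA local-mean threshold trades a small density-dependent bias
  (±1-2 points at the extremes of the density range) for robustness to
  background gradients.
* Densities are pixel fractions; no mm² areas without a pixel-size
  calibration layer.
* The Wilcoxon normal approximation omits the continuity correction;
  for n ≤ 25 the exact distribution is used anyway.
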