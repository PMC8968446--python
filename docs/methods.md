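# Methods

## Problem and model

The pipeline detects *new or growing* white-matter lesions between two
T2-FLAIR brain MRI sessions of one patient by temporal subtraction: after
spatial and intensity normalization, a new lesion appears as a positive
residual in the Timepoint-2 minus Timepoint-1 difference map ("tissue
transformation" — an intensity change inside the lesion — rather than
geometric deformation of surrounding tissue, which this design does not
model). The pipeline is deliberately sensitivity-first: candidates that
fail the false-positive test are kept in the outputs (rendered green) so a
human reader makes the final call, and the automated contrast decision
errs toward recommending injection (ties count as new lesions).

Stage order is fixed and asserted by the test suite: read → admission →
resolution harmonization → rigid registration (Timepoint-2 → Timepoint-1)
→ brain extraction (Timepoint-1 grid) → bias-field correction (both) →
histogram matching (Timepoint-2 → Timepoint-1) → subtraction → candidate
extraction → center-of-gravity classification → atlas labeling → report.
Timepoint-1 is the reference space throughout; histogram matching maps
Timepoint-2 onto Timepoint-1 rather than both onto a template, keeping the
subtraction scale interpretable in Timepoint-1 units.

## Stage notes and parameters

**Admission.** Scans whose largest voxel dimension is ≥ 5 mm are rejected
(2-D acquisitions of that slice thickness carry too little out-of-plane
information); scans between 3 and 5 mm are accepted but flagged
low-resolution.

**Resolution harmonization.** Resolution is ordered by voxel volume; the
finer scan is linearly resampled onto the coarser grid (downsampling
avoids the interpolation artifacts of inventing detail in the coarse
scan). Ties keep the Timepoint-1 grid. Masks and label volumes are always
resampled nearest-neighbor.

**Rigid/affine registration.** Mattes mutual information (32 bins),
3-level pyramid (shrink 4/2/1, smoothing σ 2/1/0 mm), regular-step
gradient descent (learning rate 1.0, minimum step 1e-5, 200 iterations,
parameter scales from physical shift), seeded random metric sampling at
5% of voxels with a floor of 50 000 samples (small volumes need the floor:
at 64³, 5% sampling leaves the affine problem under-determined and it can
converge to a mirror optimum). Sampling is seeded, so registration is
deterministic for a fixed configuration. Bitwise-identical inputs
short-circuit to the exact identity: optimizing a stochastically sampled
metric on identical images leaves ~0.1–0.3 voxel of drift, and the
resulting interpolation residue would fabricate differences between
identical scans. Convergence of the optimizer class is bounded by the
sampling noise of the metric (~0.1 voxel); rotations are further limited
by the brain's lever arm, so rotational accuracy in degrees degrades on
miniature test phantoms even when displacement accuracy in voxels is
unchanged. Known transforms on full-scale noiseless phantoms are
recovered to ≲ 0.1 mm / ≲ 0.1° / < 1% scale, comfortably inside the
0.5 voxel / 0.5° / 2% acceptance band.

**Brain extraction.** Otsu foreground threshold → largest 26-connected
component → binary closing (ball radius 2 voxels) → hole filling. This
classical chain is deterministic, self-contained and sufficient for the
phantom geometry (Dice ≥ 0.95 against the analytic brain mask); it is the
weakest stage for real clinical data, where learned extractors are
superior. Restricting all downstream analysis to the brain removes the
false positives that non-brain tissue would generate.

**Bias-field correction.** Multiplicative model: an order-3 polynomial is
fitted to log-intensities and divided out, then the masked mean is
restored. The fit uses only reliable signal — the mask eroded by 2 voxels
and intensities above half the masked median — because partial-volume
voxels at the mask edge are strong log-domain outliers that tilt the
field. The exponentiated field is clipped to e±3 so it stays positive and
bounded where the polynomial extrapolates outside the fitted region.

**Histogram matching.** 101 quantile landmarks (percentiles 0–100)
computed inside the brain mask, joined by a monotone piecewise-linear map;
voxels outside the mask pass through unchanged (only masked voxels enter
the subtraction). An affine intensity distortion is inverted exactly;
the mapping never reorders intensities.

**Candidate extraction.** Threshold `μ + kσ` with `k = 3` (in-mask mean
and standard deviation of the difference map), 26-connectivity, minimum
volume 15 mm³. The minimum volume is the package's noise gate: at `k = 3`
the per-voxel exceedance is ~1.4e-3, and over ~3.5e5 brain voxels a
3 mm³ gate would admit on the order of one spurious 3-voxel cluster per
no-change study (about half of which the coin-flip cog test would label
new), which is incompatible with a ≥ 90% negative-verdict rate on stable
patients; 15 mm³ suppresses such clusters while staying an order of
magnitude below typical new-lesion volumes (a 3 mm-radius lesion is
~113 mm³). Both `k` and the minimum volume are configuration keys. The
brain mask is eroded by 2 voxels before subtraction (configurable):
sub-voxel registration error at the parenchyma boundary, where the
intensity gradient is steepest, otherwise leaves ring-shaped residuals.
Negative residuals (resolving lesions) are deliberately not candidates —
the method reports new/growing lesions only, and it does not measure
per-lesion exact volumes or total lesion-load change.

**False-positive rule.** Only the candidate's center of gravity (the
rounded unweighted centroid of its voxel set) is consulted: if Timepoint-1
is brighter there than Timepoint-2, the candidate is a misregistration
artifact (false positive); otherwise — including exact ties — it is a new
lesion. The rule is deterministic and depends on nothing but the two
intensities, both taken from the bias-corrected, histogram-matched
volumes.

**Atlas labeling.** The atlas is an input artifact (label NIfTI + two-
column id→name TSV), not a bundled dataset. The subject is affinely
registered (12 DOF, same metric/optimizer) to the atlas reference and each
new lesion's cog is looked up nearest-neighbor; background or out-of-grid
points give "unlabeled", as does running without an atlas. Only the cog
voxel is consulted (an approximate location is the goal), not a majority
vote over the footprint.

**Decision metrics.** The 2×2 decision table counts patients by (GBCA
given / not given) × (new lesion / none). Sensitivity is
`given_new / (given_new + notgiven_new)`; specificity, PPV/NPV, FPR/FNR,
accuracy and F1 follow the standard confusion-matrix identities. A metric
with a zero denominator is reported as an explicit `None`, never as 0.
Values are kept at full precision and rounded (2 d.p.) only for
presentation. The GBCA reduction is the fraction of patients not
injected; a variant restricted to patients without new lesions is also
provided.

## The phantom: what it emulates and what it does not

`PhantomSpec` defaults are the package's reference study conditions:
128³ grid at 1 mm isotropic voxels; brain ellipsoid semi-axes
(42, 52, 38) mm at tissue level 100 inside a skull shell at 160 separated
by a dark gap (the gap is what makes classical skull-stripping work);
two persistent lesions, three new lesions (radii 3–4 mm), and one
reversed-contrast insert (brighter at Timepoint-1 — false-positive bait),
all spheres of contrast +30 with a 1 mm linear edge; rigid
inter-timepoint motion of 2° and 3 mm; per-session multiplicative bias
fields (product of three low-frequency cosine modes, 20% total
amplitude, unit mean in brain — smooth, strictly positive and
representable by the order-3 polynomial the correction fits); additive
Gaussian noise σ = 6 (lesion contrast 5× noise). Identical seeds give
bitwise-identical volumes.

Not emulated: cortical folding and tissue texture, Rician noise
statistics (additive Gaussian is an adequate approximation at this SNR
and keeps the ground truth analytic), partial-volume CSF, mass effect
(tissue deformation), scanner-specific artifacts, and spinal-cord
anatomy. Passing the phantom studies therefore demonstrates the
correctness of the pipeline's mechanics — registration recovery,
normalization, thresholding, classification and decision logic — not
clinical-grade sensitivity on patient data; the deployed-system
sensitivities reported for clinical cohorts cannot be reproduced without
clinical images.

The phantom studies (20 seeds each, run by the test suite and
`scripts/acceptance.py`) score: per-lesion detection (a candidate labeled
new-lesion overlapping the truth mask), classification of any candidate
overlapping a reversed-contrast insert, the negative-verdict rate on
stable phantoms with motion/bias/noise still present, and wall-clock per
pair (well under the 2-minute budget; registration dominates at ~5 s).
Problem sizes were chosen so the complete suite and the acceptance script
each run in minutes on a single core.

## Numerical choices, degenerate inputs, limitations

- Internal orientation is RAS; all loaders reorient on read. Voxel
  indices are 0-based; physical position = origin + direction·(spacing ⊙
  index). DICOM (LPS) geometry is converted on read/write, and rescale
  slope/intercept is always applied.
- DICOM series writing quantizes to 16 bits with a rescale slope; the
  round-trip error is bounded by (range/65535)/2.
- A flat difference map (σ = 0) yields an empty candidate list, not an
  error; a constant reference histogram raises a degenerate-histogram
  error; an all-constant volume cannot be skull-stripped and raises.
- Candidate ordering is deterministic (lexicographic by first voxel), as
  is report rendering; re-running a pipeline with the same config and
  inputs reproduces the report exactly.
- Overlay DICOMs are RGB secondary-capture derived images copying the
  patient/study identifiers of the input; layout is three panels
  (Timepoint-1, Timepoint-2, annotated Timepoint-2) over an enlarged
  unannotated Timepoint-2.
- Known limitations: classical brain extraction on clinical data;
  subtraction assumes comparable acquisition protocols; spinal-cord
  lesions and contrast-enhancing lesion detection are out of scope;
  lesion volume is voxel-count volume of the *suprathreshold change*, not
  a segmentation of the full lesion.
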