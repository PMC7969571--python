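# Methods

This note documents the models, conventions and numerical choices behind
`axistack`, what the synthetic phantom does and does not emulate, and the
known limitations.

## Geometry conventions

Pixel indices are 0-based; the world position of a voxel center is
`slice_position` along z and `(index + 0.5) × spacing` in-plane, so that
trilinear interpolation is symmetric about voxel centers. Rows run
anterior→posterior, columns left→right, and ascending `slice_position`
defines the z-axis. Stack direction does not affect any computed measure,
so no attempt is made to infer patient orientation beyond this convention.
Slices are always held sorted by ascending position; duplicate positions
are rejected at construction.

Two on-disk dialects exist: a read-only DICOM reader (tags PixelSpacing,
SliceThickness, ImagePositionPatient-z, Manufacturer) and a read/write
"sidecar" dialect (16-bit PNG image + 8-bit PNG label map + JSON geometry
per slice, one series-level JSON) that round-trips bit-exactly and lets
every test run without DICOM fixtures. A Manufacturer string that matches
neither known vendor maps to an `uncalibrated` category for which
calibration is the identity.

## Segmentation

All segmenters share one contract: `predict(image, geometry, slice_index)`
returns a label map of the input's shape over the 9-class vocabulary.
Images are standardized onto a 560×560 canvas: the longer side is scaled
to 560 with aspect preserved, the shorter side centered between
zero-padding bands; the placement record gives the exact inverse, and
label maps travel through the canvas by nearest-neighbor resampling
(identity on integer-ratio scales, at most a one-pixel boundary shift
otherwise). Per-pixel class decisions are argmax over the 9 scores with
ties broken toward the lowest class id, deterministically.

The trainable model is deliberately lightweight: a per-pixel multilayer
perceptron (one hidden ReLU layer, 48 units; ~700 parameters) over a
6-channel feature stack — normalized intensity, Gaussian-smoothed
intensity at σ = 2, 5 and 10 canvas pixels, and normalized row/column
coordinates. The coarse smoothing scales are computed on a 4×-decimated
grid and re-expanded bilinearly, which is visually and numerically
indistinguishable at these sigmas and several times faster. This model is
adequate for phantom imagery, where class identity is carried by intensity
and coarse position; the `Segmenter` contract keeps a stronger
convolutional model drop-in for real data.

Training minimizes categorical cross-entropy with Adam (default learning
rate 0.001) over minibatches of 20 images. From each image, pixels are
sampled class-balanced (equal counts per class present) so minority
structures stay visible in the loss; each 20-image batch feeds several
optimizer steps over 512-pixel sub-batches, the natural step granularity
for a per-pixel classifier. Augmentation draws one random affine per image
per epoch: rescale 0.9–1.1, rotation ±10°, shear ±5°, translation ±5% —
ranges are config-exposed. Early stopping: training ends when the
validation loss has not reached a new minimum for `patience` (default 5)
consecutive epochs, and the weights at the best validation loss are
restored. The whole run is a deterministic function of the config seed.

Two reference segmenters support pipeline testing in isolation from
segmentation error: an oracle that replays ground-truth labels with an
exactly controlled corruption rate (`floor(rate·n)` pixels flipped to a
uniformly random other class, deterministic per (seed, slice)), and a
nearest-class-mean intensity classifier that is exact on noise-free
renderings.

## 3D reconstruction

Per-slice label maps are one-hot encoded per class and interpolated as
fractional indicator fields, not argmax-relabelled: the assembled
`LabelVolume` stores per-class occupancy in [0,1], preserving
partial-volume information for volumetry (an argmax rendering exists for
NIfTI export only). Whether label maps or probability maps should be
interpolated was genuinely open; fractional one-hot interpolation is the
committed choice because it makes volumes continuous in the slice data.

Target lattice: in-plane resolution equals the finest pixel spacing in the
series; through-plane dz = min(2 mm, finest in-plane spacing). Slices
represent slabs, so the volume extends half a slice thickness beyond the
first and last slice centers by constant extension (otherwise the apical
and basal slabs would lose half their volume); inter-slice gaps are
spanned linearly with no gap-aware correction. Background occupancy is
implicit (1 − sum of foreground), which makes per-voxel normalization
exact and halves memory. Structure volume is the occupancy sum × voxel
volume; linear interpolation of one-hot fields cannot overshoot, so
occupancies stay in [0,1] and class volumes sum to the grid volume.

## Quantification and calibration

LV mass is wall volume × 1.05 g/ml, the standard myocardial density
convention. BSA defaults to Mosteller (Du Bois available). The ascending
aorta is identified, on each axial plane where the single aorta class
splits into ≥2 connected components, as the most anterior component; its
equivalent-circle diameter is `2·sqrt(area/π)` and the study value is the
maximum over qualifying planes. An aorta that never splits is reported as
not measurable (None), distinct from zero.

Calibration is simple linear regression per (manufacturer, measure),
fitted on ≥3 (raw, final) pairs and stored with n and R². It operates on
the *indexed* measures; the mass:volume ratio is calibrated directly by
default (it has its own fitted line) with a derived mode (calibrated
LVMi / calibrated LVEDVi) available. After calibration the raw values are
recomputed from the calibrated indexed values so `indexed × BSA = raw`
always holds.

Flags use strict `>`. The LVEDVi/RVEDVi/LVMi/MVR cut-offs (94, 98, 83.5,
0.84) are published values; the indexed aortic-diameter and
pleural-fluid cut-offs have no published value and are required site
configuration — when unset the corresponding flag is never raised. A
Youden-optimal pleural-fluid threshold can be derived from the ROC module
on labelled data. Note one structural consequence of these cut-offs:
LVMi > 83.5 with LVEDVi ≤ 94 forces MVR ≥ 0.888 > 0.84, so any purely
hypertrophied study necessarily also raises the mass:volume flag; the
hypertrophied phantom fixture therefore declares both as its expected
flag set.

## Synthetic phantom

The generator is the package's study condition, not a tuning knob. A
thorax is a list of geometric primitives inside an elliptical body
outline, voxelized at a requested isotropic resolution (1 mm in the test
suite): ellipsoids for chambers and atria, an outer-minus-inner ellipsoid
shell for the LV wall, vertical tubes for ascending/descending aorta and
pulmonary artery, and a posterior circular-segment prism for pleural
fluid, parameterized directly by its volume (height = volume / closed-form
segment area). Truth volumes are closed forms (4/3·π·abc; π·r²·h; outer −
inner; segment area × height). Later primitives overwrite earlier ones
(painter's algorithm); any class that loses voxels this way has its truth
re-counted voxel-exactly at build resolution so recovery tests stay fair —
the five presets are laid out overlap-free, so their truths are fully
analytic.

Slicing emulates thick-slice partial voluming: each slice's label is the
majority class over the voxel layers in its slab, per pixel column. Count
ties are resolved by the layer nearest the slab center (lower layer first
when equidistant), a choice that balances erosion at one cap of a convex
structure against dilation at the other and removes the systematic volume
shrinkage a background-biased tie-break would cause. In-plane, the voxel
containing each pixel center is sampled — a constant sub-voxel shift,
hence volume-preserving. Slice count is
`floor((z_extent − thickness)/(thickness + gap)) + 1`.

Rendering assigns each class a mean intensity (defaults spaced ≥40 apart)
plus i.i.d. Gaussian noise (default sd 5, i.e. ≥4σ between neighboring
class means), quantized to uint16; all randomness flows through explicit
seeds. The default acquisition geometry is 8 mm slices with a 2 mm gap at
2 mm in-plane spacing — a plausible localizer protocol, configurable
throughout; recovery tests slice at 2 mm/0 gap as their reference
condition.

What the phantom does **not** emulate: MR physics (coil shading, bSSFP
banding, flow artefact), cardiac and respiratory motion, oblique
anatomy, inter-subject shape variability, and intensity overlap between
tissues. Passing tests therefore demonstrate that the geometry engine —
slicing, reconstruction, volumetry, calibration, thresholding — is
correct and self-consistent, not that the lightweight segmenter would
perform on clinical images.

The five presets (`normal`, `dilated_lv`, `hypertrophied_lv`,
`dilated_aorta`, `pleural_effusion`) are sized so the flagged measure sits
≥15% beyond its cut-off and every other measure ≥15% inside it (BSA
1.818 m² from 170 cm / 70 kg); the preset aortic index cut-off is
21 mm/m² and the effusion cut-off 50 ml.

Manufacturer bias is modelled as an affine distortion of the *reported*
value: `final = slope × truth + intercept`. The pipeline's raw geometric
measurement approximates truth, so OLS on (raw, final) pairs recovers the
injected (slope, intercept) — exactly on noiseless data, and within the
usual OLS sampling error under noise.

## Statistics

Dice is `2TP/(2TP+FP+FN)` per class; two empty masks score 1.0 (vacuous
agreement on absence). Cohen's kappa uses `(p_o − p_e)/(1 − p_e)` with the
marginal-product chance agreement; statistics that are undefined for a
given matrix (e.g. sensitivity with no positives, kappa at p_e = 1) are
reported as absent, never NaN. Binomial proportions get Wilson score
intervals (via statsmodels), chosen because the Wilson interval reproduces
published small-n detection intervals that other methods do not. ROC
curves and AUC come from scikit-learn (trapezoidal, no smoothing); the
operating cut-off maximizes Youden's J with ties broken toward the lower
threshold, and a score ≥ threshold calls a case positive.

`reconstruct_confusion` inverts printed diagnostic statistics: it
exhaustively enumerates all integer (TP, FN, FP, TN) with the given total
whose sensitivity, specificity and accuracy round — half-up, at the
precision of the printed figure (one decimal for "84.3", integer for
"80") — to the printed values. This makes worked-example kappas
reproducible from a published table alone; when several matrices are
consistent, a reported kappa is accepted only if every solution rounds to
the same value.

## Problem sizes and tolerances

The test suite builds phantoms at 1 mm (pipeline accuracy) and 2 mm
(training corpus) resolution, slices at 2–8 mm, and trains the segmenter
on 200 slices for up to 18 epochs — sizes chosen so the full suite runs
in minutes on one CPU while leaving clear margins: end-to-end structure
volumes recover within 5% (observed worst case ≈3.5%, the thin pleural
crescent), the trained segmenter's held-out mean foreground Dice clears
0.80 with ≈0.08 to spare across seeds, and noiseless calibration recovery
is exact to ~1e-12. Equality tolerances elsewhere are 1e-9 absolute for
round-tripped floats and one voxel width for voxelized diameters.

## Known limitations

- Single-frame axial DICOM only; no multi-frame, oblique or compressed
  transfer syntaxes.
- The ascending/descending aorta split is heuristic (most anterior
  component) and assumes both appear on at least one common plane.
- The trainable segmenter is a desk-scale stand-in; no claim is made about
  clinical-image performance.
- Ejection fraction, atrial volumetry and pericardial effusion are out of
  scope (the label vocabulary carries no pericardial class).
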