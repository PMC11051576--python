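# Methods

## Native Agatston scoring

The reference score is computed on 3 mm axial slabs. When the input is a
thin overlapping reconstruction (the default geometry is 1 mm slices
every 0.75 mm), consecutive thin slices are averaged into
non-overlapping slabs; a trailing incomplete group becomes a final
thinner slab rather than being discarded, so no calcium is silently
dropped. Averaging (not maximum) is used because a thick-slice
reconstruction integrates attenuation across its extent.

Lesions are per-slab 2D connected components (8-connectivity) of pixels
with HU **≥ 130** — the comparison is inclusive — with components below
**1 mm²** discarded. Each lesion contributes `area × w`, the density
weight `w` stepping at a maximum HU of 200, 300 and 400. The 130 HU
cutoff is the standard for 120 kV acquisitions; the weight brackets and
the minimum-area rule follow the original method definition. Threshold,
slab thickness, minimum area and a (non-standard, off-by-default) 3D
connectivity mode are configurable, but the defaults are the method.

Calcium **volume** is measured on the un-slabbed volume: suprathreshold
voxel count × `pixel_size² × slice_increment`. With overlapping
reconstructions the increment, not the nominal thickness, tiles space,
and the same convention is used everywhere in the package (phantom
truth, CECT volumes), so volumes are directly comparable across
modules. Whether a clinical workstation de-duplicates overlapping
slices is vendor-specific; the convention here is explicit and
self-consistent.

Manual exclusion of adjacent calcified structures (coronary ostia,
aortic wall) is modelled as a mask input: excluded voxels are set to
−1024 HU before detection, so they can neither seed nor join a lesion.
No automatic structure detection is attempted.

## Dynamic-threshold CECT measurement

The luminal reference ROI is a disc concentric with the ascending-aorta
lumen, placed `round(30 mm / increment)` slices above the annulus
plane. Covering a fraction *f* of the lumen area means a radius of
`lumen_radius · √f`; the default *f* = 2/3 keeps the ROI clear of wall
voxels, and a warning is logged if the disc comes within one pixel of
the lumen boundary. ROI statistics use the **population** SD (ddof = 0),
which is what scanner consoles display; over the ~1900 pixels of a
typical aortic ROI the distinction from the sample SD is negligible,
but the choice is fixed and documented.

The calcium threshold is `mean + k·SD` with `k = 4` by default.
Segmentation is inclusive (≥), mirroring the native convention, and is
restricted to an explicit valve-region mask (or a slice interval) —
the manual valve selection of clinical practice is replaced by mask
input, and no automatic annulus or lumen detection is attempted. The
result records the threshold and ROI statistics used, so per-subject
threshold variability (which tracks enhancement and noise) is
reportable.

## Conversion and its calibration

Calculated Agatston units are an affine function of the contrast-derived
volume. The shipped preset `"paper-2024"` is `691 + 1.83 × V(mm³)`,
derived in a pre-interventional severe-aortic-stenosis cohort; because
such cohorts contain no calcium-free valves, the line does not pass
through the origin, and the intercept is therefore left free in
`calibrate` (plain OLS of native score on volume; a through-origin mode
exists only for comparison with earlier fixed-ratio approaches). No
robust-regression or outlier handling is applied — the model is the
plain least-squares line. Presets should not be transferred across
centres or protocols without local calibration.

## Agreement statistics

The default ICC form is the two-way, absolute-agreement, single-measure
coefficient ICC(A,1) — the standard choice when two fixed measurement
methods are compared and systematic offsets must count against
agreement. Estimates and F-based 95% CIs come from ANOVA mean squares
(delegated to `pingouin`; the test suite cross-checks the estimate
against an explicit sums-of-squares computation). Other forms
(consistency, one-way, average-measure) are selectable and the form used
is recorded in the report. Under perfect agreement the residual mean
square is zero and the F-based interval is undefined; the CI then
collapses onto the point estimate.

Bland–Altman analysis uses the convention **d = native − calculated**
(stated in every report), limits of agreement `mean ± 1.96·SD` with the
sample SD (ddof = 1) of the differences, and a proportional-bias test as
the two-sided t-test on the OLS slope of differences on means. When the
differences are exactly constant the slope is 0 by definition and the
t-test degenerates; the p-value is reported as 1 (no evidence of
proportional bias).

## The phantom generator

The phantom emulates the geometry the method needs and nothing more: a
soft-tissue background (30 HU), a cylindrical aortic lumen (radius
15 mm by default) filled with blood (40 HU) on the native render and
contrast (350 HU mean enhancement by default) on the paired render,
spherical uniform-HU calcific lesions in a valve region around the
annulus plane, optional distractor spheres outside it, and additive
white Gaussian noise (default SD 25 HU, a plausible soft-kernel cardiac
CT noise level; scanner noise is a free parameter of the generator, not
a reported value). The lumen begins just above the valve region, so the
valve-plane slices contain leaflet-level tissue rather than pure
contrast — this keeps calcium the only suprathreshold structure inside
the valve mask and makes noise-free recovery exact.

Voxel membership in a sphere is decided by the voxel-centre-in-sphere
rule, so the noiseless render is exactly analytic: truth volume equals
suprathreshold voxel count × voxel volume by construction, and the true
Agatston score is computed by an independent brute-force scorer
(pure-Python flood fill, explicit weight brackets) on the noiseless
volume with distractors blanked. Partial-volume averaging can be
approximated with an optional Gaussian blur, which deliberately breaks
the exact-truth property and is off by default. Seeds are mandatory for
every stochastic operation; identical specs render identical volumes.

What the phantom does **not** emulate: beam hardening, motion and
gating artifacts, blooming, anatomy beyond cylinder-plus-spheres,
spatially correlated noise, and kV-dependent calcium attenuation.
Passing tests therefore demonstrate the correctness of the measurement
and statistical machinery under the stated geometry and noise model,
not clinical performance on patient scans.

Synthetic paired cohorts for the statistical layer are generated
directly from the conversion model: volumes uniform on 300–2500 mm³
(the range spanned by severe-stenosis planning cohorts) and native
scores on the line plus Gaussian noise (default SD 400 AU). Agreement
cohorts come from a one-way variance-components model with the error
variance solved from the prescribed population ICC. Generated native
scores are deliberately not clipped at zero — truncation would bias the
calibration-recovery checks.

## Problem sizes and numerical notes

- Calibration-recovery simulations use 200 cohorts of n = 45;
  ICC/R² recovery uses 500 cohorts of n = 20. Oracle-equivalence sweeps
  use 100 randomly specified compact phantoms (25 × 48 × 48 voxels at a
  1.5 mm increment, chosen so the luminal reference plane still fits in
  the grid).
- Slab formation must be commensurate: the slab thickness has to be an
  integer multiple of the slice increment, checked to 1e-9, otherwise
  an error is raised.
- All thresholds are inclusive (≥). Native lesion weighting is defined
  only for maxima ≥ 130 HU; requesting a weight below that is an error
  rather than a silent weight of 1.
- HU are carried as float64 throughout; NIfTI round trips are bit-exact,
  and a file without voxel spacing in its header is a hard error, never
  a defaulted 1 mm.
- Cohort generation requires n ≥ 3: with free intercept and slope, two
  points leave no residual degrees of freedom, so a two-point
  "calibration" is rejected even though it determines a line.
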