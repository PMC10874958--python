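# Methods

`octlayers` quantifies the structural irregularity of retinal layers on OCT
B-scans.  Three hyperreflective structures are segmented — the inner
plexiform layer (IPL, a thin bright line), the outer plexiform layer (OPL, a
thick bright band with an upper and a lower border) and the ellipsoid zone
(EZ, a thin bright line) — and two families of biomarkers are computed in
three lateral zones around the fovea: the smoothness index SI = LL/CL of a
boundary (straight-line endpoint distance over polyline arc length, 1 for a
perfectly smooth boundary) and the trapezoidal areas S of the inter-layer
gaps (INL between IPL and the upper OPL border, OPL between the two OPL
borders, ONL between the lower OPL border and the EZ).  Group differences
(normal / non-proliferative / proliferative diabetic retinopathy) are tested
with clustered-eye GEE, and diagnostic separation with ROC/AUC.

## Image model and preprocessing

Scans are 2-D intensity grids in [0, 1], rows = axial depth (row 0 toward
the vitreous), columns = lateral position; the canonical canvas is 256 x 728
pixels.  Preprocessing:

* **Denoise** — separable Gaussian, explicit normalized 11-tap kernel per
  axis (sigma = kernel/6 ~ 1.83 px), reflect padding.  The filter is linear
  and preserves constants; output needs no clipping.  An optional
  non-local-means switch exists but is off by default.
* **Retina mask** — a small Gabor bank (nominal 6 x 6 kernels, odd-padded;
  orientations 0 and pi/2; wavelength 4 px) is applied; the mask is the
  largest connected component of the per-column vertical envelope of the
  thresholded (Otsu) response, i.e. each column is filled from its topmost
  to bottommost bright structure so the dark nuclear layers between the
  bright bands stay inside the mask.  Scans whose Gabor response has a flat
  depth profile (no layered structure; coefficient of variation of the
  column-averaged response < 0.2) are rejected as unusable, as are scans
  whose mask covers < 5% of pixels.
* **Optic-disc trim** — horizontal scans lose round(0.15 x width) columns on
  the disc side (metadata-driven; the generator sets the disc side from eye
  laterality).  The removed-column offset is tracked so outputs stay in
  original image coordinates.  Vertical scans pass through.

## Boundary segmentation

Per column, the axial profile inside the mask is scanned for local maxima
(prominence >= 0.15 of the local range).  The topmost ridge is read as the
IPL, the bottommost as the EZ, and the strongest interior peak as the OPL
band.  Sub-pixel localization is parametric, because every structure has a
known profile family after Gaussian blur:

* **Lines (IPL, EZ)** — Gaussian ridge plus an erf step sharing the ridge
  center and width.  The step models the reflectivity difference of the
  tissue above vs below the line; with a flat or linear baseline instead,
  the center is biased by ~0.2 px, which is material for the thin foveal
  INL gap.
* **Band (OPL)** — an erf-pair (a blurred constant-brightness band is
  exactly an erf-pair).  The free 5-parameter fit is used only to calibrate
  scan-level brightness and edge blur (medians over well-resolved columns);
  every column is then refit with those two frozen, because for bands not
  much wider than the blur, brightness and width enter the model mostly
  through their product and the free fit becomes degenerate and biased
  under speckle.  The final half-width comes from the integral of the
  background-subtracted band (blur redistributes but preserves the
  integral, and the integral is linear in the data, hence free of the
  nonlinear noise bias of least squares), with an erf-shape tail correction
  and local flank re-baselining.
* **Pinched fovea** — where the INL thins until the IPL ridge and the band
  upper border no longer produce separate peaks (or lie within 16 px), a
  joint ridge + band model with the scan-level shape parameters frozen is
  fit, initialized by continuation from neighbouring resolved columns.
  Columns where even the joint fit fails carry no candidates.
* **Noise pooling** — before the band fits, profiles are averaged over +/-5
  neighbouring columns after shifting each by the local quadratic trend of
  the band center (shear correction), so the averaging suppresses speckle
  without blurring tilted or curved boundaries or rounding undulation
  crests.

Each role's candidate cloud is then regressed by an epsilon-insensitive SVR
of row on normalized column position with the translation-invariant wavelet
kernel K(u, v) = cos(1.75 (u-v)/a) exp(-(u-v)^2 / 2a^2) (mother wavelet
cos(1.75x) exp(-x^2/2)), solved on a precomputed Gram matrix.  Candidates
deviating more than 8 px from the fitted curve are dropped and the model
refit once (mislabel replacement).  Columns violating the depth ordering
IPL < OPL_upper <= OPL_lower < EZ after fitting are excluded from all
biomarker computations for that scan.

Defaults: dilation a = 0.016 in normalized column units (~10 px on a
620-column domain), C = 100, epsilon = 0.25 px.  The kernel scale is the
key choice: it must sit below the wavelength of pathological boundary
undulation (tens of pixels; a scale of ~60 px would be unable to represent
such oscillations — the RKHS norm of sin(kx) grows explosively in k*a — and
would flatten exactly the irregularity the smoothness index measures) yet
above the candidate jitter scale.  epsilon is set well below a pixel so the
tube does not shave undulation amplitude; C large enough that the fit is
candidate-dominated.  All three are configurable.

## Fovea, zones, biomarkers

The fovea is the maximum of a center-surround response
`y(x) - (y(x-D) + y(x+D))/2` of the moving-average-smoothed IPL depth
(window and D = 65 px, about one undulation wavelength), searched in the
central 60% of the domain.  The surround subtraction cancels linear depth
trends; a plain smoothed argmax follows scan tilt or asymmetric thickening
and can miss the pit by tens of pixels, while an undulation-matched window
cancels the waves themselves.  If no depression stands out (< 1 px), the
domain midpoint is used and flagged.

The foveal zone holds round(0.20 x width) columns split evenly around the
fovea (odd counts put the extra column on the high-column side); the
remaining columns form the nasal zone on the optic-disc side and the
temporal zone opposite (horizontal scans), or superior (low column indices)
and inferior (vertical scans).  If the foveal interval would spill over the
domain edge it is shifted inward and flagged.

SI uses the first and last valid columns of the zone as endpoints; excluded
columns inside are bridged with their true lateral span.  SI is clamped to
1 only within floating-point rounding of a straight polyline (1e-12).
Areas are trapezoidal integrals over unit-spaced valid column pairs;
excluded columns are omitted, not bridged.  Per zone the record carries
SI of the IPL, the upper OPL border and the EZ (the lower OPL border is
segmented but its SI is not reported) and the three areas, named
`VAR.H.zone` / `VAR.V.zone` (e.g. `SI_IPL.H.Nasal`, `S_INL.V.fovea`).
Areas are in pixel^2; an optional micron-per-pixel pair rescales them.

## Synthetic cohorts

No public dataset pairs raw B-scans with per-eye retinopathy grades, so the
generator is a first-class module.  Geometry: a Gaussian foveal pit
(default depth 16 px, sigma 52 px) depressing the inner boundaries and
fading with depth (the EZ stays flat); per-zone inter-layer spacings derived
from drawn area targets, interpolated linearly between zone centers (a
sigmoid blend would cost smoothness index before any irregularity is
added); the lateral thickness trend split 35% / 65% between the EZ and the
inner boundaries so no single boundary absorbs all its curvature; and a
single-frequency sinusoid (wavelength 64 px), shared in phase across
boundaries, whose per-zone amplitude is calibrated by Brent root finding so
every boundary's zone SI matches its drawn target within +/-0.002 on the
assembled curve (pit and spacing blends included).  The OPL's lower border
reuses the upper border's amplitude, so the band moves as a whole.

Rendering: bright Gaussian ridges at IPL (amplitude 0.50, sigma 1.6 px) and
EZ (0.65), a soft-edged band between the OPL borders (0.45, edge sigma
1.2 px), a dim tissue fill between IPL and EZ (0.10) over a 0.06 background,
then multiplicative unit-mean gamma speckle (default shape 16, i.e. 25%
coefficient of variation — a moderate level representative of
frame-averaged spectral-domain scans).

Cohort defaults mirror the target study design: 33/36/15 eyes
(normal/NPDR/PDR) with ~47% of patients contributing both eyes,
group-specific age and sex distributions, and per-group, per-zone,
per-biomarker means and SDs for both scan orientations.  Area targets are
kept in their published arbitrary unit; they are far too large to be
pixel^2 on a 256-row canvas, so rendering maps them to the canvas with a
fixed axial scale (0.33).  Stored ground truth always records the rendered
geometry, so segmentation fidelity is judged like-for-like; cohort
statistics use the drawn, unit-preserving values.

Two generation modes matter for testing.  `render=False` draws biomarkers
and covariates only, with truncation solely to validity (SI in (0,1],
areas > 0): its distributions follow the configured targets exactly, which
is what the law-of-large-numbers and binormal-AUC checks exercise.
`render=True` additionally rejects draws whose geometry cannot be laid out
(inter-layer gaps below 3.5 px, or leaving the canvas) and re-draws, up to
a bounded retry count — a mild conditioning of the rendered cohort that the
statistics path does not share.

What the generator does not emulate: vessel shadows, cystoid spaces, DRIL,
scan tilt, axial PSF side lobes, or any spatial statistics of pathological
irregularity beyond a single sinusoid.  Passing tests therefore demonstrate
correctness of the measurement chain on controlled geometry, not clinical
performance on real scans.

## Statistics

Group comparisons: Gaussian-identity GEE with exchangeable working
correlation, clustered on patient (fellow eyes correlate), robust sandwich
covariance, adjusted for centered age and a male indicator; Wald tests give
the overall 2-df group p-value and the three pairwise contrasts.  Raw
p-values are reported (a Benjamini-Hochberg option exists, off by default).
ROC/AUC via the Mann-Whitney identity with ties counted 1/2, polarity
auto-chosen so AUC >= 0.5, 95% CI by DeLong (implemented here; no installed
package provides it).  Spearman correlation with a t-approximate p-value;
constant inputs are an error.

## Numerical choices and known limitations

* Solver tolerances: SVR tol 1e-4 (deterministic given fixed inputs); GEE
  convergence 1e-8, max 100 iterations; profile fits are
  Levenberg-Marquardt with analytic Jacobians and post-fit sanity gates.
* Degenerate inputs: all-zero columns yield no candidates and are filled by
  model prediction; scans with < 25% candidate columns, empty masks, or no
  layered structure raise typed errors; per-scan failures in the batch
  pipeline are logged and skipped.
* Problem sizes: the test suite segments 50 scans (256 x 728) for the
  recovery check and runs 500 simulated clustered datasets for GEE
  coverage; the acceptance script uses 20 scans and 200 datasets.
* Accuracy floor: at the default speckle level the thinnest foveal bands
  (~6-10 px) carry limited Fisher information; the zone-mean width error of
  any estimator has a standard deviation of roughly 0.04-0.1 px (lateral
  noise correlation from the 11 x 11 denoise included), i.e. ~1-1.5% of the
  thinnest foveal OPL/INL areas.  Boundary RMSE (~0.3 px) and SI recovery
  (within ~0.01) have comfortable margins, but worst-case foveal area
  recovery across a 50-scan cohort can reach 2-4% for a handful of values.
* The generator's two-eye pairing, age/sex draws and SSI values are
  simulated conveniences; SSI is metadata only (scans below 40 are
  excluded, never recomputed from signal).
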