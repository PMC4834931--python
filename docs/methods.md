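# Methods

`pbvckit` measures percentage brain volume change (PBVC) between two MRI
sessions of one subject and quantifies how reproducible that measurement is
within and across scanners. Everything is exercised on synthetic
multi-contrast phantoms whose tissue volumes are known in closed form, so
every accuracy claim is checked against analytic truth rather than against
another software package.

## The measurement pipeline

Each session contributes a 3D T1-weighted and a 3D FLAIR volume. Per
session (cross-sectional stage):

1. **Skull stripping.** The T1 histogram is split into background and
   tissue with Otsu's criterion; the working threshold is a fraction
   (default 0.35) of that split. The largest connected component is closed
   morphologically and hole-filled. Because the brain/background edge runs
   through CSF, a refinement pass re-places the boundary at the half-CSF
   crossing when the initial threshold provably cut above the CSF level
   (CSF level estimated as a low percentile of near-mask intensities above
   the background noise floor); the refined mask may grow only by bounded
   conditional dilation, so background noise cannot reconnect.
2. **Coregistration.** The FLAIR is rigidly registered to the T1 with
   Mattes mutual information (32 bins, 3 resolution levels, seeded 25%
   sampling — deterministic) and resampled with linear interpolation.
3. **Prior propagation.** Probabilistic GM/WM/CSF priors are brought into
   subject space by affine MI registration of the atlas T1. The built-in
   atlas is phantom-derived — blurred (8 mm FWHM) ground-truth tissue maps
   of the canonical lesion-free phantom — which keeps the package free of
   external downloads; external atlas NIfTIs can be passed through the same
   interface.
4. **Lesion-aware EM segmentation.** A univariate Gaussian mixture over T1
   intensity with spatially varying priors: E-step responsibilities
   `γ_c(x) ∝ prior_c(x)·N(y(x); μ_c, σ_c²)`, closed-form M-step, iterated
   to a relative log-likelihood change below 1e-5 (cap 100). Lesions are
   detected on the FLAIR as voxels above `μ_NAWM + κ·σ_NAWM` (κ = 3) that
   also have WM prior ≥ 0.5 and are not CSF; detected voxels are filled on
   the T1 with draws from the WM intensity model and the filled image is
   segmented again, until lesion masks (Dice ≥ 0.95) and hard labels
   (< 0.1 % changed) stabilize, with a hard cap of 10 outer loops flagged
   rather than raised. Three numerical details matter in practice and are
   deliberate choices:
   - the CSF veto on lesion candidates requires the *atlas prior* and the
     current posterior to agree the voxel is fluid — unfilled
     T1-hypointense lesions acquire spurious CSF posteriors on the first
     pass and must stay eligible for filling;
   - candidates must stay hyperintense after a 1-voxel blur, a
     resolution-independent speckle rejection that complements the
     15 mm³ component-size floor (which single voxels defeat on coarse
     analysis grids);
   - each detected component is trimmed at half its height above NAWM
     (full-width-half-maximum volumetry), since a κσ threshold otherwise
     counts the partial-volume ring and inflates lesion volume by ~50 %.
   A GM guard (`threshold ≥ μ_GM,FLAIR + κ·σ_NAWM`) prevents GM/WM
   partial-volume voxels — brighter than NAWM on FLAIR — from being flagged
   in the noise-free limit.

Longitudinal stage (per session pair):

5. **Rigid alignment** of session B's lesion-filled T1 onto session A's
   (Mattes MI), resampling each onto the other's grid.
6. **Intensity standardization.** Across scanners, intensities are mapped
   with a piecewise-linear landmark transform anchored at (0,0) and the two
   sessions' CSF/GM/WM plateau levels (medians of high-posterior voxels).
   For same-contrast pairs the anchors agree and the map is skipped: any
   refitted global map (least squares, moment or median matching) leaves
   plateau-level mismatches over flat tissue that the registration converts
   into spurious volume change an order of magnitude larger than a
   sub-percent atrophy signal. A smooth multiplicative shading field
   (the 25 mm-blurred ratio of observed to segmentation-predicted
   intensity) is divided out per session first; independent per-session
   shading otherwise biases the inter-scanner comparison by ~1 %. This is
   part of the registration's intensity normalization, not a separate
   bias-correction stage.
7. **Nonrigid registration.** Dense symmetric-forces demons (SimpleITK's
   `FastSymmetricForcesDemonsRegistrationFilter`), multi-resolution
   (shrink 4/2/1, 100 iterations per level), Gaussian regularization of
   update and field with σ = 0.85 mm. The field maps A-space points to
   B-space points and is tapered to zero outside the brain mask dilated by
   10 mm (the taper transition sits in background so it cannot distort the
   in-brain Jacobian). A hand-rolled demons loop was implemented first and
   abandoned after diagnosis: at the sub-voxel boundary displacements a
   −1 % change produces (~0.07 voxel on the test grids), post-hoc
   smoothing of the accumulated field erodes the converged displacement
   and perfectly flat synthetic background admits a neutral-drift ratchet;
   the SimpleITK filter's symmetric formulation recovers 97 % of a
   prescribed −1 % change on a 1.5 mm grid.
8. **Jacobian modulation.** `jdet(x) = det(I + ∇u(x))` by central finite
   differences in mm. The volume change of a tissue class is
   `ΔV = Σ p(x)·(jdet(x) − 1)·v_vox` against the reference session's
   probability map; `pbvc = 100·ΔV/V₁`. Computed for parenchyma
   (PV = GM + WM + lesion — lesions are parenchyma) and GM.
9. **Symmetric averaging.** Both directions are estimated and combined as
   `(forward − backward)/2`; negative = atrophy. The directions carry a
   common noise-induced expansion bias of up to a few percent that the
   subtraction cancels (scan-rescan medians drop to ~0.05–0.1 %), while a
   true change enters both directions with consistent sign.

## The edge-displacement comparator

A SIENA-like method used as the contrast-sensitivity benchmark: 3-class
k-means on in-mask T1 intensities (deterministic quantile initialization),
parenchyma/CSF boundary from face-adjacent voxel pairs, outward normals
from the smoothed parenchyma-indicator gradient, and per-point displacement
from the offset between derivative-magnitude peaks of intensity profiles
(±6 mm at 0.25 mm steps) sampled in both sessions along the normal, with
quadratic sub-sample refinement. Profiles are blurred by 2 mm before
differentiation — linear interpolation otherwise yields flat derivative
plateaus whose argmax cannot see sub-voxel edge motion. Both sessions
search the same window, so identical images give exactly zero. The mean
displacement converts to PBVC via
`100·c·mean(d)·edge_area/brain_volume`; the constant `c` is fitted once by
through-origin regression of true versus raw estimates on five phantom
pairs with prescribed changes spanning ±2 % (a fixed, documented stand-in
for SIENA's internal self-calibration).

## The phantom

Nested ellipsoids: a skull-bounded CSF shell around the parenchyma, a
cortical GM ribbon (outer band of the parenchyma), a WM core, two
CSF-filled ventricular ellipsoids and spherical WM lesions. All volumes
are closed-form; rasterization samples each voxel on a 3³ subgrid, giving
partial-volume fractions that carry the sub-voxel boundary information the
measurement methods rely on. Defaults: parenchyma semi-axes
(63, 80, 47) mm → PV ≈ 982 ml, inside the study population's whole-brain
range (≈ 892–1135 ml); three lesions totalling ≈ 9.4 ml, inside the
population's 2.6–61 ml lesion-load range. The GM ribbon is 10 mm thick and
yields ≈ 417 ml of GM — less than real cortical GM (~640 ml), because an
unfolded ellipsoid shell cannot host a realistic GM volume at a plausible
thickness; GM-level results are correspondingly less precise than PV
results and are reported as such.

Atrophy is applied analytically: the parenchyma semi-axes are scaled so PV
changes by exactly the prescribed percentage (ventricles, lesions and the
skull boundary stay fixed; lost volume becomes CSF), and the ribbon
thickness is re-solved so GM changes by exactly its prescribed percentage.
True PBVC is therefore exact and independent of rasterization.

Two scanner presets emulate the study's 1.5 T and 3 T protocols: the
acquisition voxel sizes (T1 0.87 × 1.25 × 1.2 mm³ vs 0.88 × 1.19 × 1 mm³,
FLAIR analogous) define the grids (a `scale` multiplier coarsens them for
desk-scale runs), and per-class intensity tables define the contrasts. The
tables are plausible arbitrary-unit levels — no per-scanner intensity
statistics exist to calibrate against — chosen once so that each preset
preserves the canonical orderings (T1: CSF < GM < WM; FLAIR: CSF < WM <
GM < lesion), the 3 T-like preset has larger GM/WM contrast and darker
CSF, and lesions are T1-hypointense/FLAIR-hyperintense. Bias fields are
products of per-axis quadratics (amplitude as a fraction of the mean,
seeded); noise is additive Gaussian with sd expressed as a fraction of the
WM mean, clipped at zero. Identical spec + seed is bit-identical. What the
phantom does *not* emulate: cortical folding, k-space acquisition, Rician
magnitude statistics, motion, and pathology-driven intensity change —
passing tests show the measurement machinery is sound, not that real-data
accuracy equals phantom accuracy.

## The simulated reproducibility study

Ten synthetic subjects (anatomy jittered ±4 % in the semi-axes, ±20 % in
lesion radii, seeded), each "scanned" twice per preset: intra-scanner
pairs share the pose *and the scanner's shading-field realization* — the
subject stays in the scanner between same-day acquisitions, so the coil
profile is common — and differ only in the noise draw; the inter-scanner
pair combines the first session of each preset with a seeded repositioning
(≤ 5°, ≤ 5 mm) and independent shading fields. True change is zero throughout, so
measured PBVC is error. Summaries are the median and IQR (linear
interpolation quantiles) of absolute and signed errors per condition and
method; the paired Wilcoxon signed-rank test (exact by full 2ⁿ sign
enumeration for n ≤ 12, normal approximation with continuity and tie
correction above; zero differences dropped) compares the two methods'
absolute PV errors; Bland–Altman tables use the difference convention
method1 − method2 with limits bias ± 1.96 sd.

At the default analysis scale (3× the acquisition voxel) the study
reproduces the qualitative structure of the real scan-rescan experiment:
intra-scanner medians ~0.05–0.1 % for both methods, inter-scanner errors an
order of magnitude larger, the Jacobian method's inter-scanner median
error roughly half the edge method's, and the edge method's inter-scanner
error appearing as a consistent, signed volume offset between the two
contrasts rather than symmetric noise.

## Numerical choices and degenerate inputs

- Grids are axis-aligned internally (readers reorient to RAS); voxel
  indices are 0-based and world coordinates refer to voxel centers.
- Linear resampling is used everywhere except label maps (nearest) and
  never overshoots; B-spline is available but excluded from label maps.
- EM variances are floored at (10⁻³ × intensity range)² so noise-free
  piecewise-constant images cannot collapse a class; a class with total
  responsibility below 10 voxels raises a named class-collapse error.
- Flat priors initialize EM at intensity quantiles to break the symmetry
  of identical prior-weighted means.
- The demons σ (0.85 mm) trades sub-voxel recovery against noise:
  1 mm attenuates a −2 % change by ~17 % under realistic noise and
  shading, 0.75 mm starts to overshoot on noiseless pairs; 0.85 mm keeps
  both the noiseless and the noisy case within a quarter percentage point.
- Degenerate cases raise informative errors: empty masks, single-mode
  histograms, fewer than three intensity classes, zero tissue volume,
  singular transforms, non-finite displacement fields.

## Problem sizes

Default experiment sizes were chosen so each experiment completes in
minutes on one CPU: the reproducibility cohort runs 10 subjects at 3× the
acquisition voxel; atrophy-recovery pairs run at 1.5× (where the demons
recovers ≥ 85 % of a −1 % change); the lesion-filling experiment runs 10
noise-free paired replicates at 2.5×. Finer grids improve recovery
monotonically (97 % at 1.5 mm isotropic on sphere phantoms).

## Known limitations

- GM PBVC at coarse analysis grids is resolution-limited (the ribbon is
  2–3 voxels thick) and inter-scanner GM errors are large; PV is the
  robust endpoint, matching the real study's emphasis.
- The edge comparator's calibration constant is grid- and
  geometry-dependent; it is refitted per analysis scale.
- The tissue-landmark intensity map assumes three dominant plateaus; it
  would need more landmarks for pathologies that create a fourth mode.
- Lesions are static between sessions (same-day design); lesion evolution
  is out of scope.
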