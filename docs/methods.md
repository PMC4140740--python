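# Methods

`earmorph` quantifies the shape of a segmented ear-cartilage sheet and asks
two questions about the measurement chain that produced it: *precision* —
do different human raters contouring the same scan obtain the same numbers?
— and *accuracy* — do the numbers obtained at clinical MRI resolution agree
with a high-resolution micro-CT reference?  Because the underlying human
scans of such studies are generally not shareable, every quantitative claim
in this package is validated on synthetic phantoms whose volume, surface and
thickness are known analytically or by fine quadrature.

## Morphometry

All metrics are computed from a binary voxel mask with physical spacing
`(sx, sy, sz)` in mm; arrays are stored `(Z, Y, X)` and every physical
quantity is derived from the spacing, never from voxel counts alone.

**Cg.V (mm³)** — foreground voxel count × voxel volume.

**Cg.S (mm²)** — area of the triangulated 0.5-isosurface of the binary
field (marching cubes, anisotropy honoured by the vertex coordinates).  The
field is pre-smoothed with a one-voxel Gaussian before extraction: raw
marching cubes on binary data inherits the voxel staircase and overestimates
curved surfaces by ~9%, while after smoothing the measured errors on
analytic phantoms at 0.1 mm are +0.25% (sphere r = 5 mm), +0.26% (spherical
shell) and −1.3% (20×20×5 mm box).  Voxel-face counting was rejected
outright (up to ~50% overestimation on curved objects).  If smoothing
erases an extremely thin object (< ~2 voxels across), the raw field is used
as a fallback.

**Cg.Th (mm)** — the model-independent local thickness: at every foreground
voxel, the diameter of the largest sphere that contains the voxel centre
and fits entirely inside the foreground; Cg.Th is the unweighted mean over
foreground voxels of an isotropic grid (= volume-weighted mean).
Implementation: Euclidean distance transform to background voxel centres,
minus half a voxel, gives the sphere radius available at each foreground
centre (distance to the voxelized surface).  Because the medial maxima of a
sheet can fall *between* voxel centres, candidate spheres are added at face
midpoints: the radius field is 1-Lipschitz, so the peak between two
adjacent samples is estimated by intersecting the one-sided slopes
(slopes of 1 from both sides give the tent value `(r1 + r2 + h)/2`; a flat
field along the axis gives `max(r1, r2)` and plateaus are not inflated).
A covering pass over descending diameters — one background-EDT per level,
at most 128 quantized levels — assigns each voxel the largest covering
sphere.  On analytic phantoms at 0.1 mm: a 1.2 mm slab measures 1.198 mm
(all interior voxels exactly 1.2), a 1.0 mm spherical shell wall measures
0.973 mm with all per-voxel values in [0.92, 1.0], and a single isolated
voxel measures one voxel diameter.  Note that for compact shapes with
corners (e.g. a cube) the volume-weighted mean is genuinely well below the
edge length — corners are covered only by small spheres — which the
brute-force oracle in the test suite confirms.

**Isotropic rescaling.**  Sphere fitting assumes isotropy, so anisotropic
masks are resampled before thickness measurement by linear interpolation of
the indicator field thresholded at 0.5.  The default target for anisotropic
input is `min(spacing)/2` rather than `min(spacing)`: the interpolated
boundary carries sub-voxel information, and measuring on the twice-finer
grid halves the distance-transform discretisation bias.  At the clinical
grid (0.45 × 0.45 × 0.40 mm) a 1.15 mm bent-sheet phantom measures 1.52 mm
at a 0.40 mm target but 1.22 mm at the 0.20 mm default — the residual
+0.07 mm is the resolution limit of ~2.6-voxel-thick sheets.  This mirrors
the clinical workflow of contouring on upscaled slices and rescaling the
mask isotropically before morphometry.  Already-isotropic input is measured
as-is; the target is a config value (`isotropic_target`) recorded in every
result.

## Micro-CT reference segmentation

The reference chain emulates scanner-vendor soft-tissue segmentation: a
truncated discrete Gaussian (σ = 1.2 voxels sampled at integer offsets,
truncated at ±1 voxel — a 3×3×3 kernel — and renormalized to unit mass),
applied separably with mirror boundary handling (zero padding would darken
the edges of specimens scanned in air), followed by a closed-interval
threshold on linear attenuation, 0.9–2.2 cm⁻¹ by default.  "Between" is
resolved inclusively on both ends.  An optional largest-26-connected-
component step (off by default, logged when used) removes debris.

## Synthetic phantoms and simulated raters

Phantoms are defined by signed-distance fields and rasterized at voxel
centres:

* **slab** — box; V, S, Th in closed form (a 30×30×1.2 mm slab has
  V = 1080 mm³ exactly).
* **spherical_shell** — wall of thickness t at inner radius r;
  V = 4/3π(r_out³−r_in³), S = 4π(r_in²+r_out²), Th = t.
* **bent_sheet** — a sheet bent over a cylinder sector (default bend radius
  18 mm, arc 1.6 rad, axial length 28 mm — a desk-scale stand-in for the
  auricular cartilage layer at roughly a third of its area, keeping the
  curved-sheet character and the ~1.15 mm thickness regime), with optional
  smooth thickness modulation (random-phase cosine field, default amplitude
  0.10 mm, length scale 8 mm) emulating local thickness variation.  Truth
  is computed by 2D quadrature over the sheet at 0.02 mm and flagged
  `numerical`.

Rasterization requires at least 2 voxels across the sheet (error below,
warning below 4 — thickness becomes resolution-limited there, which is
exactly the clinical regime: 1.15 mm / 0.45 mm ≈ 2.6).

**Simulated raters** perturb the phantom's signed-distance field by three
components, then re-threshold at zero: a fixed per-rater bias (voxel units;
systematic over/under-contouring), a per-mask global offset drawn from
N(0, `global_amplitude`·voxel) (scan-to-scan variation in how tightly the
rater contours — the component that actually drives rater-to-rater scatter
in the summary metrics), and a smooth zero-mean Gaussian random field
(SD = `noise_amplitude` voxels, correlation length 5 mm) giving local
boundary disagreement.  A spatially smooth level-set perturbation was
chosen over per-voxel label flips because human contouring errors are
smooth along the boundary; a coherent outward shift ε thickens the sheet
locally by 2ε, which propagates to Cg.V and Cg.Th together — the mechanism
behind the field observation that surface is measured more precisely than
volume and thickness.  Two properties of the local field are worth
noting: its sheet-average nearly vanishes (so it contributes little to the
per-mask metric scatter), and because local thickness is a maximal-sphere
*envelope*, symmetric ripple biases Cg.Th upward rather than averaging
out — the default local amplitude of 0.3 voxels keeps that envelope bias
to ~0.05 mm.  The default panel — biases (−0.10, 0, +0.10) voxels, global
amplitude 0.06 voxels — was calibrated once by
`scripts/calibrate_rater.py` (seeded sweep) so that the default
14-subject × 3-rater study lands its inter-rater PE %CV in the upper
single-digit regime of manual ear-cartilage contouring at clinical
resolution, with volume slightly less precise than surface and the
thickness error comparable to the between-subject thickness spread (the
regime in which mean-thickness ICC collapses while volume/surface ICC
stays high).  On the calibration seed the panel measures PE %CV of
8.7/2.0/7.6% and ICC of 0.80/0.98/0.22 for Cg.V/Cg.S/Cg.Th.

**Cohorts.**  Each subject draws a linear size scale (1 ± `size_scale_cv`,
default 0.07 — chosen so volume/surface CVs land near the ~18%/13% reported
for adult auricles) and a thickness from N(1.15, 0.10) mm.  The accuracy
study's cadaveric specimens use a wider spread (scale CV 0.25), reflecting
the greater heterogeneity of donor material.  All generators are
deterministic: per-cell seeds are derived from the study seed via
`numpy.random.SeedSequence`.

**CT emulation** rasterizes attenuation with partial volume (3×3×3
sub-voxel occupancy of the SDF; voxel value = background + occupancy ×
(cartilage − background), defaults 0.2 and 1.5 cm⁻¹) plus additive Gaussian
noise (default SD 0.1 cm⁻¹).  The desk-scale CT grid is 0.10 mm isotropic
to keep phantom volumes tractable; the device-faithful 36.8 µm remains a
parameter.  Note one physical consequence: boundary voxels always carry
intermediate attenuation values, so even tissue far above the pass band
leaves a thin partial-volume ring after thresholding — no interior voxel
survives, but the mask is not literally empty.

## Precision statistics

For n subjects × m repeats (raters), with per-subject SD over repeats using
the (m−1) denominator:

    PE_SD  = sqrt( (1/n) Σ_j SD_j² )
    PE_%CV = 100 · sqrt( (1/n) Σ_j (SD_j / mean_j)² )
    dof    = n(m−1)

The report flags designs with dof ≥ 27 as adequate (`dof_ok`); the
conventional recommendation is quoted as 27 degrees of freedom while
n(m−1) for 14×3 is 28 — both numbers are surfaced rather than reconciled.
ICC(A,1) (two-way random effects, absolute agreement, single measures) is
computed from the two-way ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

Negative values are reported as computed, not clamped — they flag the
degenerate case where between-subject variance falls below measurement
error, which is precisely the situation of interest for mean thickness.
In a full study report a metric whose table is exactly degenerate (zero
denominator) carries ICC = NaN rather than aborting the other metrics.

Voxel-level agreement between two masks of the same scan uses the Pearson
correlation of the two indicator fields over the bounding box of the union
of foregrounds padded by two voxels.  The domain choice is deliberate and
recorded: including arbitrary amounts of empty background inflates r
towards 1.  Overlap maps label common / A-only / B-only voxels with
fractions normalized by the union.

## Accuracy statistics

Across specimens measured by both chains, each metric gets a Pearson r with
the CT chain as reference on x; the least-squares slope/intercept and the
RMS identity-line residual are reported alongside because r is blind to
constant bias.  For mean thickness, per-specimen |ΔTh| is tabulated against
a 1-voxel band (0.45 mm, the MRI in-plane voxel; the bound is closed).

## Problem sizes and numerical choices

The shipped studies are desk-scale by design: bent sheets of ~1600 mm²
surface instead of ~5100 mm² auricles (the cadaveric accuracy specimens
use 0.8× that base geometry — dissected cartilage trimmed of surrounding
tissue), CT grids at 0.10 mm instead of 36.8 µm, quadrature truth at
0.02–0.05 mm.  Thickness diameters are quantized to bins of h/3 (at least
16 and at most 128 levels, assigned at bin midpoints, so the rounding is
unbiased and bounded by h/6); EDT covering passes terminate early once all
voxels are assigned, and an optional ``tail_fraction`` lets the last
voxels of thin edge bands fall back to their own-sphere lower bound (off
by default).  Binary
resampling uses `>= 0.5` on the interpolated indicator; ties at exactly 0.5
are foreground.  Degenerate inputs are contracts, not accidents: empty
masks give (0, 0, 0) morphometry but an error for thickness maps and
pairwise correlation; constant tables give PE = 0 and an ICC error.

## What passing tests do and do not show

The phantoms validate the measurement chains, not the biology: they have
no MRI contrast physics, no perichondrium/skin ambiguity, no real rater
anatomy-driven errors (the rater model is a smooth stochastic field, not a
human), and auricle geometry is idealized as a bent sheet without
convolutions.  Passing the synthetic studies shows that *if* raters behave
like the calibrated noise model, the statistics reproduce the known regime
(single-digit PE %CV, collapsed thickness ICC, r > 0.95 cross-modality
agreement); it does not certify those numbers for any particular scanner,
sequence or rater pool.

## Known limitations

* Thickness at ~2.5 voxels across a sheet carries a positive bias of
  roughly +0.05–0.1 mm even after fine isotropic rescaling; below 2 voxels
  the phantom generator refuses to rasterize.
* Surface pre-smoothing can erase structures thinner than ~1.5 voxels (the
  raw-field fallback then applies, with staircase error).
* Masks compared pairwise must share a voxel frame; no registration is
  provided.
* DICOM series reading, HU calibration and scanner artefact modelling are
  out of scope.
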