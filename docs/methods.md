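# Methods

This note documents the models, parameter choices and numerical decisions
behind `orthotrack`, and what the synthetic phantom does and does not show
about clinical data.

## Coordinate conventions and imaging geometry

All 3D quantities live in a room frame with the origin at the treatment
isocenter: +x patient-left (LR), +y posterior→anterior (AP), +z
inferior→superior (SI).  Angles are degrees at every interface and radians
internally; lengths are millimetres.

A tube/panel pose is parameterized by the beam azimuth in the axial plane.
The unperturbed source sits at radius SID = 1000 mm in the z = 0 plane
(at azimuth 0 the source is at (0, −1000, 0) and the beam axis is +y);
the panel center lies SDD = 1836 mm downstream.  The clockwise and
counterclockwise tubes of the orthogonal pair are at gantry angle +45° and
−45°, which makes their beam axes orthogonal for every gantry angle and
maps an n-port plan to 2n tube-angle-specific models.

The panel is 1024 × 768 pixels.  The physical pitch default is
0.211 · 1836/1000 ≈ 0.3874 mm so that the pixel scale demagnified to the
isocenter plane is exactly 0.211 mm.  (A nominal panel size of
222 × 168 mm at the isocenter level is inconsistent with
1024 · 0.211 = 216.1 mm; the per-pixel scale and the pixel counts are
treated as authoritative.)  Pixel (u, v) has its center at
`detector_center + (u − (n_u−1)/2)·pitch·u_axis + (v − (n_v−1)/2)·pitch·v_axis`,
with continuous sub-pixel coordinates allowed.  Downsampling by a factor k
that divides both pixel counts is exactly equivalent to k × k binning: the
binned geometry keeps the same panel with pitch k·pitch.

Augmentation perturbations rotate the *rigid* source+panel assembly about
the isocenter: first the SI tilt about the in-plane axis perpendicular to
the beam, then the AP tilt about the z axis.  The composition order and
the rigid-assembly interpretation are package choices (only the two tilt
directions are fixed by the problem); both rotations preserve SID, SDD and
panel orthonormality, which is property-tested.

## DRR rendering

A projection pixel stores the radiological path ∫μ dl with
μ = μ_water·(1 + HU/1000) clamped at zero and μ_water = 0.02 mm⁻¹
(≈70 keV effective energy; the value affects contrast only, never
geometry).  The integral is computed exactly as Σ μᵢ·ℓᵢ by a parametric
voxel traversal (Siddon): the ray is clipped to the volume bounding box,
and the sorted axis-crossing parameters partition it into per-voxel
segments, handled in a single incremental loop (numba-compiled).  Voxels
are half-open axis-aligned boxes, which resolves ties at exact plane
crossings.  Scatter, beam hardening and detector blur are intentionally
absent.

The renderer is verified against an independent dense midpoint-rule
integration at 0.01 mm steps.  The reference itself has a small
boundary-misassignment noise of roughly |Δμ|·h/√12 per voxel crossing, so
the comparison fixture uses HU in [−500, 500] at 4 mm voxels with long
chords, keeping the reference's own error near 5·10⁻⁴ relative — below
the 10⁻³ band the comparison asserts.  An axis-aligned chord through a
uniform water cube is asserted to be exact (≤ 10⁻⁹).

For display, images map through exp(−path) and are min-max rescaled to
8 bit per image (an all-zero path image maps to zeros).  The raw path grid
is preserved for all quantitative steps; in particular the GTV footprint
threshold (path > 10⁻⁶) operates on the path, never on gray levels, so it
is robust to display normalization.  The Gaussian prefilter used to match
measured projections to DRR resolution converts σ from millimetres at the
panel to pixels via the pitch and filters both grids; σ = 0 is the
identity.

## Synthetic breathing phantom

The phantom is a soft-tissue body ellipsoid (0 HU) enclosing two lung
ellipsoids (−750 HU), an ellipsoidal tumor inside the left-side lung, and
optional 1.5 mm-diameter high-density marker spheres (3000 HU) rigidly
co-moving with the tumor.  The tumor translates along a fixed motion
vector with the cos-power waveform

    w(p) = [(1 − cos(2π p / n_phases)) / 2]^power,   power = 2,

so phase 0 is end-exhale (the reference phase), the peak displacement is
mid-cycle, and the dwell near end-exhale resembles free breathing.
Hysteresis and marker migration are off by default.

Defaults emulate the study cohort: spherical tumor of 12.1 mm radius
(7.42 cm³, the cohort median; the `table1_like_spec` preset samples
1.18–25.74 cm³), tumor −176 HU (cohort mean-HU band −346 to −20), motion
vector (2, 5, 21.33) mm with norm 22 mm (cohort median; preset samples
11–28 mm, predominantly SI), and 4 markers ~17–21 mm from the tumor
center (cohort implants 2–5).

Rasterization includes a voxel iff its center is inside the analytic
shape — reproducible counts, no partial volume.  The default grid is
192 × 192 × 96 voxels at 1.25 × 1.25 × 2.0 mm (clinical in-plane pitch and
2 mm slices).  At this resolution the rasterized tumor volume is within
0.4% of the analytic ellipsoid volume and the phase-to-phase voxel count
varies by 1.7%; a 2 mm isotropic grid was rejected because voxel-center
rasterization of the median tumor then carries a +2.6% volume bias and a
3.5% phase spread, outside the 2% bands the phantom is expected to
satisfy.  Tumor and marker centers are known analytically at every phase,
so the phantom provides exact ground-truth tracks.

What the phantom does *not* emulate: rib/diaphragm anatomy, 4DCT sorting
artifacts, megavoltage scatter on treatment-time projections,
field-of-view collimation, and day-to-day anatomical change.  Passing
phantom tests therefore demonstrates the correctness of the geometry,
rendering, matching, triangulation and accounting chain — not clinical
tracking accuracy, which depends on exactly the effects listed above.

## Training-set factory

One labeled sample per (respiratory phase × grid entry): the original and
the GTV-only volume (everything outside the GTV set to −1000 HU, so the
projection shows the tumor's footprint alone) are rendered under the same
perturbed geometry.  The default grid spans ±3.5° in 0.5° steps in both
tilt directions — 15 values per direction, 225 entries built from integer
multiples of the step — giving 2250 samples from a 10-phase 4DCT per tube
angle.  If a footprint splits into several connected components the
largest is kept (a single GTV is assumed); the label polygon is the
counterclockwise 0.5-level outer boundary of the mask at pixel
resolution.  Samples whose GTV leaves the field of view are skipped with a
warning.  Exports are COCO-style instance-segmentation JSON plus PNGs and
round-trip losslessly.

## Contour predictor

The reference backend is deterministic template matching.  Fitting crops
each training image to the label's bounding box dilated by 4 px and stores
patch, mask and polygon (optionally keeping every k-th sample).
Prediction maximizes the zero-normalized cross-correlation of each
template over the query (optionally restricted to a window around the
template's training position), translates the template's mask/polygon to
the argmax and scores it (ZNCC + 1)/2.  The backend is exactly
translation-equivariant on noiseless shifted inputs and reproduces every
training sample with IoU 1 at confidence 1.

The confidence threshold defaults to 0.8 (ZNCC 0.6).  The maximum of the
ZNCC null distribution over a search area is positive with near-certainty
(≈0.15–0.25 for typical template sizes), so a threshold at the score
midpoint 0.5 cannot reject structureless images; 0.6 correlation sits far
above the null maximum and far below the ≈1.0 of true matches.  One
instance per image is assumed; ties break to the first template in stable
order.  A neural instance-segmentation backend (ResNet + feature-pyramid
features, classification/box/contour losses) fits behind the same
`fit`/`predict` contract but requires the optional `torch` dependency and
is not used by any shipped computation.

## 3D positioning

The markerless position is the midpoint of the shortest segment between
the two rays through the per-panel contour centroids (arithmetic mean of
mask pixel centers, sub-pixel).  The closest points solve the 2 × 2 linear
system from perpendicularity of the connecting segment to both ray
directions; rays with |d₁ × d₂| ≤ 10⁻⁹ raise a triangulation error.  Using
the silhouette centroid as a stand-in for the projected 3D centroid is
inherent to the method; the two coincide for the phantom's symmetric
tumor.  For noiseless sub-pixel centroids of a projected point the
construction is exact (< 10⁻⁶ mm); with whole-pixel quantization the 3D
error stays below √2 · 0.211 mm for targets within 30 mm of the isocenter
(property-tested over 1000 random targets; targets farther off-axis pick
up the source-side magnification factor SID/(SID − r)).

The marker-based chain mirrors the clinical system: per panel, the 2D
centroid of the marker polyhedron is the mean of the marker centroids; the
two centroids are triangulated and the reference-phase marker-COM→GTV
offset is added.  In simulation, marker "detection" is the forward
projection of the analytic marker positions, optionally rounded to whole
panel pixels; image-based blob detection is out of scope.  CW/CCW frames
pair by equal timestamps.

## Evaluation statistics

3D deviations are Euclidean norms at the inner join of two tracks'
timestamps.  Quartiles interpolate linearly between order statistics (the
convention is stated because nearest-rank quartiles differ at these sample
sizes); the cumulative value at threshold t is 100·|{d ≤ t}|/n with ≤
convention, reported at 1/2/3/5 mm by default.  A frame counts as
*predicted* only when both tubes produced a contour (a 3D position
exists), as *detected* when the marker chain produced a position, and as
*compared* when both did — so n_compared ≤ min(n_detected, n_predicted) ≤
n_total, which the report enforces.  Pearson correlations of per-patient
median deviation and prediction rate against GTV volume and motion range,
and of per-fraction statistics against fraction index, are computed on all
groups and, optionally, with one designated patient excluded; fewer than
three groups or degenerate variance yields NaN rather than an error.

## Reproducibility and problem sizes

A single seed is fanned out to per-stage streams by stable SHA-256 hashing
of the stage name; identical config + seed reproduces byte-identical
report JSON.  The shipped examples and the acceptance script run the full
loop at downsample 8 (128 × 96 px projections) with a reduced ±0.5°
training grid (9 entries, 90 templates per tube angle) — sizes chosen so
a complete run takes well under a minute on one CPU while leaving every
stage's contract intact; the 225-entry/2250-sample combinatorics are
exercised separately on a coarse phantom at downsample 32.  Full-resolution
1024 × 768 rendering and the full grid are supported by the same code
paths.

## Known limitations

- The template backend assumes the test-time anatomy matches the planning
  4DCT; it has no mechanism for shape change between fractions, which
  clinically drives accuracy loss with fraction index.
- Silhouette-centroid positioning is biased for strongly asymmetric GTVs.
- The DRR energy model is single-coefficient linear in HU; absolute gray
  levels are not calibrated against any specific DRR tool, and all
  quantitative guarantees are geometric/path-based.
- Only axis-aligned volumes are supported (no gantry-tilted CT, no
  deformable registration between phases).
- No latency modelling or future-position prediction: positions are
  computed per frame pair.
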