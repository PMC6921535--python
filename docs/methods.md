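# Methods

`woundmap` measures the area of a skin wound from a set of overlapping
photographs. The pipeline is 2D → 3D → 2D: multi-view reconstruction of the
wound region, conformal flattening of the reconstructed surface, and
planimetry on the flattened image under a physical scale calibration from
two adhesive tape marks of known length. This note describes the model and
the numerical choices; everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Measurement model

**Feature stage.** Keypoints are extrema of the difference-of-Gaussians
(DoG) stack of a Gaussian scale-space pyramid. The pyramid treats the input
as an unsmoothed signal and assigns level *(o, s)* the absolute scale
σ₀·k^s·2^o with σ₀ = 1.6 and k = 2^(1/3) (three interior scales per octave,
octaves until the smaller image dimension drops below 16 px; kernels
truncated at 4σ, which discards < 10⁻⁴ of the mass). We do not upsample the
input by 2× as some detectors do; the finest octave therefore starts at the
native resolution, which is sufficient for the speckle-textured surfaces
this package targets. Extrema are refined to sub-pixel by a quadratic fit
(contrast threshold 0.03 on the interpolated |DoG|, principal-curvature
edge-ratio limit 10, both configurable); tied extrema in adjacent cells that
refine to the same sub-pixel point are deduplicated, keeping the strongest.
Orientation comes from a 36-bin gradient histogram over a circular window of
radius 3·1.5σ (every peak ≥ 80 % of the maximum emits an oriented copy);
descriptors are the standard 4×4×8 gradient-histogram grid, L2-normalised,
clamped at 0.2 and renormalised. Gradients use central pixel differences,
with the direction taken as atan2 of the two differences — mapped to
[0, 2π) — so the quadrant is always resolved. Matching is
nearest-neighbour with a 0.8 ratio test and a mutual-best check; duplicated
targets keep the smallest distance.

**Epipolar verification.** Putative matches are filtered by
fundamental-matrix RANSAC (normalised 8-point minimal samples, Sampson
distance, default threshold 1.5 px, up to 2000 iterations with adaptive
early termination at 0.999 confidence, mandatory seed). Two wrinkles matter
for skin patches, which are shallow and nearly planar: (i) the all-inlier
least-squares re-estimate can leave the realisable family of fundamental
matrices, so it is kept only when it does not lose consensus, falling back
to the best minimal-sample model; (ii) the rank-deficiency guard applies to
minimal samples only. F is rank-2-enforced and Frobenius-normalised with a
deterministic sign convention.

**Structure from motion.** Tracks are connected components of the match
graph (components observing the same image twice are discarded). The seed
pair is decomposed from the essential matrix E = K′ᵀFK with cheirality
selection; because the closed-form epipole is very sensitive to noise at the
short baselines of adjacent ring views, the relative pose is then refined by
minimising the Sampson error of E over all inliers (5 degrees of freedom:
rotation vector plus spherical translation direction). Remaining views
register by RANSAC resection; coplanar 2D–3D sets (the common case here)
automatically switch from the 12-parameter DLT to a plane-to-image
homography decomposition. Bundle adjustment is a sparse trust-region
least-squares over all poses and points (first camera pinned, scale
re-pinned to the seed baseline after each run; optional shared-focal
refinement). Points are culled at 4 px mean reprojection error or < 0.5°
triangulation angle. Intrinsics default to focal = 1.2·max(width, height)
with the principal point at the image centre when no calibration metadata is
available; radial distortion is not modelled. All stochastic stages draw
per-stage seeds derived as CRC32("seed:stage").

**Meshing.** The reconstruction is metric only up to a global similarity;
no metric claim is derived from it. The sparse cloud of a photographed
wound patch is height-field-like over its PCA-dominant plane, so the mesher
bins points on a square grid over the in-plane bounding box (resolution
64, or density-adaptive at ~3 points/cell in the pipeline), takes the
median height per occupied cell, and triangulates occupied cells with
consistent orientation (normals toward the mean camera centre). Interior
holes — which are the rule, not the exception: the wound itself and the
tapes are featureless and contribute no points — are filled by a global
quadratic height fit plus linear interpolation of its residuals; the
quadratic term reproduces the patch curvature across the wound to second
order (for a 3 cm hole on a 4 cm-radius cylinder the quartic remainder is
≈ 10⁻² mm). A light Gaussian smoothing of the height grid (1 cell)
suppresses sparse-cloud noise that would otherwise wrinkle and inflate the
surface; it is exact on quadratic surfaces, so it does not flatten the
patch curvature. The pipeline additionally trims the outermost ring of
cells, whose heights are poorly constrained, before texturing. A true
screened-Poisson reconstruction is deliberately not re-implemented: it is
an off-the-shelf stage in the original workflow, and `load_mesh` provides
an injection point for externally produced meshes with identical downstream
behaviour. This substitution is the package's largest deviation from the
original workflow and is validated by the area-convergence and
developable-surface tests.

**Conformal unwrap.** Per triangle, the map from an isometric local 2D
frame to (u, v) is affine; its Cauchy–Riemann residual, squared and weighted
by triangle area, summed over triangles, is the conformal energy. The
minimiser subject to ≥ 2 pinned vertices is assembled as a sparse real
linear least-squares system (rows weighted by √area) and solved through the
normal equations — deterministic to solver precision, and verified against a
dense finite-difference quadratic oracle on small meshes. Default pins: the
two boundary vertices at (approximately, two farthest-point sweeps) maximal
geodesic distance, pinned at (0,0) and (d,0) with d their geodesic distance,
which keeps the chart near physical scale; exact scale always comes from the
tape calibration. Triangle flips are detected by signed uv areas and are
fatal only in strict mode. The chart is rasterised by an affine uv→pixel
map (longer side 1024 px by default) with per-triangle barycentric
interpolation; the photographs are projected onto the chart by evaluating,
for every covered pixel, the interpolated 3D surface position in the most
fronto-parallel registered camera that sees it (bilinear sampling).

**Scale conversion.** Two tape marks of known lengths l_x, l_y laid out in
the X and Y directions next to the wound appear on the unwrapped image with
pixel lengths L_x, L_y (Euclidean endpoint distances, measured on the
unwrapped image — the only plane where the conversion is geometrically
coherent). A traced closed polygon of shoelace pixel area S_img converts
as

    S_wound = (l_x / L_x) · (l_y / L_y) · S_img .

The two-axis product corrects axis-dependent chart scaling exactly as
stated, not as an averaged isotropic scale. Areas are reported half-up to
0.01 cm² (1 mm²), with the unrounded value retained. Self-intersecting
polygons are rejected naming the crossing edge pair (the O(n²) check is
skipped above 2000 vertices, where dense traced contours are simple by
construction). The interactive tracing GUI of the original workflow is
replaced by file-based ROI input; for synthetic scenes the operator is
emulated by intensity segmentation (below).

## Synthetic scenes: what they emulate, and what not

The generator builds ground-truthed scenes on three parametric surfaces —
plane, cylinder patch (arm/wrist-like, radius ≥ 3.5 cm, arc ≤ 120°), and
spherical cap (radius = max(8, 2.2 × chart half-extent) cm, cap angle
≤ 60°) — charted in centimetre coordinates that are arc-length for the
developable surfaces. A seeded star polygon (or rectangle) is scaled so its
exact metric area (analytic for plane/cylinder, 512² midpoint quadrature
with the exact area element for the sphere, refinement-convergent to
< 0.05 %) hits the designed value within 0.1 %; this quadrature area plays
the role of the film-coverage "real value". Two 5 cm × 0.6 cm tapes are laid
out as a non-touching L below/left of the wound with a 0.7 cm clearance
(within the 0.5–1 cm of the clinical protocol); their true centreline
lengths are computed by polyline integration. Twenty cameras (focal 1200 px
at 1280×960, principal point centred — plausible phone optics) sit on a full
ring tilted 35° from the surface normal at 3× the chart half-extent,
18° apart (≤ 30° as the capture protocol requires). Rendering is an
analytic per-pixel ray cast (closed-form intersections, back-face culling)
of a three-scale contrast-normalised speckle texture — a skin-texture
stand-in tuned so adjacent views yield hundreds of verified matches — with
the wound darkened and the tapes saturated.

The operator is emulated by segmentation on the unwrapped chart: tape ends
are the extreme principal-axis projections of the sub-pixel contour of the
two largest bright components; the wound outline is the sub-pixel contour
of the most compact dark component (area × circularity² score, which
rejects elongated rim artefacts). Both contours are extracted at the
mid-level between the local foreground and background medians, where a
blurred step edge crosses at the true edge position — this removes the
threshold-choice bias of a fixed level.

Not emulated: photometric effects (lighting, specularity, shadows), lens
distortion, motion blur, depth of field, occluding anatomy, and — most
importantly — real wound appearance: segmentation of clinical images is
interactive precisely because wound margins are ambiguous. Passing the
synthetic benchmark therefore demonstrates the geometric accuracy of the
reconstruction–unwrap–calibration chain under controlled texture, not
clinical segmentation accuracy.

## Problem sizes and accuracy

The closed-loop benchmark (10 scenes, alternating cylinder/sphere, designed
areas 0.5–8 cm²) renders at 960 px across — a deliberate reduction from the
13 MP phone images of the original study, chosen so a full scene
reconstructs in under a minute; at this scale a scene yields ≈ 700 keypoints
per view, 300–600 verified matches per adjacent pair, and a 2000–2500-point
cloud with ≈ 0.2 px mean reprojection error, and similarity-aligned camera
centres within 1 % of the ring baseline.

Measured end-to-end accuracy is surface-dependent. Cylinder scenes
(developable, so conformal flattening preserves areas) recover designed
areas within about ±3 %. Spherical caps carry an additional systematic
−4…−6 %: a conformal flattening of a cap must stretch with geodesic radius
(the per-triangle chart scale matches λ²(ρ) = sec⁴(ρ/2R) to four decimals),
and the tapes — whose 5 cm extent reaches geodesic radii of 2–4.5 cm —
therefore sample a scale ≈ 2.5 % per axis larger than the wound centre's,
deflating the converted area by Eq-12's squared ratio. This is a property
of the two-tape protocol on non-developable surfaces, not of the
implementation (a geometry-only run with the exact surface mesh reproduces
it); it shrinks quadratically with the surface radius, consistent with the
low clinical error reported on real anatomy. We state it as a known
limitation rather than recalibrating the generator's curvature to mask it.

## Known limitations

- Purely planar scenes cannot be initialised from a fundamental matrix
  (projective degeneracy); the pipeline targets the curved surfaces that
  motivate 3D measurement in the first place. Registration of additional
  views handles coplanarity, but the seed pair needs parallax and relief.
- Radial distortion is not modelled anywhere.
- The spherical-cap calibration bias above; tape marks should be kept as
  close to the wound as practical on strongly curved regions.
- The detector has no 2× upsampled octave, so structures smaller than
  ~3 px go undetected.
- Table 2's "standardized regression coefficient" from the source study is
  inconsistent with per-method simple regressions (where it would equal
  Pearson r); it is computed both ways internally but excluded from the
  reported statistics.
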