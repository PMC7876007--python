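# Methods

This note documents the models and procedures implemented in `cochleafit`,
the design choices made where the methodology is genuinely open, and what the
synthetic validation does and does not demonstrate.

## The measurement model

All three clinical quantities are defined on the outer (lateral) wall contour
of the cochlear duct, a 3-D curve from the round window to the apex.

**Angular coordinate.** Position along the contour is expressed as the
cumulative turning angle of the 3-D tangent — the running sum of angles
between consecutive tangent segments, starting at the round window.  This
avoids estimating the modiolar axis, which is both difficult and, for
vertical-trajectory questions, misleading.  Note that turning angle of a
polyline is a discrete total-curvature estimate: it converges from below as
the sampling densifies, and on the 101-point contour the 270° window endpoint
is quantized to one sample (~0.4 mm of arc).

**Basal plane and non-planarity.** The basal plane is the total-least-squares
plane (smallest principal direction of the centered points) through the first
270° of turning; its normal is oriented so the apex has positive height.
Non-planarity is the mean absolute point-to-plane distance over that window.
Because the plane is refit per contour, rigid motion and reflection leave the
value unchanged, and uniform scaling scales it linearly.  Non-planarity is
deliberately a blunt summary: it penalizes any vertical structure the tilted
plane cannot absorb, whether a single hurdle or distributed ripple.

**Reach and duct length.** Reach is the maximum Euclidean distance from the
round window to any point of the 270° window; duct length is the polyline arc
length of the full 101-point contour.  At 101 points the chordal
underestimate of a smooth cochlear arc is below 0.1%, far below measurement
noise.  Duct length is the most sensitive of the three quantities: it
integrates radial wall position along ~2.5 turns, so a 0.05 mm mean radial
bias changes it by ~0.8 mm.

**Tracing.** On template-derived surfaces the contour is traced per duct
cross-section ring (an annotation carried through any vertex-preserving
deformation): the laterally extremal ring vertex — where the surface normal
is perpendicular to the coiling axis — refined by quadratic interpolation
around the ring.  A slower generic tracer (half-plane sections swept around
the coiling axis) exists for meshes without ring annotations; it terminates
within its apex capture radius and is correspondingly coarser.

## Fitting

**Landmark initialization.** Closed-form (SVD/Umeyama) similarity between the
template's three landmarks and the operator's.  Two mirror-image triangles
are always directly congruent in 3-D, so three landmarks cannot decide
chirality; the pipeline therefore tries both chiralities and keeps the one
with the lower short-run ICP residual, the automatic analogue of an
operator's optional template reflection.

**Similarity ICP.** Template vertices pair to nearest cloud points; the
closed-form similarity update minimizes the summed squared pair distances.
The iteration history records the RMS pair distance (the quantity the update
provably does not increase).  Pairs beyond 3× the median pair distance can be
trimmed (default on); the early-stop tolerance is 1e-6 mm on top of the fixed
50-iteration budget.

**Locally affine deformation (LAD).**  Per iteration: (1) vertex→cloud
pairing with trimming; (2) for every vertex, a least-squares rigid transform
(batched Kabsch) over the surviving pairs of its Euclidean d-neighbourhood,
recomputed in the deformed configuration; (3) each vertex moves under the
proximity-weighted average of its neighbourhood's transforms.  Three details
are not fixed by the method's published description and were decided here:

- *Weight kernel*: truncated Gaussian, `w = exp(-r² / (d/2)²)` within the
  d-ball, renormalized.
- *Transform averaging*: rotations are averaged as sign-aligned quaternion
  means about the neighbourhood centroids and the centroid displacements as
  weighted means, so the blended map at each vertex is itself rigid.
  Averaging rotation matrices entrywise (or averaging vertex images directly)
  is a contraction of order θ²/2 per iteration that compounds over 50
  iterations into a visible tangential shrinkage of the spiral; averaging raw
  (R, t) pairs additionally couples the rotation spread to the world origin.
- *Convergence*: the update has no elastic memory of the template, so
  iterating past convergence lets the surface random-walk through a sparse
  cloud.  The fit monitors a symmetric chamfer objective (vertex→cloud plus
  cloud→vertex mean distance), keeps the best iterate and stops after eight
  iterations without improvement, within the fixed iteration budget.  On
  clean dense data the objective decreases monotonically and the budget is
  exhausted; on low-contrast pseudo-clinical data this rule is what makes
  "more iterations" safe.

Vertices whose neighbourhoods keep fewer than three pairs fall back to the
global rigid fit of all surviving pairs.

**Statistical shape model.**  Corresponded vertex sets are centered, scaled
to unit centroid size and rotated (proper rotations only) onto a reference;
PCA is computed from the thin SVD of the centered (n × 3V) data, giving at
most n−1 modes.  The fitted model's absolute scale lives entirely in the
similarity transform; the constrained ICP fit re-estimates that similarity
every iteration (a `freeze_similarity` flag reproduces the stricter reading
in which it is fixed after the rigid stage).  All modes are used and the
coefficients are unbounded — the method is parameter-free.  With no starting
transform the fit initializes by centroid/size matching; an identity start
from the unit-size model frame would let the free-scale update collapse the
surface onto a single cloud point.

## The phantom

Real temporal-bone micro-CT cannot be redistributed, so specimens are
synthetic, with these components (all sampled on fixed parameter grids, so
every specimen shares one vertex topology — native correspondence for SSM
training):

- **Outer wall**: logarithmic spiral `r(θ) = a·exp(−bθ)` over ~2.5 turns,
  with a cubic vertical profile `z(θ)` parameterized by the basal slope, the
  slope change across the basal window and the apex height — this pins the
  vertical curvature the basal-plane fit cannot absorb (hence non-planarity)
  while keeping the apical trajectory physiological, and supports both
  monotone and down-then-up "rollercoaster" profiles.
- **Duct**: a tapering tube (basal radius ~0.8 mm, apical ~0.27 mm at
  reference size) whose lateral extremum coincides exactly with the analytic
  outer-wall curve.  Adjacent turns are separated by hairline interscalar
  gaps that clinical-resolution imaging partly blurs away, as in real bone.
- **Canal appendage**: a torus-arc tube whose tip provides the
  canal-bifurcation landmark.  Anatomical fidelity is not a goal; it supplies
  the third landmark and off-cochlea structure for the fit.
- **Bone-shell envelope**: the outer boundary of the capsule bone, built as
  the star-shaped boundary of the union of spheres swept along the duct and
  canal (offset 2 mm), sampled on a fixed spherical grid with a solid
  modiolar core.  The capsule surface being fitted is the union of lumen
  walls and this envelope — the same double-sided boundary a thresholded
  segmentation of the bone would produce; without the envelope a similarity
  ICP on bare tubes cannot lock scale.
- **Scaling**: every geometric element (duct radii, canal, shell thickness,
  vertical profile) is proportional to `spiral_scale`, so the whole labyrinth
  co-varies with cochlear size — as in anatomy — and all three ground-truth
  measurements are exactly linear in it.

Ground truth is computed on a 20 001-sample polyline of the analytic
outer-wall curve using the same measurement definitions as the morphometry
module; tests check it against independent adaptive-quadrature and
brute-force oracles.

**Cohort distributions** (a documented choice: published gold-standard
cohorts are characterized by little more than a ~5 mm outer-wall duct-length
spread, so the shape of the distribution is ours):
uniform draws with `spiral_scale` 4.25–4.75 mm, decay 0.077–0.087 /rad,
total coiling 2.45–2.55 turns, basal slope −0.55–0.30 mm/rad, window slope
change −0.35–0.55 mm/rad, apex height 1.8–3.2 mm, and mixed left/right
sides.  This yields gold-standard duct lengths of roughly 37–44 mm (range
5–7 mm), reach ~7.6–8.6 mm and non-planarity ~0.01–0.2 mm.

**Voxelization.** Volumes are composed from two signed-distance fields
(exact point-to-triangle distances in a two-voxel band; flood-fill
classification elsewhere): lumen 90, capsule bone 230, surrounding soft
tissue 110, each interface carrying a one-voxel partial-volume ramp whose
level is calibrated so the iso-surface at grayscale 170 — the operator's
central threshold — coincides with the geometric surface.  With tissue at
110 the threshold is also the midpoint of the outer interface, which keeps
the level set unbiased under the degradation blur; this mirrors the fact
that in the real workflow template and data derive from the same
thresholding convention.  The thresholds 160 and 180 bracket the boundary on
either side.

## Pseudo-clinical CT synthesis

Per axial slice: anti-aliased downsampling to the target pitch (exact block
averaging at integer ratios), parallel-beam projection over 1.5× the Nyquist
angle count, i.i.d. zero-mean Gaussian noise scaled to a fraction of the
volume-wide sinogram dynamic range, and ramp-filtered backprojection.  The
three presets (cbct 0.15 mm, mdct 0.30 mm, poor_mdct 0.45 mm) use noise
fractions in the amplitude ratios 1 : 10^(10/20) : 10^(15/20), following the
relative decibel ordering of the three conditions, with the base fraction
(0.4% of sinogram range) calibrated once to give a plausibly noisy standard
MDCT appearance and then frozen.  Cone-beam geometry, beam hardening and
Hounsfield calibration are out of scope; what matters for segmentation
realism is the correlated FBP noise character.

## Problem sizes and defaults

Template meshes use 144 duct rings × 8 vertices, a 36-ring canal and a
36 × 17 envelope grid (~2 100 vertices; the shape is captured well below the
mesh's chord tolerance and registration cost grows quadratically with
density).  Micro-CT surrogates are rasterized at 0.15 mm for cohort
experiments (0.05 mm remains available).  Cohort experiments default to 18
specimens, threshold 170, the mdct preset, d = 5 mm and 50 iterations; the
experiment table also carries the template-measured-directly baseline and
the similarity-aligned ("unfitted") variant.

## What the validation shows — and does not

Passing the synthetic suite shows that the chain *segmentation → similarity
→ LAD/SSM → tracing → measurement* recovers analytic ground truth at
clinical degradation levels, that the expected orderings hold (full SSM
beats leave-one-out; errors grow with degradation), and that each building
block matches independent oracles.  It does not demonstrate performance on
real anatomy: the phantom has smooth low-order shape variation, no beam
hardening, perfectly known landmarks, an idealized two-tissue capsule, and
intensity statistics only loosely resembling Hounsfield units.  Non-planarity
recovery in particular is limited by the d = 5 mm regularization, which
suppresses vertical corrections that differ between adjacent turns; smaller
d recovers more vertical detail at the cost of overfitting noise — the same
sensitivity the sweep utilities expose.
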