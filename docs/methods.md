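# Methods

`seedlingpheno` estimates five phenotypes of potted conifer seedlings
(15–30 cm, *Pinus massoniana*-like morphology) from ToF depth-camera point
clouds: plant height, stem (ground) diameter, main stem length, regional
leaf length, and total leaf number. This note describes the model behind
each stage, the tunable parameters, the synthetic data the package tests
itself on, and the known limitations.

## Coordinate convention and inputs

Clouds live in a camera-aligned frame: x horizontal, y depth (positive away
from the camera), z up. Inputs are PLY/PCD clouds with per-point grayscale
(RGB is collapsed with BT.601 luminance weights), or raw depth images plus
pinhole intrinsics, back-projected as X = d(x−cx)/fx, Y = d,
Z = −d(y−cy)/fy (image rows grow downward, hence the sign flip).

## Preprocessing

1. **Background removal.** A pass-through filter along the depth axis. The
   far bound PTlb is the cloud's maximum depth (the backdrop curtain); the
   near-of-curtain bound PTub = (dcc − dcp)/dcc · PTlb, where dcc and dcp
   are the camera–curtain and camera–plant distances. The pipeline keeps
   everything nearer than PTub, which removes the curtain and keeps the
   plant, pot and platform.
2. **Platform removal.** Seeded RANSAC plane fit (1000 iterations, 5 mm
   inlier threshold, least-squares refit on inliers); inliers are deleted.
   The platform must be the dominant plane, which holds for real scans and
   for the generator's 4 mm platform sampling.
3. **Outlier removal.** Radius filter with r = 10 mm, k = 10: a point
   survives iff at least k other points of the *original* cloud lie within
   r (single pass, no cascading).
4. **Soil/pot removal.** The soil surface sits one pot height (0.12 m)
   above the detected platform; only points strictly above it remain.
5. **Registration** (two-view acquisitions). Per-point normals from PCA of
   the 10 nearest neighbours; feature points where the mean normal angle to
   neighbours exceeds 15°; FPFH descriptors (radius 2.5 cm, 11 bins per
   angle triplet); SAC-IA coarse alignment (500 samples of well-separated
   feature triples, truncated-distance scoring); point-to-point ICP on
   mutual nearest neighbours capped at 2 cm, converged when the RMS changes
   by < 1e−7 m. Non-convergence and low overlap set a warning flag rather
   than raising.

## Stem–leaf segmentation

**Skeletonization.** The plant cloud is cut into 30 uniform height slices.
Each slice is split into Euclidean clusters (linkage tolerance 1 cm,
minimum size 30 points). A cluster wider than `x_thresh` = 2 cm along x
holds stem *and* needles; it is divided into 5 uniform x-bins and the bin
with the highest mean grayscale is taken as the stem (bark reflects
brighter than needles in the IR/active illumination of a ToF camera); the
bin's centroid becomes the candidate skeleton point. Narrow clusters
contribute their plain centroid. The minimum cluster size of 30 reflects
the ~1 mm point pitch of the sensor at working distance: a stem slice
always holds ≳40 points, while isolated needle fragments (a chain cut by
the slicing) usually hold fewer; smaller thresholds let those fragments
become candidates, and the longest-path rule below is attracted to the long
hops between them.

**Main-stem extraction.** Candidates are joined by a Kruskal minimum
spanning tree on the complete Euclidean graph, rooted at the lowest point
and oriented away from it. The heaviest root-to-leaf path (one post-order
pass over the rooted tree; ties to the smaller leaf index) is the main stem
plus the apical canopy.

**Canopy removal.** The 5th path point from the tip anchors a plane
perpendicular to the local path direction (the direction is averaged over
two steps so one noisy point cannot tilt the plane). All cloud points above
the plane are projected onto it; the mean distance of the projection's
convex-hull vertices to the anchor estimates the canopy extent. Walking
down from the tip and accumulating step lengths, the first point whose
cumulative distance exceeds that estimate is the canopy/stem boundary;
everything strictly above it is discarded.

**Stem restoration.** A preliminary ground diameter is measured from
points inside a 1.5 cm capture cylinder around the lowest 6 cm of the path
(the near-soil stem carries no needles). The path is densified by linear
interpolation at that step length — between points at distance D,
⌊D/step⌋ equally spaced points are inserted — and every cloud point within
one diameter of the densified skeleton is stem; the complement is leaves.

## Traits

- **Plant height** H = z_max − z_soil over the preprocessed cloud.
- **Stem diameter.** Skeleton arc 2–4 cm above the lowest skeleton point,
  bounded by planes perpendicular to the local (windowed) skeleton tangent;
  between-plane points are projected on the lower plane, sliced per 1 cm,
  and each slice is fitted with a direct least-squares ellipse
  (ellipse-specific conic constraint); the diameter is the mean minor-axis
  length. The estimator runs on the restored *stem* cloud: the tangent
  planes extend indefinitely, and needle points slipping between them would
  corrupt the conic fit. A `projection="xoy"` variant (slice along z,
  project on the horizontal plane) exists for comparison; on leaning stems
  it smears the section and loses accuracy, which is the motivation for the
  tangent-plane method.
- **Main stem length.** Sum of consecutive skeleton-point distances from
  root to canopy base.
- **Regional leaf length.** 5 cm arc windows from the canopy base
  downward (a trailing window under 1 cm merges into its neighbour), each
  bounded by tangent planes. Between-plane points are projected on the
  lower plane; the mean distance of convex-hull vertices to the centre is
  the regional leaf length, reported only when it exceeds the stem diameter
  (otherwise "no leaves").
- **Leaf number.** Per region, the distance density d̄ (mean
  nearest-neighbour distance) of the region's leaf-side points feeds a
  linear model count = a·d̄ + b fitted by ordinary least squares on
  calibration plants with known counts; counts are rounded, floored at
  zero, and summed. Denser needle packing lowers d̄, so a < 0. The density
  is computed on the leaf cloud (stem points would dilute the signal with a
  count-independent term).
- **Accuracy metrics.** Pearson R, RMSE, MAE, and accuracy
  100·(1 − MAE/mean(actual)).

## Synthetic seedlings

The generator is first-class, tested code and defines the conditions under
which the package validates itself:

- **Stem**: a smooth centreline (lateral bump ≤ `stem_curvature`, default
  1.5 cm, zero slope at both ends; optionally a straight 10–30° lean over
  the lowest 6 cm), swept by a 2–6 mm tube of surface points; grayscale
  ~N(200, 8).
- **Needles**: chains radiating 70–110° from the stem, placed in 5 cm
  regions with golden-angle phyllotactic azimuths (the real arrangement in
  conifers; it also means azimuths within any height slice are well
  balanced), lengths drawn per region around 2.5–5.5 cm means; grayscale
  ~N(110, 12). The lowest 5 cm of stem is bare, as in the real plants.
  Needle sampling is foreshortened along ±y: the views look down the y
  axis, so a needle pointing near the view axis covers few pixels and is
  sampled sparsely. Point pitch is 1 mm (the depth camera's pixel footprint
  at ~0.45 m).
- **Canopy**: a dense whorl of short needles attached along the top 60% ×
  canopy-radius of the stem and a short bark-bright terminal shoot
  (0.5 × canopy radius), capped by a dense terminal bud — the morphology of
  a real seedling apex, and what gives the grayscale rule a bright on-axis
  target inside the whorl.
- **Scene**: platform plane at z = 0 (4 mm grid), pot cylinder (0–0.12 m),
  soil disc, sparse curtain at depth dcc, uniform speckle outliers;
  everything carries N(0, 1 mm) per-coordinate Gaussian noise, the range
  noise scale of the emulated ToF camera.
- **Ground truth**: the dense stem centreline, realized height, diameter,
  centreline arc length (= main stem length; the spline ends at the canopy
  centre, so the pipeline's canopy cut and the truth refer to the same
  quantity), per-region needle counts and realized mean lengths, and
  per-point labels. Same spec + seed reproduces the cloud bit for bit.

**What the generator does not emulate**: multi-path and flying-pixel ToF
artefacts, intensity variation with incidence angle, self-occlusion beyond
the two-view culling model, wind motion, lateral stems, overlapping
plants. Passing tests therefore demonstrate correctness of the algorithms
under realistic geometry and noise, not performance on any particular real
scanner's artefacts.

## Numerical choices

- Skeleton tangents are windowed over ±7.5 mm of arc; plane normals from
  single noisy steps tilt the diameter/region planes enough to let distant
  points between them.
- Ellipse fits require ≥ 5 points per 1 cm slice; slices that fail are
  skipped and the diameter averages the remaining slices.
- The canopy stopping rule uses a strict inequality and discards the
  points strictly above the first point whose from-tip distance exceeds the
  threshold, so a zero threshold discards exactly the tip.
- Interpolation counts ⌊D/step⌋ with a 1e−9 relative guard against
  floating-point shortfall.
- RANSAC, SAC-IA and the simulation all draw from seeded generators; a
  single pipeline seed fans out through `numpy.random.SeedSequence`.

## Expected accuracy and limitations

On 20-plant synthetic cohorts (heights 0.15–0.30 m, σ = 1 mm noise) the
pipeline recovers plant height to ≈0.3–0.5% relative MAE, main stem length
to ≈5%, regional leaf length to ≈15% (the convex hull preferentially
selects the longest needles), and total leaf count to ≈13–21% relative MAE
(the density–count relation is weak, so the calibrated slope varies between
calibration cohorts).

Stem diameter carries a physical bias: with per-coordinate noise σ on a
shell of radius r, the apparent radius of the noisy shell is close to
√(r² + σ²); at r = 1–3 mm and σ = 1 mm this inflates the fitted diameter by
5–40%, bounding the accuracy of any surface-based fit near 85% on this
cohort. The tangent-plane projection still clearly beats the horizontal
(XOY) variant on leaning stems. A further geometric note: the minor axis of
an *oblique section* of a cylinder equals the true diameter, so on a
perfectly straight tilted stem the XOY variant errs through slab smear and
fit distortion, not through the 1/cos(tilt) factor one might expect; on
curved stems the smear compounds and the tangent-plane method's advantage
grows.

The longest-path rule is structurally attracted to long hops between
spurious candidates; the minimum cluster size and the canopy cut contain
this, but single-plant failures (a junk node surviving at the trimmed tip)
remain possible, which is also why per-plant stem-length errors have heavy
tails relative to their ≈5% median.
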