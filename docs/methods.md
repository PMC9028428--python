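# Methods

`cororeg` registers a pre-operative 3D coronary centerline tree (typically
extracted from CT angiography) to intra-operative 2D centerlines segmented
from a single X-ray angiogram.  This note describes the models, the
parameters that matter, the synthetic data the package is validated on, and
the design choices made where the procedure was genuinely open.

## Geometry

The C-arm acquisition is modelled as a perspective pinhole: the X-ray source
sits at distance SOD (source-to-object) before the isocenter and the
detector at SID (source-to-detector) from the source, so an object at the
isocenter is magnified by SID/SOD.  Gantry angulation is two rotations of
the camera frame: the primary positioner angle (LAO/RAO) about the patient
y axis, then the secondary angle (CRA/CAU) about the patient x axis.
Detector coordinates are millimetres with the origin at the detector centre,
converted to pixels with the imager pixel spacing.  All five quantities are
standard DICOM attributes (`PositionerPrimaryAngle`,
`PositionerSecondaryAngle`, `ImagerPixelSpacing`,
`DistanceSourceToDetector`, `DistanceSourceToPatient`) and can be read
directly from an XA header or supplied in a YAML block.

Projection is perspective rather than orthographic: both SID and SOD are
part of the acquisition header, and only a perspective model uses both.  The
isocenter is placed at the 3D centerline centroid by default, which keeps
the bounded rigid search meaningful regardless of the patient coordinate
origin.

## Rigid alignment

The pose has six parameters: translation (Tx, Ty, Tz) in mm and Euler
rotations (Rx, Ry, Rz) in degrees composed as Rz·Ry·Rx about the 3D
centerline centroid.  The objective is the asymmetric chamfer mean: the
average Euclidean distance from each projected 3D centerline point to its
nearest 2D centerline point.  The asymmetry is deliberate — 2D data may
contain background clutter (false branches) which must not attract the
model.

Optimisation is Powell's derivative-free direction-set method in two
stages, translation first and then all six parameters, inside a box
|T| ≤ d_max (default 30 mm) and |R| ≤ th_R (default 10°) enforced by a
quadratic penalty so the objective stays smooth.  A single identity start
suffices near the true pose; an optional multistart (uniform random poses
inside half the box, default 8 in the stress protocols) guards against the
local minima that appear at large combined offsets.

Depth is the known failure mode of single-view alignment: translation along
the viewing ray changes the projection only through magnification
(roughly 0.13 %/mm at SID 1000 / SOD 750), so the recovered Tz can be tens
of millimetres off while the projection residual is a fraction of a
millimetre.  The package therefore reports in-plane and along-ray
translation errors separately and bounds only the in-plane component.

## 2D topology reconstruction

2D centerlines from an angiogram carry false bifurcations, gaps and
crossings.  They are decomposed into *smallest-unit segments*: maximal
branch-free polylines between endpoints and junction points (degree ≥ 3).
For each rigidly aligned, projected 3D segment:

1. **Candidates** — every 2D segment whose directed mean nearest-point
   distance to the projected 3D polyline is below `D_cand` (default 3 mm,
   matching the bifurcation evaluation radius).  The 2D→3D direction is
   used so that a short true fragment of a long vessel stays a candidate.
2. **Candi-lines** — every simple connected chain of candidate segments is
   enumerated exhaustively (depth-first search over the candidate subgraph,
   orientation-free deduplication, `max_paths` = 10 000 guard).  Two
   segments are connectable when their endpoints lie within the connection
   tolerance.
3. **Pruning** — the 3D tree is traversed leaf to root; a candi-line of a
   non-root segment survives only if one of its endpoints lies within the
   connection tolerance of a surviving candi-line of its parent segment.
   Passes repeat to a fixed point, so pruning is idempotent.

**Connection tolerance.**  The tolerance is 2.0 mm by default.  It must sit
*above* the width of segmentation gaps (otherwise the fragments of a broken
vessel could never be re-chained and the distal part of every gapped branch
would be pruned) and *below* the candidate threshold (otherwise chains
would jump between adjacent branches).  A skeleton-quantisation-scale
tolerance (~1.5 px ≈ 0.4 mm) was considered and rejected for exactly the
first reason.

## Point matching

Each projected 3D point v_i is assigned the candi-line point u minimising

    cost(i, u) = mean_{k∈[i−n, i+n]} d(u, tangent line at v_k) + ‖v_i − u‖

where the tangent line at v_k passes through v_k with the direction of a
symmetric total-least-squares line fit over ±3 neighbouring points
(direction-vector form, so vertical tangents are exact).  The window
(half-width n = 3 by default) is the point of the method: a decoy that is
marginally closer in Euclidean distance but lies off the local tangent fan
of the curve pays the line term at every window position, while on-branch
candidates do not.  Both term weights are configurable; with the line
weight zero and n = 0 the assignment degenerates to nearest-neighbour
matching exactly.  Matches farther than `Max_dist` (default 5 mm, chosen to
exceed the residual nonrigid displacement) are flagged invalid, H(v) = 0.
Several 3D points may share a 2D match; no injectivity is enforced, since
depth loss genuinely makes 3D points project onto the same 2D
neighbourhood.

## Candi-line selection

Each surviving candi-line is scored against its 3D segment:

    SM = α·Dθ + β·d2 + γ·DTh + δ·DL

* **Dθ** — mean per-matched-pair distance of the 2D point to the tangent
  line at its 3D point, normalised by that pair's Euclidean distance
  (floored at 0.1 mm so near-coincident pairs do not blow up).  Being a
  ratio of distances it is scale-invariant.
* **d2** — mean Euclidean distance over valid matches, mm.
* **DTh** — RMS difference between the projected 3D vessel diameter
  (2 r · SID/(SOD + depth)) and the 2D thickness (twice the distance-
  transform value at the skeleton), mm.  The raw mean-of-squares form is
  available behind a flag; RMS is the default so the term carries the same
  units as the others.  When thickness is unavailable on either side the
  term is skipped and γ effectively zeroed.
* **DL** — relative length difference |s3D − c2D| / s3D of the projected
  segment and the chain; this is what rejects chains that stray into a
  neighbouring branch or stop halfway.

Default weights (α, β, γ, δ) = (0.4, 0.7, 0.25, 0.15) follow the
simulation-tuned operating point.  Ties break on smaller d2, then on the
chain's canonical id.

## Nonrigid deformation

The selected correspondences drive a snake-type energy minimised by
explicit gradient descent over all branch points simultaneously:

    E = Σ_i μ·E_cont(v_i) + τ·E_curv(v_i) + φ·E_image(v_i)

* E_cont(v_i) = (d̄ − ‖v_i − v_{i−1}‖)², with d̄ frozen at the initial mean
  point spacing — the classic continuity term that preserves spacing.  (The
  naive reading d̄·‖Δv‖² would collapse the curve toward zero spacing,
  contradicting the term's purpose; the difference form is used.)
* E_curv(v_i) = ‖v_{i−1} − 2 v_i + v_{i+1}‖², the discrete Laplacian with
  unit parameter spacing (the centerline is resampled uniformly upstream).
* E_image(v_i) = H(v_i) · dist(v_i, ray(u̇_i))², the squared perpendicular
  distance to the back-projected source ray through the matched 2D point.
  Pulling toward the *ray* rather than a lifted 3D point is the unique
  formulation that deforms in 3D while leaving depth unconstrained — the
  honest thing to do with one view.  (A projected-2D-residual variant is
  available via configuration.)

Defaults: (μ, τ, φ) = (0.5, 0.4, 0.6), step 0.05, up to 500 iterations,
relative tolerance 1e-6.  Correspondences are refreshed every 10
iterations and frozen in between so the gradient is well defined; energy
is non-increasing between refreshes for small steps, and five consecutive
increases trigger a step halving (five halvings raise an error).  Branch
endpoints shared between branches receive the summed gradient of all
incident branches, so bifurcations remain coincident by construction.
Gradients of all three terms are analytic and verified against finite
differences in the test suite.

## Segmentation support

The CNN that produces vessel masks is external to this package; what is
provided is (a) its loss surface and (b) the bridge from masks to
centerlines.

* Pixel-wise binary cross-entropy over probability/label map pairs.
* A boundary ("shape") loss: the mean, over all K pixels, of the
  ground-truth chamfer distance sampled at predicted-edge pixels, smoothed
  by ε = 1e-7.  It is zero exactly when predicted and true edges coincide
  and grows linearly with edge displacement.  The distance map uses the
  exact Euclidean distance transform; an integer chamfer propagation would
  be a strictly less accurate stand-in and is not the default.
* `mask_to_centerlines`: morphological skeletonisation; skeleton pixels
  with ≥ 3 neighbours are branch pixels, and mutually adjacent branch
  pixels are clustered into a single junction node (skeletons routinely
  produce 2-3 adjacent branch pixels at one anatomical bifurcation);
  maximal branch-free pixel paths become smallest-unit segments, with
  per-point thickness twice the distance-transform value.

## The simulator

The built-in generator is the package's ground-truth instrument; its
defaults are the study conditions every recovery claim refers to.

* **Tree**: binary-branching, 7 branches (3 generations), branch lengths
  20-35 mm, root radius 1.75 mm tapering by 0.8 per generation, smooth
  low-frequency in-branch curvature, points every 1 mm.  This is a
  left-coronary-scale tree that fits the detector field of view.
* **Acquisition**: 512×512 detector, 0.279 mm pixels (midpoint of the
  clinical 0.258-0.293 mm range), SID 1000 mm, SOD 750 mm, primary angle
  uniform in ±40°, secondary in ±25°, isocenter at the deformed tree
  centroid.
* **Ground-truth deformation**: a rigid offset sampled uniformly within
  0.8× the search bounds, then a smooth displacement field (sum of 3
  low-frequency vector sinusoids, wavelength ~120 mm) normalised so the
  maximum point displacement equals the nominal amplitude (2 mm by
  default).  A smooth bounded field exercises the same machinery as true
  cardiac/respiratory motion while giving exact per-point error oracles.
* **2D data**: the deformed tree is projected, resampled at pixel spacing
  (real skeletons are pixel-dense), then corrupted: per branch, with
  probability 0.3 a gap of ~1.5 mm is cut at a random interior position
  (splitting the segment), and with probability 0.3 a false branch of
  4-10 mm sprouts at a random interior point, splitting the host segment
  there so the false bifurcation is topologically real.  Corruption acts on
  the centerlines, not the raster, so every 2D point keeps an exact label
  (true/false, source 3D segment); the binary mask is rasterised afterwards
  with the projected vessel thickness.
* **Markers**: 10 per case — the bifurcation vertices first, then
  mid-branch points — mirroring marker-based evaluation with 10 pairs per
  patient.

What the simulator does **not** emulate: photorealistic radiographs
(Hounsfield blending, contrast propagation), cardiac-phase motion models,
detector distortion, and vessel overlap from genuinely distinct anatomy
(the optional `crossing` corruption overlays a shifted branch copy
instead).  Passing the recovery suites therefore demonstrates that the
geometric/topological machinery is correct and robust to segment-level
segmentation error — not that a particular CNN segments real angiograms
well.

## Evaluation protocol and observed behaviour

The stages are validated in isolation so that each bound measures one
mechanism:

* **Rigid recovery** — offsets uniform in 0.8× bounds, no field: median
  in-plane translation error < 1 mm and rotation error < 1°, final
  projected distance < 1 mm (20 seeded cases; with 8 multistarts the
  typical recovery is exact to optimiser precision).  Depth error is
  reported, not bounded.
* **Graph robustness** — aligned pose, default corruption: the true chain
  (the maximal connected chain of true same-source segments — a definition
  needed because a wide-enough gap genuinely splits the truth) survives
  candidates + pruning on ≥ 95 % of segments and wins selection on ≥ 90 %.
  Observed: 100 % on 280 segments.
* **Nonrigid recovery** — aligned pose, 2 mm field, default corruption:
  median post-deformation projected residual < 0.5 mm and < 20 % of the
  pre-deformation residual; median 3D marker ADD < 1.5 mm.  The residual 3D
  error is dominated by the depth component of the field, which a single
  view cannot observe.
* Oracle equivalence, energy descent/fixed-point behaviour, loss sanity and
  metric fidelity are checked exactly or to 1e-9 where closed forms exist.

Problem sizes (7-branch trees, 10-40 cases per property) are the package's
validation operating point; all suites run in minutes on one CPU.

## Known limitations

* Single-view registration leaves depth (translation along the ray, and
  the depth component of nonrigid motion) unobservable; 3D errors quoted
  without a second view should be read accordingly.
* Candi-lines are simple chains; genuinely loopy 2D structures (full
  crossings) are represented as crossing segments around a degree-4 node
  but are not reconstructed as cycles.
* Selection is per-segment; no joint optimisation across segments is
  attempted (two adjacent segments can in principle claim the same 2D
  fragment).
* The energy descent is first-order with a fixed step; it is robust at the
  defaults but makes no global-optimality claim.
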