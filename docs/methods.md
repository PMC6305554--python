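# Methods

`perispace` charts the near-range space of a walking stick insect
(*Carausius morosus*): which part of the surrounding space each limb can
act on, where two limbs' ranges overlap so that contact information can be
handed from one limb to another, where along a limb first obstacle contacts
actually occur, and how complex a feed-forward mapping must be to translate
one leg's posture into the posture that puts a neighboring leg's foot on
the same spot.

## Body model and kinematics

The standardized body is a rigid, straight chain of head, pro-, meso- and
metathorax carrying two antennae and six legs.  Each limb stores its
insertion point in the carrying-segment frame, the slanted rotation axis of
the basal thorax-coxa (ThCx) joint given as yaw and pitch of the vertical,
and its segment lengths (coxa, femur, tibia, tarsus; the antennal flagellum
is one straight segment).  Coordinates are x forward, y left, z up; right
limbs mirror in y.

A leg has three degrees of freedom:

* **alpha** — protraction/retraction: rotation of the whole leg plane about
  the fixed slanted ThCx axis.  Because the axis is slanted, this rotation
  also pronates/supinates the leg plane, which is the empirical
  justification for treating the ThCx axis as fixed.
* **beta** — levation/depression of the femur within the leg plane.
* **gamma** — extension/flexion, the interior femur–tibia angle, in
  (0°, 180°].

The coxa is a fixed-length offset along the leg-plane base direction; the
tarsus extends the tibia in a straight line (the tibia-tarsus angle is not
tracked experimentally, so the maximally extended 0° configuration is
assumed, which maximizes the radial working range).  Forward kinematics is
a closed-form chain; inverse kinematics reduces to planar two-link
geometry inside the leg plane once alpha is recovered from the projection
of the target onto the plane normal to the ThCx axis.

Two IK branches exist: the foot can lie on the positive- or
negative-radial side of the ThCx axis (the latter occurs for strongly
flexed postures).  Both branches are solved; the branch whose angle
triplet lies within the leg's physiological bounds is returned, with the
positive-radial branch as fallback.  Within the physiological bounds the
in-bounds branch is unique because every alpha range spans less than
180°.  The knee-up branch (gamma in (0°, 180°]) is always used; the
physiological extension ranges never require the mirror knee branch.
Round-trip identities (fk∘ik and ik∘fk) hold to well below 1e-6 (mm,
degrees) across the sampled ranges.

Per-animal size variation is removed before gridding by the scaling factor
B_ref/B_curr, where B is, per limb pair, the sum of both femora, both
tibiae and the carrying segment (legs) or both antenna lengths plus head
length (antennae).  Because the factor is exactly the inverse of a uniform
body scale, gridded volumes of a uniformly scaled animal are identical to
those of the reference animal.

## Synthetic trials

Real trials are motion-capture recordings at 200 frames/s of walking,
searching and rod-climbing episodes.  The generator emulates these
paradigms parametrically:

* **walk** — all six legs oscillate at the step frequency (default 1 Hz)
  around their range midpoints with amplitude 0.35 of the range half-width,
  left/right legs in anti-phase and neighboring legs offset by a third of a
  cycle; the body translates at 20 mm/s at 10 mm clearance.
* **search** — the body is stationary at the walkway edge; only front legs
  and antennae oscillate, with amplitude 0.8 of the half-width (hence
  strictly larger excursions than walking).
* **rod** — walking toward a horizontal rod (axis across the walkway,
  default radius 1 mm, heights 5–50 mm including the experimental 18 and
  36 mm) while the antennae sweep their full default ranges (azimuth
  5–50°, elevation −10–45°, 1.4 Hz, anti-phase).  The rod is placed just
  beyond the antennal reach at trial start so contact happens mid-trial.
  The generator records the ground-truth first frame and location at which
  any sampled antennal or front-leg point enters the rod radius.

Joint-space noise is white Gaussian, low-pass filtered at 5 Hz (smooth and
physically plausible at 200 fps), then clipped to the configured bounds so
no emitted angle ever leaves its range.  Per-animal size jitter (±10%
uniform by default) scales all segment lengths uniformly, exercising the
B_ref/B_curr standardization.  Joint-angle bounds default to the observed
physiological ranges per leg class; the middle leg uses the union of its
two affordance-conditioned range sets.

What the generator deliberately does **not** reproduce: the experimental
posture distribution (so absolute volume sizes in ccm are not comparable
to the published ones), ground-reaction mechanics, gait transitions, or
marker noise.  Passing tests therefore demonstrate the correctness of the
computational machinery and the qualitative structure of the results, not
the quantitative volumes of real animals.

## Volume densities

Limb occupancy is charted on a 90×90×90 grid of 1 mm spacing centered on
the limb base.  Per frame, a discrete point scheme is computed by forward
kinematics and counted on the grid after standardization and rounding to
the nearest millimeter:

* action volume: 8 femur + 8 tibia + 4 tarsus points (legs; femur and
  tibia points at fractions 0.1…1.0 of the segment, tarsus points at
  0.25…1.0) or 20 flagellum points at fractions 0.1…1.0 (antennae);
* contact volume: 10 points at tibia scalings 0.67 to
  (tibia+tarsus)/tibia (legs; 1.33–1.39 depending on the leg) or
  flagellum fractions 0.67–1.0 (antennae);
* tip volume: the tibia-tarsus joint or flagellum tip only.

Distal points sweep longer arcs per joint excursion; to avoid inflating
proximal densities, point k of n carries weight 2k/(n(n+1)) so each frame
deposits total weight 1.  Densities are smoothed with a normalized 5×5×5
Gaussian kernel (σ = 1 node; truncated without renormalization at the grid
edge, with any lost weight reported as leakage) and thresholded at 1% of
the per-grid maximum, ties retained.  On synthetic runs the threshold
retains well over 95% of the summed density.  Binary volumes report size
in ccm (1 mm³ per node).  Affordance volumes are node-wise intersections
of two limbs' volumes after translating both node sets into the common
body frame (rigid straight body) and re-rounding to the integer lattice;
intersection is symmetric and contained in both parents by construction.

A second, geometric construction is provided for posture-pair datasets:
the *reachability-based* affordance volume, the set of grid nodes whose
position the tibia-tarsus joint of both legs can reach within the
affordance-conditioned joint bounds.  It depends only on the kinematics
and bounds, not on any recorded posture distribution, and can be sampled
at sub-millimeter node spacing to densify the dataset (default 0.5 mm for
mapping studies).  The middle leg uses the range set belonging to the
specific affordance volume (front-set with the front leg, hind-set with
the hind leg), mirroring the observed per-volume ranges.

## Contact analysis

The rod is an infinite horizontal line at height h; contact is defined as
the limb polyline (sampled at ~1 mm arc length) coming within the rod
radius (default 1 mm; the experimental rod diameter is not documented).
The detector reports the earliest such frame and the standardized location
of the closest sampled point, ties broken toward the most distal point.
Leg locations are standardized so the femur spans [0, 0.5], the tibia
[0.5, 1.0), and any tarsus contact counts as exactly 1.0; coxa contacts
fall outside this axis and map to 0 with a warning.  Only the first
contact per trial and limb is recorded, keeping successive location
samples independent.  Summaries report per-rod-height medians, quartiles
and ranges, the pooled histogram and cumulative distribution, and the
fraction of contacts in the distal third (> 2/3).  The swing/stance state
of the ipsilateral front leg at the moment of antennal contact comes from
the generator's phase ground truth (experimentally it was read from
video).

## Posture mapping

Every node of an affordance volume yields one matched posture pair: the
joint-angle triplets that place both legs' tibia-tarsus joints on that
node.  Datasets are split 80/20 (train size = floor of 80%).  The
baseline is the optimal affine map fit by least squares via the
pseudo-inverse; errors are per-output-DoF and mean squared error in deg²
on the test split (so MSE 61.0 ≈ 7.8° RMSE per joint).

The network is a single hidden layer of sigmoid units with linear outputs,
optionally with input→output skip connections so the model class strictly
contains the affine baseline.  Weights are Glorot-uniform initialized;
training uses Adam at stock hyperparameters (lr 0.001, β₁ 0.9, β₂ 0.999,
ε 1e-8) on mini-batches of 10 with epoch-end shuffling, all seeded for
bitwise reproducibility.  Inputs *and* outputs are z-scored internally on
training statistics; predictions are de-standardized so every reported
error stays in deg².  Output standardization is a numerical choice: Adam
moves each parameter by at most ≈ the learning rate per step, so raw
output biases of magnitude 60–130° cannot converge within abbreviated
training budgets, whereas the standardized problem converges comfortably;
the fitted function class is unchanged.  Divergence (non-finite loss)
aborts with diagnostics.  Gradients are verified against central finite
differences.

Complexity sweeps train each hidden size for several repetitions
(re-initialized weights, fixed split — the default reading of "repeated
runs"), report mean ± SD test MSE next to the regression baseline, and
cover both mapping directions by swapping sender and receiver.  The
default sweep uses 500 epochs — a scaled-down training schedule with the
same qualitative outcome as full 5000-epoch runs on these dataset sizes:
hidden layers of size 1–2 without skips form a bottleneck worse than the
regression, while sizes ≥ 8 are far better, and a skip network set to the
fitted affine map reproduces the regression error exactly (to floating
point).

## Pipeline, reporting, and consistency checks

`run_pipeline` wires the stages together deterministically under one
global seed and writes all artifacts (trial files, volume exports, contact
events, sweep tables, report tables, provenance metadata) as plain
delimited text; rerunning with the same configuration reproduces identical
files.  The report tables recompute every percentage from their own ccm
columns.

`check_reference_consistency` evaluates the arithmetic identities among
the published reference values of the motion-capture study this package
emulates (MSE means and RMSE relations, split sizes, length- and
volume-ratio percentages, contact distal limits, segment sums).  Known
internal inconsistencies of the printed tables — the front-left contact
distal limit computing to 1.35 against the printed 1.33–1.34 range, the
left/right ordering of the 88%/93% middle-over-hind volume ratios, the
rear affordance 24% vs computed 22%, and two segment-sum/total mismatches
— are reported as "documented discrepancy" rather than failures; the
package does not guess corrections.

## Numerical choices and limitations

* Grid extent 90³ at 1 mm covers ±45 mm around each limb base, exceeding
  the longest limb (38.67 mm); out-of-extent weight is counted and
  reported, never silently dropped.
* Threshold comparisons use ≥ (ties retained); rounding to nodes uses
  nearest-integer rounding.
* Angles are degrees externally, radians only inside trigonometry;
  angles wrap to (−180°, 180°].
* The IK rejects targets outside [|femur−tibia|, femur+tibia] of the
  coxa-corrected radial distance as out-of-workspace; callers skip such
  grid nodes.
* Absolute volume sizes, absolute MSEs, and the published contact
  distributions depend on the experimental posture corpus and are out of
  scope; the package reproduces the arithmetic, the invariances, and the
  qualitative structure (front legs largest, distal-biased antennal
  contacts, the bottleneck-vs-capacity curve).
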