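# Methods

This note documents the model behind `camfuse`, the defaults it ships, the
numerical choices, and what the synthetic test bed does and does not show.

## Geometry

Both cameras are treated as distortion-free pinholes: a world point
(X, Y, Z) maps to pixel (f·X/Z, f·Y/Z) relative to the camera center and
principal point. When all observed world points are coplanar (the
calibration checkerboard), the two image planes are related exactly by a
planar homography `H`, a non-singular homogeneous 3×3 matrix with eight
degrees of freedom. Matrices are stored normalized to `h33 = 1`; if a
fitted solution has |h33| < 1e-12 the matrix falls back to unit Frobenius
norm and is flagged (`h33_normalized = False`). Coordinates are continuous
pixels, origin top-left, y down.

### Estimation

`estimate_homography` builds the standard DLT linear system from the
transfer equations, with Hartley isotropic conditioning (centroid to the
origin, mean distance √2) applied to both point sets before the SVD solve
and undone afterwards. Degeneracy (three of four points collinear, or
(n−1)-of-n in general) is detected as rank deficiency: the second-smallest
singular value of the design matrix below 1e-8 of the largest raises an
error rather than returning an unstable fit.

Three optimization criteria are offered:

* `least_mean_square` — DLT followed by Levenberg–Marquardt refinement of
  the mean squared Euclidean transfer distance over all points (8 free
  parameters, `h33` fixed).
* `ransac` — minimal 4-point samples (default 2000 iterations), consensus
  counted under an inlier threshold (default 3 px; MSAC-style truncated
  score breaks consensus ties), final refit on the inliers.
* `least_median_square` — minimal samples (default 1000) scored by the
  median squared transfer distance; the best sample sets a robust scale
  σ = 1.4826·(1 + 5/(n−4))·√median, points within 2.5σ are refit.

The two stochastic methods require an explicit seed (or Generator): there
is no hidden global randomness anywhere in the package.

Whatever the optimization criterion, the **reported** `reprojection_error`
is always the mean Euclidean pixel distance per point, so the three
methods are directly comparable; for robust fits it is evaluated on the
inlier set. Mean (not RMS) Euclidean distance is the package's reporting
convention.

### Reprojecting boxes

A rectangle generally maps to a quadrilateral under `H`; since overlap is
defined on axis-aligned boxes (detectors emit axis-aligned boxes), `project_box`
returns the axis-aligned hull of the four mapped corners.

## Boxes

IOU is intersection area over union area on continuous boxes; edge-contact
counts as zero, and a union of zero area returns 0 rather than dividing by
zero. NMS is the standard greedy score-descending suppression: keep the
best box, discard anything overlapping it above the threshold (default
0.5 — the threshold is deliberately a configuration parameter, as no
canonical value exists). Score ties break toward smaller `x_min`, then
`y_min`, making the output deterministic and the operation idempotent.

## Fuzzy engine

Classical Mamdani configuration throughout: AND = min over antecedent
degrees, a negated antecedent contributes the complement 1 − μ,
implication clips the consequent set at the rule activation, fired rules
aggregate by pointwise max, and the crisp output is the centroid
∫x·μ(x)dx / ∫μ(x)dx of the aggregate, computed by trapezoidal quadrature
on a uniform grid over the output universe (default spacing 0.1 on 0–100;
halving the spacing moves the centroid by well under 0.05). Mamdani names
the inference scheme and centroid the defuzzifier; min/min/max are the
canonical t-norm choices and are fixed here. All rules carry weight one.
An identically-zero aggregate raises `NoRuleFiredError` — the caller
decides the fallback rather than receiving an arbitrary number.

Membership shapes are triangular, Gaussian (exp(−(x−m)²/2s²)) and
trapezoidal; parameters are validated at construction so evaluation can
never fail. Crisp inputs outside a variable's universe are clamped to the
nearest bound with a logged warning, because real detector boxes can
partially leave the frame.

## The confidence system

Inputs: `RightCam BB` and `LeftCam BB` — the vertical pixel centers of the
two boxes, each on its own image plane (the left box is measured *before*
reprojection; reprojection enters only through the IOU) — and
`IOU overlap`, 100 × IOU between the reprojected left box and the right
box. Output: `Confidence` on 0–100 %.

The 20 rules encode one idea three ways: agreement on the distance class
by all three inputs ⇒ High (R1–R4); disagreement between the cameras ⇒
Low (R5–R16, one rule per ordered class pair, deliberately carrying no IOU
antecedent — position disagreement alone condemns the frame); camera
agreement with off-anchor overlap ⇒ OK (R17–R20, negated IOU antecedent).

### Default membership parameters

* **Position sets** (universe 0–720 px, for a 720-px-high view): peaks at
  150 / 300 / 450 / 600 px for too far / far / close / too close — a
  closer object sits lower in the frame. 150 px is the rig-measured
  too-far anchor; the remaining peaks spread uniformly to the lower
  quarter of the frame. The partition is Ruspini: interior triangles with
  feet at the neighboring peaks, shouldered trapezoids at the ends, so
  the four degrees sum to one everywhere.
* **Overlap sets** (universe 0–100 %): Gaussians centered on the
  rig-calibrated anchors (see below), with each σ chosen so adjacent
  Gaussians cross at degree 0.5 (σ = gap / 2√(2 ln 2) using the nearest
  neighboring anchor).
* **Output sets**: low = tri(0, 0, 30), ok = tri(30, 50, 70),
  high = tri(70, 100, 100). The symmetric OK set forces the
  only-R20-fires scenario to defuzzify to exactly 50; the High and Low
  ramps put single-rule scenarios at 90 and 10. Because the centroid of a
  clipped set can never reach the universe edge, a perfect frame scores
  strictly below 100 — by design, a statement of residual uncertainty.

Every number above is configuration, round-trippable through YAML.

## Synthetic rig

Two identical fronto-parallel pinhole cameras (f = 700 px, 1280×720,
principal point centered) with a horizontal baseline, calibration plane at
48 in. Distance classes sit at 8 / 14 / 22 / 36 in — the two endpoint
depths are rig measurements, the middle two interpolate. Detector boxes
are fixed-size 500×350 px centered on the projected object centroid (a
450×300 variant is a parameter). The object is a fronto-planar patch at
its *own* depth, not the calibration depth: this single modeling choice
reproduces the key empirical behavior that reprojected overlap still
degrades as the object approaches, because the plane-induced map
`H = translation(f·B/Z_plane)` absorbs parallax only at the calibration
depth.

The baseline is not free: it is solved so the close-class (14 in)
reprojected IOU calibrates to exactly 15 %, the one measured overlap
anchor, giving B ≈ 10.4 in. With full vertical overlap the horizontal
residual offset d yields IOU = (w−d)/(w+d), so d_close = w(1−0.15)/1.15 ≈
369.6 px and f·B = d_close/(1/14 − 1/48).

A geometric consequence worth stating: within this rig family (fixed
500-px boxes, classes 8/14/22/36 in, calibration plane at or beyond
36 in), the residual offset ratio d(8)/d(14) = (1/8−1/Zp)/(1/14−1/Zp) is
at least 1.75 for every admissible plane depth, so d(8) ≥ 647 px exceeds
the box width and the **too-close reprojected anchor is exactly 0 %**.
The anchor ladder is then 0 / 15 / 47.1 / 81.6 % — strictly increasing
with distance, with reprojection never reducing overlap (equality only at
too-close, where both are zero). The too-close IOU Gaussian is therefore
centered at 0.

Correspondence generation projects an n×m coplanar grid (default 9×6 = 54
corners, filling ~60 % of the view) into both cameras; measurement noise
is i.i.d. Gaussian **in both views** — corner localization errors occur in
each image — and outliers replace a seeded fraction of target points with
uniform gross errors. With σ = 1 px in both views the fitted mean
Euclidean residual concentrates near σ·√2·√(π/2) ≈ 1.7 px/point
(Monte-Carlo mean over 100 seeds ≈ 1.69); individual seeds scatter roughly
±0.3 around it.

Scenario frames are noise-free apart from their defining perturbation
(optional corner jitter defaults to 0): the *ok* frame's lateral shift is
solved so the reprojected IOU lands at 50 %, far enough from the 0 %
too-close anchor that the High rule's residual activation (~4e-14) is
numerically irrelevant and the score is exactly 50.0; the *low* frame
displaces the left box to the "far" height, firing R15 alone.

### What the simulator does not model

Lens distortion, rolling shutter, image rendering and real detector
behavior (boxes come from geometry, not from a CNN on pixels), occlusion,
multi-object scenes, frame clipping of boxes, and vertical baseline
components. Passing tests therefore demonstrate the *fusion logic* —
geometry, calibration, and inference — not detector robustness on real
imagery; on a physical rig the anchors and peaks must be recalibrated from
measured data, which is why every anchor is configuration rather than
constant.

## Problem sizes

Default test and example workloads are deliberately small: 54-corner
grids, ≤2000-iteration robust loops, 100-replicate Monte-Carlo sweeps,
200-triple engine cross-checks on a 0.01-resolution reference grid. These
sizes give sub-second to few-second runs while leaving the Monte-Carlo
bands comfortably resolved.

## Known limitations

* Single-object, two-camera frames only; pairing of multiple surviving
  detections maximizes reprojected IOU, which is a heuristic.
* The score is geometric: detector class labels and scores pass through
  NMS but do not enter the rule base.
* A frame where *both* cameras err consistently can score high — the
  method assumes at least one camera is right.
* Anchors calibrated from the synthetic rig are placeholders for any real
  deployment.
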