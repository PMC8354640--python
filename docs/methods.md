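# Methods

## The measurement problem

Looping of the embryonic zebrafish heart tube (≈28–38 hpf) superimposes
three motions on every tracked cardiomyocyte: whole-heart drift in the
mounting agarose, bending of the tube about the atrioventricular (AV)
canal, and rotation of each chamber about its own long axis. Only the last
is evidence of tube torsion. The pipeline isolates it with a hinge-rooted
rigid decomposition rather than any deformable registration: each step is
a rigid transform, so cell neighbourhoods are preserved exactly and every
removed motion is explicitly accounted for.

## Model and assumptions

- **Region labels are fixed per track.** A cell is ventricle, AV canal or
  atrium for the whole movie, assigned from its starting location. Cells
  crossing the AV boundary are not re-assigned; with ~13 min frames and
  the AV canal acting as a hinge this misclassifies at most a few boundary
  cells and only dilutes, never inverts, chamber means.
- **Chamber axes from centroids.** Axis of a chamber at frame t = unit
  vector from the AV-canal centroid to that chamber's centroid (arithmetic
  mean of cell positions). Centroids are the only statistic used, so the
  construction is translation-equivariant and exactly rigid-motion
  equivariant.
- **Unfolding aligns to the first frame, not incrementally.** The minimal
  (geodesic) rotation mapping the frame-t axis onto the frame-0 axis is
  applied to the whole chamber. Direct alignment avoids compounding of
  per-step rotation error over 45 intervals.
- **Per-cell angles about the shared first-frame axis.** After unfolding
  all frames share the frame-0 axes, so the axis choice for the signed
  angle α is unambiguous. The chamber statistic per interval is the
  unweighted mean of contributing cells' α; ω = ᾱ/Δt with Δt taken from
  the actual timestamps; Θ is the running sum of ᾱ (Θ(t₀) = 0); twisting
  T = Θ_atrium − Θ_ventricle.
- **The AV canal is the hinge.** Its cells are translated but never
  rotated. Because it has no axis of its own, its rotation series is
  computed about *both* chamber reference axes and reported as two
  separate series rather than picking one.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `min_points` | 15 | frames | minimum track length retained |
| `frame_period_hours` | 13/60 | h | nominal acquisition period; actual `t_hours` wins when present |
| `window_hours` | 1.5 | h | tumbling window for mean ω and twist velocity |
| `eps_proj_um` | 0.5 | µm | minimum perpendicular offset from the rotation axis for α to be defined; below it (sub-voxel — voxels are 0.889×0.889×2 µm) the cell/frame pair is skipped and logged |
| `gap_policy` | `scale` | – | see below |
| `view_from_outflow` | off | – | sign convention (below) |

**Gap policy.** Tracks may have missing frames. Under `scale` (default) a
pair observed at frames i and j > i+1 contributes its full angle α spread
over the spanned grid intervals, each receiving α·(Δt_interval/Δt_span):
Θ then accumulates the entire rotation across the gap and ω remains a
true per-hour rate. Under `drop`, gapped pairs are ignored. The choice
only matters for heavily curated data; the default favours unbiased Θ.

**Sign conventions.** Internally, angles are right-handed about the
AV→chamber axis: positive = counterclockwise seen from the axis tip
toward the origin. The biological convention reports rotation as seen
from the outflow tract, which lies beyond the ventricle: looking from
there coincides with the mathematical convention for the ventricle and
reverses it for the atrium, so `view_from_outflow` flips every series
measured about the atrium axis. All angles are degrees, all geometry is
double precision.

**Degenerate cases.** `minimal_rotation` between antiparallel axes (never
reached in practice — it would mean a chamber centroid crossing the AV
centroid) rotates 180° about the component of global +z perpendicular to
the source axis, falling back to +x when the source axis is parallel to
z; the tie-break is fixed so re-runs are reproducible. Intervals without
any contributing cell are dropped from the series (and from the Θ sum)
with a logged warning. An exactly antiparallel signed-angle pair returns
+180° (the range is (−180, 180]).

## The synthetic generator

`heartbend.synthetic` emulates the acquisition regime of the study
movies: three coaxial cylinder segments (ventricle 60 µm × r25,
AV canal 20 µm × r12, atrium 60 µm × r25) carrying 60/20/60 surface
cells, 46 frames at 13 min (9.75 h), with imposed chamber spins
(constant or piecewise, °/h), a planar hinge swing of the atrium about an
axis through the AV centroid, linear whole-heart drift, isotropic
Gaussian positional noise (default σ = 1 µm, the scale of sub-voxel
tracking jitter), and per-cell track truncation. The wild-type-like
scenario uses ω_V = −8 and ω_A = +6 °/h — magnitudes chosen so the
cumulative rotations over the ~10 h movie reach tens of degrees with the
opposite signs characteristic of normal looping; the null scenario sets
both to zero.

Two constructional choices make the generator a usable ground truth:

- **Antipodal-pair placement.** Cells are sampled uniformly on each
  cylinder surface *in diametrically opposite pairs*, so with the even
  default counts every region centroid lies exactly on its segment axis
  at every frame. The estimated axes then equal the true axes, and in the
  noise-free case the pipeline recovers imposed spins to machine
  precision — recovery error in tests measures noise response, not axis
  estimation bias of the generator itself. Odd cell counts leave an
  O(radius/n) centroid offset and are supported but not used as defaults.
- **Hinge through the AV centroid.** The bend rotation acts about an axis
  through the AV-canal centroid (not the coordinate origin), which is
  what makes a pure bend exactly invertible by the rooting + unfolding
  steps.

Composition order per frame: spin about the (instantaneous) segment axis,
then bend, then drift, then noise. The order is documented because it
fixes the byte-level output; at tested tolerances it does not change any
statistic. All draws flow from one integer seed through named spawned
streams (placement / noise / dropout).

What the generator does **not** emulate: chamber ballooning and axis
elongation, cell division and accretion at the poles, frame-time jitter
around the 13 min period, region mislabelling, and the curved (rather
than cylindrical) chamber walls of a real heart. Passing recovery tests
therefore demonstrates correctness of the *measurement chain* under
realistic noise and dropout, not robustness to every biological
confound.

## Morphometrics

Cell roundness uses the descriptor 4A/(π·major²) with the major axis of
the best-fit second-moment ellipse, computed from exact shoelace-type
area integrals of the polygon interior (for an ellipse with semi-axes
a ≥ b this is b/a); the isoperimetric circularity 4πA/P² is available
behind a switch because the two are often conflated. The straightness
index is chord length over arc length of the boundary polyline, taking
the polyline as given rather than re-measuring a geodesic on the heart
surface. The AV-canal angle is the unsigned angle between the two
chamber axes after projection into a viewing plane (default: ventral
view); axes within 1e-6 of the view normal are rejected as degenerate.

## Statistics

Rank-sum/Mann–Whitney tests use the exact U distribution when both
samples have ≤ 8 values and no ties, otherwise the normal approximation
with mid-rank tie correction and continuity correction. Bonferroni
adjustment is min(1, m·p) with m always the explicit number of requested
comparisons. The two-sample t-test is the equal-variance form;
zero-variance degenerate inputs return the documented limits (p = 1 for
equal means, p = 0 otherwise). A one-way ANOVA wrapper is included for
report parity only.

## Problem sizes and tolerances in the validation suite

Recovery and invariance checks run on the default 140-cell, 46-frame
heart (seconds per run). The null calibration uses 20 seeds; the
rank-sum type-I calibration 1000 replicates at n = 10 per group; the
per-cell angle primitive is checked against an independent
Rodrigues-matrix oracle on 1000 random triples at 1e-9°. Rigid-motion
invariances are asserted at 1e-9 (translations, rigidity) and 1e-6
(global rotations, where the unfolding rotations are conjugated and
accumulate a few extra ulps). Recovery tolerances on noisy data (±5° on
Θ(end), ±7° on twist) are far wider than the observed ≈0.3° residuals at
σ = 1 µm; they leave room for the noise realisation, not for systematic
error.

## Known limitations

- Axis estimates on *real* data inherit sampling bias from uneven cell
  coverage; the antipodal-pair property of the generator deliberately
  removes this, so axis-estimation bias must be assessed separately if
  chambers are sparsely tracked on one side.
- Cells lying within `eps_proj` of a chamber axis carry no angular
  information and are skipped; hearts imaged so that many cells sit near
  the axis will have noisier chamber means (the n_cells column makes
  this visible).
- Region membership is frozen per track; sustained trans-boundary cell
  movement would require a time-resolved labelling upstream.
- The twisting angle compares chamber Θ series on their common time
  grid; movies with long chamber-specific gaps lose those intervals from
  the twist series.
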