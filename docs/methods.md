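# Methods

This note documents the model, the numerical choices, and what the
synthetic validation does and does not establish.

## Model and assumptions

The method treats the LV myocardium in a long-axis view as a U-shaped
band bounded by the endocardial and epicardial contours. Its core
assumptions are:

* **No out-of-plane motion.** The imaging plane passes through the LV
  mid-axis (no foreshortening), so the band's total cross-sectional
  area is approximately constant over the cycle.
* **Proportional area conservation.** Even where the absolute area is
  not perfectly conserved (segmentation noise, slight thickening
  asymmetry), each merged block is assumed to keep its *fraction* of
  its wall's area relative to end-diastole. Strict (absolute) area
  conservation is deliberately not enforced. The rule is applied to the
  septal and lateral walls separately, because septal thickness
  typically exceeds lateral thickness and the two walls thicken
  differently.
* **Frame independence.** No information flows between frames except
  through the ED-anchored area fractions; there is nothing to drift.

Strain is Lagrangian: ε(i) = (Lᵢ − L₀)/L₀ with L the centerline length
(the polyline through the 61 block-border midpoints) and L₀ its value at
the cycle's end-diastole. Shortening gives ε < 0; the reported peak
strain is max |ε| with the sign kept in metadata.

## Pipeline stages and numerical choices

**Coordinates.** Points are (x=column, y=row), origin at the top-left
pixel corner, y downward. Areas are absolute shoelace areas in px²;
`spacing` (mm/px) only scales lengths.

**Boundary tracing.** The largest 8-connected component is kept and
holes filled. The outline is traced along pixel *corners* (crack
edges), so the polygon's shoelace area equals the pixel count exactly;
at checkerboard pinch corners the tracer crosses to the diagonal
neighbour so one component yields one loop. The subpixel contours of
marching-squares methods were rejected because they undercount thin
bands by up to the half-perimeter.

**Key points.** The skeleton (Zhang thinning) is reduced to candidate
annular endpoints via the convex-hull chord-midpoint test; if several
adjacent hull pairs have exterior midpoints, the longest chord wins.
Two refinements stabilise the raw hull vertices, which otherwise jitter
by several pixels between frames:

* the endpoint is snapped to the most distal *medial* skeleton point —
  among skeleton points within a geodesic window of the vertex, those
  with near-maximal distance-transform value (thinning spurs decay
  toward their tips and are excluded), the one reaching farthest along
  the outward wall direction;
* it is then re-centred transversally on the centroid of the local band
  cross-section, cancelling the ~2 px directional bias of thinning.

The outward wall direction itself is the principal axis of skeleton
points in a geodesic distance window `[2t½, 2t½ + max(20, 2t½)]` px
from the endpoint (t½ = local half-thickness from the distance
transform). Geodesic rather than Euclidean distance matters when the
contracted ventricle brings the two base ends close together.

The apex is the boundary point extremal along the ellipse-fit major
axis (signed away from the annular midpoint). Because the rasterized
boundary is flat over several pixels at the pole, points within 2 px of
the maximal projection are averaged and the nearest boundary point to
that centroid is returned.

**Layer split.** Boundary vertices beyond a cut plane at each base end
are removed; the two surviving runs are the arcs, endo being the one
closer to the cavity centroid (convex hull minus mask). The cut plane
sits at the estimated band end (annulus + t½ along the outward
direction, with t½ looked up by bilinear interpolation to avoid
quantization jitter) minus 20% of t½. Cutting exactly at the skeleton
endpoint would discard half a wall-thickness of length per end — and
since thickness grows as 1/λ in systole, that bias grows exactly when
strain is measured; the near-end cut removes it while keeping the cap
nonempty. The inset is a thickness *fraction* so the measurement is
invariant under image rescaling.

**Smoothing and resampling.** Arcs are resampled at ~1 px spacing and
smoothed with a 7-sample moving average before the fixed-count
resampling: along a pixel staircase the traversed length overstates the
geometric length by up to √2, direction-dependently, which would make
"equal arc-length" sampling uneven. Each wall is then resampled by
linear (chord-length) interpolation to 97 points at equal arc-length
steps, with the apex projection pinned, giving 97 + 97 − 1 = 193 points
per layer. The count is configurable; 193 is the default. Linear
rather than spline interpolation avoids inventing smoothness beyond the
moving average.

**DTW registration.** Per wall, classic dynamic programming over the
97×97 Euclidean cost matrix with steps {(1,0),(0,1),(1,1)}, both ends
pinned, ties preferring the diagonal. No warping window is used — the
sequences are short and a window could clip the optimum near the thick
septal base. Per-wall alignment (rather than one 193×193 pass)
guarantees a border at the apex and matches the per-wall conservation
rule.

**Blocks.** Consecutive path nodes bound quadrilateral/triangular
units. At ED, borders are snapped to the path nodes whose cumulative
unit-area fraction is nearest k/30 (k = 1..29), kept strictly
increasing; the *achieved* post-snap fractions — not the nominal k/30 —
become the binding targets for all other frames, which makes the ED
frame exactly self-consistent and absorbs snap quantization. Blocks are
whole merged units, so block areas sum to unit areas exactly and the
achieved-vs-target deviation is bounded by the largest single-unit
fraction.

**Segmental strain.** Segment s covers blocks 10(s−1)+1..10s. Border
snapping quantizes a segment boundary at about one point spacing, which
is negligible over the 61-border global centerline but visible noise on
a ~10-block sub-length; segment *lengths* are therefore measured along
the centerline with the segment boundaries interpolated at the exact ED
area fraction (the blocks themselves stay snapped). The six
sub-lengths still sum exactly to the global centerline length. Each
segment is referenced to its own ED sub-length.

**Cycle detection.** ED frames are local maxima of the cavity-area
series (endocardial arc closed with the base chord) with prominence ≥5%
of the series range and separation ≥⅓ of the dominant period
(autocorrelation estimate). The series is treated circularly — the
beat is periodic — which lets a maximum at the clip boundary qualify
while suppressing its truncated repeat at the other end. With no
qualifying peak, the single global maximum is used. Thresholds are
exposed in `RunConfig`.

**Hopscotch.** Points are tested against block polygons in serial
order (shared borders therefore resolve to the lower serial); a point
in no block is assigned the nearest block and flagged, but kept in the
mean so n stays fixed. The score is the *signed* mean over frames 2..N
and all points of (serial − first-frame serial); the absolute mean and
per-frame means are reported alongside.

## The phantom

The generator emulates one feature of real data only: a U-shaped
myocardial band deforming with known longitudinal strain. The mid-curve
is a half-ellipse (closed-form geometry); frame τ scales it by
λ(τ) = 1 − a·sin²(πτ/n) about the base midpoint (frame 0 = ED,
mid-cycle = ES) and scales thickness by 1/λ, so band area is conserved
and the ground-truth strain is exactly λ − 1 (its minimum is exactly −a
for even n). Thickness varies linearly from the septal to the lateral
value. A pixel is foreground iff its centre lies within half the local
thickness of the mid-curve with an interior nearest point (flat base
ends). Material points keep their arc-length fraction, which makes
co-moving tracking points exact. Defaults (256×256 px, base width
110 px, long axis 170 px, septal/lateral thickness 14/11 px, 32
frames/cycle) give wall-thickness-to-length and shortening ranges
typical of adult A4C echo at moderate resolution.

The phantom's emitted "annulus" ground truth is the mid-curve point one
half-thickness in from each band end — where a thinning skeleton of a
flat-ended band terminates — plus the raw band-end centres; the outer
apex is the mid-curve apex shifted by half the local thickness.

What the phantom does **not** model: speckle/texture, dropout and
segmentation error, translational and out-of-plane motion,
non-uniform (pathological) regional deformation, valve-plane motion,
3D geometry. Passing the phantom suite therefore establishes the
geometric correctness and internal consistency of the pipeline, not
clinical accuracy; noisy AI masks may need the optional smoothing hooks
and will inherit segmentation error directly.

## Problem sizes used in validation

Validation runs use 256×256 masks, 32 frames per cycle, shortening
amplitudes 5–30%, 50 hopscotch points, one or two cycles, and 100+
random wall pairs of length ≤8 for the DTW-vs-enumeration oracle.
These sizes were chosen so the full suite exercises every stage at the
default 193-point/60-block resolution.

## Known limitations

* The annular endpoints are defined by skeleton geometry, not valve
  anatomy; on masks whose base ends are strongly oblique the detected
  base can sit a few pixels from the anatomical annulus (the strain,
  being a length ratio, is insensitive to this at the ~0.5 pp level).
* Very thick apical walls (e.g. amyloid) shrink the cavity and the
  curvature radius at the apex; if the half-thickness exceeds the
  apex curvature radius the medial geometry degenerates and key-point
  detection may fail (`KeypointFailure`) rather than silently guess.
* `detect_cycles` assumes a quasi-periodic cavity-area series; heavy
  arrhythmia with beat-to-beat morphology changes may need manual ED
  frames (pass `ed_frames` to `compute_strain_curve` directly).
* Anisotropic pixel spacing is not resampled internally; pre-scale the
  masks to isotropic spacing first.
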