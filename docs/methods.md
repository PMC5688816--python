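# Methods

`earsilk` re-creates, at desk scale, an image-analysis chain for following
maize ear and silk growth on a turntable phenotyping setup: 12 side views at
30° increments plus one top view per plant and day, a close-up image series
of the ear once it is found, and a synthetic-scene generator that stands in
for the platform so every stage is testable end to end.

## Synthetic scenes

The generator renders plants billboard-style: a leaning vertical stem built
from stacked internode quadrilaterals, leaves attached at nodes inside one
vertical plane (up to a small azimuth jitter), and a side view at camera
azimuth θ obtained analytically by foreshortening each leaf's horizontal
extent by sin(leaf azimuth − θ). This is deliberately not a 3-D render:
every downstream operator consumes binary masks or colour/texture
statistics, so silhouette-level geometry with exact pixel ground truth is
what matters, and the 2-D construction gives it cheaply and exactly.

Anatomical choices encoded in the defaults (and the randomized ranges used
for benchmarks):

- 10–14 leaves; stem height 380–460 px in a 612×512 frame (about 1/4 of a
  typical platform image); basal internode width 16–22 px.
- internode widths decline gently (to 74–84% of basal) up to the ear
  internode, then drop sharply (to 50–60%) above it — internodes above the
  ear are initiated after it and are much thinner.
- the ear internode is widened ×1.6–2.0 by the husks; the ear node sits in
  the upper half of the stem.
- leaf sheaths wrap the stem at their insertion, rendered as a symmetric
  collar, which produces the characteristic junction peaks in the width
  profile.
- stems lean consistently by 1.5–4° (random sign). This is what makes the
  stem-straightness R² meaningful: a real stem's pixels correlate almost
  perfectly along its lean, while an artefact path that detours along a
  crossing leaf reverses its lateral drift and the correlation collapses.
- the background is a constant colour plus a low-amplitude smooth pattern,
  bit-identical across the 12 side views, so the mean-image ratio is exactly
  1 off-plant.

Failure modes are generated on demand: `crossing_leaves=True` adds erect
leaves crossing above the stem top (the skeleton's highest junction then
sits off the stem), `nonplanar=True` additionally scatters leaf azimuths;
`tutor_rod=True` adds a vertical support-rod artefact (its visual realism is
unvalidated — nothing in the imaged material constrains it).

Close-up ear series: a smooth husk ellipse over a dark background, with
silks grown as 2-px-thick random-walk filaments seeded at the ear tip. The
filament pixel set is cumulative over days and its size is driven to the
two-phase target curve count(d) = rate·min(d − onset, duration), so the
rendered mask *is* the ground-truth count. `noise_sd` adds multiplicative
noise of that absolute magnitude (in pixels) to the daily targets. What the
generator does not emulate: husk growth, silk senescence browning, specular
highlights, wind motion between frames — conclusions about those must come
from real images, and a passing suite here shows algorithmic correctness,
not field robustness.

## Segmentation

Side views: each view is divided per channel by the mean image over the 12
views, as (view+1)/(mean+1); a pixel is plant when the largest channel
deviation from 1 exceeds `ratio_threshold` (default 0.5), OR when it falls
inside a green/brown HSV interval (the rescue step: stem pixels sit on the
rotation axis in every view, cancel in the ratio, and are recovered by hue).
The default threshold is 0.5 rather than a lower value because plant pixels
from *other* views contaminate the mean; a loose threshold admits large
ghost regions where several views overlapped, while the HSV union keeps
recall. Components under 30 px are dropped. Top views: a depth-12 decision
tree over the pixel expressed in 7 colour spaces (RGB, HSV, Luv, Lab, HLS,
xyz, Yuv; sRGB/D65, HLS hand-vectorised since scikit-image lacks it).

## View selection

Two robust reduced-major-axis regressions on the segmented top view. RMA
(slope = sign(cov)·sd(y)/sd(x)) treats both pixel coordinates as equivalent,
which an ordinary regression would not. Robustness is iterative trimming
(3 iterations, at most 10% of points per pass) gated on residual size
(>2.5× the median perpendicular residual), so a clean cloud loses nothing
and the rejected group stays a coherent leaf cluster. Pass 1 gives the
dominant leaf-plane azimuth θ₁; camera azimuths within ±25° of θ₁±90° see
the stem unoccluded and become candidates (25° spans one 30° camera step
minus margin). Pass 2 refits the rejected pixels — run only when they are
≥5% of plant pixels and directionally coherent (covariance anisotropy
≥0.5) — and discards candidates looking along that secondary direction.
The selection is clipped to 1–6 views nearest the perpendicular; ties break
toward the smaller azimuth. An isotropic cloud (no leaf plane) falls back
to all views before clipping.

## Ear detection

Per selected view: medial-axis skeleton (scikit-image, seeded tie-breaking)
→ graph (branch tracing; corner whiskers under 10 px pruned; touching
junction pixels merged; degree-2 chains re-merged) → stem = minimum-arc
Dijkstra path from the node nearest the pot top to the highest junction.
Straightness = squared row/col correlation of the path pixels (1.0 by
convention when the lateral spread is under 1 px); paths below the 0.82
cutoff are crossing-leaf artefacts and the view is discarded.

Width along the stem is 2× the exact Euclidean distance transform sampled
on the path (background at distance 0, so a 1-px strip has width 2). The
reference width is the nearest-rank 15th percentile of lower-half widths —
a low quantile ignores junction peaks, occluding leaves and rod artefacts,
all of which bias upward. Junction peaks for reporting are runs ≥3 samples
above 1.3× a rolling 25th-percentile baseline (window ≈ 1/4 of the profile,
so the baseline tracks the internode floor under wide bumps).

Scoring: the profile is decomposed into runs above 1.1× the reference width
and the internode stretches between them. Criterion 1 (weight 1): the run
is *long* — longer than 1.5× the median of the other upper-half runs
(junction bumps outnumber the single ear run; 5% of stem length when it
stands alone). Criterion 2 (weight 2): the next two internodes above are
clearly thinner than the reference (pooled mean < 0.75×). The weighting
makes a bulge alone (broken leaf, wide junction) insufficient: score ≥ 2 is
required, so either thinning alone (score 2) or bulge+thinning (score 3)
can win; ties break toward the lower position since the ear is the last
initiated lateral axis. A bulge candidate is placed at its run centre, a
thinning-only candidate at the node where the thinning begins. The
upper-half restriction applies to the segment's *top end* — the ear node is
what anatomy places in the upper half, and an ear internode may straddle
the midpoint. Candidates from several views are merged by iteratively
discarding the height farthest from the median until all deviations are
within 5% of plant height; the consensus is the surviving median.

## Camera geometry

Pinhole model (zero skew, no distortion terms; hooks would be k1/k2 on the
normalized coordinates) composed with a rotation of the scene about a
vertical turntable axis. Calibration fits intrinsics, camera pose and board
pose to chessboard corners observed at known table angles by trust-region
least squares on the reprojection error. The axis is fixed at the world
origin as a gauge choice: an axis offset is absorbed exactly by board and
camera translations, so estimating it is degenerate. The single-view depth
ambiguity in `pixel_to_world` is closed by intersecting the back-projected
ray with the vertical plane through the axis at the plant's leaf-plane
azimuth — the plane the platform turns perpendicular to the camera before
close-up imaging. Units are mm in the world, px in the image; angles
counter-clockwise from above.

## Silk segmentation

Five features per pixel: the three colour channels Gaussian-smoothed at
5 px, plus the two eigenvalues of the luma structure tensor (derivative
scale 1.0 px, integration scale 1.6 px — the split of one quoted scale into
derivative/integration follows standard practice and is configurable).
Eigenvalues come from the closed form for a symmetric 2×2 matrix, ordered
λ1 ≥ λ2 ≥ 0; their ratio separates filaments (λ1 ≫ λ2) from smooth husk
interiors regardless of colour. A 100-tree seeded random forest (depth
unlimited, out-of-bag accuracy reported) classifies silk vs non-silk inside
an HSV plant mask; background never reaches the forest. Labels are 2-class;
stroke masks use 0/1/2 indexed PNG (unlabeled/silk/other).

## Growth fitting

Continuous piecewise-linear least squares: for fixed breakpoints the model
is linear (hinge design matrix), so breakpoints are found by a grid search
over the observation days plus 20 uniform interior points, refined by
bounded scalar minimisation within one grid step (the RSS is only piecewise
smooth in a breakpoint, so a wider search could leave the basin). One
breakpoint (rise → plateau) by default; two adds the late decline. The
fitted RSS never exceeds the single-line RSS; negligible improvement sets a
`degenerate` flag.

Traits: rate_max is the steepest segment slope (px/day). Onset is the
fitted zero-crossing of the first rising segment, clipped into the observed
day range (with a noise-floor fallback at 2% of the series maximum) — this
puts onset at the silking day rather than the first nonzero observation.
Duration runs from onset to the first breakpoint where the slope falls
below 0.2× rate_max; defining "end of growth" as the plateau breakpoint
rather than senescence is an assumption, made because the plateau is the
identifiable feature of a 1-breakpoint fit. Panel summaries are plain
grouped means and standard errors per genotype × treatment.

## Problem sizes and verification

The end-to-end benchmark (`earsilk.pipeline.detection_rate_experiment`,
also run by `scripts/acceptance.py`) uses ≥100 randomized plants at
612×512 — a size chosen so the whole experiment completes in a few minutes
on one core while leaving internodes ~30 px, large enough for the width
machinery to behave as at full resolution. Growth-recovery experiments use
200 series with 5%-of-plateau noise. Oracles in the test suite are
independent re-computations: exhaustive nearest-boundary search for widths,
all-simple-paths enumeration for stem paths, the closed-form RMA slope, a
homogeneous 3×4 matrix product for projection, and a 2000-point dense grid
for breakpoints.

## Known limitations

- The decision rule converting the second top-view regression into per-view
  rejections is reconstructed from the geometry (the perpendicularity /
  occlusion rule above); imaged material for it is pictorial only.
- Binary criterion scores; graded scoring would need a calibration set.
- The consensus maps a single height to all views; strongly leaning ears
  (height varying with azimuth) are outside the generator and the model.
- Silk quantification is area-based (pixel counts), not filament counts,
  and pixel counts are not converted to mm (no length calibration).
- The synthetic silk colour palettes (yellow/green/red/purple) and textures
  are stylised; classifier accuracies on them do not transfer to field
  images without retraining.
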