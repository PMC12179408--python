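# Methods

## Scope and design

`cardiomorph` is a measurement pipeline, not a model-fitting library: most of
its stages are deterministic image operations whose correctness is checked
against closed-form geometry. The two genuinely statistical components — the
qualification classifier and the decantation-kinetics fit — are exposed as
scikit-learn-style estimators (`QCClassifier`, `PlateauDecay`) so they
compose with pipelines and model selection; the imaging stages are plain
functions over dataclasses in the scikit-image idiom.

## Synthetic cell model

The generator is the package's ground-truth authority; every downstream
stage is validated against it.

**Geometry.** An intact rod is a capsule (stadium): a rectangle of length
`L − W` and width `W` with semicircular caps. This gives closed forms used
as oracles throughout: area `W(L−W) + πW²/4`, maximum caliper diameter `L`,
minimum caliper diameter `W`. Striation is a multiplicative intensity
modulation `1 + a·cos(2πu/s)` along the axial coordinate `u`, with period
`s` (the sarcomere length) and default amplitude `a = 0.4`. Disqualified
classes: *touching pairs* (two capsules overlapping by 2–8 px with an axial
stagger of 15–45% of the first cell's length — a single ground-truth
object, as in real clumps), *rounded* cells (discs, diameter ~N(60, 10) µm,
chosen to match rod-scale areas at aspect ratio 1, no striation) and
*fragments* (small capsules, length ~N(35, 10) µm, width ~N(18, 5) µm,
area well below 2000 µm²).

**Populations.** Per-group length/width/sarcomere/volume (mean, sd) default
to the four hypertrophy-study groups bundled in `GROUP_PARAMS` (control,
angiotensin-II, isoproterenol, aged); lengths and widths are truncated
normals (width ≥ 5 µm, length ≥ width per cell). Class composition uses the
largest-remainder rule so realized counts equal rounded expectations exactly
— tests of composition are therefore non-flaky; a multinomial mode exists
behind the `multinomial=True` flag. The default field is 1024 × 1024 px at
0.65 µm/px, a desk-scale stand-in for full-frame ~2k × 2k sCMOS
acquisitions.

**3D solids.** A cell's z-extent is `D = depth_ratio · W` with elliptical
cross-sections perpendicular to the axis and half-spheroid ends; analytic
volume `π/4·W·D·(L−W) + π/6·W²·D`. The bare-call default is
`depth_ratio = 0.5` (cells flatten when settled on a substrate), but
populations sampled from a group with a target volume mean get a calibrated
per-group ratio such that the expected analytic volume matches that target
(control: ratio ≈ 0.39, giving E[V] ≈ 35,369 µm³); the calibration uses
normal moments, `E[V] ∝ E[W²]E[L] − E[W³](1 − 2/3)`, truncation being
negligible at these parameters.

**What the generator does not emulate.** No point-spread function, no
multi-channel staining, no intensity inhomogeneity or shading, no
out-of-focus debris, no true cell-shape irregularity (taper, curvature,
membrane blebs). Consequences worth keeping in mind: the synthetic classes
are close to linearly separable in the eight features, so classifier metrics
near 1.0 here say the plumbing is correct, not that real visually-annotated
cells (where ~94% is a realistic ceiling) would be classified as well; and
capsule areas exceed real cell areas at the same length/width (real rods
taper — the control group's measured surface mean here is ~3800 µm² versus
~3170 µm² reported for real cells), so only *relative* group contrasts, not
absolute areas, should be compared against real data.

## Segmentation

Global threshold (Otsu default; fixed value optional), optional hole
filling, 8-connected labelling, area gate 500–15,000 µm² (brackets all
group surface means by > 3 SD on both sides), optional border exclusion,
consecutive relabelling. Touching cells are deliberately not split by
watershed: the workflow's contract is that merged particles reach the
classifier and are rejected there, keeping segmentation parameter-free and
auditable. A blank image is a valid empty result (with a logged warning); a
constant/saturated image is an error naming the threshold method.

## Descriptors

All measures are computed on the binary particle mask, lengths in µm via the
pixel size.

- **Perimeter** is the length of the outer marching-squares contour
  (vertices at pixel-edge midpoints) after a circular 5-point moving average
  of the polygon. The raw contour staircases at half-pixel amplitude, which
  inflates smooth-shape perimeters by up to ~6% (a rasterized disc would
  read circularity ≈ 0.88); the 5-point window cancels the staircase while
  shortening true 90° corners by well under a pixel (square circularity
  reads 0.796 vs π/4 ≈ 0.785 at side 150 px).
- **Circularity** `4πA/P²` is clipped at 1.0 (small-particle convention).
- **Ellipse axes** come from second central moments (area-equivalent
  ellipse); the minor axis is floored at one pixel for degenerate particles
  (logged). **Aspect ratio** is the ellipse ratio; **roundness** is
  `4A/(π·major²)`.
- **Length/width** are maximum/minimum Feret diameters by rotating calipers
  on the convex hull of the smoothed contour. Note the deliberate asymmetry:
  length/width are caliper measures while AR is an ellipse measure — for a
  capsule of L/W = 4.83 the moment-ellipse AR is ≈ 4.73, and for real
  tapered cells ellipse AR typically exceeds L/W. Both conventions are
  reported; they must not be mixed across datasets.
- **Scaled perimeter-to-area ratio** is `P/√A`, the only dimensionless
  scaling of P/A (exactly 4 for a square); dimensionless features are
  exactly invariant to pixel size, and dimensionful ones are exactly
  equivariant, which the tests assert.

## Qualification classifier

Eight features in fixed order: area, perimeter, circularity, aspect ratio,
roundness, solidity, AR × solidity, scaled P/√A. Features are z-scored with
statistics from the training split only, then fit with L2-regularised
logistic regression (C = 1, deterministic lbfgs, tol 1e-8) — the
regularisation strength and the 0.5 decision threshold are conventional
defaults, both exposed. The train/test split is stratified and seeded so
benchmark metrics are stable at n = 1000. The model serialises to plain
JSON (scaler statistics, weights, feature ranges, training metadata), so it
can be audited or reloaded from any language; prediction on inputs outside
10× the training feature range proceeds but logs an extrapolation warning.
The shipped training source is the synthetic benchmark (intact rod → 1,
everything else → 0) measured through the real segmentation/descriptor
stages, standing in for a visually verified annotation set, which is not
distributable.

## Sarcomere period

The intensity profile is sampled along the maximum-Feret axis at quarter-
pixel pitch (bilinear interpolation) and averaged across a 5 µm band
restricted to the cell mask; at 0.65 µm/px a 1.8 µm period would otherwise
have < 3 samples per cycle and the estimate biases upward by several
percent. The profile is detrended by subtracting a moving average 3× the
maximum expected period wide (removes the capsule envelope), then the period
is the first local maximum of the unbiased normalized autocorrelation inside
the physiological 1.0–3.0 µm gate with height ≥ 0.25 and prominence ≥ 0.05,
refined by parabolic interpolation. A periodogram estimate (Hann window, 8×
zero padding, mainlobe-integrated confidence) serves as an independent
cross-check; the two agree within one profile sample on clean signals.
Estimates failing the gate or the confidence floor return an *invalid*
record rather than a number.

## Volumes

Thresholded stacks are labelled with 26-connectivity (6-connectivity
available) and each object's volume is exactly `voxel_count × vx·vy·vz`,
with bounding box and stack-boundary flags. No meshing: the voxel-count
identity keeps the measure exact and testable (cuboid fixtures are exact;
rendered rods match their analytic volume to < 1% at 0.5 × 0.5 × 1 µm
voxels).

## Decantation kinetics

Model: `Y = Y0` for `X < X0`, `Y = Plateau + (Y0 − Plateau)e^{−k(X−X0)}`
after. For fixed `(X0, k)` the model is linear in `(Plateau, Y0 −
Plateau)`, so the SSE is profiled in closed form over a deterministic grid
(onset over the sample times, rate log-spaced over 0.05–50 per time span)
and polished by Nelder–Mead in `(X0, log k)` from both the best grid cell
and a zero-onset start; `k > 0` by the log parametrisation, amplitude ≤ 0
(non-decaying) is rejected. There is no stochastic multi-start, so fits are
exactly reproducible, and the free fit can never have larger SSE than the
fixed-onset special case. Noiseless 8-point series are recovered to ~1e-7
relative error.

The plateau band "within 0.5% of the plateau" is ambiguous between
*span-relative* (`Yt = Plateau + f·(Y0 − Plateau)`, default — well defined
as Plateau → 0, closed form `Xt = X0 + ln(1/f)/k`) and *plateau-relative*
(`Yt = Plateau(1 + f)`, behind `convention="plateau"`). Reference settling
experiments report a minimal decantation time of ~24.4 min from this model;
that number cannot be recomputed here because the underlying absorbance
series and fitted parameters are not available — it is documented as the
motivating example only.

## Group statistics

Summaries are mean ± SD (ddof = 1; a single-cell group reports SD 0) and
SEM = SD/√n over qualified rows only — the qualified flag is the single gate
between measurement and statistics. Percent changes are computed from group
means (the convention consistent with the published deltas). Tests:
Kruskal–Wallis omnibus with Dunn's rank z-tests vs control
(tie-corrected, Bonferroni over the control comparisons — the adjustment
choice is ours; the source method statement names no adjustment), one-way
ANOVA with Tukey HSD, Mann–Whitney U, Fisher's exact; significance at
p < 0.05. Table-style outputs round to 2 decimals; a parallel raw CSV keeps
full precision.

## Pipeline and problem sizes

`run_pipeline` chains synth (or TIFF input) → segment → measure → classify →
summarize → compare with per-stage error context, seeded sub-streams per
group/field, and no timestamps in outputs, so identical configs give
byte-identical files. Synthetic cells are laid out by seeded rejection
sampling with an exact capsule-clearance test (~18 cells per 1024² field),
guaranteeing no overlap among ground-truth singles.

Validation sizes were fixed a priori: the classifier benchmark uses 1000
cells (70/30 mix); the sarcomere suite 100 rods at 0.325 µm/px; volume
populations 100 stacks; the full-pipeline determinism/sign check runs 4
groups × 2000 cells — scaled down from the ~2600–5000 cells/group of real
experiments but sized (via the generator's own effect sizes, e.g. a −3%
aspect-ratio contrast against a per-cell SD of ~1.7) so that all expected
sign contrasts exceed |z| ≈ 2.8.

## Known limitations

- Single morphology channel; no nuclei/membrane channels, so no
  binucleation calling or membrane-based declumping.
- No watershed option: heavily confluent preparations will lose merged
  cells to the classifier rather than recover them.
- Classifier metrics on synthetic data overstate real-data performance (see
  generator caveats above).
- The spectrum method's confidence is a mainlobe power share; on very short
  profiles (< ~25 µm) it can pass weak periodicity that the autocorrelation
  method (the default) rejects.
- 2D/3D linkage is statistical only: volumes are measured on separate stack
  populations, not on the same cells as the 2D features.
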