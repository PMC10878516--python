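# Methods

`colonytrack` implements a label-free single-cell analysis pipeline for
pluripotent stem-cell colonies imaged by phase-contrast time-lapse
microscopy, together with the machinery needed to develop and evaluate
it without manual annotation: a fluorescence-derived annotation
generator and a synthetic time-lapse simulator with complete ground
truth.  This note records the models, the parameters that matter, and
the design choices made where more than one reasonable option existed.

## Pipeline model

The workflow assumes time-lapse acquisition at short intervals
(default 2 min per frame, pixel area 0.406 μm²) of colonies whose
nuclei are densely packed ellipsoids.  Its stages:

1. **Pre-processing** (`imgio`): per-timepoint focal-plane selection
   (variance-of-Laplacian sharpness; ties to the lower plane index) and
   nominal-offset stitching of tile grids with 10% overlap (mean
   blending in overlap strips, no registration refinement).  Images are
   z-score normalized before classification.
2. **Nucleus segmentation** (`segmenter` + `fogbank`): a per-pixel
   classifier produces a nucleus-probability map per frame; three
   independently seeded instances of the same model vote, and a pixel
   is foreground only when at least 2 of 3 agree.  The voted mask is
   morphologically smoothed (radius-1 closing/opening) and split into
   instances by the FogBank-style separation below.
3. **Mitosis detection** (`mitosis`): a 4-class spatiotemporal mask
   (0 background, 1 nucleus, 2 mitotic nucleus, 3 daughter) is reduced
   to events by 26-connected 3-D component labeling of the merged
   class-{2,3} voxels, filtering on voxel volume (> 300) and temporal
   persistence (≥ 10 frames for classifier output; see below for
   windowed masks), resolving the division time as the first frame the
   class-3 region splits into two 8-connected 2-D objects (fallback:
   frame of maximal class-2 area, earliest on ties), and seeding two
   daughters (centroids of the two largest class-3 objects, or the
   mother's major-axis endpoints when only one is present).
4. **Tracking and lineage** (`tracker`): gated linear-sum assignment
   between consecutive frames with cost
   `w_dist·(d/gate) + w_overlap·(1 − IoU)`, gate 15 px, both weights 1
   so each term lies in [0, 1].  Unmatched tracks coast up to 5 grace
   frames; an unmatched track whose pixels fall > 50% inside a matched
   object is flagged as merged (and closed) rather than lost.  Mitosis
   events pre-empt the assignment: the mother track closes at the
   division frame and two daughter tracks open at the nearest instances
   to the daughter seeds, which builds the lineage forest.  Track ids
   are assigned in birth order (frame, then row, then column).
5. **Evaluation and dynamics** (`metrics`): assignment-based detection
   scores (F1 = 2TP/(2TP+FN+FP), additional/missing fractions
   normalized by the reference count), mitosis matching with 15 px /
   6 frame gates, per-track linkage error rates, interdivision times,
   doubling-time estimators from counts and from mitosis counts,
   windowed mitosis rates, per-cell MSD, and metric profiles versus
   distance from the colony edge.

## Object separation (FogBank-style)

Touching nuclei are split by seed detection via successive level
descent: walking the height surface from its top down to
`erode_size`, every connected component of the superlevel set that does
not yet contain a seed becomes a new seed; growing is a watershed on
the negative surface constrained to the mask.  The surface is the
Euclidean distance transform (smoothed with a σ=1 Gaussian so
single-pixel boundary bites cannot carve false saddles) or, when the
caller supplies one, an intensity surface quantized to 32 levels.
Nucleus segmentation from fluorescence passes the band-pass response as
that surface: response peaks mark nucleus centers and contacts form
saddles, which separates touching nuclei more reliably than the
distance transform when several cells merge into one mask component.
Objects smaller than `min_size` merge into their largest touching
neighbor or are dropped when isolated; background holes smaller than
`min_size` are filled first.  Defaults `erode_size=2`, `min_size=9`
sit at the center of the band that maximizes detection F1 in the
parameter sweep.  The characteristic failure mode is unchanged from
the underlying idea: cores separated by a saddle shallower than one
level stay merged.

## Annotation from fluorescence (refgen)

Nuclei: difference-of-Gaussians band-pass (σ 2/12 px), Otsu threshold
(fixed-value override available), FogBank separation on the response
surface, then a radius-1 binary erosion per object.  Condensed DNA: a
finer band-pass (σ 1/4 px); because every nucleus rim also excites this
band, the per-frame baseline is the median of per-instance peak
responses, and an instance is flagged mitotic when the response exceeds
1.6× that baseline over at least 10% of its area (minimum 2 px).
Otsu is deliberately not used here: condensed cores are rare outliers
and a bimodality-seeking threshold misfires on frames without any.

Daughters: every object at frame t₀ enters a centroid-distance
assignment against frame t₀+1, with flagged objects duplicated.  The
matrix is square-augmented — any object may instead remain unmatched at
a cost equal to the 15 px gate — so a duplicate claims a second object
only when that is genuinely cheaper than leaving it unmatched.  A
division is recorded iff the two copies map to two distinct objects.
A condensing nucleus occasionally splits in the mask a few frames
before the definitive separation; since the division completes at the
last split, an event with a second event within 15 px in the following
6 frames is treated as premature and dropped.

Class masks label the mother's pixels class 2 for the 5 frames before
the division and each daughter's pixels class 3 for the 3 frames from
the division on (later events win overlapping windows; windows running
off the stack are clipped with a warning).  These windows are a
definition, not an estimate — which has one consequence for event
extraction: a windowed mask confines each event to
`frames_before + frames_after` (8 by default) frames, so the 10-frame
persistence filter appropriate for raw classifier output would reject
every true event.  `EventFilter.for_windows` caps the persistence
threshold at the window span for this case.

## Trainable classifier

The pixel classifier is a compact multilayer perceptron (one hidden
layer, default 24 units) over a multiscale filter bank: intensity,
edge and texture features at Gaussian scales 1–8 px (scikit-image's
basic feature set).  In 4-class spatiotemporal mode the feature vector
additionally includes the same features of difference images against
frames ±3, giving the temporal contrast that distinguishes mitotic and
daughter classes.  Training minimizes cross-entropy weighted by the
per-class weights — (1, 2) for binary nucleus/background, (1, 2, 20, 20)
for the 4-class mode, strongly upweighting the short-lived mitotic and
daughter classes — with Adam, one step per tile per epoch on a random
4000-pixel subsample, and augmentation by reflections, right-angle
rotations and Gaussian blur.  All randomness derives from one seed;
identical seeds give identical weights.  `epochs=0` returns the seeded
random initialization, a valid if uninformative predictor.  The
ensemble is three instances of this model differing only in training
seed.  This classifier is small enough to train on one CPU in minutes;
it is a pixel classifier, not an encoder–decoder, so it has no learned
shape prior — instance geometry is supplied downstream by the
separation step.

`OracleMapPredictor` satisfies the same contract from precomputed
probability maps with a controlled pixel-flip error rate, so voting,
post-processing and tracking can be exercised at known error levels
without any training.

## Synthetic data (simdata)

The simulator emulates the statistical structure the pipeline assumes,
not microscope physics:

- **Geometry**: elliptical nuclei, semi-axes 6–9 px (a ~10 μm stem-cell
  nucleus at 0.406 μm²/px), placed without overlap in a central colony
  disk.
- **Motion**: per-frame Gaussian steps, SD 0.6 px at the colony edge
  (outer 30% of the colony radius) and 0.25 px in the interior,
  followed by pairwise soft repulsion (excluded volume): overlapping
  nuclei are pushed apart symmetrically to 95% contact distance.
  Without repulsion, Brownian motion piles nuclei into permanent deep
  overlaps that no segmentation could resolve; with it, overlaps are
  transient and shallow — the realistic failure mode.
- **Division**: each cell draws an interdivision time from a normal
  distribution (mean 15 h, SD 3 h) truncated to the biologically
  plausible 9–24 h band; initial cells are mid-cycle (uniformly random
  remaining fraction).  For the 5 frames before division the nucleus
  renders a condensed core (inner ellipse at 45% radius) whose extra
  flux scales with nucleus area — condensation concentrates a fixed
  amount of chromatin signal, so smaller cores are proportionally
  brighter (core ≈ 2.5× nucleus level).  At division the mother is
  replaced by two daughters at opposite poles of its orientation axis,
  clearly separated at birth as telophase nuclei are.
- **Rendering**: fluorescence is bright nuclei (level 100) on dark
  background (level 10) with additive Gaussian noise; overlapping
  nuclei sum.  The phase-like channel is a deterministic transform of
  the same noise-free scene — mid-gray background with bright edge
  halos and faintly darkened nucleus interiors — so a classifier must
  learn a genuinely different contrast, but one far cleaner than real
  phase contrast.
- **Death**: optional per-frame removal probability (default 0), used
  to demonstrate the divergence between count-based and mitosis-based
  doubling-time estimators.

What passing tests on this data do **not** show: robustness to real
phase-contrast texture, debris, focus drift, illumination gradients, or
nucleus shapes beyond ellipses.  The simulator's role is to verify the
pipeline's logic — assignment optimality, window bookkeeping, lineage
construction, estimator algebra — under controlled truth, not to claim
real-data accuracy.

`simulate_population` is a rendering-free birth–death process sharing
the interdivision model, for estimator studies at thousands of cells.
`sweep_fixture` produces mask series with touching nuclei plus the two
imperfections a thresholded mask carries (background specks, partial
fragments) for separation-parameter sweeps.

## Estimators and conventions

- Doubling time from counts: DT = ln 2 / (ln(N_t/N₀)/t) over sliding
  windows (default 30 frames = 1 h); non-growing windows give NaN.
- Doubling time from mitoses: DT = ln 2 / (ln((N_t₀+#mitoses)/N_t₀)/t).
  Each counted division adds one cell, so this estimator is blind to
  cell loss; with death present, count-based DT exceeds mitosis-based
  DT — the mechanism that separates phototoxic death from division
  slowdown.
- A population with mean interdivision time 15 h grows slightly faster
  than one 15-h doubling (earlier dividers compound); the measured DT
  on such simulations is ≈ 14.6 h.  Completed interdivision times
  observed within a finite window are censoring-biased short; tests
  therefore compare estimator output against the simulation's own
  completed lifetimes rather than the distribution mean.
- MSD(t₀) averages squared displacements over all lags up to the 1-h
  horizon (30 frames); the alternative single-lag convention was
  rejected as noisier.  Conversion to μm² multiplies px² by the pixel
  area.
- Mitosis rate: events per sliding 60-min window divided by a chosen
  denominator (initial count, or per-window count), then a 20-frame
  moving average.
- Colony edge distance: the colony mask is a morphological closing of
  the nucleus union with radius 3× the typical nucleus radius
  (estimated from the median object area); per-cell distance is the
  distance-transform value at the centroid.  Profiles bin at 25 μm.
- Linkage errors: frames where the paired test track id changes while
  the reference id persists, divided by track length; frames without a
  pairing are skipped.  Rates are reported per frame; conversion to
  errors-per-hour is left to the caller.

## Problem sizes used in tests

The test-suite simulations are sized to exercise each property at the
smallest scale where it is meaningful: the noise-free end-to-end run
uses 50 starting cells over 360 frames (12 h) in a 448² image (~40
divisions); the noisy-pipeline and training checks use 40 cells in 384²
over 24–60 frames; estimator checks use the rendering-free population
model at 1000 cells over 500 frames.  The acceptance script rebuilds
all of these from scratch from its seed.

## Known limitations

- The annotation generator's division timing can be a few frames early
  when a condensing nucleus is transiently over-segmented; events are
  deduplicated toward the later split, but a persistent premature split
  leaves the early timestamp.
- Merged tracks are flagged, not retrospectively resolved.
- Adjacent divisions closer than the matching gate can fuse into one
  3-D component and yield a single event.
- The separation step assumes roughly convex nuclei; strongly concave
  or overlapping-by-half nuclei merge (by design, mirroring the
  published method's failure mode).
- No shading correction, stage-drift registration, or vendor formats;
  stitching uses nominal offsets only.
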