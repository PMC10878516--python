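# colonytrack

Label-free single-cell analysis of pluripotent stem-cell colonies in
phase-contrast time-lapse microscopy: nuclear segmentation, mitosis
detection, cell tracking with lineage reconstruction, and single-cell
dynamics (doubling times, interdivision times, mean squared
displacement, colony-edge profiles).  The package also implements the
two pieces of machinery such a pipeline needs to be developed and
evaluated at scale without manual annotation:

- **Automated annotation** from a fluorescent nuclear reporter
  (`colonytrack.refgen`): band-pass segmentation of nuclei, detection
  of condensed DNA in cells about to divide, assignment-based
  mother→daughter linking, and 4-class spatiotemporal masks
  (0 background, 1 nucleus, 2 mitotic nucleus, 3 daughter).
- **A synthetic time-lapse simulator** with complete ground truth
  (`colonytrack.simdata`): colonies of elliptical nuclei moving with
  edge-enhanced Brownian motion under excluded volume, dividing at
  truncated-normal interdivision times (9–24 h band, 15 h mean), with
  condensed-DNA brightening before each division, rendered as paired
  fluorescence and phase-like channels.

## The method in brief

Nuclei are detected per frame by a per-pixel classifier; three
independently seeded instances of the same model vote, and a pixel is
foreground only where ≥ 2 of 3 agree.  Touching nuclei are separated by
a FogBank-style watershed: seeds found by successive level descent on a
height surface, growth constrained to the mask, parameterized by an
erosion size and a minimum object size (defaults 2, 9).  Mitoses are
3-D (x, y, time) connected components of the mitotic+daughter classes,
filtered for volume > 300 voxels and persistence, with the division
time taken as the first frame the daughter class splits in two.  Tracking
links instances across frames by gated linear-sum assignment with cost

    cost(i, j) = d_ij / 15 px + (1 − IoU_ij),    d_ij ≤ 15 px,

with a 5-frame grace window for unmatched tracks and merge flagging;
division events close the mother track and open two daughter tracks,
giving the lineage.  Evaluation uses the same gated assignment:
F1 = 2TP/(2TP+FN+FP), fractions of additional and missing objects
normalized by the reference count, mitosis matching within 15 px and
6 frames, and per-track linkage error rates.  Doubling time is
estimated both from raw counts, DT = ln2/(ln(N_t/N_0)/t), and from
counted mitoses, DT = ln2/(ln((N_t0+#mitoses)/N_t0)/t); the two
diverge exactly when cells die, which separates death from division
slowdown.

See `docs/methods.md` for the full model description, parameter
defaults and limitations.

## Worked example

Simulate a colony for 8 hours, annotate it from its own fluorescence
channel, detect mitoses, track, and score against the ground truth:

```python
import numpy as np
from colonytrack import simdata, refgen, mitosis, tracker, metrics

cfg = simdata.SimulationConfig(
    n_cells_initial=30, n_frames=240, image_shape=(384, 384),
    interdivision_mean_h=15.0, rng_seed=42,
)
fluor, phase, truth = simdata.simulate_timelapse(cfg)
print(f"simulated {cfg.n_frames} frames, {len(truth.tracks)} cells, "
      f"{len(truth.divisions)} divisions")

instances, _, classmask = refgen.annotate_timelapse(fluor)
events = mitosis.extract_events(
    classmask, mitosis.EventFilter.for_windows(refgen.AnnotationWindows())
)
print(f"detected {len(events)} mitosis events")

tracks, lineage = tracker.track_cells(instances, events)
kept = tracker.filter_tracks(tracks, 5)
print(f"{len(kept)} tracks after the 10-min filter "
      f"({len(lineage.edge_list())} lineage links)")

m = metrics.match_objects(truth.instance_masks[120], instances[120])
s = metrics.detection_scores(m)
print(f"frame 120 detection: F1={s.f1:.3f} "
      f"additional={s.fraction_additional:.3f} missing={s.fraction_missing:.3f}")

rates = metrics.linkage_error_rate(
    truth.tracks, {t: tr.positions() for t, tr in tracks.items()}
)
print(f"mean linkage error rate: {np.mean(list(rates.values())):.4f} per frame")
```

Output:

```
simulated 240 frames, 60 cells, 15 divisions
detected 15 mitosis events
72 tracks after the 10-min filter (30 lineage links)
frame 120 detection: F1=1.000 additional=0.000 missing=0.000
mean linkage error rate: 0.0025 per frame
```

All 15 simulated divisions are found (15 events, 30 lineage links =
2 daughters each); per-frame detection against truth is perfect at this
density, and identity errors occur at about 0.25% of track-frames —
they concentrate around divisions, where segmentation is hardest.

A command-line interface wraps the same steps for on-disk TIFF stacks:

```
colonytrack simulate --seed 42 --out sim/
colonytrack annotate sim/fluorescence.tif --out labels.tif
colonytrack events labels.tif --min-persistence 8 --out events.csv
colonytrack track sim/instances.tif --events events.csv --out tracks.csv
colonytrack evaluate sim/instances.tif predicted.tif
```

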