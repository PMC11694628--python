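# Methods

## Problem and representation

Given per-second GPS fixes (plus device speed over ground, SOG) for a set
of drivers and a binary per-driver label (0 = normal, 1 = abnormal /
MCI-like), the package classifies fixed-length trajectory segments and,
by aggregation, drivers. Two complementary representations of a segment
are used:

* a **tabular vector** of per-point kinematic features summarized over the
  window, and
* a **binary occupancy grid** of the cells the segment visits, which
  preserves the spatial arrangement of the path (straight run, staircase,
  loop) that window statistics cannot always express.

### Per-point features

For consecutive fixes the package computes the haversine step distance on
a spherical Earth (radius 6371.0 km, configurable), the central-difference
speed `v(p₂) = d(p₁,p₃)/Δt` in kph (one-sided at trip endpoints), the SOG
passthrough (missing values imputed from computed speed and flagged), and
the forward azimuth mapped onto the unit circle as `(sin θ, cos θ)`. The
unit-circle mapping makes North continuous: 0° and 360° both map to
(0, 1). A point with no defined heading (trip end, zero displacement)
carries the sentinel (0, 0), distinguishable because defined headings have
unit norm.

### Segmentation and gridding

A trip of `n` records yields `n − w + 1` overlapping windows (stride 1).
Each window is shifted so its first point is the local origin and
projected to km offsets with an equirectangular projection. The longitude
scale uses a **fixed reference latitude** per dataset (default: the
cohort's mean latitude) rather than each segment's own start latitude:
with a fixed scale, translating a segment changes no degree difference and
therefore no integer cell index, making translation invariance *exact*
rather than approximate. Offsets are binned by `floor(offset / c)`; the
first index is (0, 0) and indices may be negative west/south of the start.

Rotation by 90°/180°/270° counterclockwise maps `(x, y)` to `(−y, x)`,
`(−x, −y)`, `(y, −x)`, followed by re-translation so the minimum index per
axis is 0. Rasterization re-translates the same way and sets
`matrix[y, x] = 1` for visited cells (row 0 = southernmost). Segments
whose bounding box exceeds the `G × G` extent are **dropped and counted**
(`n_dropped`), never clipped — clipping would destroy exactly the shape
information the spatial stream consumes. Rotation augmentation (×4) is
applied to training folds only; evaluation sees unrotated segments.

Defaults follow the worked reference example — `w = 13`, `c = 1` km,
`G = 3` — and are configurable everywhere.

### Per-segment tabular vector

The per-point features are aggregated per segment. Two aggregations are
supported: mean only (the 5-dim default: distance, speed, SOG, azimuth_x,
azimuth_y) and mean+standard deviation (10-dim). The within-window spread
of speed distinguishes sustained anomalous episodes from ordinary traffic
variation, so the evaluation protocol uses mean+std; mean-only remains the
default for strict architectural comparability (input dim 5, or 4 in the
strict variant that folds direction into one scaled azimuth value). How
per-point features become one classifier input is a design choice of this
package; both options are exposed.

## Architectures and training

* **Naive stream:** MLP with hidden widths 128/64/32, ReLU, dropout 0.5
  after the first two hidden layers; standalone mode adds a 2-class
  softmax head, fusion mode exposes the 32-dim penultimate activation.
* **Grid stream:** one valid 3×3 convolution with 32 filters (for `G = 3`
  the output is 1×1×32 and the 2×2 max-pool is the identity), flatten,
  FC 256/64/32 with dropout 0.5 after the first FC; the final 32-dim layer
  is the stream's embedding.
* **Combined:** both streams in fusion mode; embeddings concatenated to a
  64-dim vector, refined by FC 256/64/32 (dropout 0.5 after the first FC)
  into a 2-class softmax. Each standalone baseline has its own softmax
  head rather than reusing the fusion stack.

Training uses Adam at learning rate 0.001 with cross-entropy loss,
batch 64. Tabular inputs are standardized on the training set; the fitted
scale travels with the model and is re-applied at prediction. The layers
are implemented directly on numpy with explicit reverse-mode gradients
(verified against central-difference numerical gradients in the test
suite); all randomness — initialization, dropout masks, batch order —
derives from caller-supplied seeds, so identical seeds give bitwise
identical runs. Factor-sweep configurations map a width triple and depth
onto all three architectures uniformly: the first `depth` entries of the
triple become the hidden/FC widths, and the fusion dim is twice the last
entry.

## Evaluation protocol

Precision, recall, and F1 are computed at a 0.5 threshold; AUC is the
rank statistic (threshold-free). Because stride-1 windows overlap almost
completely, segment-level fold assignment leaks near-duplicates between
training and test; folds therefore partition **drivers**, stratified by
label so both classes appear in every fold. The leaky segment-level mode
exists behind `group_by="segment"` for comparison. Reports include both
segment-level metrics and a driver-level AUC over per-driver mean scores,
since it is ambiguous at which level headline metrics of such studies are
aggregated. The data-size sweep maps calendar collection periods (4 mo /
8 mo / 1 yr / 2 yr) to corpus prefixes of 1/6, 1/3, 1/2, and all of each
driver's segments.

## The synthetic cohort

The simulator generates per-second trips on an axis-aligned lattice of
streets (125 m blocks) around a configurable origin. All drivers share the
same machinery:

* cruise speed follows an Ornstein–Uhlenbeck relaxation toward a target
  (default 35 kph; jitter 2 kph normal, 4 kph abnormal);
* turns happen only at intersections and force a slow-down to 12 kph;
  purposeful routes turn with probability `turn_rate·block` per
  intersection, alternate turn direction with probability 0.75 (staircase
  routes that make diagonal progress and never curl into loops), and
  commit to one straight block after each turn;
* traffic controls stop everyone: with probability 0.15 per intersection
  the vehicle halts 3–12 s;
* GPS positions get 12 m isotropic noise (typical consumer-GPS urban
  accuracy) and SOG gets 1 kph noise.

Abnormal drivers additionally draw episode windows of 10–60 s that are,
with the configured probabilities (defaults 0.30 / 0.20 / 0.20, ~70% of
driving time anomalous in total), one of three motifs:

* **erratic** — the speed target oscillates ±15 kph with extra jitter;
* **hesitation** — a sustained 8–20 s mid-block crawl at ~4 kph, longer
  than a typical signal stop;
* **wander** — the driver turns the same way at *every* intersection,
  closing tight loops around blocks instead of progressing.

Every second inside an episode is flagged in an `anomalous` side-channel
column so tests can verify the weak-label structure; the labels the
classifiers see are per-driver only.

Two design points deserve emphasis. First, the simulator is built so that
the spatial stream has something genuinely its own to detect: stops and
GPS noise dominate the per-step bearing channel (a stationary vehicle's
jittered bearings are uniform noise), so the tabular stream cannot reliably
read route shape from direction statistics, while 125 m occupancy cells
integrate out the noise and retain the loop-vs-staircase distinction.
Speed-profile anomalies remain tabular-visible through SOG. Earlier design
drafts in which loops were detectable from direction means, or in which
wandering had a strong turn-frequency speed shadow, made the spatial
stream informationally redundant; the shipped mechanism (matched cornering
behavior, loops that close within one window) is what gives the fused
model its measured advantage. Second, the lattice world is a deliberate
stand-in: it contains no real road topology, traffic interaction, or
clinically validated MCI kinematics, so passing results demonstrate that
the pipeline can recover weakly-labeled phenotype differences of the
simulated kind — not that it screens real drivers.

## Desk-scale evaluation conditions

End-to-end evaluation uses a 20-driver cohort (10 per class, one 180 s
trip each), windows of `w = 60` s, cells of `c = 0.125` km, extent
`G = 4`, mean+std tabular aggregation, 20 training epochs, and 5-fold
driver-grouped cross-validation; these sizes are the package's reference
configuration for a complete experiment on a single CPU. At the paper-style
defaults (`w = 13` s at 1 Hz, 1 km cells) an urban segment covers ~130 m
and virtually always occupies a single cell, leaving the spatial stream
uninformative — those defaults presume coarser time units per window
position than 1 Hz sampling provides. Typical overflow drop rates under
the desk conditions are 5–20% of segments; the rate is always reported,
never silently absorbed.

## Numerical choices and degenerate inputs

Haversine inputs are clamped to [0, 1] before `arcsin`; bearings are
reduced to [0, 360) with an explicit guard against float-rounding onto
360. Cardinal azimuths snap their unit-circle components to exact 0/±1 so
that 0° and 360° agree bitwise. Trips shorter than 3 fixes, non-increasing
timestamps, non-finite coordinates, windows `w < 2`, non-positive cell
sizes, rotation angles outside {90, 180, 270}, single-class training
labels, and prediction from unfitted models all raise typed errors.
MaxPool ties split gradients evenly; dropout is inverted (identity at
evaluation). Cross-validation requires at least `k` drivers per class.

## Known limitations

* The naive stream sees per-segment summaries, not per-point sequences; a
  sequence model might extract more from the same features.
* Weak labels cap segment-level AUC well below 1 by construction; headline
  numbers from real cohorts are not comparable to the synthetic ones here.
* The fixed-reference projection is appropriate for city-scale study
  regions; continental-scale datasets would need per-region references.
* Overflow dropping slightly biases the retained segment population toward
  slower or more compact windows; the drop count is surfaced so users can
  judge the effect.
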