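# tripgrid

Grid-index spatial deep learning for classifying drivers as **normal** or
**abnormal (MCI-like)** from per-second GPS telemetry.

Screening for Mild Cognitive Impairment (MCI) from naturalistic driving data
is attractive because driving is a demanding everyday task: confusion at
intersections, erratic speed changes, hesitation, and wandering/circling all
leave traces in a vehicle's GPS track. `tripgrid` implements a two-stream
approach to this classification problem for researchers working with
telematics loggers (1 Hz fixes plus device speed over ground):

1. **Tabular ("naive") stream.** Each fix is enriched with step distance
   (haversine, Eq. `d = 2r·arcsin√(sin²(Δφ/2) + cosφ₁·cosφ₂·sin²(Δλ/2))`),
   central-difference speed `v(p₂) = Δd(p₁,p₃)/Δt(p₁,p₃)`, device SOG, and
   heading mapped onto the unit circle,
   `(azimuth_x, azimuth_y) = (sin θ, cos θ)`, which removes the 0°/360°
   discontinuity at North. Per-segment summaries of these features feed a
   small MLP (128/64/32, ReLU, dropout 0.5).
2. **Spatial ("grid") stream.** Each trip is cut into sliding windows of
   `w` records (`n − w + 1` segments per n-record trip), shifted so the
   first point is the local origin (translation invariance), binned into
   integer grid cells of side `c` km, and rasterized into a `G × G` binary
   occupancy matrix. A small CNN (3×3 conv with 32 filters, 2×2 max-pool,
   FC 256/64/32) embeds the matrix. Training data is augmented with
   90°/180°/270° counterclockwise rotations of each segment (rotation
   invariance).
3. **Combined model.** The two 32-dim stream embeddings are concatenated
   into a 64-dim vector and refined by FC 256/64/32 into a 2-class softmax.
   Training uses Adam (lr 0.001) with cross-entropy loss.

Labels are **weak**: every segment of a driver diagnosed abnormal carries
label 1, even though such drivers also drive normally much of the time.
Evaluation therefore uses driver-grouped k-fold cross-validation (no driver
appears in both training and test folds) and reports precision, recall, F1,
and ROC AUC at both segment and driver level.

Because real MCI-cohort telemetry is not distributable, the package ships a
deterministic simulator (`tripgrid.simulate`) that generates labeled
cohorts on a lattice of city streets with traffic-control stops, GPS noise,
and three abnormal episode motifs (erratic speed, hesitation crawls, and
wandering loops). See `docs/methods.md` for the model of both phenotypes
and for what the synthetic cohort does and does not establish.

## Worked example

```python
import tripgrid as tg
from tripgrid.models import TrainingConfig
from tripgrid.evaluate import cross_validate

cfg = tg.SimulationConfig(n_drivers=20, abnormal_fraction=0.5,
                          trips_per_driver=1, trip_duration_s=180, seed=0)
telemetry, labels, _ = tg.simulate_cohort(cfg)
ds = tg.build_dataset(telemetry, labels, tg.desk_scale_conditions())
print(f"{len(ds)} segments from {len(ds.drivers)} drivers "
      f"({ds.n_dropped} dropped for grid overflow)")
for kind in ("naive", "grid", "combined"):
    _, s = cross_validate(ds, kind, k=5, seed=0,
                          training=TrainingConfig(epochs=20, seed=0))
    print(f"{kind:9s} segment AUC {s['auc_mean']:.3f} +/- {s['auc_std']:.3f}   "
          f"driver AUC {s['driver_auc_mean']:.3f}")
```

prints

```
1926 segments from 20 drivers (494 dropped for grid overflow)
naive     segment AUC 0.656 +/- 0.198   driver AUC 0.700
grid      segment AUC 0.675 +/- 0.131   driver AUC 0.900
combined  segment AUC 0.727 +/- 0.123   driver AUC 0.800
```

Segment-level AUC is capped well below 1 by the weak labels (only ~60% of
an abnormal driver's minutes contain an anomalous episode); the fused model
beats either single stream because speed anomalies are tabular-visible
while wandering loops are shape-visible. Driver-level AUC aggregates each
held-out driver's mean segment score.

The same pipeline is scriptable from the shell:

```
tripgrid simulate --drivers 20 --abnormal-frac 0.5 --trips 2 --duration 300 --seed 7 --out cohort/
tripgrid featurize --telemetry cohort/telemetry.csv --out features.csv
tripgrid gridify   --telemetry cohort/telemetry.csv --labels cohort/labels.csv \
                   --window 60 --cell-km 0.125 --extent 4 --out segments.csv
tripgrid evaluate  --telemetry cohort/telemetry.csv --labels cohort/labels.csv \
                   --model combined --window 60 --cell-km 0.125 --extent 4 --folds 5 --seed 0
tripgrid experiment --telemetry cohort/telemetry.csv --labels cohort/labels.csv \
                   --window 60 --cell-km 0.125 --extent 4 --out sweep.csv --plots plots/
```

`experiment` runs the data-size / layer-width / depth factor sweep for all
three approaches and writes the metric tables (and optional SVG plots).

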