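# phytochunk

Class-imbalance-aware chunk sampling for 3D semantic segmentation of plant
point clouds.

## The problem

High-resolution plant scans (here: single greenhouse cucumber plants with
per-point x, y, z position and r, g, b colour) are segmented into organ
classes — stem, petiole, leaf, growing point, node, ovary, tendril and
non-plant material.  Such datasets are heavily imbalanced: leaves dominate
(~79% of points) while agronomically important organs such as nodes and
ovaries each hold well under 1%.  Segmenters trained on neighbourhood
"chunks" of these clouds inherit the imbalance and fail on exactly the
organs breeders care about.

`phytochunk` implements a sampling-level remedy.  Point clouds are cut into
chunks of the k nearest neighbours around sampled *anchor points*, and the
anchors are allocated to classes either

* **class-independently** — proportional to the class distribution,
  `a_c = (n_c / n) · a`, preserving the original imbalance, or
* **class-dependently** — proportional to the *inverse* distribution,
  `a_c = ((1 − n_c/n) / Σ_i (1 − n_i/n)) · a`, concentrating chunks on
  minority organs.

Real-valued allocations are integerised by largest-remainder rounding so the
anchor budget `a` is met exactly.  Imbalance is quantified by the Shannon
entropy of the class fractions, `h = −Σ_c p_c log2 p_c` (bits): 0 for a
single-class set, `log2 C = 3` bits for 8 balanced classes.  Class-dependent
sampling raises training-set entropy — improves class balance — without
touching the model or its loss.

At test time clouds are unlabelled, so chunks are anchored at random
not-yet-covered points until every point is in at least one chunk; the
overlapping per-chunk predictions are fused by per-point majority vote
(ties broken uniformly at random).  Evaluation is on the merged full cloud:
per-class IoU `TP/(TP+FP+FN)`, precision, recall, micro/macro-averaged IoU,
row-normalised confusion matrices, and Wilcoxon signed-rank tests between
paired runs.

The segmenter itself is pluggable (`phytochunk.Segmenter` protocol — the
slot a deep point-cloud network occupies in production).  A fast baseline
(nearest class centroid over height/colour/local-shape features, with
empirical class priors) is included so the whole pipeline runs on a desktop,
and a synthetic-plant generator produces labelled cucumber-like clouds with
the realistic imbalance profile for testing and experimentation.

## Worked example

```python
import numpy as np
import phytochunk as pc

plants = pc.generate_dataset(3, pc.PlantParams(n_points=20_000), master_seed=0)
train, test = plants[:2], plants[2:]

dist = pc.class_distribution(train[0])
print("source entropy:", round(pc.shannon_entropy(dist), 2), "bits")

for strategy in ("class_independent", "class_dependent"):
    ts = pc.build_training_set(train, strategy, a=50, k=512, seed=1)
    print(f"{strategy}: {ts.n_chunks} chunks, training-set entropy "
          f"{ts.entropy_bits:.2f} bits")
    _, evals = pc.run_pipeline_once(train, test, strategy, a=50, k=512, seed=1)
    report = evals[0][2]
    minority = [dist.scheme.index(n) for n in
                ("growing_point", "node", "ovary", "tendril")]
    print(f"  micro IoU {report.iou_micro:.2f} | macro IoU {report.iou_macro:.2f} "
          f"| mean minority recall {np.nanmean(report.recall[minority]):.2f}")
```

prints

```
source entropy: 1.06 bits
class_independent: 100 chunks, training-set entropy 0.83 bits
  micro IoU 0.89 | macro IoU 0.43 | mean minority recall 0.41
class_dependent: 100 chunks, training-set entropy 2.16 bits
  micro IoU 0.92 | macro IoU 0.54 | mean minority recall 0.53
```

The source cloud sits at 1.06 bits (heavy imbalance).  Class-independent
chunking reproduces that imbalance in the training set (0.83 bits), while
class-dependent chunking more than doubles the balance (2.16 bits); with the
identical baseline segmenter this lifts macro IoU and minority-organ recall,
while micro IoU — dominated by the leaf class — barely moves.  That is the
mechanism under study, reproduced end to end at desk scale.

Every stage is also exposed on the command line:

```bash
phytochunk simulate --plants 3 --points 20000 --seed 0 -o data/
phytochunk sample data/plant_000.ply --strategy dependent --anchors 50 --k 512 -o chunks/
phytochunk cover data/plant_002.ply --k 512 -o cover.json
phytochunk experiment --config exp.toml
```

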