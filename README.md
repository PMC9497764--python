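# mwrnas

Neural architecture search for **medical microwave radiometry (MWR)**
breast-cancer risk classification.

MWR passively measures the thermal radiation naturally emitted by tissue,
giving internal temperatures at 3–5 cm depth as well as on the skin. Because
tumor growth elevates local tissue temperature, a patient's pattern of 44
temperature readings (nine points around each nipple plus the nipple itself,
an axillary point per side, and two reference points under the chest — each
at skin and at depth) carries a signal that separates low-risk from
high-risk patients. This package implements a two-phase, search-based
approach to building a small, deployable classifier from such records, plus
the constructive baseline it is usually compared against:

1. **Weight-agnostic topology search (WANN).** A population of sparse
   feedforward DAGs is evolved without ever training weights. Every genome
   is evaluated by substituting each of a fixed series of shared weights
   w ∈ {−2, −1.5, −1, −0.5, +0.5, +1, +1.5, +2} into *all* of its
   connections and scoring the thresholded output with the geometric mean
   of sensitivity and specificity (G-mean). Genomes are ranked by NSGA-II
   on three objectives — mean G-mean over the weight series, best G-mean
   over the series, and (minimized) connection count — and parents are
   chosen by size-4 tournaments. Three mutation operators grow the
   networks: insert a node into an existing connection, add an acyclic
   connection, or switch a hidden node's activation within an 11-function
   pool (linear, binary step, sin, cos, sigmoid, Gaussian, tanh, negation,
   absolute value, ReLU, square).
2. **Black-box weight training (BIPOP-CMA-ES).** The best topology's
   per-connection weights are then optimized against binary cross-entropy
   with covariance matrix adaptation: offspring xₖ ~ N(m, σ²C) are ranked,
   the mean is recombined from the best half, evolution paths update C and
   σ, and the whole strategy restarts with doubled population size
   (λ = 50, 100, 200, …) re-centered on the incumbent best. The starting
   point is the best *single* shared weight found by a linear scan over
   [−2, 2], broadcast to every connection; the returned weights are the
   candidate with the lowest validation cross-entropy ever evaluated.
3. **Cascade-correlation baseline (CCNN).** A logistic output grows one
   frozen sigmoid hidden unit at a time; each insertion step trains a pool
   of 30 candidates by gradient ascent on |Σ(v−v̄)(e−ē)|, the covariance
   between candidate output v and the current residual error e, and keeps
   the best on validation.

A synthetic generator emulates the structure of MWR cohorts — near-symmetric
bilateral temperature fields for low-risk patients, localized
depth-temperature hotspots breaking left/right symmetry for high-risk ones,
Gaussian measurement noise, configurable class imbalance — so the entire
pipeline is developed and tested without any data download.

## Worked example

```python
import numpy as np
from mwrnas import (WannConfig, BipopConfig, SyntheticConfig,
                    run_wann_search, train_wann_weights, forward,
                    classification_report, count_connections)
from mwrnas.data import generate_synthetic, split, standardize
from mwrnas.pipeline import best_fixed_shared_weight

cohort = generate_synthetic(SyntheticConfig(n_low=200, n_high=200, seed=4))
parts = split(cohort, rng=np.random.default_rng(4))
train, val, test = standardize(parts.train, parts.validation, parts.test)

genome, _ = run_wann_search(
    WannConfig(generations=30, population_size=64, seed=4),
    train.as_xy(), val.as_xy(),
)
weights, history = train_wann_weights(
    genome, train.as_xy(), val.as_xy(),
    BipopConfig(max_evaluations=2000, seed=4),
)

report = classification_report(
    test.labels, forward(genome, weights, test.features), genome=genome)
w_fixed = best_fixed_shared_weight(genome, val.as_xy())
untrained = classification_report(
    test.labels, forward(genome, w_fixed, test.features), genome=genome)

print(f"connections        : {count_connections(genome)}")
print(f"CMA-ES evaluations : {len(history)}")
print(f"untrained  F1 {untrained.f1:.3f}  G-mean {untrained.gmean:.3f}  (shared weight {w_fixed:+.1f})")
print(f"trained    F1 {report.f1:.3f}  G-mean {report.gmean:.3f}  accuracy {report.accuracy:.3f}")
```

prints

```
connections        : 20
CMA-ES evaluations : 2001
untrained  F1 0.707  G-mean 0.700  (shared weight +1.5)
trained    F1 0.829  G-mean 0.825  accuracy 0.825
```

The evolved network uses 20 connections (a dense model on 44 inputs would
use thousands). With the best single shared weight it already beats chance
(F1 0.707 against 0.5 prevalence); optimizing the individual weights lifts
test F1 to 0.829. `history` holds one record per objective evaluation with
train/validation loss and accuracy — the training curves.

The same steps are available from the shell:

```bash
mwrnas generate --out cohort.csv --n-low 200 --n-high 200 --seed 4
mwrnas search   --data cohort.csv --out genome.json --generations 30 --population-size 64 --seed 4
mwrnas train    --data cohort.csv --genome genome.json --out model.json --max-evaluations 2000 --seed 4
mwrnas evaluate --data cohort.csv --model model.json --seed 4
mwrnas compare  --data cohort.csv --model-a model.json --model-b other.json --seed 4
```

`mwrnas reproduce --out-dir runs/` chains every stage across seeds and
writes a per-seed summary table. Real MWR tables load through
`mwrnas.data.load_mwr_table`, which accepts a column mapping for files
whose headers differ from the canonical `L0_depth … T2_skin` schema.

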