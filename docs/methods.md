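# Methods

This note documents the models and procedures `mwrnas` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic experiments can and cannot show.

## Problem setting

Each patient record is 44 temperatures (°C): for each mammary gland,
points 0–8 around and on the nipple plus an axillary point, each measured
on the skin and at 3–5 cm depth, and two sub-chest reference points (T1,
T2), also at skin and depth. The label is binary: low risk (0) or high
risk (1) of breast cancer. The classifier of interest is a sparse
feedforward DAG found by topology search and then weight-trained by a
derivative-free optimizer; a cascade-correlation network is the
constructive baseline.

## Network genomes and evaluation

A genome holds typed nodes (input, bias, hidden, output) and directed
connections, each with an `enabled` flag and a compact weight-slot index
over the enabled set. Evaluation walks the unique topological order
(Kahn's algorithm with an id-ascending min-heap, so the order — and hence
every downstream number — is reproducible bit-for-bit). Pre-activations
are clamped to ±10⁴ before the activation function is applied: the
`squared` and `inverse` members of the pool otherwise overflow on deep
random topologies. Numerical choices that define edge behavior:

- The output node is always a sigmoid and is excluded from activation
  mutation, so the network's output is a probability and cross-entropy is
  well defined. Classification thresholds at 0.5 with ties predicting
  high risk.
- A constant-1 bias node is an extra input-side node; it lets evolved
  detectors learn thresholds.
- A hidden node with no enabled incoming connection emits
  `activation(0)`, so mutation can never produce an unevaluable genome.
- A genome with zero enabled connections outputs 0.5 for every input.

## Feature standardization

All pipeline entry points z-score the features column-wise with mean and
standard deviation fit on the training subset only. This is not cosmetic:
absolute breast temperatures sit near 33–36 °C, so without centering,
*any* nonzero shared weight saturates the output sigmoid and every
topology scores identically — the shared-weight fitness signal only
exists on standardized inputs.

## Topology search

Defaults (`WannConfig`): 200 generations, population 200, mutation
probabilities 0.5 / 0.25 / 0.25 (change activation / add node / add
connection), 20% initially active input→output connections, tournament
size 4, shared-weight series (−2, −1.5, −1, −0.5, +0.5, +1, +1.5, +2).
The desk-scale experiments in the tests and the acceptance script use 30
generations and population 64 so a full 10-seed study fits in minutes on
one CPU.

Fitness per genome is the triple (mean G-mean over the shared-weight
series, best G-mean over the series, enabled connection count). G-mean =
√(sensitivity × specificity) is used because it collapses to 0 whenever a
classifier ignores one class, which is the failure mode that matters for
imbalanced screening data.

Ranking is NSGA-II with all three objectives simultaneously (maximize,
maximize, minimize). An alternative `rank_mode="alternating"` implements
the probabilistic two-objective alternation used in the original WANN
lineage (80% (mean, connections), 20% (mean, best)); in our 10-seed
synthetic comparison it did not outperform the three-objective default
(mean trained F1 0.706 vs 0.725), so the default stands.

Generational replacement: the front-0 members (capped at 20% of the
population, densest-crowding first) survive unmutated; the rest of the
next generation is produced by size-4 tournaments (winner = lowest front,
then largest crowding distance, then lowest index) followed by exactly one
mutation. If a sampled mutation operator is inapplicable the fixed
fallback order add-connection → change-activation → add-node → identity
keeps the operator distribution well defined. `add_node` disables rather
than deletes the split connection (lineage is preserved; only enabled
connections count toward model size), and `add_connection` samples
uniformly among all role-respecting, not-yet-connected, acyclicity-
preserving ordered pairs. Duplicate topologies are allowed — no structural
hashing — because deduplication changes the search dynamics and there is
no principled tie-break for it.

The returned genome is the one with the best *validation* mean G-mean seen
in any generation (ties: fewer connections); front-0 genomes are
re-scored on validation each generation for this purpose. An optional
early stop ends the search after 30 generations without validation
improvement.

## Weight training

The scan stage evaluates training cross-entropy at 41 equally spaced
shared weights in [−2, 2] (step 0.1; ties prefer the smallest magnitude)
and broadcasts the argmin to every weight slot as the CMA-ES starting
point x₀. The CMA-ES core follows the canonical tutorial strategy
parameters — log-weighted recombination over the best λ/2 offspring,
cumulative step-size adaptation, rank-one plus rank-μ covariance update —
since those defaults are the de-facto definition of the algorithm; the
covariance is re-symmetrized each generation and the run aborts with an
explicit reason on condition number > 10¹⁴ or step-size degeneration.
σ₀ = 0.5, matching the length-4 interval the weights were scanned on.

The restart wrapper runs λ = 50·2ᵏ at restart k with a fresh identity
covariance, re-centered on the incumbent best — the doubling-restart
schedule, without the canonical alternation into a second small-population
regime, which would add a second budget accounting that nothing here
needs. Model selection is the lowest *validation* cross-entropy among all
candidates ever evaluated, and the per-evaluation history (train/val loss
and accuracy) is the training curve. `patience` (evaluations without
validation improvement before a restart is cut short) defaults to off:
with λ = 50, any patience below a few generations' worth of evaluations
stops the optimizer before it can adapt at all, so early stopping is
opt-in rather than a default.

## Cascade-correlation baseline

Candidates are sigmoid units over the inputs plus all previously frozen
hidden units, initialized N(0, 0.5²) with zero bias, batch-normalized and
dropped out (rate 0.5) during candidate training only. The candidate
score is the magnitude of the covariance between unit output and the
current *residual* error (target minus network output): correlation with
the raw target instead would make every unit after the first redundant,
so the residual form is the one implemented. Candidates train by full-
batch gradient ascent on that score (default learning rate 5×10⁻⁶,
200 epochs, early stop when the relative score change stays below 10⁻⁴
for 10 epochs); the winner is chosen by validation score, frozen together
with its batch-norm statistics, and the logistic output layer is
reinitialized and retrained with cross-entropy after every insertion.
Growth stops when validation loss has not improved for 5 insertions or at
`max_hidden`, and the network rolls back to the best-validation snapshot.
After k insertions on d inputs the connection count is
d + Σᵢ₌₀^{k−1}(d+i) + k.

The default learning rate (5×10⁻⁶) is sized for hours-scale runs on
thousands of rows; the toy-scale tests pass a larger rate (0.5) through
`CcnnConfig` because at 5×10⁻⁶ a 240-row task does not move in a few
hundred epochs.

## Synthetic data generator

The generator emulates the structure that makes MWR classification
possible, at desk scale (defaults: 200 + 200 patients):

- Per patient and gland point, a *common bilateral* thermal deviation is
  drawn once and shared by the left and right readings; each side adds an
  independent deviation of sd `asymmetry_sd`/√2, so the left–right
  difference has sd `asymmetry_sd` (default 0.15 °C) while each reading
  keeps total sd `noise_sd` (default 0.4 °C). Near-bilateral symmetry is
  the defining property of the low-risk class.
- Skin readings track the deep pattern with coupling 0.5 (thermal
  conduction toward the surface) plus their own surface variation;
  baselines are 36.5 °C at depth and 33.5 °C at skin, so depth exceeds
  skin in expectation at every position.
- High-risk patients add `hotspot_delta` (default 1.5 °C) to
  `hotspot_points` (default 3) contiguous depth points on one uniformly
  chosen gland, and half that on the matching skin points — a localized
  unilateral hotspot.
- T1/T2 references are baseline plus independent noise.

Baselines and noise levels are physiologically plausible placeholders,
not measurements; they are configuration, not constants. With the
defaults the classes are essentially separable by the maximum left–right
depth difference (a 10σ margin over the asymmetry noise), but *not*
linearly separable in the raw features: a logistic probe tops out near
F1 0.80 because the hotspot position and side vary, while a small
nonlinear model (e.g. an MLP) reaches ≈ 0.92.

What passing tests on this generator do and do not show: they verify the
search, the optimizer, the metrics and their interactions end-to-end, and
they reproduce the *ordering* of weight schemes (random ≤ fixed shared ≤
tuned shared ≤ CMA-ES-trained test G-mean, averaged over seeds). They do
not certify clinical performance, calibration under real measurement
artifacts, or the paper-scale result that the two-phase model overtakes
the cascade baseline: at desk scale (population 64, 30 generations) the
topology search discovers only a handful of the bilateral-difference
detectors the task rewards, the trained pipeline lands near F1 0.72–0.83,
and the cascade baseline — whose hidden units see all 44 inputs at once —
is the stronger model (≈ 0.94). Closing that gap is a search-budget
question (the evolved lineages accumulate at most ~30 structural
mutations), not an optimizer one: raising the CMA-ES budget from 2000 to
12000 evaluations leaves the trained scores unchanged.

## Data handling

Class balancing undersamples the majority class at random without
replacement (preserving only real measurements); minority oversampling is
available behind a flag. Balancing precedes the stratified 60/20/20
train/validation/test split; both consume an explicit seeded generator,
and the split is disjoint, exhaustive, and within ±1 of the exact
fractions per class. The loader drops rows with missing or unparseable
values (logging the count), maps `low`/`high`/0/1 labels to {0, 1}, and
accepts a column mapping for files whose headers differ from the
canonical schema; the test subset is only touched by the evaluation entry
points, by convention enforced throughout the package's own drivers.

## Known limitations

- Recurrent, convolutional, or layered node types are out of scope; the
  genome is a plain DAG with one output.
- No crossover, node/connection deletion, or speciation in the search.
- The restart wrapper implements only the doubling schedule, not the full
  two-regime restart strategy.
- The paired t-test on absolute errors assumes the two models were scored
  on the same test rows in the same order; nothing checks that the inputs
  actually came from the same split.
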