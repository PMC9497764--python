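"""End-to-end experiment driver: the two-phase pipeline at configurable scale.

Chains data generation/loading → balancing → stratified 60/20/20 split →
standardization → weight-agnostic topology search → shared-weight scan →
restarted CMA-ES weight training → evaluation, and the weight-scheme
ablation (random / fixed shared / tuned shared / trained). The CLI, the
test suite and the acceptance script all drive this one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmaes import BipopConfig, scan_shared_weight, train_wann_weights
from .data import (
    DataSplit,
    MwrDataset,
    SyntheticConfig,
    balance_classes,
    generate_synthetic,
    split,
    standardize,
)
from .metrics import MetricsReport, classification_report
from .network import Genome, count_connections, forward
from .wann import DEFAULT_SHARED_WEIGHTS, WannConfig, gmean_fitness, run_wann_search

__all__ = [
    "PipelineResult",
    "prepare_synthetic_split",
    "best_fixed_shared_weight",
    "weight_scheme_ablation",
    "run_pipeline",
]


@dataclass
class PipelineResult:
    genome: Genome
    weights: np.ndarray
    trained: MetricsReport
    untrained: MetricsReport  # best fixed shared weight, chosen on validation
    ablation: dict[str, float]  # test G-mean per weight scheme
    n_connections: int
    n_evaluations: int
    history: list = field(default_factory=list)


def prepare_synthetic_split(
    config: SyntheticConfig, seed: int, balance: bool = False
) -> DataSplit:
    """Generate, optionally balance, split 60/20/20 and standardize."""
    ds = generate_synthetic(config)
    rng = np.random.default_rng(seed)
    if balance:
        ds = balance_classes(ds, rng)
    sp = split(ds, rng=rng)
    tr, va, te = standardize(sp.train, sp.validation, sp.test)
    return DataSplit(tr, va, te)


def best_fixed_shared_weight(
    genome: Genome, validation: tuple[np.ndarray, np.ndarray],
    shared_weights=DEFAULT_SHARED_WEIGHTS,
) -> float:
    """The untrained network: pick the fixed shared weight with the best
    validation G-mean (ties: smaller |w|)."""
    X, y = validation
    scored = []
    for w in shared_weights:
        preds = (forward(genome, w, X) >= 0.5).astype(int)
        scored.append((gmean_fitness(y, preds), -abs(w), w))
    return max(scored)[2]


def weight_scheme_ablation(
    genome: Genome,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    trained_weights: np.ndarray,
    rng: np.random.Generator,
    n_random: int = 10,
    shared_weights=DEFAULT_SHARED_WEIGHTS,
) -> dict[str, float]:
    """Test G-mean under four weight schemes for a fixed topology.

    random — per-connection weights drawn U(-2, 2), averaged over
    ``n_random`` draws; fixed_shared — average over the fixed shared-weight
    series; tuned_shared — the scanned best single shared weight;
    trained — the CMA-ES-optimized weight vector.
    """
    X_te, y_te = test
    n_w = count_connections(genome)

    def g(wts) -> float:
        return gmean_fitness(y_te, (forward(genome, wts, X_te) >= 0.5).astype(int))

    random_scores = [g(rng.uniform(-2, 2, size=n_w)) for _ in range(n_random)]
    fixed_scores = [g(w) for w in shared_weights]
    w_tuned = scan_shared_weight(genome, *train)
    return {
        "random": float(np.mean(random_scores)),
        "fixed_shared": float(np.mean(fixed_scores)),
        "tuned_shared": g(w_tuned),
        "trained": g(trained_weights),
    }


def run_pipeline(
    data: DataSplit,
    wann_config: WannConfig,
    bipop_config: BipopConfig,
    seed: int | None = None,
) -> PipelineResult:
    """Topology search + weight training + evaluation on one data split."""
    if seed is not None:
        wann_config.seed = seed
        bipop_config.seed = seed
    tr = data.train.as_xy()
    va = data.validation.as_xy()
    te = data.test.as_xy()

    genome, search_hist = run_wann_search(wann_config, tr, va)
    weights, train_hist = train_wann_weights(genome, tr, va, bipop_config)

    p_te = forward(genome, weights, te[0])
    trained = classification_report(te[1], p_te, genome=genome)
    w_fixed = best_fixed_shared_weight(genome, va)
    untrained = classification_report(te[1], forward(genome, w_fixed, te[0]), genome=genome)

    rng = np.random.default_rng(bipop_config.seed)
    ablation = weight_scheme_ablation(genome, tr, te, weights, rng)
    return PipelineResult(
        genome=genome,
        weights=weights,
        trained=trained,
        untrained=untrained,
        ablation=ablation,
        n_connections=count_connections(genome),
        n_evaluations=len(train_hist),
        history=[search_hist, train_hist],
    )
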