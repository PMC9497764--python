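"""Evaluation and model comparison.

Scores are reported for the positive (high-risk) class at a 0.5 decision
threshold (ties predict high risk). Model comparison uses a two-sided
paired t-test on per-sample absolute errors |output - label| over a shared
test set, plus the mean element-wise absolute difference between two
models' outputs. Standard deviations use the n-1 (sample) denominator
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix

from .network import Genome, count_connections
from .wann import UndefinedMetricError, gmean_fitness

__all__ = [
    "MetricsReport",
    "classification_report",
    "paired_comparison_test",
    "mean_output_difference",
    "multi_seed_summary",
]


@dataclass(frozen=True)
class MetricsReport:
    f1: float
    accuracy: float
    precision: float
    recall: float
    gmean: float
    n_connections: int
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)

    def as_dict(self) -> dict:
        return asdict(self)


def classification_report(
    labels,
    probabilities,
    threshold: float = 0.5,
    genome: Genome | None = None,
    n_connections: int | None = None,
) -> MetricsReport:
    """Confusion-matrix scores at ``threshold`` (ties predict positive)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("labels contain a single class")
    pred = (p >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if genome is not None:
        n_connections = count_connections(genome)
    return MetricsReport(
        f1=float(f1),
        accuracy=float((tp + tn) / y.size),
        precision=float(precision),
        recall=float(recall),
        gmean=gmean_fitness(y, pred),
        n_connections=int(n_connections) if n_connections is not None else 0,
        confusion=(int(tp), int(fp), int(tn), int(fn)),
    )


def paired_comparison_test(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-sample absolute errors.

    Both sequences must come from the same test set in the same order.
    Identical sequences (zero-variance, zero-mean differences) return
    (0.0, 1.0) by convention.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length sequences of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.inf) * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def mean_output_difference(outputs_a, outputs_b) -> tuple[float, float]:
    """Mean and sample sd of the element-wise |a_i - b_i|."""
    a = np.asarray(outputs_a, dtype=float)
    b = np.asarray(outputs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    d = np.abs(a - b)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def multi_seed_summary(runs: list[dict]) -> dict[str, tuple[float, float]]:
    """Per-metric sample mean ± sd across seeded runs.

    ``runs`` is a list of {metric_name: value} dicts, one per seed.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to summarize")
    keys = runs[0].keys()
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in runs], dtype=float)
        out[k] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
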