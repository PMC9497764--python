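"""Cascade-correlation network baseline.

The network starts as a bare logistic output over the inputs and grows one
hidden unit at a time. Each growth step trains a pool of candidate sigmoid
units (weights drawn from N(0, 0.5^2), zero bias, batch normalization and
dropout applied to the unit's output during training) by gradient ascent on
the magnitude of the covariance between the unit's output and the current
network's residual error; the winning candidate — highest validation
covariance score — is inserted with its input weights and normalization
statistics frozen forever. After every insertion the output layer's weights
are reinitialized and retrained with cross-entropy, so a bad output-layer
minimum cannot survive a growth step. Training stops when the validation
loss has not improved for ``patience`` insertions or ``max_hidden`` is
reached.

Hidden unit k receives the raw inputs plus all k previously frozen units,
which is what produces the cascade's triangular connectivity: after k
insertions with d inputs the network has d + sum_{i<k}(d+i) + k
connections (bias terms not counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wann import UndefinedMetricError, gmean_fitness

__all__ = [
    "CcnnConfig",
    "CcnnNetwork",
    "HiddenUnit",
    "Candidate",
    "candidate_score",
    "train_candidates",
    "train_ccnn",
    "ccnn_connection_count",
]

_BN_EPS = 1.0e-8


@dataclass
class CcnnConfig:
    pool_size: int = 30
    learning_rate: float = 5.0e-6
    init_std: float = 0.5
    dropout_rate: float = 0.5
    patience: int = 5
    max_hidden: int = 20
    candidate_epochs: int = 200
    output_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.learning_rate <= 0:
            raise ValueError("pool_size >= 1 and learning_rate > 0 required")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class HiddenUnit:
    """A frozen cascade unit: weights over inputs + all prior hidden units."""

    weights: np.ndarray  # shape (n_inputs + k,)
    bias: float
    bn_mean: float  # batch-norm statistics frozen at insertion
    bn_std: float

    def activate(self, z_prev: np.ndarray) -> np.ndarray:
        raw = _sigmoid(z_prev @ self.weights + self.bias)
        return (raw - self.bn_mean) / (self.bn_std + _BN_EPS)


@dataclass
class CcnnNetwork:
    n_inputs: int
    hidden_units: list[HiddenUnit] = field(default_factory=list)
    output_weights: np.ndarray | None = None  # over inputs + hidden, + bias last

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """(n, n_inputs + n_hidden) design matrix fed to the output layer."""
        Z = np.asarray(X, dtype=float)
        for unit in self.hidden_units:
            h = unit.activate(Z)
            Z = np.column_stack([Z, h])
        return Z

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = self.hidden_activations(X)
        w, b = self.output_weights[:-1], self.output_weights[-1]
        return _sigmoid(Z @ w + b)

    def n_connections(self) -> int:
        return ccnn_connection_count(self.n_inputs, len(self.hidden_units))


def ccnn_connection_count(d: int, k: int) -> int:
    """d + sum_{i=0..k-1}(d+i) + k: cascade inputs plus output links."""
    return d + sum(d + i for i in range(k)) + k


def candidate_score(candidate_outputs, residual_errors) -> float:
    """|covariance sum| between a unit's output and the residual errors.

    S = |sum_i (v_i - v̄)(e_i - ē)|. A constant candidate output scores 0.
    Maximizing S drives the unit to track whatever error structure the
    current network cannot express.
    """
    v = np.asarray(candidate_outputs, dtype=float)
    e = np.asarray(residual_errors, dtype=float)
    if v.shape != e.shape or v.size < 2:
        raise ValueError("need equal-length sequences of length >= 2")
    return float(abs(np.sum((v - v.mean()) * (e - e.mean()))))


@dataclass
class Candidate:
    weights: np.ndarray
    bias: float


def _make_pool(n_in: int, config: CcnnConfig, rng: np.random.Generator) -> list[Candidate]:
    return [
        Candidate(weights=rng.normal(0.0, config.init_std, size=n_in), bias=0.0)
        for _ in range(config.pool_size)
    ]


def _train_one_candidate(
    cand: Candidate,
    Z: np.ndarray,
    residuals: np.ndarray,
    config: CcnnConfig,
    rng: np.random.Generator,
) -> None:
    """Gradient ascent on the covariance score, with batch-norm + dropout
    on the unit output during training; early stop on score plateau
    (relative change < 1e-4 over 10 epochs)."""
    n = Z.shape[0]
    e_c = residuals - residuals.mean()
    keep = 1.0 - config.dropout_rate
    prev_score = None
    flat = 0
    for _ in range(config.candidate_epochs):
        z = Z @ cand.weights + cand.bias
        v_raw = _sigmoid(z)
        mu, sd = v_raw.mean(), v_raw.std()
        v_bn = (v_raw - mu) / (sd + _BN_EPS)
        mask = (rng.random(n) < keep) / keep if keep < 1.0 else np.ones(n)
        v = v_bn * mask
        cov = float(np.sum(v * e_c))
        score = abs(cov)
        # backward: dS/dv -> dropout -> batch-norm -> sigmoid -> params
        g_v = np.sign(cov) * e_c * mask
        g_bn = (
            g_v - g_v.mean() - v_bn * np.mean(g_v * v_bn)
        ) / (sd + _BN_EPS)
        g_z = g_bn * v_raw * (1.0 - v_raw)
        cand.weights += config.learning_rate * (Z.T @ g_z)
        cand.bias += config.learning_rate * float(g_z.sum())
        if prev_score is not None and score > 0:
            if abs(score - prev_score) / max(score, _BN_EPS) < 1e-4:
                flat += 1
                if flat >= 10:
                    break
            else:
                flat = 0
        prev_score = score


def _candidate_frozen_output(
    cand: Candidate, Z_train: np.ndarray, Z_eval: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Unit output on Z_eval with batch-norm statistics taken from the
    training batch (the statistics that would be frozen at insertion)."""
    raw_tr = _sigmoid(Z_train @ cand.weights + cand.bias)
    mu, sd = float(raw_tr.mean()), float(raw_tr.std())
    raw_ev = _sigmoid(Z_eval @ cand.weights + cand.bias)
    return (raw_ev - mu) / (sd + _BN_EPS), mu, sd


def train_candidates(
    network: CcnnNetwork,
    pool: list[Candidate],
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    config: CcnnConfig,
    rng: np.random.Generator,
) -> Candidate:
    """Train every pool member against the network's residual errors and
    return the one with the highest validation covariance score."""
    if not pool:
        raise ValueError("candidate pool is empty")
    X_tr, y_tr = train
    X_va, y_va = validation
    Z_tr = network.hidden_activations(X_tr)
    Z_va = network.hidden_activations(X_va)
    res_tr = y_tr - network.predict_proba(X_tr)
    res_va = y_va - network.predict_proba(X_va)
    best, best_score = None, -1.0
    for cand in pool:
        _train_one_candidate(cand, Z_tr, res_tr, config, rng)
        v_va, _, _ = _candidate_frozen_output(cand, Z_tr, Z_va)
        score = candidate_score(v_va, res_va)
        if score > best_score:
            best, best_score = cand, score
    return best


def _train_output_layer(
    network: CcnnNetwork,
    X: np.ndarray,
    y: np.ndarray,
    config: CcnnConfig,
    rng: np.random.Generator,
) -> None:
    """(Re)initialize and train the logistic output layer by full-batch
    gradient descent on the cross-entropy."""
    Z = network.hidden_activations(X)
    n, m = Z.shape
    w = rng.normal(0.0, config.init_std, size=m)
    b = 0.0
    for _ in range(config.output_epochs):
        p = _sigmoid(Z @ w + b)
        g = p - y  # dCE/dz for the sigmoid output
        w -= config.learning_rate * (Z.T @ g) / n
        b -= config.learning_rate * float(g.mean())
    network.output_weights = np.append(w, b)


@dataclass
class CcnnIteration:
    iteration: int
    train_loss: float
    val_loss: float
    gmean: float
    connections: int


def train_ccnn(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    config: CcnnConfig,
) -> tuple[CcnnNetwork, list[CcnnIteration]]:
    """Grow a cascade network one frozen hidden unit at a time.

    Iteration 0 is the hidden-free logistic baseline; each later iteration
    inserts the winning candidate (frozen) and retrains a freshly
    reinitialized output layer. Stops when the validation loss has not
    improved for ``patience`` iterations or at ``max_hidden`` units. The
    returned network is rolled back to the best-validation snapshot.
    """
    from .cmaes import cross_entropy  # local import to avoid cycle at import time

    X_tr = np.asarray(train[0], dtype=float)
    y_tr = np.asarray(train[1], dtype=float)
    X_va = np.asarray(validation[0], dtype=float)
    y_va = np.asarray(validation[1], dtype=float)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 2:
        raise UndefinedMetricError("training and validation need both classes")

    rng = np.random.default_rng(config.seed)
    net = CcnnNetwork(n_inputs=X_tr.shape[1])
    history: list[CcnnIteration] = []
    best_val = np.inf
    best_snapshot: tuple[list[HiddenUnit], np.ndarray] | None = None
    since_improve = 0

    for it in range(config.max_hidden + 1):
        _train_output_layer(net, X_tr, y_tr, config, rng)
        p_tr = net.predict_proba(X_tr)
        p_va = net.predict_proba(X_va)
        val_loss = cross_entropy(y_va, p_va)
        history.append(
            CcnnIteration(
                iteration=it,
                train_loss=cross_entropy(y_tr, p_tr),
                val_loss=val_loss,
                gmean=gmean_fitness(y_va.astype(int), (p_va >= 0.5).astype(int)),
                connections=net.n_connections(),
            )
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = (list(net.hidden_units), net.output_weights.copy())
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break
        if it == config.max_hidden:
            break

        winner = train_candidates(
            net, _make_pool(X_tr.shape[1] + it, config, rng),
            (X_tr, y_tr), (X_va, y_va), config, rng,
        )
        Z_tr = net.hidden_activations(X_tr)
        _, mu, sd = _candidate_frozen_output(winner, Z_tr, Z_tr)
        net.hidden_units.append(
            HiddenUnit(
                weights=winner.weights.copy(),
                bias=winner.bias,
                bn_mean=mu,
                bn_std=sd,
            )
        )

    if best_snapshot is not None:
        net.hidden_units, net.output_weights = best_snapshot[0], best_snapshot[1]
    return net, history
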