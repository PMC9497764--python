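"""Black-box weight optimization for a fixed network topology.

Once topology search has produced a genome, its weights are trained with
covariance matrix adaptation (CMA-ES): offspring are sampled from an
adaptive multivariate Gaussian, ranked by cross-entropy on the training
set, and the distribution mean, step size and covariance are updated from
the ranked sample. A restart wrapper doubles the population size after
each restart (50, 100, 200, ...), re-centering on the incumbent best, which
trades early fast convergence for late global exploration. The starting
point is the best single shared weight found by a linear scan over
[-2, 2], broadcast to every connection.

The strategy parameters (recombination weights, cumulation and learning
rates, step-size damping) follow the canonical CMA-ES tutorial defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import Genome, count_connections, forward

__all__ = [
    "BipopConfig",
    "CmaesState",
    "cross_entropy",
    "scan_shared_weight",
    "cmaes_minimize",
    "bipop_optimize",
    "train_wann_weights",
    "NothingToTrainError",
]

_EPS = 1.0e-12


class NothingToTrainError(ValueError):
    """Raised when the genome has no enabled connection to optimize."""


@dataclass
class BipopConfig:
    initial_population: int = 50
    max_restarts: int = 4
    scan_lo: float = -2.0
    scan_hi: float = 2.0
    scan_points: int = 41
    sigma0: float = 0.5
    max_evaluations: int = 10_000
    # objective evaluations without (validation) improvement before a restart
    # is cut short; None uses the full budget
    patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_lo >= self.scan_hi:
            raise ValueError("scan_lo must be < scan_hi")
        if self.initial_population < 4:
            raise ValueError("initial_population must be >= 4")


@dataclass
class CmaesState:
    """One restart's optimizer state: sampling distribution + evolution paths."""

    mean: np.ndarray
    sigma: float
    covariance: np.ndarray
    path_sigma: np.ndarray
    path_c: np.ndarray
    population_size: int
    generation: int = 0
    best_solution: tuple[np.ndarray, float] | None = None


def cross_entropy(labels, probabilities) -> float:
    """Mean binary cross-entropy, probabilities clipped to [1e-12, 1-1e-12]."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs probabilities {p.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def scan_shared_weight(
    genome: Genome,
    features,
    labels,
    lo: float = -2.0,
    hi: float = 2.0,
    n_points: int = 41,
) -> float:
    """Best single shared weight by exhaustive grid evaluation.

    Evaluates training cross-entropy at ``n_points`` equally spaced values in
    [lo, hi] and returns the argmin; ties prefer the candidate with smallest
    absolute value, then the smallest value.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    grid = np.linspace(lo, hi, n_points)
    best = min(
        ((cross_entropy(y, forward(genome, w, X)), abs(w), w) for w in grid),
        key=lambda t: (t[0], t[1], t[2]),
    )
    return float(best[2])


# -- CMA-ES core -----------------------------------------------------------


def cmaes_minimize(
    objective: Callable[[np.ndarray], float],
    x0,
    sigma0: float,
    lam: int,
    budget: int,
    rng: np.random.Generator,
    patience: int | None = None,
    stop_check: Callable[[], bool] | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Minimize ``objective`` with (mu/mu_w, lambda)-CMA-ES.

    Per generation: sample ``lam`` offspring from N(mean, sigma^2 C), rank
    by objective value, recombine the weighted mean of the best half, update
    the two evolution paths, apply the rank-one + rank-mu covariance update
    and cumulative step-size adaptation. Stops on evaluation ``budget``
    exhaustion, ``patience`` evaluations without improvement, numeric
    degeneration (condition number > 1e14, step-size under/overflow), or an
    external ``stop_check``; the returned info dict reports which.
    """
    m = np.asarray(x0, dtype=float).copy()
    n = m.size
    if n < 1 or sigma0 <= 0 or lam < 4:
        raise ValueError("need dimension >= 1, sigma0 > 0, lambda >= 4")

    mu = lam // 2
    w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)
    c_sigma = (mu_eff + 2.0) / (n + mu_eff + 5.0)
    d_sigma = 1.0 + 2.0 * max(0.0, np.sqrt((mu_eff - 1.0) / (n + 1.0)) - 1.0) + c_sigma
    c_c = (4.0 + mu_eff / n) / (n + 4.0 + 2.0 * mu_eff / n)
    c_1 = 2.0 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(
        1.0 - c_1, 2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((n + 2.0) ** 2 + mu_eff)
    )
    chi_n = np.sqrt(n) * (1.0 - 1.0 / (4.0 * n) + 1.0 / (21.0 * n**2))

    state = CmaesState(
        mean=m,
        sigma=float(sigma0),
        covariance=np.eye(n),
        path_sigma=np.zeros(n),
        path_c=np.zeros(n),
        population_size=lam,
    )
    best_x = m.copy()
    best_f = np.inf
    evals = 0
    evals_at_best = 0
    reason = "budget"
    history: list[dict] = []

    while evals < budget:
        if stop_check is not None and stop_check():
            reason = "external_stop"
            break
        C = (state.covariance + state.covariance.T) / 2.0
        eigvals, B = np.linalg.eigh(C)
        if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], _EPS) > 1e14:
            reason = "condition_number"
            break
        D = np.sqrt(eigvals)

        Z = rng.standard_normal((lam, n))
        Y = Z * D @ B.T  # y_k = B D z_k, rows
        X = state.mean + state.sigma * Y
        f = np.empty(lam)
        for k in range(lam):
            f[k] = float(objective(X[k]))
            if not np.isfinite(f[k]):
                raise FloatingPointError(
                    f"objective returned non-finite value at {X[k]!r}"
                )
        evals += lam
        order = np.argsort(f, kind="stable")
        if f[order[0]] < best_f:
            best_f = float(f[order[0]])
            best_x = X[order[0]].copy()
            evals_at_best = evals
        state.best_solution = (best_x, best_f)

        y_w = w @ Y[order[:mu]]
        z_w = w @ Z[order[:mu]]
        state.mean = state.mean + state.sigma * y_w
        state.path_sigma = (1.0 - c_sigma) * state.path_sigma + np.sqrt(
            c_sigma * (2.0 - c_sigma) * mu_eff
        ) * (B @ z_w)
        g = state.generation + 1
        h_sigma = float(
            np.linalg.norm(state.path_sigma)
            / np.sqrt(1.0 - (1.0 - c_sigma) ** (2 * g))
            < (1.4 + 2.0 / (n + 1.0)) * chi_n
        )
        state.path_c = (1.0 - c_c) * state.path_c + h_sigma * np.sqrt(
            c_c * (2.0 - c_c) * mu_eff
        ) * y_w
        rank_mu = (Y[order[:mu]].T * w) @ Y[order[:mu]]
        state.covariance = (
            (1.0 - c_1 - c_mu) * C
            + c_1
            * (
                np.outer(state.path_c, state.path_c)
                + (1.0 - h_sigma) * c_c * (2.0 - c_c) * C
            )
            + c_mu * rank_mu
        )
        state.sigma *= float(
            np.exp(
                (c_sigma / d_sigma) * (np.linalg.norm(state.path_sigma) / chi_n - 1.0)
            )
        )
        state.generation = g
        history.append(
            {"generation": g, "evaluations": evals, "best_f": best_f, "sigma": state.sigma}
        )
        if not np.isfinite(state.sigma) or state.sigma < 1e-30 or state.sigma > 1e30:
            reason = "sigma_degenerate"
            break
        if patience is not None and evals - evals_at_best >= patience:
            reason = "stagnation"
            break
    else:
        reason = "budget"

    info = {
        "stop_reason": reason,
        "evaluations": evals,
        "history": history,
        "state": state,
    }
    return best_x, best_f, info


def bipop_optimize(
    objective: Callable[[np.ndarray], float],
    x0,
    config: BipopConfig,
    rng: np.random.Generator,
    stop_check: Callable[[], bool] | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Restart CMA-ES with population 50·2^k, re-centered on the best so far.

    Returns the overall best solution and a restart log with one entry per
    restart (lambda, evaluations used, best value reached).
    """
    x0 = np.asarray(x0, dtype=float)
    best_x = x0.copy()
    best_f = float(objective(best_x))
    used = 1
    log: list[dict] = []
    for k in range(config.max_restarts + 1):
        if used >= config.max_evaluations:
            break
        if stop_check is not None and stop_check():
            break
        lam = config.initial_population * (2**k)
        bx, bf, info = cmaes_minimize(
            objective,
            best_x,
            config.sigma0,
            lam,
            budget=config.max_evaluations - used,
            rng=rng,
            patience=config.patience,
            stop_check=stop_check,
        )
        used += info["evaluations"]
        if bf < best_f:
            best_f, best_x = bf, bx
        log.append(
            {
                "restart": k,
                "lambda": lam,
                "evaluations": info["evaluations"],
                "best_value": bf,
                "stop_reason": info["stop_reason"],
            }
        )
    return best_x, best_f, log


# -- WANN weight training --------------------------------------------------


@dataclass
class EvalRecord:
    evaluation: int
    train_loss: float
    val_loss: float
    train_acc: float
    val_acc: float


def train_wann_weights(
    genome: Genome,
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    config: BipopConfig,
) -> tuple[np.ndarray, list[EvalRecord]]:
    """Optimize the genome's per-connection weights with restarted CMA-ES.

    The starting point sets every weight slot to the best scanned shared
    weight; the optimization objective is training cross-entropy; the
    returned weight vector is the candidate with the lowest *validation*
    cross-entropy among everything evaluated. A restart is cut short after
    ``config.patience`` evaluations without validation improvement. The
    history holds one record per objective evaluation (the training-curve
    data).
    """
    n_w = count_connections(genome)
    if n_w == 0:
        raise NothingToTrainError("genome has no enabled connections")
    X_tr, y_tr = np.asarray(train[0], float), np.asarray(train[1], float)
    X_va, y_va = np.asarray(validation[0], float), np.asarray(validation[1], float)

    w0 = scan_shared_weight(
        genome, X_tr, y_tr, config.scan_lo, config.scan_hi, config.scan_points
    )
    x0 = np.full(n_w, w0)

    history: list[EvalRecord] = []
    best = {"val_loss": np.inf, "weights": x0.copy(), "since_improve": 0}

    def objective(wv: np.ndarray) -> float:
        p_tr = forward(genome, wv, X_tr)
        p_va = forward(genome, wv, X_va)
        tr_loss = cross_entropy(y_tr, p_tr)
        va_loss = cross_entropy(y_va, p_va)
        history.append(
            EvalRecord(
                evaluation=len(history),
                train_loss=tr_loss,
                val_loss=va_loss,
                train_acc=float(np.mean((p_tr >= 0.5) == (y_tr == 1))),
                val_acc=float(np.mean((p_va >= 0.5) == (y_va == 1))),
            )
        )
        if va_loss < best["val_loss"]:
            best["val_loss"] = va_loss
            best["weights"] = np.asarray(wv, dtype=float).copy()
            best["since_improve"] = 0
        else:
            best["since_improve"] += 1
        return tr_loss

    def val_stagnant() -> bool:
        return (
            config.patience is not None
            and best["since_improve"] >= config.patience
        )

    rng = np.random.default_rng(config.seed)
    bipop_optimize(objective, x0, config, rng, stop_check=val_stagnant)
    return best["weights"], history
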