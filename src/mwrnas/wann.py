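"""Weight-agnostic topology search.

Networks are evolved without ever training their weights: each candidate
topology is scored by substituting a fixed series of shared weight values
into every connection and measuring classification performance, so fitness
reflects the architecture's inductive bias alone. Topologies are ranked by
NSGA-II on three objectives — mean performance across the shared weights,
best performance over the shared weights, and (minimized) connection count —
and parents are chosen by tournament selection. The three mutation
operators only ever grow the network: insert a node into an existing
connection, add a new connection, or change a hidden node's activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .network import (
    ActivationKind,
    ConnectionGene,
    Genome,
    NodeGene,
    NodeRole,
    count_connections,
    forward,
    topological_order,
)

__all__ = [
    "WannConfig",
    "FitnessRecord",
    "init_population",
    "mutate",
    "apply_mutation",
    "gmean_fitness",
    "evaluate_genome",
    "nsga2_rank",
    "tournament_select",
    "run_wann_search",
    "UndefinedMetricError",
]

DEFAULT_SHARED_WEIGHTS = (-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0)


class UndefinedMetricError(ValueError):
    """G-mean is undefined when the labels contain a single class."""


@dataclass
class WannConfig:
    generations: int = 200
    population_size: int = 200
    p_change_activation: float = 0.5
    p_add_node: float = 0.25
    p_add_connection: float = 0.25
    initial_active_fraction: float = 0.2
    tournament_size: int = 4
    shared_weights: tuple[float, ...] = DEFAULT_SHARED_WEIGHTS
    elite_fraction: float = 0.2
    stagnation_patience: int | None = 30
    # "three_objective": rank on (mean, best, connections) simultaneously;
    # "alternating": per generation rank on (mean, connections) with
    # probability 0.8, else (mean, best) — the original WANN lineage's
    # scheme, which concentrates selection pressure when populations are
    # small.
    rank_mode: str = "three_objective"
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_change_activation + self.p_add_node + self.p_add_connection
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mutation probabilities must sum to 1")
        if not self.shared_weights or 0.0 in self.shared_weights:
            raise ValueError("shared_weights must be non-empty and exclude 0")


@dataclass(frozen=True)
class FitnessRecord:
    """Per-genome objectives: (mean, best) G-mean over shared weights + size."""

    mean_perf: float
    best_perf: float
    n_connections: int


# -- population initialization --------------------------------------------


def _base_nodes(n_inputs: int, n_outputs: int) -> list[NodeGene]:
    nodes = [
        NodeGene(i, NodeRole.INPUT, ActivationKind.LINEAR) for i in range(n_inputs)
    ]
    nodes.append(NodeGene(n_inputs, NodeRole.BIAS, ActivationKind.LINEAR))
    nodes.extend(
        NodeGene(n_inputs + 1 + k, NodeRole.OUTPUT, ActivationKind.SIGMOID)
        for k in range(n_outputs)
    )
    return nodes


def init_population(
    config: WannConfig, n_inputs: int, n_outputs: int, rng: np.random.Generator
) -> list[Genome]:
    """Sparse seed networks: no hidden nodes; each possible (input|bias) →
    output link independently enabled with probability
    ``initial_active_fraction``."""
    population = []
    source_ids = list(range(n_inputs + 1))  # inputs + bias
    output_ids = list(range(n_inputs + 1, n_inputs + 1 + n_outputs))
    for _ in range(config.population_size):
        mask = rng.random((len(source_ids), n_outputs)) < config.initial_active_fraction
        conns = []
        cid = 0
        for si, s in enumerate(source_ids):
            for oi, t in enumerate(output_ids):
                if mask[si, oi]:
                    conns.append(ConnectionGene(cid, s, t, True, -1))
                    cid += 1
        g = Genome(
            nodes=_base_nodes(n_inputs, n_outputs),
            connections=conns,
            n_inputs=n_inputs,
            n_outputs=n_outputs,
        )
        g.compact_slots()
        population.append(g)
    return population


# -- mutation --------------------------------------------------------------

_OPS = ("change_activation", "add_node", "add_connection")
# Fixed fallback order when the sampled operator is inapplicable.
_FALLBACK = ("add_connection", "change_activation", "add_node")


def _next_ids(genome: Genome) -> tuple[int, int]:
    nid = max(n.node_id for n in genome.nodes) + 1
    cid = max((c.conn_id for c in genome.connections), default=-1) + 1
    return nid, cid


def _valid_new_edges(genome: Genome) -> list[tuple[int, int]]:
    """Ordered pairs (u, v) that keep the graph acyclic, respect node roles,
    and are not already connected (enabled or disabled)."""
    existing = {(c.source, c.target) for c in genome.connections}
    roles = {n.node_id: n.role for n in genome.nodes}
    ids = sorted(roles)
    # transitive closure over enabled edges, computed once in reverse
    # topological order: reach[v] = every node reachable from v
    succ: dict[int, list[int]] = {i: [] for i in ids}
    for c in genome.enabled_connections():
        succ[c.source].append(c.target)
    reach: dict[int, set[int]] = {}
    for v in reversed(topological_order(genome)):
        r: set[int] = set()
        for w in succ[v]:
            r.add(w)
            r |= reach[w]
        reach[v] = r
    pairs = []
    for u in ids:
        if roles[u] is NodeRole.OUTPUT:
            continue
        for v in ids:
            if v == u or roles[v] in (NodeRole.INPUT, NodeRole.BIAS):
                continue
            if (u, v) in existing:
                continue
            if u in reach[v]:  # u->v would close a cycle
                continue
            pairs.append((u, v))
    return pairs


def _op_change_activation(genome: Genome, rng: np.random.Generator) -> Genome | None:
    hidden = genome.hidden_ids
    if not hidden:
        return None
    nid = hidden[int(rng.integers(len(hidden)))]
    node = genome.node_by_id(nid)
    pool = [a for a in ActivationKind if a != node.activation]
    new_act = pool[int(rng.integers(len(pool)))]
    g = genome.copy()
    g.nodes = [
        replace(n, activation=new_act) if n.node_id == nid else n for n in g.nodes
    ]
    g._topo_cache = None
    return g


def _op_add_node(genome: Genome, rng: np.random.Generator) -> Genome | None:
    enabled = genome.enabled_connections()
    if not enabled:
        return None
    c = enabled[int(rng.integers(len(enabled)))]
    act = list(ActivationKind)[int(rng.integers(len(ActivationKind)))]
    nid, cid = _next_ids(genome)
    g = genome.copy()
    g.nodes = g.nodes + [NodeGene(nid, NodeRole.HIDDEN, act)]
    g.connections = [
        replace(k, enabled=False) if k.conn_id == c.conn_id else k
        for k in g.connections
    ] + [
        ConnectionGene(cid, c.source, nid, True, -1),
        ConnectionGene(cid + 1, nid, c.target, True, -1),
    ]
    g.compact_slots()
    return g


def _op_add_connection(genome: Genome, rng: np.random.Generator) -> Genome | None:
    pairs = _valid_new_edges(genome)
    if not pairs:
        return None
    u, v = pairs[int(rng.integers(len(pairs)))]
    _, cid = _next_ids(genome)
    g = genome.copy()
    g.connections = g.connections + [ConnectionGene(cid, u, v, True, -1)]
    g.compact_slots()
    return g


_OP_FNS = {
    "change_activation": _op_change_activation,
    "add_node": _op_add_node,
    "add_connection": _op_add_connection,
}


def apply_mutation(
    genome: Genome, config: WannConfig, rng: np.random.Generator
) -> tuple[Genome, str, str]:
    """Mutate and report (child, sampled_op, applied_op).

    One operator is sampled with probabilities (p_change_activation,
    p_add_node, p_add_connection). If it is inapplicable the fixed fallback
    order add_connection → change_activation → add_node is tried; if nothing
    applies the genome is returned unchanged (applied_op = "identity").
    The input genome is never modified.
    """
    probs = (config.p_change_activation, config.p_add_node, config.p_add_connection)
    r = rng.random()
    if r < probs[0]:
        sampled = "change_activation"
    elif r < probs[0] + probs[1]:
        sampled = "add_node"
    else:
        sampled = "add_connection"
    for op in (sampled,) + tuple(o for o in _FALLBACK if o != sampled):
        child = _OP_FNS[op](genome, rng)
        if child is not None:
            return child, sampled, op
    return genome.copy(), sampled, "identity"


def mutate(genome: Genome, config: WannConfig, rng: np.random.Generator) -> Genome:
    """Return a mutated copy of ``genome`` (exactly one operator applied)."""
    child, _, _ = apply_mutation(genome, config, rng)
    return child


# -- fitness ---------------------------------------------------------------


def gmean_fitness(labels, predictions) -> float:
    """G-mean = sqrt(sensitivity × specificity) from the confusion matrix.

    The balanced score for two-class problems: it is 0 whenever either class
    is entirely missed, which is what makes it suitable for the imbalanced
    low/high-risk task.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape or y.size == 0:
        raise ValueError("labels and predictions must have equal non-zero length")
    pos = y == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("labels contain a single class")
    sensitivity = float(np.mean(p[pos] == 1))
    specificity = float(np.mean(p[neg] == 0))
    return math.sqrt(sensitivity * specificity)


def evaluate_genome(
    genome: Genome, features, labels, shared_weights=DEFAULT_SHARED_WEIGHTS
) -> FitnessRecord:
    """Score one topology under each fixed shared weight.

    For every shared weight the network is run on all rows, thresholded at
    0.5 (ties predict high-risk), and scored with the G-mean; the record
    carries the mean and best score over the weight series plus the enabled
    connection count.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    scores = []
    for w in shared_weights:
        probs = forward(genome, w, X)
        preds = (probs >= 0.5).astype(int)
        scores.append(gmean_fitness(y, preds))
    return FitnessRecord(
        mean_perf=float(np.mean(scores)),
        best_perf=float(np.max(scores)),
        n_connections=count_connections(genome),
    )


# -- NSGA-II ranking -------------------------------------------------------


def _dominates(a: FitnessRecord, b: FitnessRecord) -> bool:
    """a dominates b: no worse in all objectives, strictly better in one.

    Objectives: maximize mean_perf, maximize best_perf, minimize
    n_connections.
    """
    ge = (
        a.mean_perf >= b.mean_perf
        and a.best_perf >= b.best_perf
        and a.n_connections <= b.n_connections
    )
    gt = (
        a.mean_perf > b.mean_perf
        or a.best_perf > b.best_perf
        or a.n_connections < b.n_connections
    )
    return ge and gt


def nsga2_rank(
    records: list[FitnessRecord], objectives: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fast non-dominated sorting + per-front crowding distance.

    Returns (front_index, crowding_distance) arrays aligned with
    ``records``; front 0 is the non-dominated set, boundary points of each
    front get infinite crowding distance. ``objectives`` restricts the
    comparison to a subset of ("mean_perf", "best_perf", "n_connections");
    default is all three.
    """
    n = len(records)
    if n == 0:
        raise ValueError("need at least one record")

    if objectives is None:
        dom = _dominates
    else:
        signs = {"mean_perf": 1.0, "best_perf": 1.0, "n_connections": -1.0}
        keys = tuple(objectives)

        def dom(a: FitnessRecord, b: FitnessRecord) -> bool:
            av = [signs[k] * getattr(a, k) for k in keys]
            bv = [signs[k] * getattr(b, k) for k in keys]
            return all(x >= y for x, y in zip(av, bv)) and any(
                x > y for x, y in zip(av, bv)
            )

    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dom(records[i], records[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dom(records[j], records[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = np.full(n, -1, dtype=int)
    current = [i for i in range(n) if n_dominating[i] == 0]
    level = 0
    while current:
        nxt = []
        for i in current:
            fronts[i] = level
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
        level += 1

    crowding = np.zeros(n)
    if objectives is None:
        objs = np.array(
            [[r.mean_perf, r.best_perf, -float(r.n_connections)] for r in records]
        )
    else:
        signs = {"mean_perf": 1.0, "best_perf": 1.0, "n_connections": -1.0}
        objs = np.array(
            [[signs[k] * getattr(r, k) for k in objectives] for r in records]
        )
    for f in range(level):
        members = np.flatnonzero(fronts == f)
        if members.size <= 2:
            crowding[members] = np.inf
            continue
        for k in range(objs.shape[1]):
            vals = objs[members, k]
            order = members[np.argsort(vals, kind="stable")]
            lo, hi = objs[order[0], k], objs[order[-1], k]
            crowding[order[0]] = np.inf
            crowding[order[-1]] = np.inf
            if hi > lo:
                span = hi - lo
                for a, b, m in zip(order[:-2], order[2:], order[1:-1]):
                    crowding[m] += (objs[b, k] - objs[a, k]) / span
    return fronts, crowding


def tournament_select(
    population: list[Genome],
    ranks: tuple[np.ndarray, np.ndarray],
    size: int,
    rng: np.random.Generator,
) -> Genome:
    """Sample ``size`` members with replacement; the winner has the lowest
    front index, ties broken by larger crowding distance, then lower index."""
    fronts, crowding = ranks
    idx = rng.integers(len(population), size=size)
    best = min(idx, key=lambda i: (fronts[i], -crowding[i], i))
    return population[int(best)]


# -- search loop -----------------------------------------------------------


@dataclass
class GenerationStats:
    generation: int
    best_mean_perf: float
    best_best_perf: float
    min_connections: int


def run_wann_search(
    config: WannConfig,
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    n_inputs: int | None = None,
) -> tuple[Genome, list[GenerationStats]]:
    """Evolve topologies on the training set; pick the winner on validation.

    Each generation: evaluate every genome under the shared-weight series,
    rank with NSGA-II, carry the front-0 elites over unmutated (capped at
    ``elite_fraction`` of the population, densest-first), and fill the rest
    with tournament-selected, mutated offspring. Front-0 genomes are
    re-scored on the validation set and the best validation mean G-mean
    (ties: fewer connections) is tracked across the whole run; that genome
    is returned. Optional early stop after ``stagnation_patience``
    generations without validation improvement.
    """
    X_tr, y_tr = np.asarray(train[0], float), np.asarray(train[1], int)
    X_va, y_va = np.asarray(validation[0], float), np.asarray(validation[1], int)
    if n_inputs is None:
        n_inputs = X_tr.shape[1]
    rng = np.random.default_rng(config.seed)
    population = init_population(config, n_inputs, 1, rng)

    best_genome: Genome | None = None
    best_key = (-1.0, float("inf"))  # (val mean_perf, -(-connections))
    history: list[GenerationStats] = []
    stagnant = 0

    for gen in range(max(config.generations, 1)):
        records = [
            evaluate_genome(g, X_tr, y_tr, config.shared_weights) for g in population
        ]
        if config.rank_mode == "alternating":
            objectives = (
                ("mean_perf", "n_connections")
                if rng.random() < 0.8
                else ("mean_perf", "best_perf")
            )
        else:
            objectives = None
        fronts, crowding = nsga2_rank(records, objectives)
        front0 = [i for i in np.flatnonzero(fronts == 0)]

        # validation re-scoring of the current Pareto set
        improved = False
        for i in front0:
            rec_va = evaluate_genome(population[i], X_va, y_va, config.shared_weights)
            key = (rec_va.mean_perf, -rec_va.n_connections)
            if key > (best_key[0], -best_key[1]):
                best_key = (rec_va.mean_perf, rec_va.n_connections)
                best_genome = population[i].copy()
                improved = True
        stagnant = 0 if improved else stagnant + 1

        best_mean = max(r.mean_perf for r in records)
        history.append(
            GenerationStats(
                generation=gen,
                best_mean_perf=best_mean,
                best_best_perf=max(r.best_perf for r in records),
                min_connections=min(r.n_connections for r in records),
            )
        )
        if gen == config.generations - 1 or config.generations == 0:
            break
        if (
            config.stagnation_patience is not None
            and stagnant >= config.stagnation_patience
        ):
            break

        # next generation: elites + mutated tournament offspring
        n_elite = min(len(front0), max(1, int(config.elite_fraction * len(population))))
        elite_order = sorted(front0, key=lambda i: (-crowding[i], i))[:n_elite]
        next_pop = [population[i].copy() for i in elite_order]
        while len(next_pop) < config.population_size:
            parent = tournament_select(
                population, (fronts, crowding), config.tournament_size, rng
            )
            next_pop.append(mutate(parent, config, rng))
        population = next_pop

    if best_genome is None:  # generations == 0 edge case handled above
        best_genome = population[0].copy()
    return best_genome, history
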