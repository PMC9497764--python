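"""Feedforward-DAG genomes and their deterministic evaluation.

A genome is the unit of topology evolution: typed nodes (input / bias /
hidden / output), each hidden node carrying one activation function from an
11-member pool, and directed weighted connections forming an acyclic graph.
Evaluation supports two weight modes:

* *shared* — one scalar substituted into every enabled connection, the
  weight-agnostic evaluation used during topology search;
* *vector* — one weight per enabled connection (indexed by ``weight_slot``),
  used once the topology is frozen and the weights are optimized.

The single output node is always passed through a sigmoid so the network
emits a probability of the positive (high-risk) class.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ActivationKind",
    "NodeRole",
    "NodeGene",
    "ConnectionGene",
    "Genome",
    "CyclicGenomeError",
    "activation_apply",
    "topological_order",
    "forward",
    "count_connections",
    "save_genome",
    "load_genome",
]

# Pre-activations are clamped to this symmetric interval before any
# activation is applied: `squared` and `inverse` otherwise overflow on
# unbounded random topologies.
PREACT_CLIP = 1.0e4


class NodeRole(str, Enum):
    INPUT = "input"
    BIAS = "bias"
    HIDDEN = "hidden"
    OUTPUT = "output"


class ActivationKind(str, Enum):
    """The 11-function activation pool sampled during topology search."""

    LINEAR = "linear"
    BINARY_STEP = "binary_step"
    SIN = "sin"
    COSINE = "cosine"
    SIGMOID = "sigmoid"
    GAUSSIAN = "gaussian"
    TANH = "tanh"
    INVERSE = "inverse"
    ABSOLUTE = "absolute"
    RELU = "relu"
    SQUARED = "squared"


_ACTIVATIONS = {
    ActivationKind.LINEAR: lambda x: x,
    ActivationKind.BINARY_STEP: lambda x: np.where(x >= 0, 1.0, 0.0),
    ActivationKind.SIN: np.sin,
    ActivationKind.COSINE: np.cos,
    ActivationKind.SIGMOID: lambda x: 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
    ActivationKind.GAUSSIAN: lambda x: np.exp(-np.square(x)),
    ActivationKind.TANH: np.tanh,
    ActivationKind.INVERSE: lambda x: -x,
    ActivationKind.ABSOLUTE: np.abs,
    ActivationKind.RELU: lambda x: np.maximum(x, 0.0),
    ActivationKind.SQUARED: np.square,
}


class CyclicGenomeError(ValueError):
    """Raised when a genome's enabled connections contain a directed cycle."""


def activation_apply(kind: ActivationKind, x):
    """Apply one pool activation elementwise; scalar in, scalar out."""
    try:
        fn = _ACTIVATIONS[ActivationKind(kind)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown activation kind: {kind!r}") from exc
    out = fn(np.asarray(x, dtype=float))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NodeGene:
    node_id: int
    role: NodeRole
    activation: ActivationKind


@dataclass(frozen=True)
class ConnectionGene:
    conn_id: int
    source: int
    target: int
    enabled: bool
    weight_slot: int  # index into the weight vector; -1 when disabled


@dataclass
class Genome:
    """A feedforward DAG with compact weight slots over enabled connections.

    Invariants (checked by :meth:`validate`): acyclic on enabled edges;
    input/bias nodes have no incoming and output nodes no outgoing enabled
    connections; ``weight_slot`` over enabled connections is exactly
    ``0..n_enabled-1`` in connection order.
    """

    nodes: list[NodeGene]
    connections: list[ConnectionGene]
    n_inputs: int = 44
    n_outputs: int = 1
    _topo_cache: tuple[int, ...] | None = field(
        default=None, repr=False, compare=False
    )

    # -- structure ---------------------------------------------------------

    def node_by_id(self, node_id: int) -> NodeGene:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def input_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.role is NodeRole.INPUT]

    @property
    def bias_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.role is NodeRole.BIAS]

    @property
    def hidden_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.role is NodeRole.HIDDEN]

    @property
    def output_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.role is NodeRole.OUTPUT]

    def enabled_connections(self) -> list[ConnectionGene]:
        return [c for c in self.connections if c.enabled]

    def compact_slots(self) -> None:
        """Reassign weight slots 0..n_enabled-1 in connection order."""
        slot = 0
        new = []
        for c in self.connections:
            if c.enabled:
                new.append(replace(c, weight_slot=slot))
                slot += 1
            else:
                new.append(replace(c, weight_slot=-1))
        self.connections = new
        self._topo_cache = None

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        roles = {n.node_id: n.role for n in self.nodes}
        slots = []
        for c in self.enabled_connections():
            if roles[c.source] is NodeRole.OUTPUT:
                raise ValueError(f"output node {c.source} has outgoing connection")
            if roles[c.target] in (NodeRole.INPUT, NodeRole.BIAS):
                raise ValueError(f"{roles[c.target].value} node {c.target} has incoming connection")
            slots.append(c.weight_slot)
        if sorted(slots) != list(range(len(slots))):
            raise ValueError("weight slots are not compact 0..n_enabled-1")
        topological_order(self)  # raises CyclicGenomeError on a cycle

    def copy(self) -> "Genome":
        return Genome(
            nodes=list(self.nodes),
            connections=list(self.connections),
            n_inputs=self.n_inputs,
            n_outputs=self.n_outputs,
        )


def count_connections(genome: Genome) -> int:
    """Number of enabled connections — the model-size ranking objective."""
    return len(genome.enabled_connections())


def topological_order(genome: Genome) -> list[int]:
    """Unique topological order of all nodes, ties broken by ascending id.

    Kahn's algorithm with a min-heap over node ids, so the returned order is
    deterministic and reproducible. Only enabled connections constrain the
    order. Raises :class:`CyclicGenomeError` naming one offending edge.
    """
    if genome._topo_cache is not None:
        return list(genome._topo_cache)
    ids = [n.node_id for n in genome.nodes]
    indeg = {i: 0 for i in ids}
    succ: dict[int, list[int]] = {i: [] for i in ids}
    for c in genome.enabled_connections():
        indeg[c.target] += 1
        succ[c.source].append(c.target)
    ready = [i for i in ids if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        u = heapq.heappop(ready)
        order.append(u)
        for v in succ[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(ready, v)
    if len(order) != len(ids):
        stuck = [i for i in ids if indeg[i] > 0]
        for c in genome.enabled_connections():
            if c.source in stuck and c.target in stuck:
                raise CyclicGenomeError(
                    f"cycle through edge {c.source}->{c.target}"
                )
        raise CyclicGenomeError("cycle detected")
    genome._topo_cache = tuple(order)
    return order


def forward(genome: Genome, weights, features) -> np.ndarray | float:
    """Evaluate the genome; returns probability of the positive class.

    Parameters
    ----------
    weights
        Either a scalar (shared-weight mode: the same value substituted into
        every enabled connection) or a vector of length
        ``count_connections(genome)`` indexed by ``weight_slot``.
    features
        One sample of ``n_inputs`` values, or a matrix (n_samples, n_inputs);
        evaluation is vectorized over samples.

    Nodes are evaluated in the unique topological order; each node's
    pre-activation is the weighted sum of its enabled incoming values,
    clamped to ±1e4. The bias node emits constant 1. Hidden nodes with no
    enabled incoming connection emit ``activation(0)``. The output node is
    always mapped through a sigmoid.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != genome.n_inputs:
        raise ValueError(
            f"expected {genome.n_inputs} features, got {X.shape[1]}"
        )
    enabled = genome.enabled_connections()
    if np.ndim(weights) == 0:
        w = np.full(len(enabled), float(weights))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(enabled),):
            raise ValueError(
                f"expected weight vector of length {len(enabled)}, got {w.shape}"
            )
    n = X.shape[0]
    order = topological_order(genome)
    roles = {nd.node_id: nd for nd in genome.nodes}
    incoming: dict[int, list[tuple[int, float]]] = {i: [] for i in order}
    for c in enabled:
        incoming[c.target].append((c.source, w[c.weight_slot]))

    values: dict[int, np.ndarray] = {}
    input_ids = genome.input_ids
    input_pos = {nid: k for k, nid in enumerate(input_ids)}
    out = None
    for nid in order:
        nd = roles[nid]
        if nd.role is NodeRole.INPUT:
            values[nid] = X[:, input_pos[nid]]
            continue
        if nd.role is NodeRole.BIAS:
            values[nid] = np.ones(n)
            continue
        pre = np.zeros(n)
        for src, wk in incoming[nid]:
            pre = pre + wk * values[src]
        np.clip(pre, -PREACT_CLIP, PREACT_CLIP, out=pre)
        if nd.role is NodeRole.OUTPUT:
            out = 1.0 / (1.0 + np.exp(-np.clip(pre, -500, 500)))
            values[nid] = out
        else:
            values[nid] = _ACTIVATIONS[nd.activation](pre)
    assert out is not None, "genome has no output node"
    return float(out[0]) if single else out


# -- serialization ---------------------------------------------------------


def genome_to_dict(genome: Genome, weights: Sequence[float] | None = None) -> dict:
    d = {
        "n_inputs": genome.n_inputs,
        "n_outputs": genome.n_outputs,
        "nodes": [
            {"node_id": n.node_id, "role": n.role.value, "activation": n.activation.value}
            for n in genome.nodes
        ],
        "connections": [
            {
                "conn_id": c.conn_id,
                "source": c.source,
                "target": c.target,
                "enabled": c.enabled,
                "weight_slot": c.weight_slot,
            }
            for c in genome.connections
        ],
    }
    if weights is not None:
        d["weights"] = [float(v) for v in weights]
    return d


def genome_from_dict(d: dict) -> tuple[Genome, np.ndarray | None]:
    g = Genome(
        nodes=[
            NodeGene(n["node_id"], NodeRole(n["role"]), ActivationKind(n["activation"]))
            for n in d["nodes"]
        ],
        connections=[
            ConnectionGene(
                c["conn_id"], c["source"], c["target"], c["enabled"], c["weight_slot"]
            )
            for c in d["connections"]
        ],
        n_inputs=d["n_inputs"],
        n_outputs=d["n_outputs"],
    )
    w = np.asarray(d["weights"], dtype=float) if "weights" in d else None
    return g, w


def save_genome(genome: Genome, path, weights: Sequence[float] | None = None) -> None:
    """Write the genome (and optionally trained weights) as JSON text."""
    Path(path).write_text(
        json.dumps(genome_to_dict(genome, weights), indent=1, sort_keys=True)
    )


def load_genome(path) -> tuple[Genome, np.ndarray | None]:
    """Round-trips bit-exactly with :func:`save_genome`."""
    return genome_from_dict(json.loads(Path(path).read_text()))
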