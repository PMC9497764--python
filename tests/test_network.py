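"""Genome representation, activation pool, and deterministic evaluation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)

from mwrnas.network import (
    ActivationKind,
    CyclicGenomeError,
    Genome,
    activation_apply,
    count_connections,
    forward,
    load_genome,
    save_genome,
    topological_order,
)
from mwrnas.wann import WannConfig, mutate

from conftest import make_genome

SIGMA_2 = 1.0 / (1.0 + math.exp(-2.0))  # 0.8807970779778823


@pytest.mark.parametrize(
    "kind, x, expected",
    [
        (ActivationKind.SIGMOID, 0.0, 0.5),
        (ActivationKind.BINARY_STEP, -0.3, 0.0),
        (ActivationKind.BINARY_STEP, 0.0, 1.0),
        (ActivationKind.GAUSSIAN, 1.0, math.exp(-1.0)),
        (ActivationKind.SQUARED, -2.0, 4.0),
        (ActivationKind.INVERSE, 3.0, -3.0),
        (ActivationKind.ABSOLUTE, -1.5, 1.5),
        (ActivationKind.RELU, -1.0, 0.0),
        (ActivationKind.LINEAR, 0.7, 0.7),
    ],
)
def test_activation_values(kind, x, expected):
    assert activation_apply(kind, x) == pytest.approx(expected, abs=1e-12)


def test_unknown_activation_rejected():
    with pytest.raises(ValueError):
        activation_apply("softplus", 1.0)


# closed ranges each activation must respect (a hair of float slack)
_RANGES = {
    ActivationKind.SIN: (-1, 1),
    ActivationKind.COSINE: (-1, 1),
    ActivationKind.SIGMOID: (0, 1),
    ActivationKind.GAUSSIAN: (0, 1),
    ActivationKind.TANH: (-1, 1),
    ActivationKind.ABSOLUTE: (0, np.inf),
    ActivationKind.RELU: (0, np.inf),
    ActivationKind.SQUARED: (0, np.inf),
    ActivationKind.BINARY_STEP: (0, 1),
}


def test_activation_ranges_random_inputs(rng):
    x = rng.uniform(-100, 100, size=100_000)
    for kind, (lo, hi) in _RANGES.items():
        out = activation_apply(kind, x)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12), kind
        assert np.all(np.isfinite(out)), kind


def test_activation_pool_has_eleven_members():
    assert len(ActivationKind) == 11


@settings(max_examples=200, derandomize=True)
@given(x=finite_floats)
def test_activation_ranges_hold_pointwise(x):
    for kind, (lo, hi) in _RANGES.items():
        v = activation_apply(kind, x)
        assert lo - 1e-12 <= v <= hi + 1e-12


@settings(max_examples=100, derandomize=True)
@given(w=st.floats(min_value=-3, max_value=3, allow_nan=False))
def test_forward_shared_scalar_equals_full_vector(w):
    g = make_genome([(0, 10), (1, 10), (10, 3), (2, 3)], n_inputs=2)
    X = np.array([[0.3, -1.2], [2.0, 0.1]])
    n = count_connections(g)
    assert np.array_equal(forward(g, w, X), forward(g, np.full(n, w), X))


# -- topological order -----------------------------------------------------


def _brute_force_orders(ids, edges):
    return [
        p
        for p in itertools.permutations(ids)
        if all(p.index(s) < p.index(t) for s, t in edges)
    ]


def test_topological_order_chain():
    g = make_genome([(0, 10), (10, 11), (11, 2)], n_inputs=2)
    order = topological_order(g)
    assert order.index(0) < order.index(10) < order.index(11) < order.index(2)


def test_topological_order_matches_brute_force_tiebreak(rng):
    # random DAGs on <= 8 nodes: the unique id-ascending tie-break must pick
    # the lexicographically smallest of all valid orders (enumerated by
    # brute force), mapped into the genome's hidden-node id space
    for _ in range(50):
        n = int(rng.integers(3, 9))
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.35
        ]
        if not edges:
            continue
        present = sorted({v for e in edges for v in e})
        all_orders = _brute_force_orders(present, edges)
        expected = min(all_orders)  # id-ascending tie-break == lexicographic min
        g = make_genome([(s + 100, t + 100) for s, t in edges], n_inputs=2)
        order = [nid - 100 for nid in topological_order(g) if nid >= 100]
        assert tuple(order) == expected


def test_cycle_raises():
    g = make_genome([(0, 45)], n_inputs=44)
    # splice a cycle between two hidden nodes by hand
    g2 = make_genome([(0, 10), (10, 11), (11, 10), (11, 2)], n_inputs=2)
    with pytest.raises(CyclicGenomeError):
        topological_order(g2)
    topological_order(g)  # the acyclic one is fine


# -- forward pass ----------------------------------------------------------


def test_forward_hand_values(one_link_genome):
    x0 = np.zeros(44)
    assert forward(one_link_genome, 1.0, x0) == pytest.approx(0.5, abs=1e-12)
    x1 = np.zeros(44)
    x1[0] = 1.0
    assert forward(one_link_genome, 2.0, x1) == pytest.approx(SIGMA_2, abs=1e-12)


def test_forward_disconnected_output_is_half():
    g = make_genome([], n_inputs=44)
    X = np.random.default_rng(0).normal(size=(5, 44))
    assert np.allclose(forward(g, 1.0, X), 0.5)
    assert count_connections(g) == 0


def test_forward_shared_equals_vector(one_link_genome, rng):
    X = rng.normal(size=(10, 44))
    for w in (-1.5, 0.3, 2.0):
        shared = forward(one_link_genome, w, X)
        vector = forward(one_link_genome, np.full(1, w), X)
        assert np.array_equal(shared, vector)


def test_forward_is_pure(one_link_genome, rng):
    X = rng.normal(size=(7, 44))
    a = forward(one_link_genome, 0.7, X)
    b = forward(one_link_genome, 0.7, X)
    assert np.array_equal(a, b)


def test_forward_shape_errors(one_link_genome):
    with pytest.raises(ValueError):
        forward(one_link_genome, 1.0, np.zeros(43))
    with pytest.raises(ValueError):
        forward(one_link_genome, np.zeros(2), np.zeros(44))


def test_hidden_node_without_inputs_emits_activation_of_zero():
    # hidden gaussian node with no incoming edge: gaussian(0) = 1 feeds output
    g = make_genome(
        [(10, 3)], n_inputs=2,
        activations={10: ActivationKind.GAUSSIAN},
    )
    # output pre-activation = w * gaussian(0) = w
    out = forward(g, 2.0, np.zeros(2))
    assert out == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), abs=1e-12)


# -- counting and serialization -------------------------------------------


def test_count_connections_after_add_node_split(rng):
    g = make_genome([(0, 45)], n_inputs=44)
    cfg = WannConfig(p_change_activation=0.0, p_add_node=1.0, p_add_connection=0.0)
    child = mutate(g, cfg, rng)
    assert count_connections(child) == 2  # split: disable old, add two
    assert len(child.connections) == 3  # the disabled one is retained
    assert len(child.nodes) == len(g.nodes) + 1


def test_serialization_round_trip(tmp_path, rng):
    g = make_genome(
        [(0, 10), (1, 10), (10, 3), (2, 3)],
        n_inputs=2,
        activations={10: ActivationKind.TANH},
    )
    w = rng.normal(size=count_connections(g))
    path = tmp_path / "genome.json"
    save_genome(g, path, weights=w)
    g2, w2 = load_genome(path)
    assert np.array_equal(w, w2)
    assert g2.n_inputs == g.n_inputs
    assert [(n.node_id, n.role, n.activation) for n in g2.nodes] == [
        (n.node_id, n.role, n.activation) for n in g.nodes
    ]
    assert g2.connections == g.connections
    X = rng.normal(size=(4, 2))
    assert np.array_equal(forward(g, w, X), forward(g2, w2, X))
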