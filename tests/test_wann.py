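"""Topology evolution: mutations, shared-weight fitness, ranking, selection."""

import itertools
import math

import numpy as np
import pytest

from mwrnas.network import CyclicGenomeError, count_connections, topological_order
from mwrnas.wann import (
    FitnessRecord,
    UndefinedMetricError,
    WannConfig,
    apply_mutation,
    evaluate_genome,
    gmean_fitness,
    init_population,
    mutate,
    nsga2_rank,
    run_wann_search,
    tournament_select,
)

from conftest import make_genome, xor_data


# -- config ----------------------------------------------------------------


def test_config_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        WannConfig(p_change_activation=0.5, p_add_node=0.5, p_add_connection=0.5)
    with pytest.raises(ValueError):
        WannConfig(shared_weights=(1.0, 0.0))


# -- population initialization --------------------------------------------


@pytest.mark.parametrize("fraction, expected", [(0.0, 0), (1.0, 45)])
def test_init_population_extreme_fractions(fraction, expected, rng):
    cfg = WannConfig(population_size=20, initial_active_fraction=fraction)
    pop = init_population(cfg, 44, 1, rng)
    assert len(pop) == 20
    assert all(count_connections(g) == expected for g in pop)
    assert all(not g.hidden_ids for g in pop)


def test_init_population_enabled_fraction_matches_binomial(rng):
    cfg = WannConfig(population_size=200, initial_active_fraction=0.2)
    pop = init_population(cfg, 44, 1, rng)
    frac = np.mean([count_connections(g) / 45 for g in pop])
    assert frac == pytest.approx(0.2, abs=0.02)


# -- mutation --------------------------------------------------------------


def test_add_node_split_structure(rng):
    g = make_genome([(0, 45)], n_inputs=44)
    cfg = WannConfig(p_change_activation=0.0, p_add_node=1.0, p_add_connection=0.0)
    child, sampled, applied = apply_mutation(g, cfg, rng)
    assert (sampled, applied) == ("add_node", "add_node")
    assert len(child.nodes) == len(g.nodes) + 1
    assert count_connections(child) == 2
    # original untouched
    assert count_connections(g) == 1 and len(g.nodes) == 46


def test_fallback_when_operator_inapplicable(rng):
    # no hidden nodes: change_activation must fall back to add_connection
    g = make_genome([(0, 45)], n_inputs=44)
    cfg = WannConfig(p_change_activation=1.0, p_add_node=0.0, p_add_connection=0.0)
    child, sampled, applied = apply_mutation(g, cfg, rng)
    assert sampled == "change_activation"
    assert applied == "add_connection"
    assert count_connections(child) == 2


def test_fully_saturated_genome_falls_back_to_identity(rng):
    # single input directly wired to the output, nothing else possible:
    # n_inputs=1 gives sources {input0, bias}, both already connected
    g = make_genome([(0, 2), (1, 2)], n_inputs=1)
    cfg = WannConfig(p_change_activation=0.0, p_add_node=0.0, p_add_connection=1.0)
    child, sampled, applied = apply_mutation(g, cfg, rng)
    assert sampled == "add_connection"
    assert applied in ("add_node", "identity")  # add-connection impossible


def test_mutation_chain_invariants(rng):
    """Mutations never decrease the enabled count and never create cycles."""
    cfg = WannConfig(population_size=1)
    for _ in range(40):
        g = init_population(cfg, 8, 1, rng)[0]
        prev = count_connections(g)
        for _ in range(25):
            g = mutate(g, cfg, rng)
            now = count_connections(g)
            assert now >= prev
            prev = now
            topological_order(g)  # raises on a cycle
            g.validate()


def test_operator_frequencies(rng):
    cfg = WannConfig()
    g = make_genome([(0, 10), (1, 10), (10, 3)], n_inputs=2)
    counts = {"change_activation": 0, "add_node": 0, "add_connection": 0}
    n = 3000
    for _ in range(n):
        _, sampled, _ = apply_mutation(g, cfg, rng)
        counts[sampled] += 1
    assert counts["change_activation"] / n == pytest.approx(0.5, abs=0.03)
    assert counts["add_node"] / n == pytest.approx(0.25, abs=0.03)
    assert counts["add_connection"] / n == pytest.approx(0.25, abs=0.03)


# -- G-mean ----------------------------------------------------------------


@pytest.mark.parametrize(
    "y, p, expected",
    [
        ([1, 1, 0, 0], [1, 1, 0, 0], 1.0),
        ([1, 1, 0, 0], [1, 1, 1, 1], 0.0),
        # TP=3 FN=1 TN=2 FP=2 -> sqrt(0.75 * 0.5)
        ([1, 1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 0, 1, 1, 0, 0], math.sqrt(0.375)),
    ],
)
def test_gmean_hand_values(y, p, expected):
    assert gmean_fitness(y, p) == pytest.approx(expected, abs=1e-12)


def test_gmean_single_class_rejected():
    with pytest.raises(UndefinedMetricError):
        gmean_fitness([1, 1, 1], [1, 0, 1])


def test_gmean_permutation_invariant(rng):
    y = rng.integers(0, 2, size=50)
    y[:2] = [0, 1]
    p = rng.integers(0, 2, size=50)
    perm = rng.permutation(50)
    assert gmean_fitness(y, p) == pytest.approx(gmean_fitness(y[perm], p[perm]))


# -- genome evaluation -----------------------------------------------------


def test_evaluate_zero_connection_genome_scores_zero():
    g = make_genome([], n_inputs=44)
    X = np.zeros((4, 44))
    y = np.array([0, 0, 1, 1])
    rec = evaluate_genome(g, X, y)
    # constant 0.5 -> everything predicted positive -> specificity 0
    assert rec == FitnessRecord(0.0, 0.0, 0)


def test_evaluate_matches_manual_per_weight(one_link_genome):
    from mwrnas.network import forward

    X = np.zeros((4, 44))
    X[:, 0] = [-2.0, -0.5, 0.5, 2.0]
    y = np.array([0, 0, 1, 1])
    weights = (-1.0, 1.0)
    rec = evaluate_genome(one_link_genome, X, y, weights)
    manual = []
    for w in weights:
        preds = (forward(one_link_genome, w, X) >= 0.5).astype(int)
        manual.append(gmean_fitness(y, preds))
    assert rec.mean_perf == pytest.approx(np.mean(manual))
    assert rec.best_perf == pytest.approx(np.max(manual))
    assert rec.best_perf >= rec.mean_perf
    assert rec.n_connections == 1


# -- NSGA-II ---------------------------------------------------------------


def _brute_force_fronts(records):
    """Independent oracle: peel non-dominated layers by pairwise dominance."""

    def dominates(a, b):
        av = (a.mean_perf, a.best_perf, -a.n_connections)
        bv = (b.mean_perf, b.best_perf, -b.n_connections)
        return all(x >= y for x, y in zip(av, bv)) and av != bv

    remaining = set(range(len(records)))
    fronts = np.empty(len(records), dtype=int)
    level = 0
    while remaining:
        layer = {
            i
            for i in remaining
            if not any(dominates(records[j], records[i]) for j in remaining if j != i)
        }
        for i in layer:
            fronts[i] = level
        remaining -= layer
        level += 1
    return fronts


def test_nsga2_hand_examples():
    dominated = [FitnessRecord(0.9, 0.95, 10), FitnessRecord(0.8, 0.85, 20)]
    fronts, _ = nsga2_rank(dominated)
    assert list(fronts) == [0, 1]
    tradeoff = [FitnessRecord(0.9, 0.95, 20), FitnessRecord(0.8, 0.85, 10)]
    fronts, _ = nsga2_rank(tradeoff)
    assert list(fronts) == [0, 0]


def test_nsga2_matches_brute_force_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(2, 51))
        records = [
            FitnessRecord(
                float(rng.choice([0.1, 0.5, 0.9, rng.random()])),
                float(rng.random()),
                int(rng.integers(0, 30)),
            )
            for _ in range(n)
        ]
        records = [
            FitnessRecord(r.mean_perf, max(r.mean_perf, r.best_perf), r.n_connections)
            for r in records
        ]
        fronts, _ = nsga2_rank(records)
        assert np.array_equal(fronts, _brute_force_fronts(records))


def test_crowding_boundaries_infinite():
    # better performance costs more connections: mutually non-dominated
    records = [FitnessRecord(0.1 * k, 0.1 * k, k) for k in range(1, 8)]
    fronts, crowding = nsga2_rank(records)
    assert np.all(fronts == 0)
    assert np.isinf(crowding[0]) and np.isinf(crowding[-1])
    assert np.all(np.isfinite(crowding[1:-1]))


# -- tournament ------------------------------------------------------------


def test_tournament_population_of_one(rng):
    g = make_genome([(0, 45)], n_inputs=44)
    picked = tournament_select([g], (np.zeros(1), np.zeros(1)), 4, rng)
    assert picked is g


def test_tournament_prefers_lower_front(rng):
    pop = [make_genome([(0, 45)], n_inputs=44) for _ in range(8)]
    fronts = np.array([2, 2, 2, 0, 2, 2, 2, 2])
    crowding = np.zeros(8)
    wins = sum(
        tournament_select(pop, (fronts, crowding), 50, rng) is pop[3]
        for _ in range(50)
    )
    # 50 draws with replacement from 8: index 3 enters the tournament (and
    # then wins) with probability 1 - (7/8)^50 > 0.998
    assert wins >= 48


def test_tournament_frequencies_match_enumeration(rng):
    """Selection frequencies over many tournaments match the exact
    distribution computed by enumerating all size-2 draws."""
    pop = [make_genome([(0, 45)], n_inputs=44) for _ in range(3)]
    fronts = np.array([1, 0, 2])
    crowding = np.array([0.0, 0.0, 0.0])
    n_draw = 20_000
    counts = np.zeros(3)
    for _ in range(n_draw):
        g = tournament_select(pop, (fronts, crowding), 2, rng)
        counts[next(i for i, x in enumerate(pop) if x is g)] += 1
    # enumerate all 9 equally likely ordered draws; winner = best front,
    # ties by lower index
    exact = np.zeros(3)
    for i, j in itertools.product(range(3), repeat=2):
        w = min((fronts[i], i), (fronts[j], j))[1]
        exact[w] += 1 / 9
    assert np.allclose(counts / n_draw, exact, atol=0.02)


# -- search loop -----------------------------------------------------------


def test_search_zero_generations_returns_initial_best(rng):
    X, y = xor_data(60, rng)
    cfg = WannConfig(generations=0, population_size=8, seed=3)
    best, history = run_wann_search(cfg, (X, y), (X, y))
    assert len(history) == 1
    assert not best.hidden_ids  # no mutation ever ran


def test_search_beats_chance_on_separable_task(rng):
    # linearly separable: y = 1 iff x0 > 0
    X = rng.uniform(-1, 1, size=(200, 2))
    y = (X[:, 0] > 0).astype(int)
    Xv = rng.uniform(-1, 1, size=(80, 2))
    yv = (Xv[:, 0] > 0).astype(int)
    cfg = WannConfig(generations=30, population_size=64, seed=7)
    best, history = run_wann_search(cfg, (X, y), (Xv, yv))
    rec = evaluate_genome(best, Xv, yv)
    assert rec.mean_perf > 0.5
    assert len(history) <= 30


def test_search_is_deterministic(rng):
    X, y = xor_data(80, rng)
    cfg = dict(generations=5, population_size=16, seed=11)
    best1, h1 = run_wann_search(WannConfig(**cfg), (X, y), (X, y))
    best2, h2 = run_wann_search(WannConfig(**cfg), (X, y), (X, y))
    assert best1.connections == best2.connections
    assert [(n.node_id, n.activation) for n in best1.nodes] == [
        (n.node_id, n.activation) for n in best2.nodes
    ]
    assert h1 == h2
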