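import numpy as np
import pytest

from mwrnas.network import (
    ActivationKind,
    ConnectionGene,
    Genome,
    NodeGene,
    NodeRole,
)
from mwrnas.wann import _base_nodes


def make_genome(edges, n_inputs=2, n_outputs=1, activations=None, disabled=()):
    """Small genome builder for tests.

    ``edges`` is a list of (source, target) over node ids: inputs are
    0..n_inputs-1, bias is n_inputs, outputs follow, hidden ids above that.
    Hidden nodes referenced by edges are created automatically with linear
    activation unless ``activations`` overrides them.
    """
    activations = activations or {}
    nodes = _base_nodes(n_inputs, n_outputs)
    known = {n.node_id for n in nodes}
    for s, t in edges:
        for nid in (s, t):
            if nid not in known:
                nodes.append(
                    NodeGene(nid, NodeRole.HIDDEN,
                             activations.get(nid, ActivationKind.LINEAR))
                )
                known.add(nid)
    conns = [
        ConnectionGene(k, s, t, (s, t) not in disabled, -1)
        for k, (s, t) in enumerate(edges)
    ]
    g = Genome(nodes=nodes, connections=conns, n_inputs=n_inputs, n_outputs=n_outputs)
    g.compact_slots()
    return g


@pytest.fixture
def one_link_genome():
    """input0 -> output, 44 inputs (the MWR geometry)."""
    return make_genome([(0, 45)], n_inputs=44)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def xor_data(n, rng):
    """2-feature task where the classes are the product-sign quadrants."""
    X = rng.uniform(-1, 1, size=(n, 2))
    y = ((X[:, 0] * X[:, 1]) > 0).astype(int)
    return X, y
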