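import numpy as np
import pytest

from hbnet.bayesnet import DAGStructure, DiscreteBayesNet
from hbnet.synth import CausalSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_net(n_nodes: int, rng: np.random.Generator, p_arc: float = 0.3,
               max_card: int = 3) -> DiscreteBayesNet:
    """Random DAG + random strictly positive CPTs (canonical node order)."""
    labels = [f"n{i:02d}" for i in range(n_nodes)]
    arcs = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_arc:
                arcs.add((labels[i], labels[j]))
    cards = {l: int(rng.integers(2, max_card + 1)) for l in labels}
    dag = DAGStructure(labels, arcs)
    cpts = {}
    for l in labels:
        shape = tuple(cards[p] for p in dag.parents_of(l)) + (cards[l],)
        raw = rng.random(shape) + 0.05
        cpts[l] = raw / raw.sum(-1, keepdims=True)
    return DiscreteBayesNet(dag, cards, cpts)


def joint_tensor(net: DiscreteBayesNet) -> np.ndarray:
    """Full joint distribution as a dense tensor (independent oracle).

    Built by broadcasting CPT factors into the full-rank tensor product,
    with no variable elimination involved.
    """
    labels = net.nodes
    axis = {l: k for k, l in enumerate(labels)}
    shape = tuple(net.cards[l] for l in labels)
    joint = np.ones(shape)
    for l in labels:
        dims = [axis[p] for p in net.structure.parents_of(l)] + [axis[l]]
        expand = [1] * len(labels)
        for d in dims:
            expand[d] = shape[d]
        perm = np.argsort(dims)
        cpt = np.transpose(net.cpts[l], perm) if len(dims) > 1 else net.cpts[l]
        joint = joint * cpt.reshape(expand)
    return joint


def enum_marginals(net: DiscreteBayesNet, evidence=None):
    """Conditional marginals from the dense joint tensor."""
    evidence = dict(evidence or {})
    joint = joint_tensor(net)
    labels = net.nodes
    for node, value in evidence.items():
        k = labels.index(node)
        sl = [slice(None)] * joint.ndim
        mask = np.zeros(net.cards[node])
        mask[value] = 1.0
        shape = [1] * joint.ndim
        shape[k] = net.cards[node]
        joint = joint * mask.reshape(shape)
    z = joint.sum()
    out = {}
    for k, node in enumerate(labels):
        axes = tuple(a for a in range(joint.ndim) if a != k)
        out[node] = joint.sum(axis=axes) / z
    return out, z


@pytest.fixture
def chain_spec():
    """Three-node causal chain a -> b -> c with strong links."""
    return CausalSpec.from_simple(
        arcs=[("a", "b"), ("b", "c")],
        cpts={
            "a": np.array([0.4, 0.6]),
            "b": np.array([[0.85, 0.15], [0.15, 0.85]]),
            "c": np.array([[0.9, 0.1], [0.1, 0.9]]),
        },
    )
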