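"""Discrete Bayesian networks: structures, parameters, exact inference.

The network variables are H-bond node counts (small integer ranges).  CPTs
are stored as dense arrays with parent axes first and the child axis last.
Inference is exact, by variable elimination with barren-node pruning and a
min-fill elimination order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DAGStructure",
    "DiscreteBayesNet",
    "Evidence",
    "ImpossibleEvidenceError",
    "fit_parameters",
    "infer_marginals",
    "loglik_frame",
]


class ImpossibleEvidenceError(ValueError):
    """The evidence has probability zero under the network."""


@dataclass
class DAGStructure:
    """Node labels plus a set of directed arcs (ordered label pairs)."""

    nodes: list[str]
    arcs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for u, v in self.arcs:
            if u not in known or v not in known:
                raise ValueError(f"arc ({u}, {v}) references unknown node")
        if not self.is_acyclic():
            raise ValueError("structure contains a directed cycle")

    def parents_of(self, node: str) -> list[str]:
        return sorted(u for (u, v) in self.arcs if v == node)

    def children_of(self, node: str) -> list[str]:
        return sorted(v for (u, v) in self.arcs if u == node)

    def is_acyclic(self) -> bool:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for u, v in self.arcs:
            children[u].append(v)
            indeg[v] += 1
        stack = [n for n in self.nodes if indeg[n] == 0]
        seen = 0
        while stack:
            n = stack.pop()
            seen += 1
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        return seen == len(self.nodes)

    def topological_order(self) -> list[str]:
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        indeg = {n: 0 for n in self.nodes}
        for u, v in self.arcs:
            children[u].append(v)
            indeg[v] += 1
        stack = sorted((n for n in self.nodes if indeg[n] == 0), reverse=True)
        order = []
        while stack:
            n = stack.pop()
            order.append(n)
            for c in sorted(children[n], reverse=True):
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        return order

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self.arcs):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


Evidence = Mapping[str, int]


@dataclass
class DiscreteBayesNet:
    """A DAG plus posterior-mean CPTs over integer-valued nodes.

    ``cards[label]`` is the number of states of a node (counts 0..card-1).
    ``cpts[label]`` has shape ``(*parent_cards, card)`` with parents in the
    order given by ``structure.parents_of(label)``.
    """

    structure: DAGStructure
    cards: dict[str, int]
    cpts: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.structure.nodes:
            cpt = self.cpts[label]
            parents = self.structure.parents_of(label)
            expected = tuple(self.cards[p] for p in parents) + (self.cards[label],)
            if cpt.shape != expected:
                raise ValueError(f"CPT shape mismatch for {label}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of {label} must sum to 1")
            if (cpt < 0).any():
                raise ValueError(f"CPT of {label} has negative entries")

    @property
    def nodes(self) -> list[str]:
        return self.structure.nodes

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {"label": n, "cardinality": self.cards[n]} for n in self.nodes
            ],
            "arcs": sorted(list(a) for a in self.structure.arcs),
            "cpts": {n: self.cpts[n].tolist() for n in self.nodes},
            "training_meta": self.training_meta,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesNet":
        payload = json.loads(text)
        nodes = [n["label"] for n in payload["nodes"]]
        cards = {n["label"]: int(n["cardinality"]) for n in payload["nodes"]}
        structure = DAGStructure(nodes, {tuple(a) for a in payload["arcs"]})
        cpts = {n: np.asarray(payload["cpts"][n], dtype=float) for n in nodes}
        return cls(structure, cards, cpts, payload.get("training_meta", {}))


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------


def fit_parameters(
    dag: DAGStructure,
    data: np.ndarray,
    labels: Sequence[str],
    cards: Mapping[str, int],
    iss: float = 5.0,
    training_meta: Optional[dict] = None,
) -> DiscreteBayesNet:
    """Bayesian (posterior-mean) CPT estimation with imaginary sample size.

    theta_ijk = (N_ijk + iss/(r_i q_i)) / (N_ij + iss/q_i); with no data
    for a parent configuration this reduces to a uniform distribution.
    """
    col = {lab: i for i, lab in enumerate(labels)}
    cpts: dict[str, np.ndarray] = {}
    for node in dag.nodes:
        parents = dag.parents_of(node)
        r = cards[node]
        pc = [cards[p] for p in parents]
        q = int(np.prod(pc)) if pc else 1
        shape = tuple(pc) + (r,)
        counts = np.zeros(shape, dtype=float)
        if data.shape[0]:
            idx = tuple(data[:, col[p]] for p in parents) + (data[:, col[node]],)
            np.add.at(counts, idx, 1.0)
        alpha = iss / (r * q)
        num = counts + alpha
        cpts[node] = num / num.sum(axis=-1, keepdims=True)
    return DiscreteBayesNet(
        structure=DAGStructure(list(dag.nodes), set(dag.arcs)),
        cards=dict(cards),
        cpts=cpts,
        training_meta=training_meta or {"n_samples": int(data.shape[0]), "iss": iss},
    )


def loglik_frame(net: DiscreteBayesNet, assignment: Mapping[str, int]) -> float:
    """Log-probability of one complete frame under the network."""
    total = 0.0
    for node in net.nodes:
        parents = net.structure.parents_of(node)
        idx = tuple(assignment[p] for p in parents) + (assignment[node],)
        total += float(np.log(net.cpts[node][idx]))
    return total


# ---------------------------------------------------------------------------
# Exact inference (variable elimination)
# ---------------------------------------------------------------------------


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        all_vars = list(self.vars) + [v for v in other.vars if v not in self.vars]
        def expand(f: "_Factor") -> np.ndarray:
            shape = [1] * len(all_vars)
            perm = [f.vars.index(v) for v in all_vars if v in f.vars]
            arr = np.transpose(f.values, perm) if f.vars else f.values
            for i, v in enumerate(all_vars):
                if v in f.vars:
                    shape[i] = arr.shape[[v2 for v2 in all_vars if v2 in f.vars].index(v)]
            return arr.reshape(shape)
        return _Factor(tuple(all_vars), expand(self) * expand(other))

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        new_vars = tuple(v for v in self.vars if v != var)
        return _Factor(new_vars, self.values.sum(axis=axis))

    def reduce(self, var: str, value: int) -> "_Factor":
        axis = self.vars.index(var)
        new_vars = tuple(v for v in self.vars if v != var)
        return _Factor(new_vars, np.take(self.values, value, axis=axis))


def _relevant_nodes(net: DiscreteBayesNet, keep: set[str]) -> set[str]:
    """Drop barren nodes: non-kept nodes with no kept descendants."""
    relevant = set(keep)
    changed = True
    while changed:
        changed = False
        for node in net.nodes:
            if node in relevant:
                continue
            if any(c in relevant for c in net.structure.children_of(node)):
                relevant.add(node)
                changed = True
    # ancestors of kept nodes are always needed
    stack = list(relevant)
    while stack:
        node = stack.pop()
        for p in net.structure.parents_of(node):
            if p not in relevant:
                relevant.add(p)
                stack.append(p)
    return relevant


def _min_fill_order(factors: list[_Factor], to_eliminate: set[str]) -> list[str]:
    adjacency: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            adjacency.setdefault(v, set()).update(set(f.vars) - {v})
    order = []
    remaining = set(to_eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = [n for n in adjacency.get(v, set()) if n != v]
            fill = sum(
                1
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if b not in adjacency.get(a, set())
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        nbrs = adjacency.get(best, set())
        for a in nbrs:
            adjacency[a] = (adjacency[a] | nbrs) - {a, best}
            adjacency[a].discard(best)
        adjacency.pop(best, None)
        remaining.discard(best)
    return order


def _eliminate(factors: list[_Factor], order: list[str]) -> list[_Factor]:
    factors = list(factors)
    for var in order:
        touched = [f for f in factors if var in f.vars]
        if not touched:
            continue
        factors = [f for f in factors if var not in f.vars]
        prod = touched[0]
        for f in touched[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize(var))
    return factors


def infer_marginals(
    net: DiscreteBayesNet, evidence: Optional[Evidence] = None
) -> dict[str, np.ndarray]:
    """Exact conditional marginal P(X_i | evidence) for every node.

    Evidence nodes are returned as point masses.  Raises
    :class:`ImpossibleEvidenceError` if the evidence has zero probability.
    """
    evidence = dict(evidence or {})
    for node, value in evidence.items():
        if node not in net.cards:
            raise KeyError(f"evidence node {node!r} not in network")
        if not 0 <= value < net.cards[node]:
            raise ValueError(f"evidence value {value} outside range of {node}")
    out: dict[str, np.ndarray] = {}
    for node, value in evidence.items():
        mass = np.zeros(net.cards[node])
        mass[value] = 1.0
        out[node] = mass
    query_nodes = [n for n in net.nodes if n not in evidence]
    if not query_nodes:
        return out

    relevant = _relevant_nodes(net, keep=set(query_nodes) | set(evidence))
    base_factors: dict[str, _Factor] = {}
    for node in net.nodes:
        if node not in relevant:
            continue
        parents = net.structure.parents_of(node)
        f = _Factor(tuple(parents) + (node,), net.cpts[node])
        for ev_node, ev_val in evidence.items():
            if ev_node in f.vars:
                f = f.reduce(ev_node, ev_val)
        base_factors[node] = f

    for node in query_nodes:
        keep = _relevant_nodes(net, keep={node} | set(evidence))
        factors = [f for owner, f in base_factors.items() if owner in keep]
        to_elim = {v for f in factors for v in f.vars} - {node}
        order = _min_fill_order(factors, to_elim)
        remaining = _eliminate(factors, order)
        result = remaining[0]
        for f in remaining[1:]:
            result = result.multiply(f)
        z = result.values.sum()
        if z <= 0:
            raise ImpossibleEvidenceError("evidence has zero probability")
        out[node] = result.values.reshape(net.cards[node]) / z
    return out
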