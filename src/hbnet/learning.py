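"""Hybrid structure learning: constraint-based restrict + score-based search.

The restrict phase runs Semi-Interleaved HITON-PC with a shrinking
candidate queue per target, testing conditional independence with a
mutual-information G² statistic whose null degrees of freedom are
estimated semi-parametrically (mean of the statistic over within-stratum
permutations, then a χ² tail).  The maximize phase is a tabu search over
skeleton-consistent arcs scoring structures with the Bayesian Dirichlet
equivalent uniform (BDe) marginal likelihood.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .bayesnet import DAGStructure
from .hbonds import ArcBlacklist, OccupancyTable

__all__ = [
    "LearningConfig",
    "g2_statistic",
    "semiparametric_ci_test",
    "restrict_skeleton",
    "bde_score",
    "family_bde_score",
    "maximize_structure",
    "learn_structure",
]


@dataclass
class LearningConfig:
    """Knobs of the two-phase learner.

    alpha: type-I error threshold of the independence tests.
    iss:   imaginary sample size of the BDe Dirichlet prior.
    tabu_length: number of recently visited structures kept forbidden.
    max_nonimproving: tabu iterations without improvement before stopping.
    permutations_for_df: permutations used to estimate the null df.
    max_cond_set: largest conditioning-set size tried inside HITON-PC.
    """

    alpha: float = 0.01
    iss: float = 5.0
    tabu_length: int = 50
    max_nonimproving: int = 50
    permutations_for_df: int = 100
    max_cond_set: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.iss <= 0:
            raise ValueError("iss must be positive")


# ---------------------------------------------------------------------------
# Independence testing
# ---------------------------------------------------------------------------


def g2_statistic(
    x: np.ndarray, y: np.ndarray, strata: np.ndarray, cx: int, cy: int, ns: int
) -> float:
    """G² = 2N * conditional mutual information, over ``strata`` of Z."""
    joint = np.bincount(
        (strata * cx + x) * cy + y, minlength=ns * cx * cy
    ).reshape(ns, cx, cy).astype(float)
    nz = joint.sum(axis=(1, 2), keepdims=True)
    nxz = joint.sum(axis=2, keepdims=True)
    nyz = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint * nz / (nxz * nyz)
        terms = joint * np.log(ratio)
    return float(2.0 * np.nansum(terms[joint > 0]))


def semiparametric_ci_test(
    data: np.ndarray,
    cards: np.ndarray,
    i: int,
    j: int,
    cond: Sequence[int],
    rng: np.random.Generator,
    n_perm: int = 100,
) -> tuple[float, float]:
    """Test X_i independent of X_j given X_cond; returns (statistic, p).

    The χ² degrees of freedom are not taken from the nominal contingency
    dimensions but estimated as the mean of the statistic over random
    permutations of X_j within each conditioning stratum, which is robust
    to sparse strata.
    """
    x = data[:, i]
    y = data[:, j]
    cx, cy = int(cards[i]), int(cards[j])
    if cond:
        strata = np.zeros(len(x), dtype=np.int64)
        ns = 1
        for k in cond:
            strata = strata * int(cards[k]) + data[:, k]
            ns *= int(cards[k])
    else:
        strata = np.zeros(len(x), dtype=np.int64)
        ns = 1
    stat = g2_statistic(x, y, strata, cx, cy, ns)
    # permute y within strata to sample the null
    order = np.argsort(strata, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    y_sorted = y[order]
    boundaries = np.flatnonzero(np.diff(strata[order])) + 1
    null_stats = np.empty(n_perm)
    for b in range(n_perm):
        perm_sorted = y_sorted.copy()
        start = 0
        for end in list(boundaries) + [len(y_sorted)]:
            if end - start > 1:
                perm_sorted[start:end] = rng.permutation(perm_sorted[start:end])
            start = end
        null_stats[b] = g2_statistic(x, perm_sorted[inv], strata, cx, cy, ns)
    df = float(null_stats.mean())
    if df < 1e-9:
        return stat, 1.0 if stat < 1e-9 else 0.0
    return stat, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Restrict phase: Semi-Interleaved HITON-PC
# ---------------------------------------------------------------------------


def _table_matrix(table: OccupancyTable) -> tuple[np.ndarray, list[str], np.ndarray]:
    data = table.counts.to_numpy(dtype=np.int64)
    labels = table.labels
    cards = data.max(axis=0) + 1
    return data, labels, cards


def restrict_skeleton(
    table: OccupancyTable,
    blacklist: Optional[ArcBlacklist] = None,
    config: Optional[LearningConfig] = None,
) -> set[frozenset]:
    """Candidate undirected skeleton via Semi-Interleaved HITON-PC.

    Per target, candidates are ranked by marginal association and admitted
    only if no conditioning subset of the current parent-children set (up
    to ``max_cond_set``) renders them independent of the target; a final
    backward pass re-checks every member.  The skeleton keeps an edge only
    when each endpoint recovers the other (AND symmetry), and blacklisted
    pairs are never tested.
    """
    config = config or LearningConfig()
    data, labels, cards = _table_matrix(table)
    n_nodes = len(labels)
    rng = np.random.default_rng(config.seed)
    constant = [
        i for i in range(n_nodes) if data[:, i].min() == data[:, i].max()
    ]
    if constant:
        warnings.warn(
            f"{len(constant)} constant node(s) excluded from skeleton search",
            stacklevel=2,
        )
    cache: dict[tuple, tuple[float, float]] = {}

    def test(i: int, j: int, cond: tuple[int, ...]) -> tuple[float, float]:
        key = (min(i, j), max(i, j), frozenset(cond))
        if key not in cache:
            cache[key] = semiparametric_ci_test(
                data, cards, i, j, list(cond), rng, config.permutations_for_df
            )
        return cache[key]

    def is_blacklisted(i: int, j: int) -> bool:
        return blacklist is not None and (labels[i], labels[j]) in blacklist

    def independent_given_subset(t: int, v: int, pool: list[int]) -> bool:
        for size in range(0, min(config.max_cond_set, len(pool)) + 1):
            for subset in combinations(pool, size):
                _, p = test(t, v, subset)
                if p > config.alpha:
                    return True
        return False

    pc_sets: dict[int, set[int]] = {}
    for t in range(n_nodes):
        if t in constant:
            pc_sets[t] = set()
            continue
        cands = []
        for v in range(n_nodes):
            if v == t or v in constant or is_blacklisted(t, v):
                continue
            stat, p = test(t, v, ())
            if p <= config.alpha:
                cands.append((stat, v))
        cands.sort(key=lambda sv: (-sv[0], sv[1]))
        pc: list[int] = []
        for _, v in cands:
            if not independent_given_subset(t, v, pc):
                pc.append(v)
        # backward re-check against the final set
        for v in list(pc):
            pool = [u for u in pc if u != v]
            if independent_given_subset(t, v, pool):
                pc.remove(v)
        pc_sets[t] = set(pc)

    skeleton: set[frozenset] = set()
    for t in range(n_nodes):
        for v in pc_sets[t]:
            if t in pc_sets[v]:
                skeleton.add(frozenset((labels[t], labels[v])))
    return skeleton


# ---------------------------------------------------------------------------
# BDe scoring
# ---------------------------------------------------------------------------


def family_bde_score(
    data: np.ndarray,
    cards: np.ndarray,
    child: int,
    parents: tuple[int, ...],
    iss: float,
) -> float:
    """BDeu marginal log-likelihood of one family (child given parents)."""
    r = int(cards[child])
    q = int(np.prod([cards[p] for p in parents])) if parents else 1
    pidx = np.zeros(data.shape[0], dtype=np.int64)
    for p in parents:
        pidx = pidx * int(cards[p]) + data[:, p]
    joint = np.bincount(pidx * r + data[:, child], minlength=q * r).reshape(q, r)
    nij = joint.sum(axis=1)
    a_ijk = iss / (r * q)
    a_ij = iss / q
    score = float(
        np.sum(gammaln(a_ij) - gammaln(a_ij + nij))
        + np.sum(gammaln(a_ijk + joint) - gammaln(a_ijk))
    )
    return score


def bde_score(
    dag: DAGStructure,
    table: OccupancyTable,
    iss: float = 5.0,
) -> float:
    """Decomposable BDe log score of a DAG on the occupancy data."""
    data, labels, cards = _table_matrix(table)
    col = {lab: i for i, lab in enumerate(labels)}
    total = 0.0
    for node in dag.nodes:
        parents = tuple(sorted(col[p] for p in dag.parents_of(node)))
        total += family_bde_score(data, cards, col[node], parents, iss)
    return total


# ---------------------------------------------------------------------------
# Maximize phase: tabu search
# ---------------------------------------------------------------------------


def _creates_cycle(parents: dict[int, set[int]], u: int, v: int) -> bool:
    """Would adding u -> v close a cycle (i.e. is u reachable from v)?"""
    children: dict[int, set[int]] = {}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(child)
    stack, seen = [v], set()
    while stack:
        n = stack.pop()
        if n == u:
            return True
        if n in seen:
            continue
        seen.add(n)
        stack.extend(children.get(n, ()))
    return False


def maximize_structure(
    table: OccupancyTable,
    skeleton: set[frozenset],
    blacklist: Optional[ArcBlacklist] = None,
    config: Optional[LearningConfig] = None,
) -> DAGStructure:
    """Tabu search over orientations/subsets of skeleton edges.

    Moves are single-arc add/delete/reverse, restricted to the skeleton
    minus the blacklist; the tabu list stores hashes of recently visited
    structures.  The search starts from the empty graph and returns the
    best structure seen, so its score is never below the empty graph's.
    """
    config = config or LearningConfig()
    data, labels, cards = _table_matrix(table)
    n = len(labels)
    col = {lab: i for i, lab in enumerate(labels)}
    allowed: set[tuple[int, int]] = set()
    for pair in skeleton:
        a, b = sorted(pair)
        if blacklist is not None and (a, b) in blacklist:
            continue
        allowed.add((col[a], col[b]))
        allowed.add((col[b], col[a]))

    family_cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(child: int, parents: frozenset) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in family_cache:
            family_cache[key] = family_bde_score(
                data, cards, child, key[1], config.iss
            )
        return family_cache[key]

    parents: dict[int, set[int]] = {i: set() for i in range(n)}
    score = sum(family(i, frozenset()) for i in range(n))
    best_parents = {i: set() for i in range(n)}
    best_score = score
    tabu: deque = deque(maxlen=config.tabu_length)

    def structure_hash(ps: dict[int, set[int]]):
        return frozenset((p, c) for c, s in ps.items() for p in s)

    tabu.append(structure_hash(parents))
    nonimproving = 0
    while nonimproving <= config.max_nonimproving:
        candidates = []  # (delta, move_key, new_parents_changes)
        for (u, v) in sorted(allowed):
            if u in parents[v]:
                # delete u -> v
                new_pv = frozenset(parents[v] - {u})
                delta = family(v, new_pv) - family(v, frozenset(parents[v]))
                candidates.append((delta, ("del", u, v), {v: set(new_pv)}))
                # reverse u -> v
                if not _creates_cycle(
                    {k: (s - {u} if k == v else s) for k, s in parents.items()},
                    v,
                    u,
                ):
                    new_pu = frozenset(parents[u] | {v})
                    delta_rev = (
                        family(v, new_pv)
                        - family(v, frozenset(parents[v]))
                        + family(u, new_pu)
                        - family(u, frozenset(parents[u]))
                    )
                    candidates.append(
                        (delta_rev, ("rev", u, v), {v: set(new_pv), u: set(new_pu)})
                    )
            elif v not in parents[u]:
                # add u -> v
                if _creates_cycle(parents, u, v):
                    continue
                new_pv = frozenset(parents[v] | {u})
                delta = family(v, new_pv) - family(v, frozenset(parents[v]))
                candidates.append((delta, ("add", u, v), {v: set(new_pv)}))
        moved = False
        for delta, _key, changes in sorted(
            candidates, key=lambda c: (-c[0], c[1])
        ):
            trial = {k: set(s) for k, s in parents.items()}
            trial.update({k: set(s) for k, s in changes.items()})
            h = structure_hash(trial)
            if h in tabu:
                continue
            parents = trial
            score += delta
            tabu.append(h)
            moved = True
            break
        if not moved:
            break
        if score > best_score + 1e-9:
            best_score = score
            best_parents = {k: set(s) for k, s in parents.items()}
            nonimproving = 0
        else:
            nonimproving += 1
    arcs = {
        (labels[p], labels[c]) for c, ps in best_parents.items() for p in ps
    }
    return DAGStructure(list(labels), arcs)


def learn_structure(
    table: OccupancyTable,
    blacklist: Optional[ArcBlacklist] = None,
    config: Optional[LearningConfig] = None,
) -> DAGStructure:
    """Full two-phase structure learning (restrict then maximize)."""
    config = config or LearningConfig()
    skeleton = restrict_skeleton(table, blacklist, config)
    return maximize_structure(table, skeleton, blacklist, config)
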