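"""Cross-validation, model averaging and feature uncertainty.

Repeated k-fold cross-validation over trajectory frames yields a family of
networks (10 repeats x 5 folds = 50 models by default).  Arcs that recur in
more than 90% of the models form the robust consensus network, drawn as
directed only when more than 80% of the occurrences agree on orientation.
The spread of HB features over the model family provides error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayesnet import (
    DAGStructure,
    DiscreteBayesNet,
    ImpossibleEvidenceError,
    fit_parameters,
    loglik_frame,
)
from .features import HBFeature, MutationSpec, compute_hb, mutation_to_evidence
from .hbonds import ArcBlacklist, OccupancyTable
from .learning import LearningConfig, learn_structure

__all__ = [
    "CVResult",
    "AveragedNetwork",
    "cross_validate",
    "average_models",
    "feature_stats",
    "readd_constant_nodes",
]

ARC_FREQUENCY_THRESHOLD = 0.9
DIRECTION_AGREEMENT_THRESHOLD = 0.8


@dataclass
class CVResult:
    models: list[DiscreteBayesNet]
    fold_losses: list[float]
    config: LearningConfig

    @property
    def mean_loss(self) -> float:
        return float(np.mean(self.fold_losses))


def _fold_assignment(
    n_frames: int, folds: int, rng: np.random.Generator, contiguous: bool
) -> np.ndarray:
    """Assign frames to folds, by contiguous blocks unless iid shuffling.

    Contiguous blocks respect the residual autocorrelation of trajectory
    frames; the block-to-fold mapping is shuffled per repeat.
    """
    if contiguous:
        edges = np.linspace(0, n_frames, folds + 1).astype(int)
        block_ids = np.empty(n_frames, dtype=int)
        for b in range(folds):
            block_ids[edges[b] : edges[b + 1]] = b
        mapping = rng.permutation(folds)
        return mapping[block_ids]
    return rng.permutation(np.arange(n_frames) % folds)


def cross_validate(
    table: OccupancyTable,
    blacklist: Optional[ArcBlacklist] = None,
    config: Optional[LearningConfig] = None,
    repeats: int = 10,
    folds: int = 5,
    contiguous_folds: bool = True,
) -> CVResult:
    """Repeated k-fold CV with log-likelihood loss on held-out frames.

    Each model is learned (restrict + maximize + Bayesian parameters) on
    the training folds; the loss is the mean negative log-likelihood of
    the held-out frames.  Cardinalities are fixed from the full table so
    held-out values always lie in range.
    """
    config = config or LearningConfig()
    n_frames = table.n_frames
    if n_frames < folds:
        raise ValueError(f"need at least {folds} frames for {folds}-fold CV")
    labels = table.labels
    data = table.counts.to_numpy(dtype=np.int64)
    cards = {lab: int(data[:, k].max()) + 1 for k, lab in enumerate(labels)}
    rng = np.random.default_rng(config.seed)
    models: list[DiscreteBayesNet] = []
    losses: list[float] = []
    for rep in range(repeats):
        assignment = _fold_assignment(n_frames, folds, rng, contiguous_folds)
        for fold in range(folds):
            train_mask = assignment != fold
            sub = OccupancyTable(
                table.counts[train_mask].reset_index(drop=True),
                dict(table.residue_names),
            )
            fold_config = LearningConfig(
                alpha=config.alpha,
                iss=config.iss,
                tabu_length=config.tabu_length,
                max_nonimproving=config.max_nonimproving,
                permutations_for_df=config.permutations_for_df,
                max_cond_set=config.max_cond_set,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            dag = learn_structure(sub, blacklist, fold_config)
            net = fit_parameters(
                dag,
                data[train_mask],
                labels,
                cards,
                iss=config.iss,
                training_meta={
                    "repeat": rep,
                    "fold": fold,
                    "n_train": int(train_mask.sum()),
                    "seed": fold_config.seed,
                },
            )
            held = data[~train_mask]
            loss = -np.mean(
                [
                    loglik_frame(net, dict(zip(labels, row)))
                    for row in held
                ]
            )
            models.append(net)
            losses.append(float(loss))
    return CVResult(models=models, fold_losses=losses, config=config)


@dataclass
class AveragedNetwork:
    """Consensus arc statistics over a family of learned structures.

    ``arcs`` maps an unordered label pair to (frequency, direction
    agreement, majority direction, class), where class is
    "strong-directed", "weak-undirected" or "excluded".
    """

    nodes: list[str]
    arcs: dict[frozenset, dict]

    def included(self) -> dict[frozenset, dict]:
        return {k: v for k, v in self.arcs.items() if v["class"] != "excluded"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pair, info in sorted(self.arcs.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "frequency": info["frequency"],
                    "direction_agreement": info["agreement"],
                    "direction": "->".join(info["direction"])
                    if info["direction"]
                    else "",
                    "class": info["class"],
                }
            )
        return pd.DataFrame(rows)

    def to_dot(self) -> str:
        """Solid arrows for strong causality, dashed lines otherwise."""
        lines = ["digraph consensus {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for pair, info in sorted(self.arcs.items(), key=lambda kv: sorted(kv[0])):
            if info["class"] == "strong-directed":
                u, v = info["direction"]
                lines.append(f'  "{u}" -> "{v}";')
            elif info["class"] == "weak-undirected":
                a, b = sorted(pair)
                lines.append(f'  "{a}" -> "{b}" [dir=none, style=dashed];')
        lines.append("}")
        return "\n".join(lines)


def classify_arc(frequency: float, agreement: float) -> str:
    """Pure classification rule on (frequency, direction agreement)."""
    if frequency <= ARC_FREQUENCY_THRESHOLD:
        return "excluded"
    if agreement > DIRECTION_AGREEMENT_THRESHOLD:
        return "strong-directed"
    return "weak-undirected"


def average_models(
    models: Sequence[Union[DAGStructure, DiscreteBayesNet]]
) -> AveragedNetwork:
    """Model averaging: keep arcs present in > 90% of models.

    Frequency counts an unordered pair present in either direction over
    all models; direction agreement is the majority-orientation fraction
    among the models that contain the arc.
    """
    if len(models) < 2:
        raise ValueError("model averaging needs at least two models")
    structures = [
        m.structure if isinstance(m, DiscreteBayesNet) else m for m in models
    ]
    nodes = sorted({n for s in structures for n in s.nodes})
    counts: dict[frozenset, dict[tuple[str, str], int]] = {}
    for s in structures:
        for u, v in s.arcs:
            pair = frozenset((u, v))
            counts.setdefault(pair, {})
            counts[pair][(u, v)] = counts[pair].get((u, v), 0) + 1
    arcs: dict[frozenset, dict] = {}
    n_models = len(structures)
    for pair, directions in counts.items():
        present = sum(directions.values())
        frequency = present / n_models
        majority = max(sorted(directions), key=lambda d: directions[d])
        agreement = directions[majority] / present
        cls = classify_arc(frequency, agreement)
        arcs[pair] = {
            "frequency": frequency,
            "agreement": agreement,
            "direction": majority if cls == "strong-directed" else tuple(),
            "class": cls,
        }
    return AveragedNetwork(nodes=nodes, arcs=arcs)


def feature_stats(
    models: Sequence[DiscreteBayesNet],
    evidence_or_mutation: Union[Mapping[str, int], MutationSpec, None],
) -> HBFeature:
    """Mean and sample sd (n−1) of HB/ΔHB across a model family.

    Models under which the evidence is impossible are skipped with a
    warning; the count of skipped models is recorded in the result via
    the warning message.
    """
    if len(models) < 2:
        raise ValueError("feature statistics need at least two models")
    hb_values, dhb_values = [], []
    skipped = 0
    for net in models:
        if isinstance(evidence_or_mutation, MutationSpec):
            evidence = mutation_to_evidence(evidence_or_mutation, net)
        else:
            evidence = dict(evidence_or_mutation or {})
            evidence = {k: v for k, v in evidence.items() if k in net.cards}
        try:
            feat = compute_hb(net, evidence)
        except ImpossibleEvidenceError:
            skipped += 1
            continue
        hb_values.append(feat.hb)
        dhb_values.append(feat.delta_hb)
    if skipped:
        warnings.warn(
            f"evidence impossible under {skipped} of {len(models)} models; skipped",
            stacklevel=2,
        )
    if len(hb_values) < 2:
        raise ValueError("fewer than two models admit the evidence")
    return HBFeature(
        hb=float(np.mean(hb_values)),
        delta_hb=float(np.mean(dhb_values)),
        sd=float(np.std(dhb_values, ddof=1))
        if evidence_or_mutation
        else float(np.std(hb_values, ddof=1)),
    )


def readd_constant_nodes(
    net: DiscreteBayesNet, constants: Mapping[str, int]
) -> DiscreteBayesNet:
    """Re-add constant-occupancy nodes as isolated point-mass variables.

    Nontrivial H-bonds with the same count in every snapshot carry no
    signal for learning but still contribute their constant value to HB.
    """
    for label in constants:
        if label in net.cards:
            raise ValueError(f"node {label!r} already present in network")
    nodes = list(net.nodes) + list(constants)
    arcs = set(net.structure.arcs)
    cards = dict(net.cards)
    cpts = {n: net.cpts[n].copy() for n in net.nodes}
    for label, value in constants.items():
        cards[label] = value + 1
        mass = np.zeros(value + 1)
        mass[value] = 1.0
        cpts[label] = mass
    return DiscreteBayesNet(
        structure=DAGStructure(nodes, arcs),
        cards=cards,
        cpts=cpts,
        training_meta=dict(net.training_meta),
    )
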