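"""HB / ΔHB / ΔΔHB features and mutational screening.

HB is the expected total H-bond count of a network, Σ_i E(X_i).  A
"mutation" is hard evidence forcing the H-bond counts of selected nodes to
zero; ΔHB = HB under evidence minus the unperturbed HB, and
ΔΔHB(state2→state1) = ΔHB(state1) − ΔHB(state2) compares the perturbation
across two conformational states the way a thermodynamic cycle compares
ΔΔG.  Positive ΔΔHB(OF→IF) means the mutation biases the ensemble toward
the inward-facing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayesnet import DiscreteBayesNet, Evidence, infer_marginals
from .hbonds import parse_node_label

__all__ = [
    "HBFeature",
    "MutationSpec",
    "compute_hb",
    "mutation_to_evidence",
    "delta_delta_hb",
    "screen_mutations",
]


@dataclass
class HBFeature:
    """Expected total H-bond count and its evidence-induced changes."""

    hb: float
    delta_hb: float = 0.0
    delta_delta_hb: Optional[float] = None
    sd: Optional[float] = None


@dataclass
class MutationSpec:
    """Which H-bond nodes a residue substitution disables.

    ``side_chain_all`` zeroes every node with an SC moiety of the residue
    (a polar-to-nonpolar substitution), ``all_moieties`` zeroes every node
    touching the residue, ``specific_pairs`` zeroes only the listed nodes.
    """

    residue_index: int
    scope: str = "side_chain_all"  # side_chain_all | all_moieties | specific_pairs
    pairs: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scope not in {"side_chain_all", "all_moieties", "specific_pairs"}:
            raise ValueError(f"unknown mutation scope {self.scope!r}")


def expected_counts(
    net: DiscreteBayesNet, evidence: Optional[Evidence] = None
) -> dict[str, float]:
    """E(X_i | evidence) for every node."""
    marginals = infer_marginals(net, evidence)
    return {
        node: float(np.dot(np.arange(net.cards[node]), dist))
        for node, dist in marginals.items()
    }


def compute_hb(
    net: DiscreteBayesNet, evidence: Optional[Evidence] = None
) -> HBFeature:
    """HB = Σ_i E(X_i | evidence); ΔHB relative to the evidence-free HB."""
    base = sum(expected_counts(net).values())
    if not evidence:
        return HBFeature(hb=base, delta_hb=0.0)
    mutated = sum(expected_counts(net, evidence).values())
    return HBFeature(hb=mutated, delta_hb=mutated - base)


def mutation_to_evidence(
    mutation: MutationSpec, net: DiscreteBayesNet
) -> dict[str, int]:
    """Resolve a mutation to hard evidence (all affected nodes forced to 0)."""
    if mutation.scope == "specific_pairs":
        missing = [p for p in mutation.pairs if p not in net.cards]
        if missing:
            raise KeyError(f"node(s) not in network: {', '.join(missing)}")
        return {p: 0 for p in mutation.pairs}
    evidence = {}
    for label in net.nodes:
        for m in parse_node_label(label):
            if m.residue_index != mutation.residue_index:
                continue
            if mutation.scope == "side_chain_all" and m.part != "SC":
                continue
            evidence[label] = 0
    return evidence


def delta_delta_hb(
    net_state1: DiscreteBayesNet,
    net_state2: DiscreteBayesNet,
    mutation: MutationSpec,
) -> HBFeature:
    """ΔΔHB(state2→state1) = ΔHB(state1) − ΔHB(state2).

    Nodes of the mutation absent from one state's network simply contribute
    no evidence there (per-state networks need not share node sets).
    """
    features = []
    for net in (net_state1, net_state2):
        if mutation.scope == "specific_pairs":
            pairs = [p for p in mutation.pairs if p in net.cards]
            evidence = {p: 0 for p in pairs}
        else:
            evidence = mutation_to_evidence(mutation, net)
        features.append(compute_hb(net, evidence))
    ddhb = features[0].delta_hb - features[1].delta_hb
    return HBFeature(
        hb=features[0].hb, delta_hb=features[0].delta_hb, delta_delta_hb=ddhb
    )


def screen_mutations(
    state_nets: Mapping[str, Mapping[str, DiscreteBayesNet]],
    residues: Sequence[int],
    if_of_threshold: float = 0.7,
    ts_threshold: float = 0.5,
    scope: str = "side_chain_all",
) -> pd.DataFrame:
    """Classify residue mutations by their per-state ΔΔHB pattern.

    ``state_nets`` maps system name → {state: network} with states "IF",
    "OF" and optionally "TS".  A residue is IF-favoring when
    ΔΔHB(OF→IF) > +threshold in every system and OF-favoring when below
    −threshold in every system.  With a TS network, barrier-creating
    mutations have both ΔΔHB(IF→TS) and ΔΔHB(OF→TS) below −ts_threshold
    and barrier-removing ones have both above +ts_threshold.
    """
    systems = list(state_nets)
    for sys_name, nets in state_nets.items():
        for state in ("IF", "OF"):
            if state not in nets:
                raise KeyError(f"system {sys_name!r} is missing state {state!r}")
    has_ts = all("TS" in nets for nets in state_nets.values())
    rows = []
    for residue in residues:
        mutation = MutationSpec(residue_index=residue, scope=scope)
        row: dict = {"residue": residue}
        of_if = []
        if_ts, of_ts = [], []
        for sys_name in systems:
            nets = state_nets[sys_name]
            value = delta_delta_hb(nets["IF"], nets["OF"], mutation).delta_delta_hb
            row[f"ddhb_of_to_if[{sys_name}]"] = value
            of_if.append(value)
            if has_ts:
                v1 = delta_delta_hb(nets["TS"], nets["IF"], mutation).delta_delta_hb
                v2 = delta_delta_hb(nets["TS"], nets["OF"], mutation).delta_delta_hb
                row[f"ddhb_if_to_ts[{sys_name}]"] = v1
                row[f"ddhb_of_to_ts[{sys_name}]"] = v2
                if_ts.append(v1)
                of_ts.append(v2)
        if all(v > if_of_threshold for v in of_if):
            row["classification"] = "IF-favoring"
        elif all(v < -if_of_threshold for v in of_if):
            row["classification"] = "OF-favoring"
        else:
            row["classification"] = "unclassified"
        if has_ts:
            if all(v < -ts_threshold for v in if_ts) and all(
                v < -ts_threshold for v in of_ts
            ):
                row["ts_classification"] = "barrier-creating"
            elif all(v > ts_threshold for v in if_ts) and all(
                v > ts_threshold for v in of_ts
            ):
                row["ts_classification"] = "barrier-removing"
            else:
                row["ts_classification"] = "unclassified"
        rows.append(row)
    return pd.DataFrame(rows)
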