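"""Geometric hydrogen-bond detection and moiety-pair occupancy tables.

Each residue is split into a backbone (BB) and a side-chain (SC) moiety.
A network node is the number of simultaneous H-bonds between one unordered
moiety pair in a snapshot; the per-frame counts over all nodes form the
occupancy table that trains the Bayesian network models.  Detection uses
the standard geometric criterion: donor-acceptor heavy-atom distance
<= 3.0 Å and donor-vertex angle between the D->H and D->A vectors <= 45°.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import AtomRecord, Ensemble

__all__ = [
    "HBondCriteria",
    "Moiety",
    "HBNode",
    "OccupancyTable",
    "ArcBlacklist",
    "detect_hbonds",
    "build_occupancy",
    "filter_trivial",
    "filter_flexible_loops",
    "build_blacklist",
    "node_label",
    "parse_node_label",
]

#: Heavy-atom elements that can act as H-bond donors or acceptors.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: Maximum covalent D-H distance used to assign hydrogens to donors (Å).
COVALENT_H_CUTOFF = 1.3

_3TO1_TITLE = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}


@dataclass(frozen=True)
class HBondCriteria:
    """Distance (donor-acceptor) and angle (at the donor) cutoffs."""

    distance_cutoff: float = 3.0
    angle_cutoff: float = 45.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True, order=True)
class Moiety:
    """One backbone or side-chain half of a residue."""

    residue_index: int
    part: str  # "BB" or "SC"

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.residue_index, 0 if self.part == "BB" else 1)


def node_label(a: Moiety, b: Moiety, residue_names: dict[int, str]) -> str:
    """Canonical label, lower residue index first, BB before SC on ties."""
    first, second = sorted((a, b), key=lambda m: m.sort_key)
    def fmt(m: Moiety) -> str:
        raw = residue_names.get(m.residue_index, "UNK")
        name = _3TO1_TITLE.get(raw.upper(), raw.capitalize())
        return f"{name}{m.residue_index}_{m.part}"
    return f"{fmt(first)}-{fmt(second)}"


def parse_node_label(label: str) -> tuple[Moiety, Moiety]:
    """Invert :func:`node_label` (residue names are not recovered)."""
    def parse(half: str) -> Moiety:
        stem, part = half.rsplit("_", 1)
        digits = "".join(ch for ch in stem if ch.isdigit())
        return Moiety(int(digits), part)
    left, right = label.split("-")
    return parse(left), parse(right)


@dataclass(frozen=True)
class HBNode:
    """Moiety-pair random variable; ``cardinality = max observed count + 1``."""

    moieties: tuple[Moiety, Moiety]
    label: str
    cardinality: int


@dataclass
class OccupancyTable:
    """Frames x nodes matrix of integer H-bond counts.

    ``counts`` is a DataFrame whose columns are canonical node labels and
    whose index is the frame index.  ``residue_names`` keeps the 3-letter
    codes needed to re-derive labels.
    """

    counts: pd.DataFrame
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.counts)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def nodes(self) -> list[HBNode]:
        out = []
        for label in self.labels:
            a, b = parse_node_label(label)
            card = int(self.counts[label].max()) + 1
            out.append(HBNode(moieties=(a, b), label=label, cardinality=card))
        return out

    def constant_nodes(self) -> dict[str, int]:
        """Nodes whose count is the same nonzero value in every frame.

        These carry no statistical signal for structure learning but still
        contribute H-bonds; they are flagged here and re-added to the model
        after learning (see :func:`hbnet.bn_ensemble.readd_constant_nodes`).
        """
        out = {}
        for label in self.labels:
            col = self.counts[label].to_numpy()
            if col.min() == col.max() and col[0] > 0:
                out[label] = int(col[0])
        return out

    def drop(self, labels: Sequence[str]) -> "OccupancyTable":
        keep = [c for c in self.counts.columns if c not in set(labels)]
        return OccupancyTable(self.counts[keep].copy(), dict(self.residue_names))

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, residue_names: Optional[dict[int, str]] = None):
        df = pd.read_csv(path, sep="\t")
        df = df.drop(columns=["frame"])
        return cls(df.astype(int), residue_names or {})


@dataclass
class ArcBlacklist:
    """Unordered node-label pairs that can never be connected by an arc."""

    forbidden: set[frozenset]

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self.forbidden

    def to_tsv(self, path) -> None:
        rows = sorted(tuple(sorted(p)) for p in self.forbidden)
        pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls({frozenset((a, b)) for a, b in zip(df.node_a, df.node_b)})


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def _moiety_of(atom: AtomRecord) -> Moiety:
    return Moiety(atom.residue_index, atom.moiety_class)


def assign_hydrogens(
    frame: np.ndarray, topology: Sequence[AtomRecord]
) -> list[tuple[int, int]]:
    """Pair each hydrogen with its covalent heavy atom.

    A hydrogen is bonded to the nearest heavy atom of the same residue
    within 1.3 Å; hydrogens without such a neighbour are ignored.
    """
    pairs = []
    heavy_by_res: dict[int, list[int]] = {}
    for i, atom in enumerate(topology):
        if not atom.is_hydrogen:
            heavy_by_res.setdefault(atom.residue_index, []).append(i)
    for i, atom in enumerate(topology):
        if not atom.is_hydrogen:
            continue
        candidates = heavy_by_res.get(atom.residue_index, [])
        if not candidates:
            continue
        dists = np.linalg.norm(frame[candidates] - frame[i], axis=1)
        j = int(np.argmin(dists))
        if dists[j] <= COVALENT_H_CUTOFF:
            pairs.append((candidates[j], i))
    return pairs


def detect_hbonds(
    frame: np.ndarray,
    topology: Sequence[AtomRecord],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, int, int]]:
    """Geometric H-bond scan, returning (donor, hydrogen, acceptor) indices.

    Donors are N/O/S heavy atoms with a covalently bonded hydrogen;
    acceptors are N/O/S heavy atoms.  A triple is reported when the
    donor-acceptor distance is within the cutoff, the angle at the donor
    between D->H and D->A is within the cutoff, and donor and acceptor
    belong to different moieties.
    """
    if not any(a.is_hydrogen for a in topology):
        raise ValueError(
            "topology has no hydrogens; H-bond detection requires an "
            "explicitly protonated structure"
        )
    donor_h = [
        (d, h)
        for d, h in assign_hydrogens(frame, topology)
        if topology[d].element.upper() in POLAR_ELEMENTS
    ]
    acceptors = [
        i
        for i, a in enumerate(topology)
        if not a.is_hydrogen and a.element.upper() in POLAR_ELEMENTS
    ]
    if not donor_h or not acceptors:
        return []
    acc_idx = np.array(acceptors)
    acc_pos = frame[acc_idx]
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    out = []
    for d, h in donor_h:
        da = acc_pos - frame[d]
        dist = np.linalg.norm(da, axis=1)
        dh = frame[h] - frame[d]
        dh_norm = np.linalg.norm(dh)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da @ dh) / (dist * dh_norm)
        ok = (dist <= criteria.distance_cutoff) & (cosang >= cos_cut) & (dist > 0)
        for a in acc_idx[ok]:
            if int(a) == d:
                continue
            if _moiety_of(topology[d]) == _moiety_of(topology[int(a)]):
                continue
            out.append((d, h, int(a)))
    return out


def build_occupancy(
    ensemble: Ensemble, criteria: HBondCriteria = HBondCriteria()
) -> OccupancyTable:
    """Count H-bonds per moiety pair per frame.

    Only pairs with at least one nonzero count across the ensemble become
    nodes; each node's value range follows from its observed maximum.
    """
    residue_names = {a.residue_index: a.residue_name for a in ensemble.topology}
    records: list[dict[str, int]] = []
    for f in range(ensemble.n_frames):
        counts: dict[str, int] = {}
        for d, _h, a in detect_hbonds(ensemble.frame(f), ensemble.topology, criteria):
            label = node_label(
                _moiety_of(ensemble.topology[d]),
                _moiety_of(ensemble.topology[a]),
                residue_names,
            )
            counts[label] = counts.get(label, 0) + 1
        records.append(counts)
    df = pd.DataFrame.from_records(records).fillna(0).astype(int)
    df = df[sorted(df.columns, key=lambda c: tuple(m.sort_key for m in parse_node_label(c)))]
    df.index = pd.RangeIndex(ensemble.n_frames)
    return OccupancyTable(df, residue_names)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_trivial(table: OccupancyTable, threshold: float = 0.10) -> OccupancyTable:
    """Drop nodes present (count > 0) in fewer than ``threshold`` of frames.

    A node occupied in exactly the threshold fraction is retained.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frac = (table.counts > 0).mean(axis=0)
    drop = [c for c in table.labels if frac[c] < threshold]
    return table.drop(drop)


def filter_flexible_loops(
    table: OccupancyTable,
    rmsf: Optional[dict[int, float]] = None,
    cutoff: float = 2.0,
    excluded_ranges: Optional[Sequence[tuple[int, int]]] = None,
) -> OccupancyTable:
    """Drop nodes that touch flexible-loop residues.

    A residue is excluded when its RMSF exceeds ``cutoff`` (2.0 Å default)
    or when it falls inside an explicitly excluded range; short biased
    simulations cannot guarantee converged sampling for such loops.
    """
    excluded: set[int] = set()
    if excluded_ranges:
        for lo, hi in excluded_ranges:
            excluded.update(range(lo, hi + 1))
    drop = []
    for label in table.labels:
        hit = False
        for m in parse_node_label(label):
            if m.residue_index in excluded:
                hit = True
            elif rmsf is not None:
                if m.residue_index not in rmsf:
                    raise ValueError(
                        f"no RMSF value for residue {m.residue_index} ({label})"
                    )
                if rmsf[m.residue_index] > cutoff:
                    hit = True
        if hit:
            drop.append(label)
    return table.drop(drop)


# ---------------------------------------------------------------------------
# Contact blacklist
# ---------------------------------------------------------------------------


def build_blacklist(
    ensemble: Ensemble,
    table: OccupancyTable,
    contact_cutoff: float = 4.0,
    min_mean_pairs: float = 1.0,
) -> ArcBlacklist:
    """Forbid arcs between nodes whose moieties never physically contact.

    Two moieties are "in contact" when the mean (over frames) number of
    heavy-atom pairs within ``contact_cutoff`` exceeds ``min_mean_pairs``
    (strictly), or when a nontrivial H-bond node exists between them.  A
    node pair is a candidate arc iff the nodes share a moiety or at least
    one cross-node moiety pair is in contact; every other unordered node
    pair is blacklisted.
    """
    moieties = sorted(
        {m for label in table.labels for m in parse_node_label(label)},
        key=lambda m: m.sort_key,
    )
    heavy_idx = {
        m: [
            i
            for i, a in enumerate(ensemble.topology)
            if not a.is_hydrogen
            and a.residue_index == m.residue_index
            and a.moiety_class == m.part
        ]
        for m in moieties
    }
    bonded_pairs = {
        frozenset(parse_node_label(label)) for label in table.labels
    }

    def in_contact(ma: Moiety, mb: Moiety) -> bool:
        if frozenset((ma, mb)) in bonded_pairs:
            return True
        ia, ib = heavy_idx[ma], heavy_idx[mb]
        if not ia or not ib:
            return False
        total = 0
        for f in range(ensemble.n_frames):
            diff = ensemble.coords[f, ia][:, None, :] - ensemble.coords[f, ib][None, :, :]
            total += int((np.linalg.norm(diff, axis=2) <= contact_cutoff).sum())
        return total / ensemble.n_frames > min_mean_pairs

    contact_cache: dict[frozenset, bool] = {}

    def cached_contact(ma: Moiety, mb: Moiety) -> bool:
        key = frozenset((ma, mb))
        if key not in contact_cache:
            contact_cache[key] = in_contact(ma, mb)
        return contact_cache[key]

    labels = table.labels
    forbidden: set[frozenset] = set()
    for i in range(len(labels)):
        mi = parse_node_label(labels[i])
        for j in range(i + 1, len(labels)):
            mj = parse_node_label(labels[j])
            if set(mi) & set(mj):
                continue  # shared moiety: always a candidate arc
            if any(cached_contact(a, b) for a in mi for b in mj):
                continue
            forbidden.add(frozenset((labels[i], labels[j])))
    return ArcBlacklist(forbidden)
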