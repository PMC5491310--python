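"""Synthetic fixtures with known ground truth.

Everything the analysis modules consume can be generated here with its
answer known in advance: occupancy tables forward-sampled from a specified
causal network, atomic ensembles whose H-bond geometry realizes those
sampled counts exactly, ideal/bent α-helices, umbrella-sampling series
drawn from an analytic free-energy surface, and morphing path ensembles
with a known window correspondence.  These are statistical/geometric
constructs, not force-field physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayesnet import DAGStructure, DiscreteBayesNet
from .ensemble import AtomRecord, Ensemble, ideal_helix_calpha
from .hbonds import Moiety, OccupancyTable, node_label
from .free_energy import KB_KCAL, UmbrellaWindow

__all__ = [
    "CausalNodeSpec",
    "CausalSpec",
    "ToyPMFSpec",
    "gen_occupancy",
    "gen_causal_ensemble",
    "gen_umbrella_series",
    "gen_helix",
    "gen_matched_paths",
]

# Geometry margins of the H-bond template: a formed bond sits at
# 2.8 Å / 10° (inside the 3.0 Å / 45° criteria), an absent one at
# 3.5 Å / 60° (outside both), leaving safety margins around the cutoffs.
BOND_DISTANCE = 2.8
BOND_ANGLE_DEG = 10.0
NOBOND_DISTANCE = 3.5
NOBOND_ANGLE_DEG = 60.0
NODE_SPACING = 20.0  # Å between the donor clusters of different nodes
SLOT_ANGLE_DEG = 120.0  # angular separation of slots sharing a donor


@dataclass
class CausalNodeSpec:
    """One H-bond node of the ground-truth network.

    The moieties name the residues and BB/SC parts between which the
    template places donor/hydrogen/acceptor triples; ``max_count`` bounds
    the node's value range (up to 3 slots are realizable per pair).
    """

    moiety_a: Moiety
    moiety_b: Moiety
    max_count: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.max_count <= 3:
            raise ValueError("template supports 1-3 H-bond slots per node")
        if self.moiety_a == self.moiety_b:
            raise ValueError("node moieties must differ")


@dataclass
class CausalSpec:
    """Ground-truth causal network plus its geometric realization plan."""

    nodes: dict[str, CausalNodeSpec]
    dag: DAGStructure
    cpts: dict[str, np.ndarray]
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.dag.nodes:
            if label not in self.nodes:
                raise ValueError(f"no geometry spec for node {label!r}")
        self.cards = {
            label: spec.max_count + 1 for label, spec in self.nodes.items()
        }
        for label in self.dag.nodes:
            parents = self.dag.parents_of(label)
            expected = tuple(self.cards[p] for p in parents) + (self.cards[label],)
            cpt = np.asarray(self.cpts[label], dtype=float)
            if cpt.shape != expected:
                raise ValueError(f"CPT shape mismatch for {label!r}")
            if not np.allclose(cpt.sum(axis=-1), 1.0):
                raise ValueError(f"CPT of {label!r} must normalize")
            self.cpts[label] = cpt

    def to_bayesnet(self) -> DiscreteBayesNet:
        return DiscreteBayesNet(
            structure=DAGStructure(list(self.dag.nodes), set(self.dag.arcs)),
            cards=dict(self.cards),
            cpts={k: v.copy() for k, v in self.cpts.items()},
            training_meta={"source": "ground-truth spec"},
        )

    @classmethod
    def from_simple(
        cls,
        arcs: Sequence[tuple[str, str]],
        cpts: dict[str, np.ndarray],
        max_counts: Optional[dict[str, int]] = None,
    ) -> "CausalSpec":
        """Build a spec from arc list + CPTs, inventing the geometry plan.

        Node labels are generated as ``Ser{2j+1}_SC-Thr{2j+2}_SC``; the
        given names in ``cpts`` keys are used as-is if they already look
        like canonical labels.
        """
        names = sorted(cpts)
        max_counts = max_counts or {}
        nodes = {}
        residue_names = {}
        relabel = {}
        for j, name in enumerate(names):
            ra, rb = 2 * j + 1, 2 * j + 2
            ma, mb = Moiety(ra, "SC"), Moiety(rb, "SC")
            residue_names[ra] = "SER"
            residue_names[rb] = "THR"
            label = node_label(ma, mb, residue_names)
            relabel[name] = label
            mc = max_counts.get(name, 0)
            card = np.asarray(cpts[name]).shape[-1]
            nodes[label] = CausalNodeSpec(ma, mb, max_count=max(card - 1, mc))
        dag = DAGStructure(
            [relabel[n] for n in names],
            {(relabel[u], relabel[v]) for u, v in arcs},
        )
        return cls(
            nodes=nodes,
            dag=dag,
            cpts={relabel[n]: np.asarray(cpts[n], dtype=float) for n in names},
            residue_names=residue_names,
        )


def demo_spec_8node() -> CausalSpec:
    """Canonical 8-node ground-truth network for recovery studies.

    Contains a chain, a collider (v-structure), a fork and an isolated
    pair, with strong CPTs so the skeleton and the collider orientation
    are identifiable from moderate sample sizes.
    """
    arcs = [("a", "b"), ("b", "c"), ("d", "c"), ("d", "e"), ("e", "f"), ("g", "h")]
    edge = lambda eps: np.array([[1 - eps, eps], [eps, 1 - eps]])
    cpts = {
        "a": np.array([0.5, 0.5]),
        "b": edge(0.15),
        # collider b, d -> c (parent axes in alphabetical order)
        "c": np.array([[[0.95, 0.05], [0.4, 0.6]], [[0.4, 0.6], [0.05, 0.95]]]),
        "d": np.array([0.6, 0.4]),
        "e": edge(0.2),
        "f": edge(0.15),
        "g": np.array([0.4, 0.6]),
        "h": edge(0.1),
    }
    return CausalSpec.from_simple(arcs, cpts)


def gen_occupancy(spec: CausalSpec, n_frames: int, seed: int) -> OccupancyTable:
    """Forward-sample frames from the spec's joint distribution."""
    rng = np.random.default_rng(seed)
    order = spec.dag.topological_order()
    data = {label: np.empty(n_frames, dtype=int) for label in order}
    for label in order:
        parents = spec.dag.parents_of(label)
        cpt = spec.cpts[label]
        card = spec.cards[label]
        if not parents:
            data[label] = rng.choice(card, size=n_frames, p=cpt)
        else:
            u = rng.random(n_frames)
            for f in range(n_frames):
                idx = tuple(data[p][f] for p in parents)
                data[label][f] = int(np.searchsorted(np.cumsum(cpt[idx]), u[f]))
    labels = sorted(
        spec.dag.nodes,
        key=lambda lab: (
            spec.nodes[lab].moiety_a.sort_key,
            spec.nodes[lab].moiety_b.sort_key,
        ),
    )
    df = pd.DataFrame({lab: data[lab] for lab in labels})
    return OccupancyTable(df, dict(spec.residue_names))


def _slot_geometry(base: np.ndarray, slot: int, formed: bool):
    """Donor N, hydrogen H and acceptor positions for one bond slot."""
    phi = np.deg2rad(SLOT_ANGLE_DEG * slot)
    direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    perp = np.array([-np.sin(phi), np.cos(phi), 0.0])
    hydrogen = base + 1.0 * direction
    if formed:
        ang = np.deg2rad(BOND_ANGLE_DEG)
        acceptor = base + BOND_DISTANCE * (
            np.cos(ang) * direction + np.sin(ang) * perp
        )
    else:
        ang = np.deg2rad(NOBOND_ANGLE_DEG)
        acceptor = base + NOBOND_DISTANCE * (
            np.cos(ang) * direction + np.sin(ang) * perp
        )
    return hydrogen, acceptor


_SC_DONOR_NAMES = ["ND1", "ND2", "NE2"]
_SC_DONOR_H = ["HD1", "HD2", "HE2"]
_SC_ACCEPTOR_NAMES = ["OD1", "OD2", "OE1"]
_BB_ACCEPTOR_NAMES = ["O", "N"]


def gen_causal_ensemble(
    spec: CausalSpec, n_frames: int, seed: int
) -> tuple[Ensemble, OccupancyTable]:
    """Atomic ensemble whose H-bond counts equal a forward-sampled table.

    For every node and frame value v, the first v bond slots adopt formed
    geometry and the rest broken geometry; donor clusters of different
    nodes sit on a 20 Å lattice so no spurious bonds arise.  Returns the
    ensemble and the intended occupancy table (the round-trip contract:
    ``build_occupancy`` on the ensemble reproduces it exactly).
    """
    table = gen_occupancy(spec, n_frames, seed)
    labels = list(table.labels)
    topology: list[AtomRecord] = []
    # (node label, slot) -> (donor atom idx, hydrogen idx, acceptor idx)
    slot_atoms: dict[tuple[str, int], tuple[int, int, int]] = {}
    bases: dict[str, np.ndarray] = {}
    seen_ca: set[int] = set()

    def add_atom(res: int, name: str, element: str) -> int:
        resname = spec.residue_names.get(res, "SER")
        topology.append(AtomRecord(res, resname, name, element))
        return len(topology) - 1

    for j, label in enumerate(labels):
        node = spec.nodes[label]
        base = np.array([NODE_SPACING * (j + 1), 0.0, 0.0])
        bases[label] = base
        ma, mb = node.moiety_a, node.moiety_b
        for res in (ma.residue_index, mb.residue_index):
            if res not in seen_ca:
                add_atom(res, "CA", "C")
                seen_ca.add(res)
        # shared donor heavy atom of moiety A
        if ma.part == "BB":
            donor = add_atom(ma.residue_index, "N", "N")
        else:
            donor = add_atom(ma.residue_index, _SC_DONOR_NAMES[j % 3], "N")
        for s in range(node.max_count):
            if ma.part == "BB":
                hname = ["H", "HN"][s] if s < 2 else "HA"
            else:
                hname = f"{_SC_DONOR_H[j % 3]}{s + 1}"
            hyd = add_atom(ma.residue_index, hname, "H")
            if mb.part == "BB":
                aname = _BB_ACCEPTOR_NAMES[s % 2]
            else:
                aname = f"{_SC_ACCEPTOR_NAMES[s % 3]}{s + 1}"
            acc = add_atom(mb.residue_index, aname, "O")
            slot_atoms[(label, s)] = (donor, hyd, acc)

    n_atoms = len(topology)
    coords = np.zeros((n_frames, n_atoms, 3))
    # CA atoms parked on a row far below the bond lattice
    ca_counter = 0
    for i, atom in enumerate(topology):
        if atom.atom_name == "CA":
            coords[:, i] = np.array([ca_counter * 10.0, -50.0, 0.0])
            ca_counter += 1
    for label in labels:
        node = spec.nodes[label]
        base = bases[label]
        values = table.counts[label].to_numpy()
        for s in range(node.max_count):
            donor, hyd, acc = slot_atoms[(label, s)]
            coords[:, donor] = base
            h_on, a_on = _slot_geometry(base, s, formed=True)
            h_off, a_off = _slot_geometry(base, s, formed=False)
            formed = values > s
            coords[:, hyd] = np.where(formed[:, None], h_on, h_off)
            coords[:, acc] = np.where(formed[:, None], a_on, a_off)
    ensemble = Ensemble(topology=topology, coords=coords)
    return ensemble, table


# ---------------------------------------------------------------------------
# Umbrella series from a known PMF
# ---------------------------------------------------------------------------


@dataclass
class ToyPMFSpec:
    """Analytic free-energy surface for umbrella-sampling fixtures.

    ``form`` is "quadratic" (F = a (x − x0)²), "double-well"
    (F = h ((x/w)² − 1)²) or "flat"; parameters in kcal/mol and Å.
    """

    form: str = "quadratic"
    params: dict = field(default_factory=lambda: {"a": 1.0, "x0": 0.0})
    support: tuple[float, float] = (-5.0, 5.0)
    temperature: float = 310.0

    def free_energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "quadratic":
            return self.params["a"] * (x - self.params.get("x0", 0.0)) ** 2
        if self.form == "double-well":
            w = self.params.get("w", 1.0)
            h = self.params.get("h", 1.0)
            return h * ((x / w) ** 2 - 1.0) ** 2
        if self.form == "flat":
            return np.zeros_like(x)
        raise ValueError(f"unknown PMF form {self.form!r}")


def gen_umbrella_series(
    pmf: ToyPMFSpec,
    centers: Sequence[float],
    force_constant: float,
    n_per_window: int,
    seed: int,
    thinning: int = 10,
    burn_in: int = 1000,
    step_scale: float = 0.5,
) -> list[UmbrellaWindow]:
    """Sample biased windows from p(ζ) ∝ exp(−[F(ζ)+U_bias]/k_B T).

    A quadratic PMF with harmonic bias is sampled exactly as the implied
    Gaussian; other forms use a seeded Metropolis random walk with burn-in
    and thinning.
    """
    rng = np.random.default_rng(seed)
    kt = KB_KCAL * pmf.temperature
    windows = []
    for center in centers:
        if not (pmf.support[0] <= center <= pmf.support[1]):
            raise ValueError(f"window center {center} outside PMF support")
        if pmf.form == "quadratic" and force_constant > 0:
            a = pmf.params["a"]
            x0 = pmf.params.get("x0", 0.0)
            curv = 2.0 * a + force_constant
            mean = (2.0 * a * x0 + force_constant * center) / curv
            sd = np.sqrt(kt / curv)
            samples = rng.normal(mean, sd, size=n_per_window)
        else:
            samples = _metropolis(
                lambda x: pmf.free_energy(x)
                + 0.5 * force_constant * (x - center) ** 2,
                kt,
                pmf.support,
                n_per_window,
                rng,
                thinning=thinning,
                burn_in=burn_in,
                step_scale=step_scale,
                start=center,
            )
        windows.append(
            UmbrellaWindow(
                center=np.array([center]),
                force_constant=force_constant,
                samples=samples,
            )
        )
    return windows


def _metropolis(
    energy, kt, support, n_samples, rng, thinning, burn_in, step_scale, start
):
    x = float(start)
    e = float(energy(np.array(x)))
    out = np.empty(n_samples)
    total = burn_in + n_samples * thinning
    kept = 0
    for step in range(total):
        prop = x + rng.normal(0.0, step_scale)
        if prop < support[0] or prop > support[1]:
            accept = False
        else:
            e_prop = float(energy(np.array(prop)))
            accept = np.log(rng.random()) < -(e_prop - e) / kt
        if accept:
            x, e = prop, e_prop
        if step >= burn_in and (step - burn_in) % thinning == 0:
            out[kept] = x
            kept += 1
    return out[:kept] if kept < n_samples else out


# ---------------------------------------------------------------------------
# Helices and matched paths
# ---------------------------------------------------------------------------


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place the next atom from three predecessors by internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n

# Ideal backbone internal coordinates (Å / degrees) for an alpha-helix.
_BB_GEOM = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "phi": -57.8,
    "psi": -47.0,
    "omega": 180.0,
}


def gen_helix(
    n_residues: int, bend_angle: float = 0.0, seed: int = 0
) -> Ensemble:
    """Single-frame poly-Ala α-helix, optionally bent at its midpoint.

    The backbone (N, CA, C per residue) is chained from ideal internal
    coordinates (φ = −57.8°, ψ = −47°), giving ~1.5 Å rise and ~100° twist
    per turn residue.  ``bend_angle`` rotates the second half rigidly
    about an axis through the junction Cα, perpendicular to the helix
    axis.
    """
    if n_residues < 7:
        raise ValueError("need at least 7 residues")
    g = _BB_GEOM
    atoms = [
        np.array([0.0, 0.0, 0.0]),
        np.array([g[("N", "CA")], 0.0, 0.0]),
    ]
    atoms.append(
        _nerf(
            np.array([0.0, 1.0, 0.0]),
            atoms[0],
            atoms[1],
            g[("CA", "C")],
            g["angle_N_CA_C"],
            0.0,
        )
    )
    names = ["N", "CA", "C"]
    for r in range(1, n_residues):
        atoms.append(
            _nerf(atoms[-3], atoms[-2], atoms[-1], g[("C", "N")],
                  g["angle_CA_C_N"], g["psi"])
        )
        atoms.append(
            _nerf(atoms[-3], atoms[-2], atoms[-1], g[("N", "CA")],
                  g["angle_C_N_CA"], g["omega"])
        )
        atoms.append(
            _nerf(atoms[-3], atoms[-2], atoms[-1], g[("CA", "C")],
                  g["angle_N_CA_C"], g["phi"])
        )
        names.extend(["N", "CA", "C"])
    coords = np.array(atoms)
    topology = [
        AtomRecord(i // 3 + 1, "ALA", names[i], names[i][0])
        for i in range(len(atoms))
    ]
    if bend_angle != 0.0:
        ca_idx = [i for i, a in enumerate(topology) if a.atom_name == "CA"]
        half = n_residues // 2
        junction = coords[ca_idx[half]]
        # helix axis from the Calpha trace of the first half
        ca = coords[ca_idx]
        axis = _principal_axis(ca[: half + 1])
        perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
        perp /= np.linalg.norm(perp)
        rot = _rotation_about_axis(perp, np.deg2rad(bend_angle))
        second_half = np.array(
            [a.residue_index > half for a in topology]
        )
        coords[second_half] = (coords[second_half] - junction) @ rot.T + junction
    return Ensemble(topology=topology, coords=coords[None, :, :])


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(points[-1] - points[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def gen_matched_paths(
    n_windows: int,
    n_paths: int = 3,
    drift: float = 0.0,
    noise: float = 0.0,
    n_atoms: int = 20,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Morphing structure sequences with known window correspondence.

    A base conformational morph between two random structures is sampled
    at ``n_windows`` progress values per path; each path's progress grid
    is warped monotonically (strength ``drift``) and coordinates receive
    Gaussian noise.  Returns per-path coordinate stacks of shape
    ``(n_windows, n_atoms, 3)`` and the (n_paths, n_windows) matrix of
    true morph-progress values for correspondence checks.
    """
    if n_windows < 2:
        raise ValueError("need at least two windows")
    rng = np.random.default_rng(seed)
    start = rng.normal(scale=5.0, size=(n_atoms, 3))
    delta = rng.normal(scale=3.0, size=(n_atoms, 3))
    paths = []
    progress = np.empty((n_paths, n_windows))
    for p in range(n_paths):
        t = np.linspace(0.0, 1.0, n_windows)
        if drift > 0:
            jitter = rng.random(n_windows - 1)
            warped = np.concatenate([[0.0], np.cumsum(1.0 + drift * jitter)])
            t = warped / warped[-1]
        progress[p] = t
        frames = start[None, :, :] + t[:, None, None] * delta[None, :, :]
        if noise > 0:
            frames = frames + rng.normal(scale=noise, size=frames.shape)
        paths.append(frames)
    return paths, progress
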