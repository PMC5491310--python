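"""Structural ensembles and the geometric observables built on them.

An :class:`Ensemble` is a fixed topology (atom templates) plus an ordered
stack of coordinate frames, the in-memory form of a multi-model PDB.  On top
of it live the observables every downstream analysis consumes: least-squares
superposition, RMSD/RMSF, gate distances between Cα-group centroids, the
helix kink angle, and Cartesian PCA of Cα coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BACKBONE_ATOMS",
    "AtomRecord",
    "Ensemble",
    "SelectionSpec",
    "GateDefinition",
    "RigidTransform",
    "EnsembleFormatError",
    "DegenerateSelectionError",
    "read_ensemble",
    "write_ensemble",
    "superpose",
    "rmsd",
    "rmsf",
    "gate_distance",
    "kink_angle",
    "pca_modes",
    "ideal_helix_calpha",
    "parse_residue_ranges",
]

#: Atom names classified as backbone; everything else is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HN", "HA"})

#: Ideal alpha-helix construction parameters (rise per residue, twist per
#: residue, Calpha radius), all in Angstrom / degrees.
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3


class EnsembleFormatError(ValueError):
    """Raised when an input file violates the ensemble invariants."""


class DegenerateSelectionError(ValueError):
    """Raised when a selection cannot support the requested geometry."""


@dataclass(frozen=True)
class AtomRecord:
    """Template for one atom of the topology (coordinates live in frames)."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str

    @property
    def moiety_class(self) -> str:
        """``"BB"`` for backbone atom names, ``"SC"`` otherwise."""
        return "BB" if self.atom_name in BACKBONE_ATOMS else "SC"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class SelectionSpec:
    """Residue-range (inclusive, 1-based) and optional atom-name selection."""

    residue_ranges: Sequence[tuple[int, int]]
    atom_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not self.residue_ranges:
            raise ValueError("selection needs at least one residue range")
        for lo, hi in self.residue_ranges:
            if lo > hi:
                raise ValueError(f"invalid residue range {lo}-{hi}")

    def residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.residue_ranges:
            out.update(range(lo, hi + 1))
        return out

    def mask(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        residues = self.residues()
        names = set(self.atom_names) if self.atom_names is not None else None
        return np.array(
            [
                (a.residue_index in residues)
                and (names is None or a.atom_name in names)
                for a in topology
            ],
            dtype=bool,
        )


def parse_residue_ranges(text: str) -> list[tuple[int, int]]:
    """Parse ``"28-34,58-63,178-183"`` into inclusive range pairs."""
    ranges = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-")
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(chunk), int(chunk)))
    return ranges


@dataclass
class GateDefinition:
    """Two disjoint Cα residue groups whose centroid separation is a gate."""

    label: str
    group_a: SelectionSpec
    group_b: SelectionSpec

    def __post_init__(self) -> None:
        if self.group_a.residues() & self.group_b.residues():
            raise ValueError("gate groups must be disjoint")


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Ensemble:
    """Topology plus an ``(n_frames, n_atoms, 3)`` coordinate stack."""

    topology: list[AtomRecord]
    coords: np.ndarray
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.topology], dtype=int)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def select(self, selection: SelectionSpec) -> np.ndarray:
        return selection.mask(self.topology)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_KNOWN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HID HIE HIP ILE LEU LYS MET PHE
    PRO SER THR TRP TYR VAL HOH WAT""".split()
)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def read_ensemble(path, format: str = "pdb", topology_path=None) -> Ensemble:
    """Read a structural ensemble.

    ``format="pdb"`` reads a multi-model PDB.  ``format="trajectory"`` reads
    a binary trajectory (DCD/XTC) against a PDB/PSF topology via MDAnalysis.
    """
    if format == "trajectory":
        return _read_trajectory(path, topology_path)
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # inconsistent models, malformed records
        raise EnsembleFormatError(f"cannot parse multi-model PDB: {exc}") from exc
    topology = []
    for res_id, res_name, atom_name, element in zip(
        stack.res_id, stack.res_name, stack.atom_name, stack.element
    ):
        res_name = str(res_name).strip()
        if res_name.upper() not in _KNOWN_RESIDUES:
            warnings.warn(
                f"unknown residue {res_name}; atoms default to SC unless "
                "their names are backbone names",
                stacklevel=2,
            )
        elem = str(element).strip() or _guess_element(str(atom_name))
        topology.append(
            AtomRecord(int(res_id), res_name, str(atom_name).strip(), elem)
        )
    return Ensemble(topology=topology, coords=np.asarray(stack.coord, dtype=float))


def _read_trajectory(path, topology_path) -> Ensemble:
    import MDAnalysis as mda

    if topology_path is None:
        raise ValueError("trajectory input requires a topology file")
    uni = mda.Universe(str(topology_path), str(path))
    topology = [
        AtomRecord(
            int(atom.resid),
            str(atom.resname),
            str(atom.name),
            str(getattr(atom, "element", "") or _guess_element(atom.name)),
        )
        for atom in uni.atoms
    ]
    coords = np.array([uni.atoms.positions.copy() for _ in uni.trajectory])
    times = np.array([ts.time for ts in uni.trajectory])
    return Ensemble(topology=topology, coords=coords, frame_times=times)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a multi-model PDB (fixed-column ATOM/MODEL/ENDMDL records)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = ensemble.coords
    stack.res_id = np.array([a.residue_index for a in ensemble.topology])
    stack.res_name = np.array([a.residue_name for a in ensemble.topology])
    stack.atom_name = np.array([a.atom_name for a in ensemble.topology])
    stack.element = np.array([a.element for a in ensemble.topology])
    stack.chain_id = np.full(n_atoms, "A")
    stack.hetero = np.full(n_atoms, False)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Superposition and derived observables
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Closed-form least-squares proper rotation (reflections rejected)."""
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    h = (mobile - mob_center).T @ (reference - ref_center)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref_center - rotation @ mob_center
    return RigidTransform(rotation=rotation, translation=translation)


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (paired atoms).

    Returns the transform and the post-fit RMSD in Angstrom.  Requires at
    least three non-collinear atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must pair atom-for-atom")
    if mobile.shape[0] < 3:
        raise DegenerateSelectionError("need at least 3 atoms to superpose")
    centered = mobile - mobile.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError("collinear selection cannot fix a rotation")
    if weights is not None:
        raise NotImplementedError("weighted superposition is not exposed")
    transform = _kabsch(mobile, reference)
    moved = transform.apply(mobile)
    return transform, rmsd(moved, reference)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD of two paired atom sets (no fitting)."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=-1))))


def fitted_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal superposition of ``a`` onto ``b``."""
    _, value = superpose(a, b)
    return value


def rmsf(
    ensemble: Ensemble,
    selection: SelectionSpec,
    align_selection: Optional[SelectionSpec] = None,
) -> dict[int, float]:
    """Per-residue RMS fluctuation about the frame-average position.

    Frames are first superposed onto the first frame over
    ``align_selection`` when given (otherwise they are assumed
    pre-superposed).  The per-residue value aggregates the selected atoms of
    that residue as the root of their mean squared fluctuation.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    coords = ensemble.coords
    if align_selection is not None:
        amask = ensemble.select(align_selection)
        ref = coords[0, amask]
        aligned = np.empty_like(coords)
        for i in range(ensemble.n_frames):
            tr, _ = superpose(coords[i, amask], ref)
            aligned[i] = tr.apply(coords[i])
        coords = aligned
    mask = ensemble.select(selection)
    sel_coords = coords[:, mask]
    mean = sel_coords.mean(axis=0)
    msf = np.mean(np.sum((sel_coords - mean) ** 2, axis=2), axis=0)
    res_ids = ensemble.residue_indices()[mask]
    out: dict[int, float] = {}
    for res in np.unique(res_ids):
        out[int(res)] = float(np.sqrt(np.mean(msf[res_ids == res])))
    return out


def _group_centroid(
    frame: np.ndarray, topology: Sequence[AtomRecord], spec: SelectionSpec
) -> np.ndarray:
    spec = SelectionSpec(spec.residue_ranges, atom_names=["CA"])
    mask = spec.mask(topology)
    if not mask.any():
        raise ValueError("gate group resolves to no Calpha atoms")
    return frame[mask].mean(axis=0)


def gate_distance(
    frame: np.ndarray, topology: Sequence[AtomRecord], gate: GateDefinition
) -> float:
    """Distance between the Cα centroids of the two gate groups (Å)."""
    ca = _group_centroid(frame, topology, gate.group_a)
    cb = _group_centroid(frame, topology, gate.group_b)
    return float(np.linalg.norm(ca - cb))


def ideal_helix_calpha(n_residues: int) -> np.ndarray:
    """Cα trace of an ideal α-helix (1.5 Å rise, 100° twist, 2.3 Å radius).

    The construction axis is +z; used both as the kink-angle fitting
    template and by the synthetic helix generator.
    """
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST * i)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def _fit_helix_axis(calpha: np.ndarray) -> np.ndarray:
    """Direction of an ideal 7-residue helix rigidly fitted to ``calpha``."""
    template = ideal_helix_calpha(len(calpha))
    transform, _ = superpose(template, calpha)
    return transform.rotation @ np.array([0.0, 0.0, 1.0])


def kink_angle(
    frame: np.ndarray,
    topology: Sequence[AtomRecord],
    half_a: SelectionSpec,
    half_b: SelectionSpec,
) -> float:
    """Angle (degrees) between ideal-helix axes fitted to two helix halves.

    Each half must resolve to 7 consecutive residues' Cα atoms; the ideal
    (Ala)7 template is fitted to each half and the angle between the two
    fitted construction axes is returned in [0°, 180°].
    """
    axes = []
    for half in (half_a, half_b):
        spec = SelectionSpec(half.residue_ranges, atom_names=["CA"])
        mask = spec.mask(topology)
        res = sorted({a.residue_index for a, m in zip(topology, mask) if m})
        if len(res) != 7 or res != list(range(res[0], res[0] + 7)):
            raise ValueError("each helix half must cover 7 consecutive residues")
        order = np.argsort([topology[i].residue_index for i in np.where(mask)[0]])
        axes.append(_fit_helix_axis(frame[mask][order]))
    cosang = float(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def pca_modes(
    ensembles: Sequence[Ensemble],
    selection: SelectionSpec,
    alignment: Optional[SelectionSpec] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of Cartesian Cα coordinates pooled over ensembles.

    Frames are superposed on ``alignment`` (the N-terminal domain in the
    transporter use case) before the covariance eigendecomposition.
    Returns ``(components, explained_variance_fractions)`` with components
    as rows ordered by decreasing variance.
    """
    frames = []
    for ens in ensembles:
        coords = ens.coords
        if alignment is not None:
            amask = ens.select(alignment)
            ref = ensembles[0].coords[0, ensembles[0].select(alignment)]
            aligned = np.empty_like(coords)
            for i in range(ens.n_frames):
                tr, _ = superpose(coords[i, amask], ref)
                aligned[i] = tr.apply(coords[i])
            coords = aligned
        mask = ens.select(selection)
        frames.append(coords[:, mask].reshape(ens.n_frames, -1))
    data = np.concatenate(frames, axis=0)
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least two frames")
    data = data - data.mean(axis=0)
    cov = data.T @ data / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    total = evals.sum()
    fractions = evals / total if total > 0 else evals
    return evecs[:, order].T, fractions
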