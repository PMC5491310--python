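"""Transition-path selection, image redistribution and window alignment.

A discretized transition path is an ordered list of conformations (images)
spanning two end states.  A-priori paths are picked from unbiased
trajectories by three criteria: equal spacing along the first principal
component, neighbour Cα RMSD below 1.4 Å, and minimal total boost energy
among feasible choices.  Discretized paths from different systems are
aligned by monotone minimal-RMSD routes through the inter-path RMSD
matrix; window triplets matched in all three pairwise routes define the
cross-system window correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ensemble import Ensemble, SelectionSpec, rmsd, superpose

__all__ = [
    "AMDBoostParams",
    "PathImage",
    "DiscretizedPath",
    "AlignmentRoute",
    "WindowTriplet",
    "amd_boost",
    "select_apriori_path",
    "redistribute_images",
    "align_paths_pairwise",
    "align_paths_multi",
    "representative_structure",
    "matched_residue_rmsd",
]

NEIGHBOR_RMSD_CUTOFF = 1.4  # Å, a-priori path criterion on adjacent images
INTERVAL_RADIUS_FRACTION = 0.2  # candidate radius around PC1 junctures


# ---------------------------------------------------------------------------
# Accelerated-MD boost energy
# ---------------------------------------------------------------------------


@dataclass
class AMDBoostParams:
    """Dual-boost accelerated-MD reference energies and tuning parameters.

    Derived from the dimensionless lambdas and the mean potentials of an
    unbiased run: E_d = V̄_d (1+λ_d), α_d = λ_d V̄_d / 5,
    E_p = V̄ + λ_p N_atom, α_p = λ_p N_atom.
    """

    e_p: float
    alpha_p: float
    e_d: float
    alpha_d: float

    @classmethod
    def from_lambdas(
        cls,
        lambda_d: float,
        lambda_p: float,
        mean_total: float,
        mean_dihedral: float,
        n_atoms: int,
    ) -> "AMDBoostParams":
        return cls(
            e_p=mean_total + lambda_p * n_atoms,
            alpha_p=lambda_p * n_atoms,
            e_d=mean_dihedral * (1.0 + lambda_d),
            alpha_d=lambda_d * mean_dihedral / 5.0,
        )


def amd_boost(v: float, v_d: float, params: AMDBoostParams) -> float:
    """Boost potential ΔV (kcal/mol) added below the reference energies.

    Each term (E−V)²/(α+E−V) applies only while the corresponding
    potential lies below its reference, and vanishes continuously at it.
    """
    dv = 0.0
    if v < params.e_p:
        gap = params.e_p - v
        dv += gap * gap / (params.alpha_p + gap)
    if v_d < params.e_d:
        gap = params.e_d - v_d
        dv += gap * gap / (params.alpha_d + gap)
    return dv


# ---------------------------------------------------------------------------
# A-priori path selection
# ---------------------------------------------------------------------------


@dataclass
class PathImage:
    index: int
    frame: int
    collective_coordinate: float
    boost_energy: float = 0.0


@dataclass
class DiscretizedPath:
    images: list[PathImage]
    neighbor_rmsd: list[float]

    @property
    def total_boost(self) -> float:
        return sum(im.boost_energy for im in self.images)


class PathSelectionError(RuntimeError):
    pass


def select_apriori_path(
    trajectory: Ensemble,
    endpoints: tuple[int, int],
    n_images: int = 51,
    selection: Optional[SelectionSpec] = None,
    boost_energies: Optional[np.ndarray] = None,
    rmsd_cutoff: float = NEIGHBOR_RMSD_CUTOFF,
) -> DiscretizedPath:
    """Select a discretized a-priori path from an unbiased trajectory.

    The trajectory is projected on the first principal component of the
    selected Cα coordinates; ``n_images - 1`` equal intervals are laid
    between the two endpoint projections and candidate frames are gathered
    within 20% of the interval length around each juncture.  Among chains
    of candidates whose neighbour RMSD stays below the cutoff, the one
    with the lowest total boost energy is returned (dynamic programming,
    exact over the candidate sets).
    """
    if boost_energies is None:
        boost_energies = np.zeros(trajectory.n_frames)
    boost_energies = np.asarray(boost_energies, dtype=float)
    mask = (
        trajectory.select(SelectionSpec(selection.residue_ranges, atom_names=["CA"]))
        if selection is not None
        else np.array([a.atom_name == "CA" for a in trajectory.topology])
    )
    coords = trajectory.coords[:, mask]
    ref = coords[endpoints[0]]
    aligned = np.empty_like(coords)
    for i in range(len(coords)):
        tr, _ = superpose(coords[i], ref)
        aligned[i] = tr.apply(coords[i])
    flat = aligned.reshape(len(coords), -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / max(len(flat) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    pc1 = evecs[:, np.argmax(evals)]
    proj = centered @ pc1
    p0, p1 = proj[endpoints[0]], proj[endpoints[1]]
    junctures = np.linspace(p0, p1, n_images)
    radius = INTERVAL_RADIUS_FRACTION * abs(junctures[1] - junctures[0])

    candidates: list[list[int]] = []
    for k, juncture in enumerate(junctures):
        if k == 0:
            candidates.append([endpoints[0]])
        elif k == n_images - 1:
            candidates.append([endpoints[1]])
        else:
            frames = sorted(np.flatnonzero(np.abs(proj - juncture) <= radius))
            if not frames:
                raise PathSelectionError(
                    f"no candidate frames within radius of juncture {k}"
                )
            candidates.append([int(f) for f in frames])

    def pair_rmsd(fa: int, fb: int) -> float:
        _, value = superpose(aligned[fa], aligned[fb])
        return value

    # DP over junctures minimizing total boost with RMSD feasibility.
    # Ties are broken by total projection distance from the junctures,
    # an intrinsic criterion invariant to frame-order permutations.
    INF = (float("inf"), float("inf"))

    def step_cost(k: int, f: int) -> tuple[float, float]:
        return (float(boost_energies[f]), float(abs(proj[f] - junctures[k])))

    def add(a, b):
        return (a[0] + b[0], a[1] + b[1])

    cost = [dict.fromkeys(c, INF) for c in candidates]
    back: list[dict[int, int]] = [dict() for _ in candidates]
    for f in candidates[0]:
        cost[0][f] = step_cost(0, f)
    for k in range(1, n_images):
        for f in candidates[k]:
            for g in candidates[k - 1]:
                if cost[k - 1][g] == INF:
                    continue
                if pair_rmsd(g, f) >= rmsd_cutoff:
                    continue
                c = add(cost[k - 1][g], step_cost(k, f))
                if c < cost[k][f]:
                    cost[k][f] = c
                    back[k][f] = g
        if all(v == INF for v in cost[k].values()):
            raise PathSelectionError(
                f"no RMSD-feasible continuation into interval {k}"
            )
    end = min(candidates[-1], key=lambda f: cost[-1][f])
    chain = [end]
    for k in range(n_images - 1, 0, -1):
        chain.append(back[k][chain[-1]])
    chain.reverse()
    images = [
        PathImage(
            index=i,
            frame=f,
            collective_coordinate=float(proj[f]),
            boost_energy=float(boost_energies[f]),
        )
        for i, f in enumerate(chain)
    ]
    neighbor = [pair_rmsd(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
    return DiscretizedPath(images=images, neighbor_rmsd=neighbor)


# ---------------------------------------------------------------------------
# Image redistribution (string-method reparameterization)
# ---------------------------------------------------------------------------


def redistribute_images(
    positions: np.ndarray, n_new: Optional[int] = None
) -> np.ndarray:
    """Re-space images at equal arc length by linear interpolation.

    With L(k) the cumulative arc length of old image k and S(i) the target
    separation of new image i, each new position interpolates linearly
    between the bracketing old images; the endpoints are preserved
    exactly.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] < 2:  # accept 1-D input given as a flat vector
        positions = positions.T
    n_old = positions.shape[0]
    if n_old < 2:
        raise ValueError("need at least two images")
    seg = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive images (zero-length segment)")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n_new = n_new or n_old
    targets = np.linspace(0.0, cum[-1], n_new)
    out = np.empty((n_new, positions.shape[1]))
    out[0] = positions[0]
    out[-1] = positions[-1]
    for i in range(1, n_new - 1):
        s = targets[i]
        k = int(np.searchsorted(cum, s, side="right"))
        k = min(max(k, 1), n_old - 1)
        lo, hi = cum[k - 1], cum[k]
        w = (s - lo) / (hi - lo)
        out[i] = positions[k - 1] * (1.0 - w) + positions[k] * w
    return out


# ---------------------------------------------------------------------------
# Window alignment
# ---------------------------------------------------------------------------

AlignmentRoute = list  # list of (i, j) index pairs


def align_paths_pairwise(matrix: np.ndarray) -> list[tuple[int, int]]:
    """Monotone staircase route with minimal summed RMSD through ``matrix``.

    The route runs from (0,0) to (n−1,m−1), each step incrementing exactly
    one index; ties are broken deterministically by preferring to advance
    the first path's index.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("RMSD matrix must be non-empty and 2-D")
    n, m = a.shape
    suffix = np.full((n, m), np.inf)
    suffix[n - 1, m - 1] = a[n - 1, m - 1]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if i == n - 1 and j == m - 1:
                continue
            down = suffix[i + 1, j] if i + 1 < n else np.inf
            right = suffix[i, j + 1] if j + 1 < m else np.inf
            suffix[i, j] = a[i, j] + min(down, right)
    route = [(0, 0)]
    i = j = 0
    while (i, j) != (n - 1, m - 1):
        down = suffix[i + 1, j] if i + 1 < n else np.inf
        right = suffix[i, j + 1] if j + 1 < m else np.inf
        if down <= right:
            i += 1
        else:
            j += 1
        route.append((i, j))
    return route


@dataclass
class WindowTriplet:
    """Matched window indices across three paths with their total RMSD."""

    indices: tuple[int, int, int]
    total_rmsd: float


def align_paths_multi(
    route_ab: Sequence[tuple[int, int]],
    route_bc: Sequence[tuple[int, int]],
    route_ac: Sequence[tuple[int, int]],
    matrix_ab: np.ndarray,
    matrix_bc: np.ndarray,
    matrix_ac: np.ndarray,
) -> list[WindowTriplet]:
    """Match windows across three paths via their pairwise routes.

    A triplet (a, b, c) is matched when (a,b), (b,c) and (a,c) each lie on
    the corresponding route.  Among triplets sharing any window the one
    with the lowest summed pairwise RMSD wins, scanned in ascending total
    RMSD, so every window appears in at most one triplet.
    """
    set_ab = set(map(tuple, route_ab))
    set_bc = set(map(tuple, route_bc))
    set_ac = set(map(tuple, route_ac))
    raw = []
    for a, b in set_ab:
        for b2, c in set_bc:
            if b2 != b or (a, c) not in set_ac:
                continue
            total = float(matrix_ab[a, b] + matrix_bc[b, c] + matrix_ac[a, c])
            raw.append(WindowTriplet((a, b, c), total))
    raw.sort(key=lambda t: (t.total_rmsd, t.indices))
    used_a: set[int] = set()
    used_b: set[int] = set()
    used_c: set[int] = set()
    chosen = []
    for t in raw:
        a, b, c = t.indices
        if a in used_a or b in used_b or c in used_c:
            continue
        chosen.append(t)
        used_a.add(a)
        used_b.add(b)
        used_c.add(c)
    chosen.sort(key=lambda t: t.indices)
    return chosen


# ---------------------------------------------------------------------------
# Representative structures
# ---------------------------------------------------------------------------


def representative_structure(
    window_frames: Sequence[np.ndarray],
    reference: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-atom mean after superposing every frame onto the reference.

    The first frame serves as reference by default; the average stands in
    for the whole umbrella window during path alignment.
    """
    if len(window_frames) == 0:
        raise ValueError("window has no frames")
    ref = np.asarray(reference if reference is not None else window_frames[0], float)
    if len(window_frames) == 1 and reference is None:
        return np.array(window_frames[0], dtype=float)
    acc = np.zeros_like(ref)
    for frame in window_frames:
        tr, _ = superpose(np.asarray(frame, float), ref)
        acc += tr.apply(np.asarray(frame, float))
    return acc / len(window_frames)


def matched_residue_rmsd(
    structure_a: Ensemble,
    structure_b: Ensemble,
    residue_map: Sequence[tuple[tuple[int, int], tuple[int, int]]],
    frame_a: int = 0,
    frame_b: int = 0,
) -> float:
    """Cα RMSD between two proteins over mapped equal-length residue ranges.

    Each map entry pairs an inclusive range of structure A with an
    equal-length range of structure B; the Cα sets are superposed before
    the RMSD is computed over the same atoms.
    """
    coords = []
    for structure, frame, side in (
        (structure_a, frame_a, 0),
        (structure_b, frame_b, 1),
    ):
        ca_of = {
            atom.residue_index: i
            for i, atom in enumerate(structure.topology)
            if atom.atom_name == "CA"
        }
        picked = []
        for ranges in residue_map:
            lo, hi = ranges[side]
            other_lo, other_hi = ranges[1 - side]
            if hi - lo != other_hi - other_lo:
                raise ValueError(f"mapped ranges {ranges} differ in length")
            for r in range(lo, hi + 1):
                if r not in ca_of:
                    raise ValueError(f"residue {r} has no CA atom")
                picked.append(ca_of[r])
        coords.append(structure.coords[frame, picked])
    _, value = superpose(coords[0], coords[1])
    return value
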