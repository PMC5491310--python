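"""Path selection, image redistribution, window alignment, aMD boost."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbnet.ensemble import AtomRecord, Ensemble, rmsd
from hbnet.paths import (
    AMDBoostParams,
    PathSelectionError,
    align_paths_multi,
    align_paths_pairwise,
    amd_boost,
    matched_residue_rmsd,
    redistribute_images,
    representative_structure,
    select_apriori_path,
)
from hbnet.synth import gen_matched_paths


def enumerate_routes(n, m):
    steps = ["d"] * (n - 1) + ["r"] * (m - 1)
    for perm in set(itertools.permutations(steps)):
        route = [(0, 0)]
        i = j = 0
        for s in perm:
            if s == "d":
                i += 1
            else:
                j += 1
            route.append((i, j))
        yield route


class TestAmdBoost:
    def _params(self):
        return AMDBoostParams.from_lambdas(
            lambda_d=0.3, lambda_p=0.2, mean_total=-1000.0,
            mean_dihedral=500.0, n_atoms=100,
        )

    def test_derived_reference_energies(self):
        p = self._params()
        assert p.e_d == pytest.approx(500.0 * 1.3)
        assert p.alpha_d == pytest.approx(0.3 * 500.0 / 5.0)
        assert p.e_p == pytest.approx(-1000.0 + 0.2 * 100)
        assert p.alpha_p == pytest.approx(0.2 * 100)

    def test_zero_above_both_references(self):
        p = self._params()
        assert amd_boost(p.e_p + 1.0, p.e_d + 1.0, p) == 0.0

    def test_gap_equal_alpha_gives_half_alpha(self):
        """(E−V)²/(α+E−V) with E−V = α reduces to α/2."""
        p = self._params()
        assert amd_boost(p.e_p - p.alpha_p, p.e_d + 1.0, p) == pytest.approx(
            p.alpha_p / 2.0
        )

    def test_continuous_at_the_reference(self):
        p = self._params()
        eps = 1e-8
        assert amd_boost(p.e_p - eps, p.e_d + 1.0, p) == pytest.approx(0.0, abs=1e-12)


class TestRedistribute:
    def test_midpoint_1d(self):
        out = redistribute_images(np.array([[0.0], [10.0]]), 3)
        assert np.allclose(out.ravel(), [0.0, 5.0, 10.0])

    def test_interpolates_inside_bracketing_segment(self):
        """{0, 2, 10} at 3 images → middle point at arc length 5 in (2,10)."""
        out = redistribute_images(np.array([[0.0], [2.0], [10.0]]), 3)
        assert np.allclose(out.ravel(), [0.0, 5.0, 10.0])

    def test_endpoints_and_arc_length_preserved(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(9, 2)), axis=0)
        out = redistribute_images(pts, 14)
        assert np.allclose(out[0], pts[0])
        assert np.allclose(out[-1], pts[-1])
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert seg.std() / seg.mean() < 0.25  # near-uniform spacing on a polyline
        total_old = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        # arc length can only shrink by chord-cutting, never grow
        assert seg.sum() <= total_old + 1e-9

    def test_zero_segment_rejected(self):
        with pytest.raises(ValueError):
            redistribute_images(np.array([[0.0], [0.0], [1.0]]), 3)


class TestPairwiseAlignment:
    def test_single_cell(self):
        assert align_paths_pairwise(np.array([[2.0]])) == [(0, 0)]

    def test_diagonal_matrix_hugs_diagonal(self):
        a = np.full((3, 3), 10.0)
        np.fill_diagonal(a, 0.0)
        route = align_paths_pairwise(a)
        assert set([(0, 0), (1, 1), (2, 2)]).issubset(set(route))
        best = min(sum(a[i, j] for i, j in r) for r in enumerate_routes(3, 3))
        assert sum(a[i, j] for i, j in route) == pytest.approx(best)

    def test_tie_prefers_advancing_first_path(self):
        a = np.array([[0.0, 5.0], [5.0, 0.0]])
        route = align_paths_pairwise(a)
        assert route == [(0, 0), (1, 0), (1, 1)]
        # both staircase routes tie at the enumeration optimum
        sums = {sum(a[i, j] for i, j in r) for r in enumerate_routes(2, 2)}
        assert sums == {5.0}

    def test_route_length_is_n_plus_m_minus_1(self, rng):
        for _ in range(10):
            n, m = rng.integers(1, 7, size=2)
            route = align_paths_pairwise(rng.random((n, m)))
            assert len(route) == n + m - 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 6), m=st.integers(1, 6),
        seed=st.integers(0, 10_000),
    )
    def test_equals_exhaustive_enumeration(self, n, m, seed):
        a = np.random.default_rng(seed).random((n, m))
        got = sum(a[i, j] for i, j in align_paths_pairwise(a))
        best = min(sum(a[i, j] for i, j in r) for r in enumerate_routes(n, m))
        assert got == pytest.approx(best, abs=1e-12)


class TestMultiAlignment:
    def _routes_and_matrices(self, paths):
        mats = {}
        for key, (a, b) in {"ab": (0, 1), "bc": (1, 2), "ac": (0, 2)}.items():
            mats[key] = np.array(
                [[rmsd(x, y) for y in paths[b]] for x in paths[a]]
            )
        routes = {k: align_paths_pairwise(m) for k, m in mats.items()}
        return routes, mats

    def test_identical_paths_match_identity(self):
        paths, _ = gen_matched_paths(5, 3, drift=0.0, noise=0.0, seed=2)
        routes, mats = self._routes_and_matrices(paths)
        trips = align_paths_multi(
            routes["ab"], routes["bc"], routes["ac"],
            mats["ab"], mats["bc"], mats["ac"],
        )
        assert [t.indices for t in trips] == [(i, i, i) for i in range(5)]

    def test_equals_exhaustive_triplet_scan_on_4_windows(self, rng):
        paths, _ = gen_matched_paths(4, 3, drift=0.6, noise=0.3, seed=8)
        routes, mats = self._routes_and_matrices(paths)
        got = align_paths_multi(
            routes["ab"], routes["bc"], routes["ac"],
            mats["ab"], mats["bc"], mats["ac"],
        )
        # oracle: scan all consistent triplets, greedy-unique by total RMSD
        set_ab, set_bc, set_ac = (
            set(map(tuple, routes[k])) for k in ("ab", "bc", "ac")
        )
        raw = []
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    if (a, b) in set_ab and (b, c) in set_bc and (a, c) in set_ac:
                        raw.append(
                            ((a, b, c),
                             mats["ab"][a, b] + mats["bc"][b, c] + mats["ac"][a, c])
                        )
        raw.sort(key=lambda t: (t[1], t[0]))
        used = [set(), set(), set()]
        expected = []
        for idx, total in raw:
            if any(idx[k] in used[k] for k in range(3)):
                continue
            expected.append(idx)
            for k in range(3):
                used[k].add(idx[k])
        assert [t.indices for t in got] == sorted(expected)

    def test_windows_unique_and_monotone(self):
        paths, _ = gen_matched_paths(8, 3, drift=0.5, noise=0.2, seed=4)
        routes, mats = self._routes_and_matrices(paths)
        trips = align_paths_multi(
            routes["ab"], routes["bc"], routes["ac"],
            mats["ab"], mats["bc"], mats["ac"],
        )
        idx = np.array([t.indices for t in trips])
        for k in range(3):
            assert len(set(idx[:, k])) == len(idx)
            assert (np.diff(idx[:, k]) > 0).all()

    def test_known_warp_recovered_at_small_noise(self):
        paths, progress = gen_matched_paths(10, 3, drift=0.4, noise=0.02, seed=6)
        routes, mats = self._routes_and_matrices(paths)
        trips = align_paths_multi(
            routes["ab"], routes["bc"], routes["ac"],
            mats["ab"], mats["bc"], mats["ac"],
        )
        # matched windows should pair nearly equal morph-progress values
        hits = 0
        for t in trips:
            a, b, c = t.indices
            spread = np.ptp([progress[0][a], progress[1][b], progress[2][c]])
            if spread <= 0.12:  # about one window of progress
                hits += 1
        assert hits >= 0.9 * len(trips) and len(trips) >= 5


def linear_morph_ensemble(rng, n_res=10, n_frames=200, displacement=3.0):
    topo = [AtomRecord(i + 1, "ALA", "CA", "C") for i in range(n_res)]
    base = rng.normal(scale=4, size=(n_res, 3))
    delta = rng.normal(size=(n_res, 3))
    delta *= displacement / np.linalg.norm(delta)
    t = np.linspace(0, 1, n_frames)
    coords = base[None] + t[:, None, None] * delta[None]
    coords = coords + rng.normal(scale=0.01, size=coords.shape)
    return Ensemble(topo, coords)


class TestAprioriSelection:
    def test_low_noise_morph_picks_juncture_frames(self, rng):
        ens = linear_morph_ensemble(rng)
        path = select_apriori_path(ens, (0, 199), n_images=11)
        frames = np.array([im.frame for im in path.images])
        # frames must track the 11 evenly spaced junctures of the morph
        assert frames[0] == 0 and frames[-1] == 199
        assert np.all(np.abs(frames - np.linspace(0, 199, 11)) <= 8)

    def test_lower_boost_candidate_wins(self, rng):
        ens = linear_morph_ensemble(rng)
        boost = np.full(200, 5.0)
        junctures = np.round(np.linspace(0, 199, 11)).astype(int)[1:-1]
        cheap = {int(j) - 2 for j in junctures}  # inside the 20% radius
        boost[list(cheap)] = 1.0
        path = select_apriori_path(ens, (0, 199), n_images=11, boost_energies=boost)
        interior = [im.frame for im in path.images[1:-1]]
        assert sum(f in cheap for f in interior) >= 8

    def test_neighbor_rmsd_invariant_holds(self, rng):
        ens = linear_morph_ensemble(rng)
        path = select_apriori_path(ens, (0, 199), n_images=11)
        assert max(path.neighbor_rmsd) < 1.4

    def test_infeasible_interval_reported(self, rng):
        ens = linear_morph_ensemble(rng, displacement=40.0)  # giant steps
        with pytest.raises(PathSelectionError):
            select_apriori_path(ens, (0, 199), n_images=11, rmsd_cutoff=0.2)

    def test_invariant_to_candidate_frame_permutation(self, rng):
        ens = linear_morph_ensemble(rng)
        perm = np.concatenate([[0], rng.permutation(np.arange(1, 199)), [199]])
        shuffled = Ensemble(ens.topology, ens.coords[perm])
        p1 = select_apriori_path(ens, (0, 199), n_images=11)
        p2 = select_apriori_path(shuffled, (0, 199), n_images=11)
        # compare the underlying structures, not the frame numbers
        for im1, im2 in zip(p1.images, p2.images):
            assert np.allclose(
                ens.coords[im1.frame], shuffled.coords[im2.frame], atol=1e-12
            )


class TestRepresentative:
    def test_single_frame_is_itself(self, rng):
        frame = rng.normal(size=(6, 3))
        assert np.allclose(representative_structure([frame]), frame)

    def test_symmetric_displacement_averages_to_midpoint(self):
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4.0]])
        up = base.copy()
        up[0, 2] += 0.3
        down = base.copy()
        down[0, 2] -= 0.3
        rep = representative_structure([up, down], reference=base)
        # the ±d displacements cancel (small residual from the re-fitting)
        assert rep[0, 2] == pytest.approx(0.0, abs=1e-3)
        assert np.allclose(rep[0], base[0], atol=1e-2)

    def test_representative_within_member_spread(self, rng):
        frames = [rng.normal(size=(8, 3)) * 0.3 + rng.normal(size=(8, 3))
                  for _ in range(5)]
        rep = representative_structure(frames)
        max_pair = max(
            rmsd(a, b) for a in frames for b in frames
        )
        assert all(rmsd(rep, f) <= max_pair + 1e-9 for f in frames)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            representative_structure([])


class TestMatchedResidueRmsd:
    def _structure(self, rng, n_res, seed_shift=0):
        topo = [AtomRecord(i + 1, "ALA", "CA", "C") for i in range(n_res)]
        coords = rng.normal(scale=5, size=(1, n_res, 3))
        return Ensemble(topo, coords)

    def test_identity_map_gives_zero(self, rng):
        s = self._structure(rng, 10)
        assert matched_residue_rmsd(s, s, [((1, 10), (1, 10))]) < 1e-9

    def test_rotated_copy_gives_zero(self, rng):
        from scipy.spatial.transform import Rotation

        s = self._structure(rng, 10)
        rot = Rotation.random(random_state=2).as_matrix()
        other = Ensemble(s.topology, (s.coords[0] @ rot.T + 3.0)[None])
        assert matched_residue_rmsd(s, other, [((1, 10), (1, 10))]) < 1e-6

    def test_matches_superpose_oracle_with_offset_map(self, rng):
        from hbnet.ensemble import superpose

        a = self._structure(rng, 12)
        b = self._structure(rng, 12)
        value = matched_residue_rmsd(a, b, [((3, 8), (5, 10))])
        _, expected = superpose(a.coords[0, 2:8], b.coords[0, 4:10])
        assert value == pytest.approx(expected, abs=1e-9)

    def test_unequal_ranges_rejected(self, rng):
        a = self._structure(rng, 8)
        with pytest.raises(ValueError):
            matched_residue_rmsd(a, a, [((1, 4), (1, 5))])
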