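"""Hydrogen-bond detection, occupancy tables, filters and the blacklist."""

import numpy as np
import pytest

from hbnet.ensemble import AtomRecord, Ensemble
from hbnet.hbonds import (
    COVALENT_H_CUTOFF,
    HBondCriteria,
    Moiety,
    OccupancyTable,
    POLAR_ELEMENTS,
    build_blacklist,
    build_occupancy,
    detect_hbonds,
    filter_flexible_loops,
    filter_trivial,
    node_label,
    parse_node_label,
)
from hbnet.synth import CausalSpec, gen_causal_ensemble
import pandas as pd


def triple_topology():
    """Donor backbone N-H of residue 1, acceptor side-chain O of residue 2."""
    return [
        AtomRecord(1, "ALA", "N", "N"),
        AtomRecord(1, "ALA", "H", "H"),
        AtomRecord(2, "SER", "OG", "O"),
    ]


class TestDetect:
    def test_collinear_bond_detected(self):
        frame = np.array([[0, 0, 0], [1, 0, 0], [2.9, 0, 0.0]])
        hits = detect_hbonds(frame, triple_topology())
        assert hits == [(0, 1, 2)]

    def test_distance_cutoff_excludes(self):
        frame = np.array([[0, 0, 0], [1, 0, 0], [3.2, 0, 0.0]])
        assert detect_hbonds(frame, triple_topology()) == []

    def test_angle_cutoff_excludes_with_dot_product_oracle(self):
        ang = np.deg2rad(50.0)
        frame = np.array(
            [[0, 0, 0], [1, 0, 0], [2.8 * np.cos(ang), 2.8 * np.sin(ang), 0.0]]
        )
        da = frame[2] - frame[0]
        dh = frame[1] - frame[0]
        oracle_angle = np.degrees(
            np.arccos(da @ dh / (np.linalg.norm(da) * np.linalg.norm(dh)))
        )
        assert oracle_angle == pytest.approx(50.0, abs=1e-9)
        assert np.linalg.norm(da) < 3.0
        assert detect_hbonds(frame, triple_topology()) == []

    def test_same_moiety_pairs_excluded(self):
        # donor and acceptor both backbone of residue 1
        topo = [
            AtomRecord(1, "ALA", "N", "N"),
            AtomRecord(1, "ALA", "H", "H"),
            AtomRecord(1, "ALA", "O", "O"),
        ]
        frame = np.array([[0, 0, 0], [1, 0, 0], [2.9, 0, 0.0]])
        assert detect_hbonds(frame, topo) == []

    def test_missing_hydrogens_is_an_error(self):
        topo = [AtomRecord(1, "ALA", "N", "N"), AtomRecord(2, "SER", "OG", "O")]
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(np.zeros((2, 3)), topo)

    def test_matches_brute_force_scan_on_random_frames(self, rng):
        """Exact set equality against an all-triples geometric scan."""
        names = ["N", "CA", "O", "OG", "ND2", "SD", "H", "HG", "HA"]
        elements = {"N": "N", "CA": "C", "O": "O", "OG": "O", "ND2": "N",
                    "SD": "S", "H": "H", "HG": "H", "HA": "H"}
        criteria = HBondCriteria()
        for _ in range(25):
            n = 50
            topo = [
                AtomRecord(int(rng.integers(1, 6)), "UNK", nm, elements[nm])
                for nm in rng.choice(names, size=n)
            ]
            frame = rng.uniform(0, 12, size=(n, 3))
            got = set(detect_hbonds(frame, topo, criteria))

            # independent brute force: nested loops, explicit geometry
            expected = set()
            for h in range(n):
                if topo[h].element != "H":
                    continue
                best, best_d = None, np.inf
                for d in range(n):
                    if topo[d].element == "H" or topo[d].residue_index != topo[h].residue_index:
                        continue
                    dist = float(np.linalg.norm(frame[d] - frame[h]))
                    if dist < best_d:
                        best, best_d = d, dist
                if best is None or best_d > COVALENT_H_CUTOFF:
                    continue
                d = best
                if topo[d].element not in POLAR_ELEMENTS:
                    continue
                for a in range(n):
                    if a == d or topo[a].element == "H":
                        continue
                    if topo[a].element not in POLAR_ELEMENTS:
                        continue
                    if (topo[a].residue_index, topo[a].moiety_class) == (
                        topo[d].residue_index, topo[d].moiety_class
                    ):
                        continue
                    da = frame[a] - frame[d]
                    dh = frame[h] - frame[d]
                    dist = float(np.linalg.norm(da))
                    if dist == 0 or dist > criteria.distance_cutoff:
                        continue
                    cosang = float(da @ dh / (dist * np.linalg.norm(dh)))
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if angle <= criteria.angle_cutoff:
                        expected.add((d, h, a))
            assert got == expected


class TestOccupancy:
    def test_persistent_single_bond(self):
        frame = np.array([[0, 0, 0], [1, 0, 0], [2.9, 0, 0.0]])
        ens = Ensemble(triple_topology(), np.repeat(frame[None], 3, axis=0))
        table = build_occupancy(ens)
        assert table.labels == ["Ala1_BB-Ser2_SC"]
        assert (table.counts["Ala1_BB-Ser2_SC"] == 1).all()

    def test_bidentate_counts_two(self):
        """Two simultaneous bonds between one moiety pair give count 2."""
        spec = CausalSpec.from_simple(
            arcs=[], cpts={"a": np.array([0.0, 0.0, 1.0])}
        )
        ens, table = gen_causal_ensemble(spec, 2, seed=0)
        built = build_occupancy(ens)
        label = built.labels[0]
        assert (built.counts[label] == 2).all()
        assert built.nodes[0].cardinality == 3  # value range {0, 1, 2}

    def test_round_trip_with_generator(self, chain_spec):
        ens, intended = gen_causal_ensemble(chain_spec, 200, seed=9)
        built = build_occupancy(ens)
        aligned = built.counts.reindex(columns=intended.labels, fill_value=0)
        assert aligned.equals(intended.counts)


def make_table(columns: dict[str, list[int]]) -> OccupancyTable:
    return OccupancyTable(pd.DataFrame(columns), {})


class TestFilters:
    def test_trivial_threshold_boundary(self):
        n = 20
        cols = {
            "Ala1_BB-Ser2_SC": [1] * 1 + [0] * 19,     # 5% -> dropped
            "Ala1_BB-Ser3_SC": [1] * 2 + [0] * 18,     # exactly 10% -> kept
            "Ala1_SC-Ser4_SC": [1] * 5 + [0] * 15,     # 25% -> kept
        }
        table = filter_trivial(make_table(cols), threshold=0.10)
        assert table.labels == ["Ala1_BB-Ser3_SC", "Ala1_SC-Ser4_SC"]

    def test_all_zero_column_dropped_defensively(self):
        table = filter_trivial(make_table({"Ala1_BB-Ser2_SC": [0] * 10}))
        assert table.labels == []

    def test_flexible_loop_rmsf_rule(self):
        table = make_table({
            "Ala1_BB-Ser2_SC": [1] * 10,
            "Ala3_BB-Ser4_SC": [1] * 10,
        })
        rmsf = {1: 0.5, 2: 2.5, 3: 1.0, 4: 2.0}
        out = filter_flexible_loops(table, rmsf=rmsf, cutoff=2.0)
        # residue 2 exceeds 2.0 Å; residue 4 at exactly 2.0 Å is retained
        assert out.labels == ["Ala3_BB-Ser4_SC"]

    def test_explicit_ranges_override_rmsf(self):
        table = make_table({"Ala110_BB-Ser200_SC": [1] * 4})
        out = filter_flexible_loops(
            table, rmsf={110: 0.1, 200: 0.1}, excluded_ranges=[(106, 123)]
        )
        assert out.labels == []

    def test_missing_rmsf_is_an_error(self):
        table = make_table({"Ala1_BB-Ser2_SC": [1] * 4})
        with pytest.raises(ValueError, match="residue 2"):
            filter_flexible_loops(table, rmsf={1: 0.5})

    def test_filters_commute_and_are_idempotent(self):
        cols = {
            "Ala1_BB-Ser2_SC": [1] * 1 + [0] * 19,
            "Ala3_BB-Ser4_SC": [1] * 20,
            "Ala5_BB-Ser6_SC": [1] * 10 + [0] * 10,
        }
        rmsf = {1: 0.1, 2: 0.1, 3: 3.0, 4: 0.1, 5: 0.1, 6: 0.1}
        t = make_table(cols)
        ab = filter_flexible_loops(filter_trivial(t), rmsf=rmsf)
        ba = filter_trivial(filter_flexible_loops(t, rmsf=rmsf))
        assert ab.labels == ba.labels == ["Ala5_BB-Ser6_SC"]
        assert filter_trivial(ab).labels == ab.labels
        assert filter_flexible_loops(ab, rmsf=rmsf).labels == ab.labels

    def test_constant_nodes_flagged_not_dropped(self):
        table = make_table({"Ala1_BB-Ser2_SC": [2] * 8, "Ala3_BB-Ser4_SC": [0, 1] * 4})
        kept = filter_trivial(table)
        assert kept.constant_nodes() == {"Ala1_BB-Ser2_SC": 2}


class TestBlacklist:
    def _ensemble(self):
        # three well-separated bonded pairs; A shares moiety with nothing
        spec = CausalSpec.from_simple(
            arcs=[],
            cpts={
                "a": np.array([0.2, 0.8]),
                "b": np.array([0.2, 0.8]),
                "c": np.array([0.2, 0.8]),
            },
        )
        return gen_causal_ensemble(spec, 50, seed=3)

    def test_distant_nodes_blacklisted(self):
        ens, table = self._ensemble()
        bl = build_blacklist(ens, table)
        labels = table.labels
        # donor clusters sit 20 Å apart -> no contact between different nodes
        assert (labels[0], labels[1]) in bl
        assert (labels[1], labels[2]) in bl

    def test_shared_moiety_always_candidate(self):
        cols = {"Ala1_SC-Ser2_SC": [1] * 4, "Ala1_SC-Ser3_SC": [1] * 4}
        table = make_table(cols)
        topo = [AtomRecord(r, "ALA", "CB", "C") for r in (1, 2, 3)]
        ens = Ensemble(topo, np.zeros((1, 3, 3)) + np.arange(3)[None, :, None] * 50)
        bl = build_blacklist(ens, table)
        assert ("Ala1_SC-Ser2_SC", "Ala1_SC-Ser3_SC") not in bl

    def test_mean_exactly_one_contact_pair_is_blacklisted(self):
        """The contact rule is strictly 'more than one pair on average'."""
        # residues 1-2 bonded (node A), residues 3-4 bonded (node B);
        # exactly one heavy-atom pair between residue 2 and 3 within 4 Å.
        topo = [
            AtomRecord(1, "ALA", "N", "N"), AtomRecord(1, "ALA", "H", "H"),
            AtomRecord(2, "SER", "OG", "O"),
            AtomRecord(3, "ALA", "N", "N"), AtomRecord(3, "ALA", "H", "H"),
            AtomRecord(4, "SER", "OG", "O"),
        ]
        frame = np.array([
            [0, 0, 0], [1, 0, 0], [2.9, 0, 0],
            [2.9 + 3.9, 0, 0], [2.9 + 3.9 + 1, 0, 0], [2.9 + 3.9 + 2.9, 0, 0],
        ])
        ens = Ensemble(topo, frame[None])
        table = build_occupancy(ens)
        assert len(table.labels) == 2
        bl = build_blacklist(ens, table, contact_cutoff=4.0, min_mean_pairs=1.0)
        assert (table.labels[0], table.labels[1]) in bl
        # with two contacting pairs the arc becomes a candidate
        bl2 = build_blacklist(ens, table, contact_cutoff=4.0, min_mean_pairs=0.5)
        assert (table.labels[0], table.labels[1]) not in bl2

    def test_symmetric_and_no_shared_moiety(self):
        ens, table = self._ensemble()
        bl = build_blacklist(ens, table)
        for pair in bl.forbidden:
            a, b = tuple(pair)
            assert frozenset((b, a)) in bl.forbidden
            assert not set(parse_node_label(a)) & set(parse_node_label(b))


def test_node_label_canonical_ordering():
    names = {27: "ASP", 133: "ARG"}
    assert node_label(Moiety(133, "SC"), Moiety(27, "SC"), names) == "Asp27_SC-Arg133_SC"
    assert node_label(Moiety(27, "SC"), Moiety(27, "BB"), names) == "Asp27_BB-Asp27_SC"
    a, b = parse_node_label("Asp27_SC-Arg133_SC")
    assert (a.residue_index, a.part) == (27, "SC")
    assert (b.residue_index, b.part) == (133, "SC")


def test_occupancy_tsv_round_trip(tmp_path, chain_spec):
    from hbnet.synth import gen_occupancy

    table = gen_occupancy(chain_spec, 30, seed=2)
    path = tmp_path / "occ.tsv"
    table.to_tsv(path)
    back = OccupancyTable.from_tsv(path)
    assert back.counts.equals(table.counts)
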