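"""Contact predicate, RIN construction, comparison and export."""

import numpy as np
import pytest

from ppimutscan.contact_network import (
    ContactCriterion,
    atom_overlap,
    build_rin,
    compare_rins,
    export_rin,
    import_rin_graphml,
    residue_contacts_frame,
)
from ppimutscan.ensemble_io import Ensemble
from ppimutscan.synthetic_data import SyntheticTruth, make_ensemble, make_toy_complex
from conftest import two_chain_structure


def brute_force_contacts(structure, criterion):
    """All-pairs reference implementation of the residue contact map."""
    idx = [
        i
        for i in range(structure.n_atoms)
        if criterion.include_hydrogens or structure.elements[i] != "H"
    ]
    counts = {}
    for ai in idx:
        for aj in idx:
            if aj <= ai:
                continue
            ra = (str(structure.chain_ids[ai]), int(structure.residue_numbers[ai]))
            rb = (str(structure.chain_ids[aj]), int(structure.residue_numbers[aj]))
            if ra == rb:
                continue
            if criterion.interchain_only and ra[0] == rb[0]:
                continue
            d = np.linalg.norm(structure.positions[ai] - structure.positions[aj])
            overlap = structure.vdw_radii[ai] + structure.vdw_radii[aj] - d
            if overlap > criterion.overlap_threshold:
                key = (ra, rb) if ra < rb else (rb, ra)
                counts[key] = counts.get(key, 0) + 1
    return counts


def random_two_chain(rng, n_atoms=200):
    """Random 200-atom two-chain fixture with mixed radii."""
    half = n_atoms // 2
    pos = rng.uniform(0, 18.0, size=(n_atoms, 3))
    radii = rng.choice([1.2, 1.52, 1.55, 1.7, 1.8], size=n_atoms)
    s = two_chain_structure(pos[:half], pos[half:])
    s.vdw_radii[:] = radii
    # several atoms per residue
    s.residue_numbers[:] = np.concatenate(
        [np.sort(rng.integers(1, 1 + half // 4, size=half)) for _ in range(2)]
    )
    s.names[:] = [f"X{i}" for i in range(n_atoms)]  # keep atom keys unique
    return s


class TestAtomOverlap:
    @pytest.mark.parametrize(
        "d,expected,is_contact",
        [(3.00, 0.22, True), (3.70, -0.48, False), (3.62, -0.40, False)],
        ids=["overlapping", "separated", "exact-threshold-excluded"],
    )
    def test_overlap_arithmetic_and_strict_predicate(self, d, expected, is_contact):
        ov = atom_overlap(1.70, 1.52, d)
        assert ov == pytest.approx(expected)
        assert (ov > -0.4) is is_contact

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            atom_overlap(1.7, 1.7, -0.1)


class TestResidueContactsFrame:
    def test_minimal_contact_pair(self):
        s = two_chain_structure([[0.0, 0, 0]], [[3.0, 0, 0]])
        s.vdw_radii[:] = [1.7, 1.52]
        contacts = residue_contacts_frame(s, ContactCriterion())
        assert contacts == {(("A", 1), ("B", 1)): 1}

    def test_far_pair_empty(self):
        s = two_chain_structure([[0.0, 0, 0]], [[50.0, 0, 0]])
        assert residue_contacts_frame(s, ContactCriterion()) == {}

    @pytest.mark.parametrize("seed", range(50))
    def test_kdtree_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = random_two_chain(rng)
        crit = ContactCriterion(overlap_threshold=float(rng.uniform(-1.0, 0.5)))
        assert residue_contacts_frame(s, crit) == brute_force_contacts(s, crit)

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_two_chain(rng)
        tight = residue_contacts_frame(s, ContactCriterion(overlap_threshold=0.0))
        loose = residue_contacts_frame(s, ContactCriterion(overlap_threshold=-0.8))
        assert set(tight) <= set(loose)
        for key in tight:
            assert loose[key] >= tight[key]

    def test_unparameterized_radii_rejected(self):
        s = two_chain_structure([[0.0, 0, 0]], [[3.0, 0, 0]])
        s.vdw_radii[:] = np.nan
        with pytest.raises(ValueError):
            residue_contacts_frame(s, ContactCriterion())


class TestBuildRin:
    def test_persistence_enumeration(self, toy_structure):
        # pair (A3,B3) planted in 2 of 3 frames by persistence machinery
        base = toy_structure.positions
        coords = np.repeat(base[None], 3, axis=0)
        # break the (A3,B3) contact in frame 2 by moving A3's CB bead away
        cb3 = [
            i
            for i in toy_structure.residue_atom_indices()[("A", 3)]
            if toy_structure.names[i] == "CB"
        ][0]
        coords[2, cb3, 1] -= 3.0
        ens = Ensemble(toy_structure, coords, 100.0 * np.arange(3))
        rin = build_rin(ens)
        assert rin.persistence(("A", 3), ("B", 3)) == pytest.approx(2 / 3)
        assert rin.persistence(("A", 7), ("B", 7)) == pytest.approx(1.0)

    def test_static_ensemble_persistence_one(self, toy_structure):
        coords = np.repeat(toy_structure.positions[None], 4, axis=0)
        ens = Ensemble(toy_structure, coords, 100.0 * np.arange(4))
        rin = build_rin(ens)
        single = residue_contacts_frame(toy_structure, ContactCriterion())
        assert set(rin.edges()) == set(single)
        assert all(e["persistence"] == 1.0 for e in rin.edges().values())

    def test_planted_contact_gain_raises_degree(self, variant_suite):
        rin_wt = build_rin(variant_suite.wild_type)
        rin_gain = build_rin(variant_suite.contact_gain)
        res = ("A", variant_suite.gain_residue)
        assert rin_gain.degree(res) > rin_wt.degree(res)

    def test_bipartite_degree_conservation(self, variant_suite):
        rin = build_rin(variant_suite.contact_gain)
        degs = rin.degrees()
        sum_a = sum(d for (c, _), d in degs.items() if c == "A")
        sum_b = sum(d for (c, _), d in degs.items() if c == "B")
        assert sum_a == sum_b == rin.n_edges

    def test_mean_atom_pairs_includes_zero_frames(self, toy_structure):
        coords = np.repeat(toy_structure.positions[None], 4, axis=0)
        cb3 = [
            i
            for i in toy_structure.residue_atom_indices()[("A", 3)]
            if toy_structure.names[i] == "CB"
        ][0]
        coords[3, cb3, 1] -= 3.0  # one frame without the contact
        ens = Ensemble(toy_structure, coords, 100.0 * np.arange(4))
        rin = build_rin(ens)
        assert rin.edges()[(("A", 3), ("B", 3))]["mean_atom_pairs"] == pytest.approx(3 / 4)


class TestCompareRins:
    def test_identity_all_zero(self, variant_suite):
        rin = build_rin(variant_suite.wild_type)
        diff = compare_rins(rin, rin)
        assert not diff.gained_edges and not diff.lost_edges
        assert all(v == 0 for v in diff.degree_delta.values())
        assert all(v == 0.0 for v in diff.persistence_delta.values())

    def test_single_added_edge(self, variant_suite):
        import networkx as nx

        from ppimutscan.contact_network import ContactGraph

        rin = build_rin(variant_suite.wild_type)
        g2 = rin.graph.copy()
        g2.add_edge(("A", 1), ("B", 1), persistence=1.0, mean_atom_pairs=1.0)
        rin2 = ContactGraph(graph=g2, criterion=rin.criterion, n_frames=rin.n_frames)
        diff = compare_rins(rin, rin2)
        assert diff.gained_edges == [(("A", 1), ("B", 1))]
        assert diff.degree_delta[("A", 1)] == 1
        assert diff.degree_delta[("B", 1)] == 1

    def test_planted_mutant_gained_edges(self, variant_suite):
        diff = compare_rins(
            build_rin(variant_suite.wild_type), build_rin(variant_suite.contact_gain)
        )
        planted = {
            (("A", a), ("B", b)) for a, b in variant_suite.gain_pairs
        }
        assert planted <= set(diff.gained_edges)

    def test_criterion_mismatch_refused(self, variant_suite):
        rin1 = build_rin(variant_suite.wild_type)
        rin2 = build_rin(
            variant_suite.wild_type, criterion=ContactCriterion(overlap_threshold=0.0)
        )
        with pytest.raises(ValueError, match="criteria"):
            compare_rins(rin1, rin2)


class TestExport:
    def test_sif_minimal(self, tmp_path):
        s = two_chain_structure([[0.0, 0, 0]], [[3.0, 0, 0]])
        ens = Ensemble(s, s.positions[None], np.array([0.0]))
        rin = build_rin(ens)
        p = tmp_path / "net.sif"
        export_rin(rin, p)
        assert p.read_text().strip() == "A:1\tcontact\tB:1"

    def test_graphml_round_trip(self, tmp_path, variant_suite):
        rin = build_rin(variant_suite.contact_gain)
        p = tmp_path / "net.graphml"
        export_rin(rin, p)
        back = import_rin_graphml(p)
        assert set(back.edges()) == set(rin.edges())
        for key, data in rin.edges().items():
            assert back.edges()[key]["persistence"] == pytest.approx(data["persistence"])
        assert back.degrees() == rin.degrees()

    def test_csv_export_has_all_edges(self, tmp_path, variant_suite):
        rin = build_rin(variant_suite.wild_type)
        p = tmp_path / "net.csv"
        export_rin(rin, p)
        assert len(p.read_text().strip().splitlines()) == rin.n_edges + 1

    def test_empty_graph_refused(self, tmp_path):
        s = two_chain_structure([[0.0, 0, 0]], [[50.0, 0, 0]])
        ens = Ensemble(s, s.positions[None], np.array([0.0]))
        rin = build_rin(ens)
        with pytest.raises(ValueError):
            export_rin(rin, tmp_path / "empty.graphml")

    def test_unknown_format_rejected(self, tmp_path, variant_suite):
        rin = build_rin(variant_suite.wild_type)
        with pytest.raises(ValueError):
            export_rin(rin, tmp_path / "net.xyz", format="xyz")
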