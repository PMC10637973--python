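"""Superposition, identity and interface census against oracles and geometry."""

import math

import numpy as np
import pytest

from looptag.compare import (
    DegenerateGeometryError,
    buried_surface_area,
    find_hbonds,
    find_salt_bridges,
    interface_report,
    kabsch,
    sequence_align,
    structure_superpose,
)
from looptag.fixtures import (
    make_compact_bundle,
    perturb,
    random_rotation,
    rigid_transform,
)
from looptag.structure import Chain, transform_model

from conftest import make_atom, make_model, make_residue


class TestKabsch:
    def test_identity_on_equal_sets(self):
        P = np.random.default_rng(0).normal(size=(12, 3))
        res = kabsch(P, P.copy())
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_recovers_planted_rotation(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(10, 3))
        R = random_rotation(seed + 1000)
        t = rng.uniform(-10, 10, 3)
        res = kabsch(P, P @ R.T + t)
        assert np.abs(res.rotation - R).max() < 1e-6
        assert res.rmsd < 1e-9

    def test_rotation_always_proper_even_near_planar(self):
        rng = np.random.default_rng(99)
        for trial in range(2000):
            P = rng.normal(size=(5, 3))
            P[:, 2] *= 1e-4  # near-planar
            Q = rng.normal(size=(5, 3))
            res = kabsch(P, Q)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_agrees_with_independent_least_squares_oracle(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        for seed in range(20):
            P = rng.normal(size=(10, 3))
            Q = P @ random_rotation(seed).T + rng.normal(scale=0.5, size=(10, 3))
            ours = kabsch(P, Q)
            ref, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
            assert np.abs(ours.rotation - ref.as_matrix()).max() < 1e-6
            assert ours.rmsd == pytest.approx(rssd / math.sqrt(len(P)), rel=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)


class TestSequenceAlign:
    def test_identical_sequences_are_100_percent(self):
        assert sequence_align("MQIFVKTLTGK", "MQIFVKTLTGK").identity_pct == pytest.approx(100.0)

    def test_single_substitution_hand_count(self):
        res = sequence_align("ACDEFG", "ACDQFG")
        assert res.identity_pct == pytest.approx(100.0 * 5 / 6)
        assert res.n_identical == 5

    def test_identity_is_symmetric(self):
        a, b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKTAYIAKQRGISFVKSHFSRQLEERLGLIEVA"
        assert sequence_align(a, b).identity_pct == pytest.approx(
            sequence_align(b, a).identity_pct
        )

    def test_gapped_alignment_counts_non_gap_pairs(self):
        # deleting 3 residues: remaining 12 columns all identical
        a = "ACDEFGHIKLMNPQR"
        b = "ACDEFGIKLMNPQR"[:6] + "KLMNPQR"  # ACDEFG + KLMNPQR (HI + one more removed)
        res = sequence_align(a, "ACDEFGKLMNPQR")
        assert res.n_identical == 13
        assert res.identity_pct == pytest.approx(100.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_align("", "ACD")


class TestStructureSuperpose:
    def test_chain_against_itself(self):
        chain = make_compact_bundle(60, 6.3, seed=1).chains[0]
        res = structure_superpose(chain, chain)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_pairs_used == res.n_pairs_total == 60

    def test_displaced_segment_rejected_core_rmsd_matches_noise(self):
        model = make_compact_bundle(100, 6.3, seed=2)
        noisy = perturb(make_compact_bundle(100, 6.3, seed=2), 0.3, seed=3)
        # displace 10% of residues by 8 Å
        for res in noisy.chains[0].polymer_residues[45:55]:
            for atom in res.atoms:
                atom.xyz = atom.xyz + np.array([8.0, 0.0, 0.0])
        moved, _, _ = rigid_transform(noisy, seed=4)
        result = structure_superpose(model.chains[0], moved.chains[0])
        assert result.n_pairs_total == 100
        assert result.n_pairs_used == 90
        expected = 0.3 * math.sqrt(3)
        assert result.rmsd == pytest.approx(expected, rel=0.25)

    def test_rmsd_symmetric_in_argument_order(self):
        a = make_compact_bundle(80, 6.3, seed=5).chains[0]
        b = perturb(make_compact_bundle(80, 6.3, seed=5), 0.4, seed=6).chains[0]
        assert structure_superpose(a, b).rmsd == pytest.approx(
            structure_superpose(b, a).rmsd, abs=1e-6
        )

    def test_rmsd_invariant_under_rigid_motion_of_either_chain(self):
        a = make_compact_bundle(50, 6.3, seed=7)
        b = perturb(make_compact_bundle(50, 6.3, seed=7), 0.5, seed=8)
        base = structure_superpose(a.chains[0], b.chains[0]).rmsd
        moved, _, _ = rigid_transform(b, seed=9)
        assert structure_superpose(a.chains[0], moved.chains[0]).rmsd == pytest.approx(
            base, abs=1e-6
        )


def two_sphere_model(d: float, radius_element: str = "C"):
    a = Chain("A", polymer_residues=[make_residue("ALA", 1, [("CA", radius_element, [0, 0, 0])])])
    b = Chain("B", polymer_residues=[make_residue("ALA", 1, [("CA", radius_element, [d, 0, 0])])])
    return make_model([a, b])


class TestBuriedSurfaceArea:
    def test_distant_chains_bury_nothing(self):
        bsa = buried_surface_area(two_sphere_model(100.0), ["A"], ["B"], n_points=400)
        assert bsa.total_buried == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [3.0, 4.0, 5.0])
    def test_two_sphere_contact_matches_analytic_caps(self, d):
        R = 1.7 + 1.4  # carbon + probe
        bsa = buried_surface_area(two_sphere_model(d), ["A"], ["B"], n_points=4000)
        analytic = 2.0 * (2.0 * math.pi * R * (R - d / 2.0))  # two equal caps
        assert bsa.total_buried == pytest.approx(analytic, rel=0.03)
        assert bsa.per_side == pytest.approx(bsa.total_buried / 2)

    def test_symmetric_under_partner_swap(self):
        model = two_sphere_model(4.0)
        ab = buried_surface_area(model, ["A"], ["B"], n_points=800)
        ba = buried_surface_area(model, ["B"], ["A"], n_points=800)
        assert ab.total_buried == pytest.approx(ba.total_buried, abs=1e-9)

    def test_overlapping_partition_rejected(self):
        from looptag.structure import LoopTagError

        with pytest.raises(LoopTagError):
            buried_surface_area(two_sphere_model(4.0), ["A"], ["A"])


def polar_interface_model(seed: int, n_per_side: int = 8):
    """Random two-chain arrangement of polar/charged residues (oracle food)."""
    rng = np.random.default_rng(seed)
    kinds = [
        ("SER", [("OG", "O")]), ("ASN", [("OD1", "O"), ("ND2", "N")]),
        ("LYS", [("NZ", "N")]), ("GLU", [("OE1", "O"), ("OE2", "O")]),
        ("ARG", [("NH1", "N"), ("NH2", "N"), ("NE", "N")]),
        ("ASP", [("OD1", "O"), ("OD2", "O")]), ("GLY", []),
    ]
    chains = []
    for cid, x_shift in (("A", 0.0), ("B", 3.0)):
        residues = []
        for i in range(n_per_side):
            name, side_atoms = kinds[rng.integers(0, len(kinds))]
            ca = rng.uniform(0, 12, 3) + np.array([x_shift, 0.0, 0.0])
            atoms = [("CA", "C", ca), ("N", "N", ca + [0.8, 0.5, 0.0]),
                     ("C", "C", ca + [-0.8, 0.5, 0.0]), ("O", "O", ca + [-1.2, 1.5, 0.0])]
            for aname, elem in side_atoms:
                atoms.append((aname, elem, ca + rng.uniform(-2, 2, 3)))
            residues.append(make_residue(name, i + 1, atoms))
        chains.append(Chain(cid, polymer_residues=residues))
    return make_model(chains)


DONORS = {"SER": ["OG"], "ASN": ["ND2"], "LYS": ["NZ"], "ARG": ["NH1", "NH2", "NE"],
          "GLU": [], "ASP": [], "GLY": []}
ACCEPTORS = {"SER": ["OG"], "ASN": ["OD1"], "GLU": ["OE1", "OE2"],
             "ASP": ["OD1", "OD2"], "LYS": [], "ARG": [], "GLY": []}


def brute_force_hbonds(model, d_max=3.5):
    """All-pairs oracle over the test's own donor/acceptor tables."""
    found = set()
    chains = {c.chain_id: c for c in model.chains}
    for da_side, acc_side in (("A", "B"), ("B", "A")):
        for res_d in chains[da_side].polymer_residues:
            d_names = DONORS[res_d.name3] + ["N"]
            for res_a in chains[acc_side].polymer_residues:
                a_names = ACCEPTORS[res_a.name3] + ["O"]
                for dn in d_names:
                    datom = res_d.get_atom(dn)
                    if datom is None:
                        continue
                    for an in a_names:
                        aatom = res_a.get_atom(an)
                        if aatom is None:
                            continue
                        if math.dist(datom.xyz, aatom.xyz) <= d_max:
                            found.add(frozenset([
                                (da_side, res_d.author_seq, dn),
                                (acc_side, res_a.author_seq, an),
                            ]))
    return found


BASIC = {"ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"]}
ACIDIC = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}


def brute_force_salt_bridges(model, d_max=4.0):
    found = set()
    chains = {c.chain_id: c for c in model.chains}
    for b_side, a_side in (("A", "B"), ("B", "A")):
        for res_b in chains[b_side].polymer_residues:
            b_names = list(BASIC.get(res_b.name3, []))
            if res_b is chains[b_side].polymer_residues[0]:
                b_names.append("N")
            for res_a in chains[a_side].polymer_residues:
                a_names = list(ACIDIC.get(res_a.name3, []))
                for bn in b_names:
                    batom = res_b.get_atom(bn)
                    if batom is None:
                        continue
                    for an in a_names:
                        aatom = res_a.get_atom(an)
                        if aatom is not None and math.dist(batom.xyz, aatom.xyz) <= d_max:
                            found.add((
                                (b_side, res_b.author_seq, ""),
                                (a_side, res_a.author_seq, ""),
                            ))
    return found


class TestHbonds:
    def test_planted_cross_chain_pair(self):
        a = Chain("A", polymer_residues=[make_residue("SER", 1, [
            ("CA", "C", [0, 0, 0]), ("OG", "O", [0, 0, 1.0])])])
        b = Chain("B", polymer_residues=[make_residue("ASN", 1, [
            ("CA", "C", [3.5, 0, 1.0]), ("ND2", "N", [2.9, 0, 1.0])])])
        contacts = find_hbonds(make_model([a, b]), ["A"], ["B"])
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(2.9)

    def test_pair_beyond_cutoff_ignored(self):
        a = Chain("A", polymer_residues=[make_residue("SER", 1, [
            ("CA", "C", [0, 0, 0]), ("OG", "O", [0, 0, 1.0])])])
        b = Chain("B", polymer_residues=[make_residue("ASN", 1, [
            ("CA", "C", [5.0, 0, 1.0]), ("ND2", "N", [4.2, 0, 1.0])])])
        assert find_hbonds(make_model([a, b]), ["A"], ["B"]) == []

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        model = polar_interface_model(seed)
        ours = {
            frozenset([(c.res_a[0], c.res_a[1], c.atom_a), (c.res_b[0], c.res_b[1], c.atom_b)])
            for c in find_hbonds(model, ["A"], ["B"])
        }
        assert ours == brute_force_hbonds(model)

    def test_no_intra_chain_contact_reported(self):
        for seed in range(10):
            model = polar_interface_model(seed)
            for c in find_hbonds(model, ["A"], ["B"]):
                assert {c.res_a[0], c.res_b[0]} == {"A", "B"}


class TestSaltBridges:
    def test_planted_arg_glu_pair(self):
        a = Chain("A", polymer_residues=[make_residue("ARG", 1, [
            ("CA", "C", [0, 0, 0]), ("NH1", "N", [0, 0, 1.0])])])
        b = Chain("B", polymer_residues=[make_residue("GLU", 1, [
            ("CA", "C", [4.0, 0, 1.0]), ("OE1", "O", [3.2, 0, 1.0])])])
        bridges = find_salt_bridges(make_model([a, b]), ["A"], ["B"])
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.2)

    def test_like_charges_never_bridge(self):
        a = Chain("A", polymer_residues=[make_residue("ARG", 1, [
            ("CA", "C", [0, 0, 0]), ("NH1", "N", [0, 0, 1.0])])])
        b = Chain("B", polymer_residues=[make_residue("ARG", 1, [
            ("CA", "C", [4.0, 0, 1.0]), ("NH1", "N", [3.2, 0, 1.0])])])
        assert find_salt_bridges(make_model([a, b]), ["A"], ["B"]) == []

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        model = polar_interface_model(seed + 500)
        ours = {(s.basic_res, s.acidic_res) for s in find_salt_bridges(model, ["A"], ["B"])}
        assert ours == brute_force_salt_bridges(model)


class TestInterfaceReport:
    def test_census_invariant_under_rigid_motion(self):
        model = polar_interface_model(3)
        base = interface_report(model, ["A"], ["B"], sasa_points=300)
        R = random_rotation(11)
        moved = transform_model(model, R, np.array([5.0, -3.0, 9.0]))
        after = interface_report(moved, ["A"], ["B"], sasa_points=300)
        assert len(after.hbonds) == len(base.hbonds)
        assert len(after.salt_bridges) == len(base.salt_bridges)
        assert after.bsa.total_buried == pytest.approx(base.bsa.total_buried, rel=0.02, abs=1.0)

    def test_record_is_json_serializable(self):
        import json

        model = polar_interface_model(4)
        record = interface_report(model, ["A"], ["B"], sasa_points=200).to_record()
        assert json.loads(json.dumps(record))["partners"] == {"A": ["A"], "B": ["B"]}
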