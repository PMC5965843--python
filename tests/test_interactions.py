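"""Hydrogen-bond detection/differencing and packing-contact counting."""

import numpy as np
import pytest

import ploopflex as pf
from ploopflex.interaction_analysis import HBondCriteria
from ploopflex.structure_io import Atom, Chain, Model, Residue, Structure


def _two_residue_hbond_fixture(distance: float = 2.9) -> Structure:
    """Backbone amide N of residue 10 pointing at carbonyl O of residue 20.

    Geometry is ideal by construction: the N->O direction is opposite the
    CA/C-prev bisector, so the donor-angle criterion is comfortably met.
    """
    chain = Chain("A")
    # donor residue: N at origin, CA and C(prev substitute) behind it
    donor = Residue("A", 10, "", "ALA")
    donor.atoms = [
        Atom(1, "N", "N", [0.0, 0.0, 0.0]),
        Atom(2, "CA", "C", [-0.9, 1.2, 0.0]),
        Atom(3, "C", "C", [-2.3, 1.0, 0.3]),
        Atom(4, "O", "O", [-3.0, 2.0, 0.3]),
    ]
    acceptor = Residue("A", 20, "", "ALA")
    acceptor.atoms = [
        Atom(5, "N", "N", [distance + 2.4, -1.0, 0.0]),
        Atom(6, "CA", "C", [distance + 1.9, 0.3, 0.0]),
        Atom(7, "C", "C", [distance + 1.23, 0.0, 0.0]),
        Atom(8, "O", "O", [distance, 0.0, 0.0]),
    ]
    chain.residues = [donor, acceptor]
    return Structure("HBFIX", [Model(chains=[chain])])


class TestFindHbonds:
    def test_ideal_geometry_one_bond(self):
        s = _two_residue_hbond_fixture(2.9)
        bonds = pf.find_hbonds(s)
        nn = [b for b in bonds if b.donor[3] == "N" and b.acceptor[3] == "O"
              and b.donor[1] == 10]
        assert len(nn) == 1
        assert nn[0].distance == pytest.approx(2.9, abs=0.01)
        assert nn[0].donor_angle >= 90.0

    def test_stretched_fixture_no_bond(self):
        s = _two_residue_hbond_fixture(5.0)
        bonds = [b for b in pf.find_hbonds(s)
                 if b.donor[1] == 10 and b.acceptor[1] == 20]
        assert bonds == []

    def test_tightening_cutoff_never_adds_bonds(self, motif_peptide):
        loose = pf.find_hbonds(motif_peptide, criteria=HBondCriteria(3.5))
        tight = pf.find_hbonds(motif_peptide, criteria=HBondCriteria(3.0))
        assert set(tight) <= set(loose)

    def test_empty_region_rejected(self, motif_peptide):
        with pytest.raises(ValueError, match="no residues"):
            pf.find_hbonds(motif_peptide, pf.Selection(residues=(500, 600)))

    def test_rigid_motion_invariance(self):
        s = _two_residue_hbond_fixture(2.9)
        moved = Structure("M", [s.models[0]]).transformed(
            pf.RigidTransform.from_axis_angle([1, 2, 3], 50.0).rotation,
            np.array([3.0, -2.0, 1.0]))
        b0 = {(b.donor, b.acceptor) for b in pf.find_hbonds(s)}
        b1 = {(b.donor, b.acceptor) for b in pf.find_hbonds(moved)}
        assert b0 == b1


class TestNetworkDiff:
    def test_self_diff_empty(self):
        s = _two_residue_hbond_fixture(2.9)
        diff = pf.compare_hbond_networks(s, s)
        assert diff.only_in_a == [] and diff.only_in_b == []
        assert len(diff.shared) >= 1

    def test_broken_bond_appears_in_only_a(self):
        a = _two_residue_hbond_fixture(2.9)
        b = _two_residue_hbond_fixture(5.0)  # same topology, bond broken
        diff = pf.compare_hbond_networks(a, b)
        labels = {h.label for h in diff.only_in_a}
        assert (10, "N", 20, "O") in labels
        assert all(h.label != (10, "N", 20, "O") for h, _ in diff.shared)

    def test_missing_region_warns(self, motif_peptide):
        diff = pf.compare_hbond_networks(
            motif_peptide, motif_peptide,
            pf.Selection(residues=(500, 600)))
        assert diff.warning is not None


def _brute_force_cc(s: Structure, seq_num: int, cutoff: float) -> int:
    """Independent O(N^2) double loop over all carbon pairs."""
    ch = s.first_chain
    query = ch.residue(seq_num)
    backbone = {"N", "CA", "C", "O", "OXT"}
    count = 0
    for a in query.atoms:
        if a.element != "C" or a.name in backbone:
            continue
        for r in ch.residues:
            if r.key == query.key:
                continue
            for b in r.atoms:
                if b.element != "C":
                    continue
                if np.linalg.norm(a.coords - b.coords) <= cutoff:
                    count += 1
    return count


class TestContactCounts:
    def test_glycine_has_zero(self, motif_peptide):
        cc = pf.count_cc_contacts(motif_peptide, 4)  # Gly at motif position 4
        assert cc.count == 0

    def test_constructed_three_pairs_match_brute_force(self):
        chain = Chain("A")
        r1 = Residue("A", 1, "", "VAL")
        r1.atoms = [Atom(1, "CB", "C", [0, 0, 0]),
                    Atom(2, "CG1", "C", [1.5, 0, 0])]
        r2 = Residue("A", 2, "", "LEU")
        r2.atoms = [Atom(3, "CB", "C", [0, 3.0, 0]),     # near both (3.0, 3.35)
                    Atom(4, "CG", "C", [0, 4.4, 0]),     # near CB only (4.4; 4.65 to CG1)
                    Atom(5, "CD1", "C", [0, 30.0, 0])]   # far from everything
        chain.residues = [r1, r2]
        s = Structure("CC3", [Model(chains=[chain])])
        cc = pf.count_cc_contacts(s, 1, cutoff=4.5)
        assert cc.count == 3
        assert cc.count == _brute_force_cc(s, 1, 4.5)

    def test_matches_brute_force_on_peptide(self, motif_peptide):
        for seq in (1, 2, 3, 6, 8):
            cc = pf.count_cc_contacts(motif_peptide, seq)
            assert cc.count == _brute_force_cc(motif_peptide, seq, 4.5)

    def test_cutoff_monotonicity(self, motif_peptide):
        for seq in (1, 3, 6):
            c_small = pf.count_cc_contacts(motif_peptide, seq, cutoff=4.0).count
            c_large = pf.count_cc_contacts(motif_peptide, seq, cutoff=5.0).count
            assert c_small <= c_large

    def test_removing_atoms_never_increases(self, motif_peptide):
        import copy
        full = pf.count_cc_contacts(motif_peptide, 6).count
        pruned = copy.deepcopy(motif_peptide)
        for r in pruned.first_chain.residues:
            if r.seq_num != 6:
                r.atoms = [a for a in r.atoms if a.name != "CB"]
        assert pf.count_cc_contacts(pruned, 6).count <= full

    def test_rigid_motion_invariance_exact(self, motif_peptide):
        moved = pf.perturb_rigid(motif_peptide, [0, 1, 1], 120.0, (7.0, 0.0, -3.0))
        for seq in (1, 3, 6, 8):
            assert (pf.count_cc_contacts(motif_peptide, seq).count
                    == pf.count_cc_contacts(moved, seq).count)

    def test_absent_residue_errors(self, motif_peptide):
        with pytest.raises(KeyError):
            pf.count_cc_contacts(motif_peptide, 99)


class TestContactProfile:
    def test_single_residue_structure_zero(self):
        chain = Chain("A")
        r = Residue("A", 1, "", "VAL")
        r.atoms = [Atom(1, "CB", "C", [0, 0, 0])]
        chain.residues = [r]
        s = Structure("ONE", [Model(chains=[chain])])
        prof = pf.contact_profile(s)
        assert prof["contacts"].sum() == 0

    def test_profile_consistent_with_per_residue_counts(self, motif_peptide):
        prof = pf.contact_profile(motif_peptide)
        for _, row in prof.iterrows():
            assert row["contacts"] == pf.count_cc_contacts(
                motif_peptide, row["seq_num"]).count

    def test_hydrophilic_group_exclusion_never_increases(self, motif_peptide):
        full = pf.contact_profile(motif_peptide)
        excl = pf.contact_profile(motif_peptide, exclude_hydrophilic_groups=True)
        assert (excl["contacts"] <= full["contacts"]).all()
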