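"""Dihedral tables, Ramachandran classes, flips, P-loop state, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ploopflex as pf
from ploopflex.conformation_analysis import DihedralRecord, classify_rama
from ploopflex.geometry_core import RigidTransform

from conftest import random_rotation, wrap_diff


class TestBackboneDihedrals:
    def test_helix_round_trip(self, helix):
        recs = pf.backbone_dihedrals(helix.first_chain)
        for rec in recs[1:-1]:
            assert rec.phi == pytest.approx(-57.0, abs=1e-6)
            assert rec.psi == pytest.approx(-47.0, abs=1e-6)
            assert wrap_diff(rec.omega, 180.0) < 1e-6

    def test_termini_flagged_absent(self, helix):
        recs = pf.backbone_dihedrals(helix.first_chain)
        assert recs[0].phi is None and recs[0].omega is None
        assert recs[0].psi is not None
        assert recs[-1].psi is None and recs[-1].phi is not None

    def test_chain_break_blanks_angles(self, helix):
        # displace the second half far away: CA-CA gap > 4.5 A
        chain = helix.first_chain
        for r in chain.residues[5:]:
            for a in r.atoms:
                a.coords = a.coords + np.array([50.0, 0, 0])
        recs = pf.backbone_dihedrals(chain)
        assert recs[4].psi is None  # break after residue 5
        assert recs[5].phi is None and recs[5].omega is None

    def test_no_backbone_errors(self):
        from ploopflex.structure_io import Chain
        empty = Chain("A")
        with pytest.raises(ValueError):
            pf.backbone_dihedrals(empty)


class TestRamaClassification:
    @pytest.mark.parametrize("res", ["ALA", "GLY", "LEU"])
    def test_canonical_helix_point_favored(self, res):
        rec = DihedralRecord(("A", 1, ""), res, -57.0, -47.0, 180.0)
        assert classify_rama(rec).label == "favored-general"

    def test_glycine_only_region(self):
        # a phi>0 mirror-region point: fine for glycine, outlier otherwise
        rec_g = DihedralRecord(("A", 1, ""), "GLY", 100.0, -170.0, 180.0)
        rec_a = DihedralRecord(("A", 1, ""), "ALA", 100.0, -170.0, 180.0)
        assert classify_rama(rec_g).label == "glycine-only"
        assert classify_rama(rec_a).label == "outlier"

    def test_absent_angles_not_classifiable(self):
        rec = DihedralRecord(("A", 1, ""), "ALA", None, -47.0, 180.0)
        with pytest.raises(ValueError, match="absent"):
            classify_rama(rec)

    @given(st.integers(-179, 180), st.integers(-179, 180))
    @settings(max_examples=200, deadline=None)
    def test_total_and_deterministic_on_grid(self, phi, psi):
        for res in ("ALA", "GLY"):
            rec = DihedralRecord(("A", 1, ""), res, float(phi), float(psi), None)
            first = classify_rama(rec)
            second = classify_rama(rec)
            assert first.label == second.label
            assert first.label in {"favored-general", "allowed-general",
                                   "glycine-only", "outlier"}
            if res == "ALA":
                assert first.label != "glycine-only"


class TestPeptideFlip:
    def test_identical_structures_no_flip(self, motif_peptide):
        rep = pf.detect_peptide_flip(motif_peptide, motif_peptide, 4)
        assert rep.carbonyl_rotation_deg == pytest.approx(0.0, abs=1e-6)
        assert not rep.flipped

    def test_constructed_flip_detected_only_at_site(self):
        spec = pf.PeptideSpec.uniform("AAAAAAAA", -70.0, -30.0)
        a, b = pf.make_flip_pair(spec, 4)
        assert pf.detect_peptide_flip(a, b, 4).flipped
        for other in (2, 3, 5, 6):
            assert not pf.detect_peptide_flip(a, b, other).flipped

    def test_symmetric_in_argument_order(self):
        spec = pf.PeptideSpec.uniform("AAAAAAAA", -70.0, -30.0)
        a, b = pf.make_flip_pair(spec, 4)
        ab = pf.detect_peptide_flip(a, b, 4).carbonyl_rotation_deg
        ba = pf.detect_peptide_flip(b, a, 4).carbonyl_rotation_deg
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_missing_carbonyl_errors(self, motif_peptide):
        other = pf.build_peptide(pf.PeptideSpec.uniform("HCMGGLGR", -70.0, -30.0))
        res = other.first_chain.residue(4)
        res.atoms = [a for a in res.atoms if a.name != "O"]
        with pytest.raises(ValueError, match="carbonyl|missing"):
            pf.detect_peptide_flip(motif_peptide, other, 4)


class TestPLoopState:
    def test_fixture_states_recovered(self):
        active = pf.make_ploop_fixture("active")
        inactive = pf.make_ploop_fixture("inactive")
        st_a = pf.ploop_state(active, 1)
        st_i = pf.ploop_state(inactive, 1)
        assert st_a.state == "active" and st_a.mean_cosine > 0.2
        assert st_i.state == "inactive" and st_i.mean_cosine < -0.2
        assert st_a.pocket_tag == "ligand-centroid"
        assert len(st_a.orientations) == 4

    def test_sgamma_fallback_without_ligand(self):
        s = pf.make_ploop_fixture("active")
        s.first_model.hetero.clear()
        st = pf.ploop_state(s, 1)
        assert st.pocket_tag == "catalytic-S-gamma"

    def test_ligand_centroid_required_but_absent(self):
        s = pf.make_ploop_fixture("active")
        s.first_model.hetero.clear()
        st = pf.ploop_state(s, 1, pocket="ligand-centroid")
        assert st.state == "indeterminate"
        assert st.warning is not None

    def test_missing_motif_errors(self, helix):
        with pytest.raises(ValueError, match="motif"):
            pf.ploop_state(helix, 5)  # needs residues 5..12, chain has 10

    def test_rigid_motion_invariance(self):
        s = pf.make_ploop_fixture("active")
        moved = pf.perturb_rigid(s, [1, 1, 0], 73.0, (4.0, -2.0, 9.0))
        st0 = pf.ploop_state(s, 1)
        st1 = pf.ploop_state(moved, 1)
        assert st1.state == st0.state
        assert st1.mean_cosine == pytest.approx(st0.mean_cosine, abs=1e-8)


class TestEnsembleHistogram:
    def test_single_model_single_bin(self, motif_peptide):
        h = pf.ensemble_dihedral_histogram(motif_peptide, 4, "phi")
        assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(h.frequencies) == 1

    def test_uniform_angles_uniform_histogram(self):
        rng = np.random.default_rng(7)
        m = 10_000
        # uniform on (-180, 180]
        phis = 180.0 - rng.random(m) * 360.0
        spec = pf.PeptideSpec.uniform("AAAA", -57.0, -47.0)
        s = pf.make_ensemble(spec, phis, np.full(m, -47.0), residue=2)
        h = pf.ensemble_dihedral_histogram(s, 2, "phi")
        assert h.ensemble_size == m
        p = 1 / 36
        sigma = np.sqrt(p * (1 - p) / m)
        # 4-sigma per-bin bound keeps the family-wise error across the 36
        # simultaneous binomial comparisons well below 1%
        assert np.all(np.abs(h.frequencies - p) < 4 * sigma)

    def test_bin_edges_right_inclusive(self):
        spec = pf.PeptideSpec.uniform("AAAA", -57.0, -47.0)
        s = pf.make_ensemble(spec, [180.0, -170.0], [-47.0, -47.0], residue=2)
        h = pf.ensemble_dihedral_histogram(s, 2, "phi")
        assert h.frequencies[35] == pytest.approx(0.5)  # 180 in last bin
        assert h.frequencies[0] == pytest.approx(0.5)   # -170 in first bin


def test_conformational_quantities_rigid_invariant(motif_peptide):
    """Dihedrals and flip angles unchanged under a common rigid motion."""
    t_axis, t_ang, t_tr = [2.0, -1.0, 0.5], 61.0, (3.0, 4.0, -5.0)
    moved = pf.perturb_rigid(motif_peptide, t_axis, t_ang, t_tr)
    recs0 = pf.backbone_dihedrals(motif_peptide.first_chain)
    recs1 = pf.backbone_dihedrals(moved.first_chain)
    for r0, r1 in zip(recs0, recs1):
        for attr in ("phi", "psi", "omega"):
            v0, v1 = getattr(r0, attr), getattr(r1, attr)
            if v0 is None:
                assert v1 is None
            else:
                assert wrap_diff(v1, v0) < 1e-8
    rep = pf.detect_peptide_flip(motif_peptide, moved, 4)
    assert rep.carbonyl_rotation_deg == pytest.approx(0.0, abs=1e-6)
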