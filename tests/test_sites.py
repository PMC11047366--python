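"""Ligand transfer, contact/clash geometry and binding-site annotation."""

import numpy as np
import pytest

import homolig as h
from homolig.sites import TransferredLigand, load_correspondence, load_topology
from homolig.superpose import RigidTransform, SuperpositionResult


def make_result(transform):
    return SuperpositionResult(transform=transform, rmsd=0.0, n_pairs_initial=10,
                               n_pairs_retained=10, n_cycles=1,
                               mode="sequence_dependent")


def simple_ligand(coords, name="LIG"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return TransferredLigand(name, "A", 900,
                             [f"C{i+1}" for i in range(len(coords))], coords)


@pytest.fixture
def pocket_model():
    """Four residues at 3–4 Å from the origin, the rest far away."""
    residues = []
    near = [(3.0, 0, 0), (0, 3.5, 0), (-3.8, 0, 0), (0, -4.0, 0)]
    for i, xyz in enumerate(near):
        residues.append(h.Residue(i + 1, "ALA",
                                  [h.Atom("CA", "C", np.array(xyz, dtype=float))]))
    for i in range(4, 12):
        residues.append(h.Residue(i + 1, "GLY",
                                  [h.Atom("CA", "C", np.array([20.0 + 3 * i, 0, 0]))]))
    return h.Structure("pocket", {"A": residues})


class TestTransfer:
    def test_identity_transform_leaves_coordinates(self, planted_ligand_structure):
        res = make_result(RigidTransform.identity())
        ligs = h.transfer_ligands(res, planted_ligand_structure)
        assert len(ligs) == 1  # water excluded
        assert ligs[0].ccd_id == "GPP"
        assert np.allclose(ligs[0].coords, [[0.0, 3.0, 0.0]])

    def test_transfer_matches_analytic_transform(self, planted_ligand_structure):
        T = RigidTransform.from_axis_angle((0, 1, 0), 63.0, (1.0, -5.0, 2.5))
        ligs = h.transfer_ligands(make_result(T), planted_ligand_structure)
        expected = T.apply(np.array([[0.0, 3.0, 0.0]]))
        assert np.allclose(ligs[0].coords, expected, atol=1e-6)

    def test_source_structure_untouched(self, planted_ligand_structure):
        before = np.array([a.coords for _, _, a in planted_ligand_structure.all_atoms()])
        T = RigidTransform.from_axis_angle((1, 0, 0), 90.0, (9.0, 9.0, 9.0))
        h.transfer_ligands(make_result(T), planted_ligand_structure)
        after = np.array([a.coords for _, _, a in planted_ligand_structure.all_atoms()])
        assert np.array_equal(before, after)

    def test_missing_ligand_id_named_in_error(self, planted_ligand_structure):
        with pytest.raises(ValueError, match="NOPE"):
            h.transfer_ligands(make_result(RigidTransform.identity()),
                               planted_ligand_structure, ligand_ids=["NOPE"])

    def test_magnesium_tagged_cofactor(self):
        res = [h.Residue(1, "ALA", [h.Atom("CA", "C", np.zeros(3))]),
               h.Residue(2, "MG", [h.Atom("MG", "MG", np.ones(3))], is_hetero=True)]
        st = h.Structure("m", {"A": res})
        ligs = h.transfer_ligands(make_result(RigidTransform.identity()), st)
        assert ligs[0].category == "cofactor"


class TestContacts:
    def test_distant_ligand_no_contacts(self, pocket_model):
        lig = simple_ligand([(100.0, 100.0, 100.0)])
        assert h.find_contact_residues(pocket_model, lig, 5.0) == []

    def test_planted_pocket_exactly_recovered(self, pocket_model):
        lig = simple_ligand([(0.0, 0.0, 0.0)])
        contacts = h.find_contact_residues(pocket_model, lig, 5.0)
        assert sorted(c.seq_id for c in contacts) == [1, 2, 3, 4]
        by_id = {c.seq_id: c.min_distance for c in contacts}
        assert by_id[1] == pytest.approx(3.0)
        assert [c.min_distance for c in contacts] == sorted(c.min_distance for c in contacts)

    def test_contacts_monotone_in_cutoff(self, pocket_model):
        lig = simple_ligand([(0.0, 0.0, 0.0)])
        small = {c.seq_id for c in h.find_contact_residues(pocket_model, lig, 3.2)}
        large = {c.seq_id for c in h.find_contact_residues(pocket_model, lig, 5.0)}
        assert small <= large

    def test_clash_detected_at_planted_distance(self, pocket_model):
        lig = simple_ligand([(2.0, 0.0, 0.0)])  # 1.0 Å from residue 1 CA
        clashes = h.detect_clashes(pocket_model, lig, 2.0)
        assert len(clashes) == 1
        assert clashes[0].seq_id == 1
        assert clashes[0].distance == pytest.approx(1.0)

    def test_no_clash_beyond_cutoff(self, pocket_model):
        lig = simple_ligand([(0.0, 0.0, 0.0)])
        assert h.detect_clashes(pocket_model, lig, 2.0) == []

    def test_every_clash_is_a_contact(self, pocket_model):
        lig = simple_ligand([(1.5, 0.0, 0.0), (0.0, 2.0, 0.0)])
        clash_ids = {c.seq_id for c in h.detect_clashes(pocket_model, lig, 2.0)}
        contact_ids = {c.seq_id for c in h.find_contact_residues(pocket_model, lig, 5.0)}
        assert clash_ids <= contact_ids

    def test_frame_independence_of_centroid_distance(self, pocket_model):
        lig = simple_ligand([(0.0, 0.0, 0.0), (1.0, 1.0, 0.0)])
        model_centroid = np.mean([a.coords for _, _, a in pocket_model.all_atoms()], axis=0)
        d0 = np.linalg.norm(lig.coords.mean(axis=0) - model_centroid)
        T = RigidTransform.from_axis_angle((1, 1, 1), 120.0, (5.0, -7.0, 3.0))
        moved = pocket_model.copy()
        for _, _, a in moved.all_atoms():
            a.coords = T.apply(a.coords)
        lig2 = simple_ligand(T.apply(lig.coords))
        moved_centroid = np.mean([a.coords for _, _, a in moved.all_atoms()], axis=0)
        d1 = np.linalg.norm(lig2.coords.mean(axis=0) - moved_centroid)
        assert d0 == pytest.approx(d1, abs=1e-9)


class TestAnnotation:
    def contact(self, seq_id):
        from homolig.sites import Contact
        return Contact("A", seq_id, "ALA", 3.2)

    def test_motif_residue_flagged(self):
        (ann,) = h.annotate_contacts([self.contact(136)])
        assert ann.motifs == ["Asp134xxxAsp138"]
        assert ann.segment == "S2-S3"
        assert ann.side == "matrix"

    def test_variant_residue_flagged(self):
        (ann,) = h.annotate_contacts([self.contact(96)])
        assert ann.variant == "p.Ser96Asn"
        assert ann.segment == "S1"
        assert ann.on_portal_helix  # S1 delimits the lateral portal

    def test_position_outside_annotation_flagged_unannotated(self):
        (ann,) = h.annotate_contacts([self.contact(4000)])
        assert ann.unannotated
        assert ann.segment is None and ann.motifs == [] and ann.variant is None

    def test_topology_segments_ordered_disjoint(self):
        topo = load_topology()
        assert (topo["start"] <= topo["end"]).all()
        assert (topo["start"].iloc[1:].to_numpy() > topo["end"].iloc[:-1].to_numpy()).all()

    def test_correspondence_one_to_one(self):
        table = load_correspondence()
        assert table["query_residue"].is_unique
        assert "R123" in set(table["query_residue"])
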