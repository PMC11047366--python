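"""Shared fixtures: hand-written parser inputs and synthetic structures."""

import textwrap

import numpy as np
import pytest
from hypothesis import settings

import homolig as h

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def pdb_line(serial, name, resname, chain, resseq, xyz, occ=1.0, b=0.0,
             element="C", altloc=" ", record="ATOM"):
    x, y, z = xyz
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {name_f}{altloc}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal 3-residue ALA-GLY-SER chain."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0), element="N"),
        pdb_line(2, "CA", "ALA", "A", 1, (1.5, 0.0, 0.0), b=77.12),
        pdb_line(3, "C", "ALA", "A", 1, (2.2, 1.3, 0.0)),
        pdb_line(4, "N", "GLY", "A", 2, (3.5, 1.3, 0.0), element="N"),
        pdb_line(5, "CA", "GLY", "A", 2, (4.4, 2.4, 0.0), b=88.34),
        pdb_line(6, "C", "GLY", "A", 2, (5.8, 2.0, 0.0)),
        pdb_line(7, "N", "SER", "A", 3, (6.7, 3.0, 0.0), element="N"),
        pdb_line(8, "CA", "SER", "A", 3, (8.1, 2.7, 0.0), b=90.00),
        pdb_line(9, "OG", "SER", "A", 3, (8.9, 3.9, 0.0), element="O"),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_ccd_cif(tmp_path):
    """Hand-written 3-component dictionary (GPP, PHB, MG) in CCD mmCIF form."""
    text = textwrap.dedent("""\
        data_GPP
        _chem_comp.id GPP
        _chem_comp.name "GERANYL DIPHOSPHATE"
        loop_
        _pdbx_chem_comp_descriptor.comp_id
        _pdbx_chem_comp_descriptor.type
        _pdbx_chem_comp_descriptor.program
        _pdbx_chem_comp_descriptor.descriptor
        GPP SMILES_CANONICAL "OpenEye OEToolkits" "CC(C)=CCC/C(C)=C/COP(O)(=O)OP(O)(O)=O"
        GPP SMILES CACTVS "CC(C)=CCCC(C)=CCOP(O)(=O)OP(O)(O)=O"
        data_PHB
        _chem_comp.id PHB
        _chem_comp.name "P-HYDROXYBENZOIC ACID"
        loop_
        _pdbx_chem_comp_descriptor.comp_id
        _pdbx_chem_comp_descriptor.type
        _pdbx_chem_comp_descriptor.program
        _pdbx_chem_comp_descriptor.descriptor
        PHB SMILES_CANONICAL CACTVS "Oc1ccc(cc1)C(O)=O"
        data_MG
        _chem_comp.id MG
        _chem_comp.name "MAGNESIUM ION"
        loop_
        _pdbx_chem_comp_descriptor.comp_id
        _pdbx_chem_comp_descriptor.type
        _pdbx_chem_comp_descriptor.program
        _pdbx_chem_comp_descriptor.descriptor
        MG SMILES_CANONICAL "OpenEye OEToolkits" "[Mg+2]"
        """)
    path = tmp_path / "toy_ccd.cif"
    path.write_text(text)
    return path


@pytest.fixture
def toy_hhr(tmp_path):
    """Hand-written HHR summary with three hits."""
    text = textwrap.dedent("""\
        Query         QUERY_PROTEIN
        Match_columns 371

         No Hit                             Prob E-value P-value  Score    SS Cols Query HMM  Template HMM
          1 4OD4_A UbiA prenyltransferase  99.1 1.1E-22 2.0E-27  175.2   0.0  230   60-320    15-250  (280)
          2 6M31_B DGGGP synthase          50.0 3.0E-05 4.0E-09   60.0   0.0  200   70-280    20-230  (270)
          3 7XYZ_C unrelated protein       12.0 1.5E+00 2.0E-03   20.0   0.0   80  100-190    10-95   (120)

        No 1
        >4OD4_A alignment details follow but are not part of the summary
        """)
    path = tmp_path / "toy.hhr"
    path.write_text(text)
    return path


@pytest.fixture
def bundle_and_homolog():
    spec = h.FixtureSpec(noise_sigma=0.3, identity=0.6, transform_angle_deg=25.0,
                         transform_axis=(1.0, 1.0, 0.0), translation=(5.0, -3.0, 2.0),
                         seed=3)
    bundle = h.make_helical_bundle(spec)
    hom, truth, pocket = h.make_homolog(bundle, spec)
    return spec, bundle, hom, truth, pocket


@pytest.fixture
def planted_ligand_structure():
    """Structure with a single hetero component contacting chain B only."""
    res_a = [h.Residue(i + 1, "ALA",
                       [h.Atom("CA", "C", np.array([0.0, 50.0 + 5 * i, 0.0]))])
             for i in range(3)]
    res_b = [h.Residue(i + 1, "ALA",
                       [h.Atom("CA", "C", np.array([float(4 * i), 0.0, 0.0]))])
             for i in range(3)]
    lig = h.Residue(101, "GPP", [h.Atom("C1", "C", np.array([0.0, 3.0, 0.0]))],
                    is_hetero=True)
    wat = h.Residue(102, "HOH", [h.Atom("O", "O", np.array([0.0, 2.0, 0.0]))],
                    is_hetero=True)
    return h.Structure("planted", {"A": res_a, "B": res_b + [lig, wat]})
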