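"""Structure I/O, implicit hydrogens, residue electron bookkeeping."""

import numpy as np
import pytest

from solscat.formfactors import load_volume_table, lookup_volume
from solscat.hydration import WaterSet
from solscat.structures import (Atom, Structure, assign_implicit_hydrogens,
                                load_residue_hydrogens, read_pdb, vdw_radius,
                                write_pdb)

SINGLE_CA = ("ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
             "  1.00  0.00           C\n")


def test_read_single_atom(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(SINGLE_CA + "END\n")
    s = read_pdb(p)
    assert len(s) == 1
    a = s.atoms[0]
    assert a.element == "C"
    assert np.allclose(a.position, [1.0, 2.0, 3.0])


def test_solvent_only_file_strips_to_empty(tmp_path):
    p = tmp_path / "wat.pdb"
    p.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
        "  1.00  0.00           O\nEND\n")
    s = read_pdb(p)
    stripped = s.strip_solvent()
    assert len(stripped) == 0
    with pytest.raises(ValueError):
        stripped.require_atoms()


def test_missing_and_empty_files(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_pdb(tmp_path / "nope.pdb")
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(ValueError):
        read_pdb(p)


def test_round_trip_preserves_atoms(tmp_path, toy30):
    p = tmp_path / "toy.pdb"
    write_pdb(toy30, p)
    back = read_pdb(p)
    assert len(back) == len(toy30)
    assert [a.element for a in back] == [a.element for a in toy30]
    assert np.allclose(back.positions, toy30.positions, atol=1.5e-3)
    # second round trip is exact (coordinates already quantized)
    p2 = tmp_path / "toy2.pdb"
    write_pdb(back, p2)
    again = read_pdb(p2)
    assert np.array_equal(again.positions, back.positions)


def test_write_with_waters_round_trips(tmp_path, toy30):
    waters = WaterSet(positions=np.array([[10.0, 0, 0], [0, 10.0, 0],
                                          [0, 0, 10.0]]))
    p = tmp_path / "hydrated.pdb"
    write_pdb(toy30, p, waters=waters)
    text = p.read_text()
    assert text.count("HOH") == 3
    back = read_pdb(p)
    assert len(back) == len(toy30) + 3
    assert sum(a.is_solvent for a in back) == 3
    # solvent serial numbers continue the atom numbering
    lines = [ln for ln in text.splitlines() if ln.startswith(("ATOM", "HETATM"))]
    serials = [int(ln[6:11]) for ln in lines]
    assert serials == list(range(1, len(toy30) + 4))


def test_element_inference_calcium_vs_calpha(tmp_path):
    p = tmp_path / "amb.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       1.458   0.000   0.000"
        "  1.00  0.00\n"
        "HETATM    2 CA    CA A   2       8.000   0.000   0.000"
        "  1.00  0.00          CA\nEND\n")
    s = read_pdb(p)
    assert s.atoms[0].element == "C"
    assert s.atoms[1].element == "CA"
    assert s.atoms[1].is_ion


# -- implicit hydrogens -----------------------------------------------------

def _residue(name, atom_names_elements):
    return Structure(atoms=[
        Atom(position=np.array([i, 0.0, 0.0]), element=el,
             residue_name=name, atom_name=an)
        for i, (an, el) in enumerate(atom_names_elements)])


def test_glycine_alpha_carbon_and_carbonyl():
    s = _residue("GLY", [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")])
    s = assign_implicit_hydrogens(s)
    by_name = {a.atom_name: a for a in s}
    assert by_name["CA"].n_implicit_h == 2
    assert by_name["CA"].effective_electrons == 8
    assert by_name["CA"].ff_class == "CH2"
    assert by_name["C"].n_implicit_h == 0
    assert by_name["N"].n_implicit_h == 1  # peptide-context amide


def test_alanine_carbonyl_has_no_hydrogens():
    s = assign_implicit_hydrogens(_residue("ALA", [("C", "C")]))
    assert s.atoms[0].n_implicit_h == 0


def test_unknown_residue_degrades_to_vacuum():
    s = assign_implicit_hydrogens(
        _residue("XYZ", [("Q1", "C"), ("Q2", "N")]))
    assert all(a.n_implicit_h == 0 for a in s)
    assert [a.ff_class for a in s] == ["C", "N"]


def test_explicit_hydrogen_structure_rejected():
    s = Structure(atoms=[Atom(position=np.zeros(3), element="C")],
                  has_explicit_hydrogens=True)
    with pytest.raises(ValueError):
        assign_implicit_hydrogens(s)


@pytest.mark.parametrize("residue, formula_electrons", [
    # in-chain residues: formula electron counts including hydrogens
    ("GLY", 30),   # C2 H3 N O
    ("ALA", 38),   # C3 H5 N O
    ("SER", 46),   # C3 H5 N O2
    ("VAL", 54),   # C5 H9 N O
    ("CYS", 54),   # C3 H5 N O S
    ("LEU", 62),   # C6 H11 N O
    ("LYS", 71),   # C6 H13 N2 O (protonated NZ)
    ("PHE", 78),   # C9 H9 N O
    ("HOH", 10),   # water
])
def test_residue_electron_totals(residue, formula_electrons):
    """Summed effective electrons reproduce the residue formula count."""
    table = load_residue_hydrogens()
    atoms = [(an, an[0]) for (rn, an) in table if rn == residue]
    s = assign_implicit_hydrogens(_residue(residue, atoms))
    assert s.total_electrons == formula_electrons


def test_all_standard_residues_resolve_in_volume_tables():
    """Every form-factor class of the 20 amino acids plus water resolves
    in each bundled table, in both hydrogen modes."""
    table_defs = load_residue_hydrogens()
    residues = {rn for rn, _ in table_defs}
    classes = set()
    for rn in residues:
        atoms = [(an, an[0]) for (r, an) in table_defs if r == rn]
        s = assign_implicit_hydrogens(_residue(rn, atoms))
        classes |= {a.ff_class for a in s}
    for table_id in ("minimum_fluctuation", "voronoi", "vdw", "traube"):
        imp = load_volume_table(table_id, "implicit")
        for cls in classes:
            assert lookup_volume(cls, imp) > 0
        exp = load_volume_table(table_id, "explicit")
        for el in ("H", "C", "N", "O", "S", "P"):
            assert lookup_volume(el, exp) > 0


def test_vdw_radii_positive_and_sane():
    for el in ("H", "C", "N", "O", "S", "P"):
        assert 1.0 < vdw_radius(el) < 2.0
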