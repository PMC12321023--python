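"""Atomic structures: PDB I/O, implicit hydrogens, radii.

A :class:`Structure` is an ordered list of :class:`Atom` records. Structures
read from PDB files typically contain heavy atoms only; the number of
covalently bound hydrogens is then assigned per (residue, atom name) from a
bundled residue-composition table and folded into each atom's scattering
weight (``effective_electrons = Z + n_implicit_h``) and unified-group form
factor. Unrecognized residues or atom names degrade gracefully to zero
implicit hydrogens with plain vacuum form factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import gemmi
import numpy as np

from .formfactors import group_id

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "write_pdb",
    "assign_implicit_hydrogens",
    "load_residue_hydrogens",
    "vdw_radius",
]

# Residue names treated as solvent / monoatomic ions; retained on read but
# flagged so callers can strip them before scattering calculations.
_SOLVENT_RESIDUES = {"HOH", "WAT", "DOD", "H2O", "SOL"}
_ION_RESIDUES = {
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CU1",
    "NI", "CO", "CD", "IOD", "BR", "F", "LI", "RB", "CS", "SR", "BA",
}


def _load_vdw_radii() -> Dict[str, float]:
    radii: Dict[str, float] = {}
    text = resources.files("solscat").joinpath(
        "data", "vdw_radii.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, r = line.split("\t")
        radii[el] = float(r)
    return radii


_VDW_RADII = _load_vdw_radii()
_VDW_DEFAULT = 1.7  # fallback for elements outside the bundled table


def vdw_radius(element: str) -> float:
    """Van der Waals radius [A] of an element (bundled Bondi-style table)."""
    return _VDW_RADII.get(element.upper(), _VDW_DEFAULT)


@dataclass
class Atom:
    """A point scatterer with chemical identity.

    ``n_implicit_h`` hydrogens are folded into the scattering weight;
    ``ff_class`` names the matching unified-group (or vacuum) form factor.
    """

    position: np.ndarray
    element: str
    residue_name: str = ""
    atom_name: str = ""
    n_implicit_h: int = 0
    is_solvent: bool = False
    is_ion: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.element = self.element.upper()
        if self.n_implicit_h < 0:
            raise ValueError("n_implicit_h must be >= 0")

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element.capitalize()).atomic_number

    @property
    def effective_electrons(self) -> float:
        return float(self.atomic_number + self.n_implicit_h)

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)

    @property
    def ff_class(self) -> str:
        return group_id(self.element, self.n_implicit_h)


@dataclass
class Structure:
    """Ordered collection of atoms forming one solute structure."""

    atoms: List[Atom] = field(default_factory=list)
    has_explicit_hydrogens: bool = False

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.effective_electrons for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def ff_classes(self) -> List[str]:
        return [a.ff_class for a in self.atoms]

    @property
    def total_electrons(self) -> float:
        return float(sum(a.effective_electrons for a in self.atoms))

    def strip_solvent(self) -> "Structure":
        """Drop solvent molecules, ions and explicit hydrogens.

        Mirrors the usual preprocessing of experimental structure files
        before a scattering calculation.
        """
        kept = [a for a in self.atoms
                if not (a.is_solvent or a.is_ion or a.element == "H")]
        return Structure(atoms=kept, has_explicit_hydrogens=False)

    def require_atoms(self):
        if not self.atoms:
            raise ValueError("structure contains no atoms")


def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records from a fixed-column PDB file.

    Elements come from the element field when present, falling back to
    atom-name heuristics (with residue context deciding ambiguous names
    such as calcium vs C-alpha). Solvent and ions are retained but flagged.
    Alternate locations are reduced to a single conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_alternative_conformations()
    atoms: List[Atom] = []
    any_h = False
    for model in st:
        for chain in model:
            for residue in chain:
                res = residue.name.strip().upper()
                is_solvent = res in _SOLVENT_RESIDUES
                is_ion = res in _ION_RESIDUES
                for at in residue:
                    el = at.element.name.upper()
                    if not el or el == "X":
                        el = at.name.strip()[:1].upper()
                    if el == "H":
                        any_h = True
                    atoms.append(Atom(
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=el,
                        residue_name=res,
                        atom_name=at.name.strip(),
                        is_solvent=is_solvent,
                        is_ion=is_ion,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return Structure(atoms=atoms, has_explicit_hydrogens=any_h)


def _pdb_atom_line(record: str, serial: int, name: str, res: str, chain: str,
                   resseq: int, pos: np.ndarray, element: str) -> str:
    # wwPDB v3.3 fixed columns; single-character elements start in column 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"{record:<6s}{serial % 100000:5d} {name_field} {res:<3s} {chain}"
            f"{resseq % 10000:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element.capitalize():>2s}\n")


def write_pdb(structure: Structure, path, waters=None) -> None:
    """Write a structure (plus optional dummy waters) as fixed-column PDB.

    Dummy hydration waters are appended as HETATM HOH oxygen positions with
    serial numbers continuing the atom numbering, so a hydrated model can be
    inspected with standard tools and round-trips through :func:`read_pdb`.
    """
    lines: List[str] = []
    serial = 0
    resseq = 0
    last_res = None
    for a in structure.atoms:
        serial += 1
        if a.residue_name != last_res:
            resseq += 1
            last_res = a.residue_name
        record = "HETATM" if (a.is_solvent or a.is_ion) else "ATOM"
        name = a.atom_name or a.element
        lines.append(_pdb_atom_line(record, serial, name,
                                    a.residue_name or "UNK", "A", resseq,
                                    a.position, a.element))
    if waters is not None:
        positions = getattr(waters, "positions", waters)
        for pos in np.asarray(positions, dtype=float).reshape(-1, 3):
            serial += 1
            resseq += 1
            lines.append(_pdb_atom_line("HETATM", serial, "O", "HOH", "B",
                                        resseq, pos, "O"))
    lines.append("END\n")
    Path(path).write_text("".join(lines))


_residue_cache: Optional[Dict[Tuple[str, str], int]] = None


def load_residue_hydrogens() -> Dict[Tuple[str, str], int]:
    """Bundled residue-composition table: (residue, atom name) -> n hydrogens.

    Counts are for in-chain residues: every backbone amide nitrogen already
    carries the peptide-context (reduced-by-one) hydrogen count.
    """
    global _residue_cache
    if _residue_cache is None:
        table: Dict[Tuple[str, str], int] = {}
        text = resources.files("solscat").joinpath(
            "data", "residue_hydrogens.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, atom, n = line.split("\t")
            table[(res, atom)] = int(n)
        _residue_cache = table
    return _residue_cache


def assign_implicit_hydrogens(structure: Structure,
                              residue_table: Optional[Dict] = None) -> Structure:
    """Assign per-atom implicit hydrogen counts from residue definitions.

    Unknown residue/atom combinations get zero hydrogens and keep their
    plain vacuum form factor. Returns a new Structure; the input is not
    modified.
    """
    if structure.has_explicit_hydrogens:
        raise ValueError(
            "structure has explicit hydrogens; strip them first or skip "
            "implicit-hydrogen assignment")
    table = residue_table if residue_table is not None else load_residue_hydrogens()
    atoms = []
    for a in structure.atoms:
        if a.is_ion:
            n_h = 0
        elif a.residue_name in _SOLVENT_RESIDUES:
            n_h = 2 if a.element == "O" else 0
        else:
            n_h = table.get((a.residue_name, a.atom_name), 0)
        atoms.append(dataclasses.replace(a, n_implicit_h=n_h))
    return Structure(atoms=atoms, has_explicit_hydrogens=False)
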