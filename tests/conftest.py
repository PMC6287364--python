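import numpy as np
import pytest

from acidbridge.structio import Atom, Residue, Structure
from acidbridge.synth import ToyStructureSpec, make_toy_structure


def build_residue(chain, resnum, resname, atom_spec, serial_start=1):
    """atom_spec: list of (name, element, coords)."""
    atoms = [
        Atom(
            serial=serial_start + i, name=name, element=element,
            residue_name=resname, chain=chain, residue_number=resnum,
            coords=np.asarray(coords, dtype=float),
        )
        for i, (name, element, coords) in enumerate(atom_spec)
    ]
    return Residue(chain=chain, residue_number=resnum, residue_name=resname, atoms=atoms)


def build_structure(residue_specs, struct_id="test"):
    """residue_specs: list of (chain, resnum, resname, atom_spec)."""
    residues = []
    serial = 1
    for chain, resnum, resname, atom_spec in residue_specs:
        residues.append(build_residue(chain, resnum, resname, atom_spec, serial))
        serial += len(atom_spec)
    return Structure(id=struct_id, residues=residues).sort()


@pytest.fixture
def arg_glu_structure():
    """One planted ARG-GLU pair at 3.5 A on a toy helix."""
    return make_toy_structure(ToyStructureSpec(planted_pairs=[("ARG", "GLU", 3.5)]))


@pytest.fixture
def two_residue_structure():
    """Two 8-atom residues (16 atoms) for I/O round-trip checks."""
    return build_structure([
        ("A", 1, "GLU", [
            ("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.5, 0.0, 0.0)),
            ("C", "C", (2.2, 1.3, 0.0)), ("O", "O", (1.7, 2.4, 0.0)),
            ("CB", "C", (2.1, -1.3, 0.5)), ("CG", "C", (3.5, -1.5, 0.1)),
            ("OE1", "O", (4.2, -2.4, 0.7)), ("OE2", "O", (3.9, -0.8, -0.9)),
        ]),
        ("A", 2, "ARG", [
            ("N", "N", (3.6, 1.5, 0.2)), ("CA", "C", (4.4, 2.7, 0.1)),
            ("C", "C", (5.9, 2.4, 0.3)), ("O", "O", (6.4, 1.3, 0.2)),
            ("CB", "C", (4.0, 3.6, 1.3)), ("CZ", "C", (4.8, 4.9, 1.5)),
            ("NH1", "N", (5.6, 5.3, 2.4)), ("NH2", "N", (4.5, 5.8, 0.6)),
        ]),
    ])
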