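"""Protein structure and ensemble I/O, geometry primitives and crystal packing.

Structures are plain in-memory containers (lists of residues holding atoms)
read from and written to PDB files through :mod:`gemmi`.  Coordinates are in
Angstrom throughout, residue numbering is taken verbatim from the file
(1-based, gaps allowed, never renumbered) and hydrogens are ignored by every
geometry operation: the salt-bridge criterion used downstream is a
heavy-atom criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "CrystalPacking",
    "EmptyStructureError",
    "TopologyMismatchError",
    "AA3_TO_1",
    "STANDARD_AA",
    "read_pdb",
    "write_pdb",
    "neighbor_count",
    "crystal_packing",
    "solvent_fraction_from_vm",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA = frozenset(AA3_TO_1)

#: maximum |coordinate| representable in the fixed-width PDB field (%8.3f)
_PDB_COORD_LIMIT = 9999.999


class EmptyStructureError(ValueError):
    """Raised when a PDB file or Structure contains no atoms."""


class TopologyMismatchError(ValueError):
    """Raised when ensemble frames do not share an identical atom topology."""


@dataclass
class Atom:
    """A heavy atom with its residue identity and position.

    ``occupancy`` and ``altloc`` carry alternate-conformer bookkeeping
    (side chains refined in two states with 0.5 occupancy each are common
    in high-resolution structures); the default read policy collapses
    altlocs to the highest-occupancy conformer.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray
    insertion_code: str = ""
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue: shared identity plus its atoms."""

    chain: str
    residue_number: int
    residue_name: str
    atoms: list[Atom]
    insertion_code: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if (a.chain, a.residue_number, a.residue_name) != (
                self.chain, self.residue_number, self.residue_name
            ):
                raise ValueError(
                    f"atom {a.name} does not belong to residue "
                    f"{self.chain}{self.residue_number}{self.residue_name}"
                )
            key = (a.name, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom (name, altloc) {key} in residue")
            seen.add(key)

    @property
    def is_protein(self) -> bool:
        return self.residue_name in STANDARD_AA

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT", "DOD")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.residue_name}{self.residue_number}{self.insertion_code}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_coords(self, names: Sequence[str]) -> np.ndarray:
        """Coordinates of the named atoms that are present, shape (k, 3)."""
        found = [a.coords for a in self.atoms if a.name in names]
        if not found:
            return np.empty((0, 3))
        return np.vstack(found)


@dataclass
class Structure:
    """An ordered collection of residues (one conformer)."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def sort(self) -> "Structure":
        self.residues.sort(key=lambda r: (r.chain, r.residue_number, r.insertion_code))
        return self

    def atoms(self, protein_only: bool = False, heavy_only: bool = False) -> Iterator[Atom]:
        for r in self.residues:
            if protein_only and not r.is_protein:
                continue
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                yield a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def heavy_coords(self, protein_only: bool = True) -> np.ndarray:
        pts = [a.coords for a in self.atoms(protein_only=protein_only, heavy_only=True)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out

    def protein_residues(self, chain: str | None = None) -> list[Residue]:
        return [
            r for r in self.residues
            if r.is_protein and (chain is None or r.chain == chain)
        ]

    def sequence(self, chain: str) -> str:
        return "".join(AA3_TO_1[r.residue_name] for r in self.protein_residues(chain))

    def get_residue(self, chain: str, residue_number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, residue_number, insertion_code):
                return r
        raise KeyError(f"no residue {chain}:{residue_number}{insertion_code}")

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                Residue(
                    chain=r.chain,
                    residue_number=r.residue_number,
                    residue_name=r.residue_name,
                    insertion_code=r.insertion_code,
                    het=r.het,
                    atoms=[
                        Atom(
                            serial=a.serial, name=a.name, element=a.element,
                            residue_name=a.residue_name, chain=a.chain,
                            residue_number=a.residue_number,
                            coords=a.coords.copy(),
                            insertion_code=a.insertion_code,
                            altloc=a.altloc, occupancy=a.occupancy,
                        )
                        for a in r.atoms
                    ],
                )
                for r in self.residues
            ],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every atom mapped through x -> R x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for r in out.residues:
            for a in r.atoms:
                a.coords = rotation @ a.coords + translation
        return out

    def topology(self) -> tuple:
        return tuple(
            (r.chain, r.residue_number, r.insertion_code, r.residue_name,
             tuple(a.name for a in r.atoms))
            for r in self.residues
        )


@dataclass
class Ensemble:
    """Ordered frames sharing an identical topology (an MD-trajectory stand-in).

    ``frame_interval`` is informational (time between frames in whatever unit
    the producer used, e.g. ps between trajectory snapshots).
    """

    frames: list[Structure]
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStructureError("ensemble must contain at least one frame")
        ref = self.frames[0].topology()
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.topology() != ref:
                raise TopologyMismatchError(f"frame {i} topology differs from frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class CrystalPacking:
    """Matthews-coefficient bookkeeping for a crystal form."""

    cell_a: float
    cell_b: float
    cell_c: float
    alpha: float
    beta: float
    gamma: float
    z: int
    protein_mass: float
    vbar: float
    volume: float
    vm: float
    solvent_fraction: float


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _from_gemmi_model(model: gemmi.Model, struct_id: str, altloc_policy: str) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            icode = gres.seqid.icode.strip()
            atoms: list[Atom] = []
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, group in by_name.items():
                if altloc_policy == "keep-first" and len(group) > 1:
                    # highest occupancy wins; ties broken by altloc letter
                    group = [sorted(group, key=lambda g: (-g.occ, g.altloc))[0]]
                for ga in group:
                    altloc = ga.altloc if ga.altloc not in ("\0", "\x00") else ""
                    atoms.append(Atom(
                        serial=ga.serial,
                        name=name,
                        element=ga.element.name,
                        residue_name=gres.name,
                        chain=chain.name,
                        residue_number=gres.seqid.num,
                        insertion_code=icode,
                        altloc="" if altloc_policy == "keep-first" else altloc,
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    ))
            residues.append(Residue(
                chain=chain.name,
                residue_number=gres.seqid.num,
                residue_name=gres.name,
                insertion_code=icode,
                het=gres.het_flag == "H",
                atoms=atoms,
            ))
    return Structure(id=struct_id, residues=residues).sort()


def read_pdb(path: Union[str, Path], altloc_policy: str = "keep-first") -> Union[Structure, Ensemble]:
    """Read a PDB file into a :class:`Structure` (one model) or :class:`Ensemble`.

    HETATM records (waters, ligands, cofactors) are retained but flagged so
    that geometry operations can restrict themselves to protein residues.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM/HETATM record.
    altloc_policy:
        ``"keep-first"`` keeps, per atom name, the alternate location with
        the highest occupancy (ties broken by altloc letter); ``"keep-all"``
        keeps every conformer.
    """
    if altloc_policy not in ("keep-first", "keep-all"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    frames = [
        _from_gemmi_model(model, struct_id=path.stem, altloc_policy=altloc_policy)
        for model in gst
    ]
    frames = [f for f in frames if f.n_atoms > 0]
    if not frames:
        raise EmptyStructureError(f"no atoms in {path}")
    if len(frames) == 1:
        return frames[0]
    return Ensemble(frames=frames)


def _to_gemmi(frames: Sequence[Structure], struct_id: str) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = struct_id
    for i, frame in enumerate(frames, start=1):
        model = gemmi.Model(str(i))
        chains: dict[str, gemmi.Chain] = {}
        serial = 0
        for res in frame.residues:
            if res.chain not in chains:
                chains[res.chain] = gemmi.Chain(res.chain)
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
            gres.het_flag = "H" if res.het else "A"
            for a in res.atoms:
                if np.any(np.abs(a.coords) > _PDB_COORD_LIMIT):
                    raise ValueError(
                        f"coordinate {a.coords} of atom {a.name} exceeds the PDB field width"
                    )
                serial += 1
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[0])
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.serial = serial
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            chains[res.chain].add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        gst.add_model(model)
    return gst


def write_pdb(structure_or_ensemble: Union[Structure, Ensemble], path: Union[str, Path]) -> Path:
    """Write a Structure (single model) or Ensemble (MODEL/ENDMDL blocks).

    Round-trips through :func:`read_pdb` preserve atom counts, names and
    coordinates to 3 decimals (the fixed-width PDB precision).
    """
    path = Path(path)
    if isinstance(structure_or_ensemble, Ensemble):
        frames = structure_or_ensemble.frames
        struct_id = frames[0].id
    else:
        frames = [structure_or_ensemble]
        struct_id = structure_or_ensemble.id
    if any(f.n_atoms == 0 for f in frames):
        raise EmptyStructureError("refusing to write a structure with no atoms")
    gst = _to_gemmi(frames, struct_id)
    gst.write_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def neighbor_count(structure: Structure, center: np.ndarray, radius: float) -> int:
    """Number of protein heavy atoms within ``radius`` of ``center``.

    Atoms exactly at the center (distance 0) are excluded, so the count can
    be used as a burial proxy for a site's own charged-atom centroid.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = structure.heavy_coords(protein_only=True)
    if coords.shape[0] == 0:
        return 0
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(coords - center, axis=1)
    return int(np.sum((d <= radius) & (d > 0.0)))


class _NeighborCounter:
    """KD-tree-backed neighbor_count for repeated queries on one structure."""

    def __init__(self, structure: Structure):
        self._coords = structure.heavy_coords(protein_only=True)
        self._tree = cKDTree(self._coords) if self._coords.shape[0] else None

    def __call__(self, center: np.ndarray, radius: float) -> int:
        if self._tree is None:
            return 0
        idx = self._tree.query_ball_point(np.asarray(center, dtype=float), radius)
        d = np.linalg.norm(self._coords[idx] - center, axis=1) if idx else np.empty(0)
        return int(np.sum(d > 0.0))


# ---------------------------------------------------------------------------
# Crystal packing (Matthews coefficient)
# ---------------------------------------------------------------------------

def _cell_volume(a: float, b: float, c: float, alpha: float, beta: float, gamma: float) -> float:
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise ValueError("degenerate unit cell")
    return a * b * c * math.sqrt(arg)


def solvent_fraction_from_vm(vm: float, vbar: float = 0.74) -> float:
    """Solvent fraction from the Matthews coefficient: 1 - 1.66*vbar/vm.

    ``vm`` is crystal volume per unit protein mass (A^3/Da) and ``vbar`` the
    protein partial specific volume (cm^3/g, 0.74 for a typical protein).
    """
    if vm <= 0:
        raise ValueError("Matthews coefficient must be positive")
    return 1.0 - (1.66 * vbar) / vm


def crystal_packing(
    cell_a: float,
    cell_b: float,
    cell_c: float,
    alpha: float,
    beta: float,
    gamma: float,
    z: int,
    protein_mass: float,
    vbar: float = 0.74,
) -> CrystalPacking:
    """Matthews coefficient and solvent content for ``z`` copies of mass ``protein_mass``.

    VM = V_cell / (z * mass); solvent fraction = 1 - 1.66*vbar/VM.
    """
    if min(cell_a, cell_b, cell_c) <= 0:
        raise ValueError("cell lengths must be positive")
    for ang in (alpha, beta, gamma):
        if not 0.0 < ang < 180.0:
            raise ValueError("cell angles must lie in (0, 180) degrees")
    if z < 1:
        raise ValueError("z must be >= 1")
    if protein_mass <= 0:
        raise ValueError("protein mass must be positive")
    volume = _cell_volume(cell_a, cell_b, cell_c, alpha, beta, gamma)
    vm = volume / (z * protein_mass)
    if vm <= 0:
        raise ValueError("non-positive Matthews coefficient")
    return CrystalPacking(
        cell_a=cell_a, cell_b=cell_b, cell_c=cell_c,
        alpha=alpha, beta=beta, gamma=gamma,
        z=z, protein_mass=protein_mass, vbar=vbar,
        volume=volume, vm=vm,
        solvent_fraction=solvent_fraction_from_vm(vm, vbar),
    )
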