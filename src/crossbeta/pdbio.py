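"""Structures and multi-model PDB I/O.

The in-memory containers are deliberately small: an :class:`Atom` carries
name, element, mass and coordinates; a :class:`Structure` is an ordered atom
list whose chain order defines 1-based strand indices; a :class:`Trajectory`
is one template structure plus an ``(n_frames, n_atoms, 3)`` coordinate
array.  Multi-model PDB (``MODEL``/``ENDMDL``) is the trajectory interchange
format, read and written through biotite.  All coordinates are in Angstrom,
times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Union

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack, stack as _stack
from biotite.structure.io.pdb import PDBFile

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .topology import ZipperTopology

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "sidechain_center_of_mass",
    "ATOMIC_MASSES",
    "BACKBONE_ATOM_NAMES",
    "THREE_TO_ONE",
]

#: Standard atomic masses (Da) for the elements occurring in peptides.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Backbone heavy-atom names; everything else heavy is side chain.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBFormatError(ValueError):
    """Raised for malformed or internally inconsistent PDB input."""


def mass_of_element(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise PDBFormatError(f"no atomic mass known for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    mass: float
    residue_position: int
    residue_name: str
    chain_id: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=float).reshape(3)
        )


@dataclass
class Structure:
    """An ordered list of atoms; chain order defines strand indices 1..n."""

    atoms: list[Atom]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    def strand_index(self, chain_id: str) -> int:
        """1-based strand index of a chain (file order)."""
        return self.chain_ids.index(chain_id) + 1

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        return Structure(
            atoms=[replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        )

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain, in residue-position order."""
        res: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                res.setdefault(a.residue_position, a.residue_name)
        return "".join(
            THREE_TO_ONE.get(res[p], "X") for p in sorted(res)
        )

    def ca_indices(self) -> np.ndarray:
        """Indices of CA atoms, in atom order."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=int
        )

    def atom_index(self, chain_id: str, residue_position: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_position == residue_position
                and a.name == name
            ):
                return i
        raise KeyError(f"no atom {name} in chain {chain_id} residue {residue_position}")


@dataclass
class Trajectory:
    """Frames sharing one topology: a template structure plus coordinates.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; atom ordering is that of
    ``structure``.  ``times`` are per-frame times in ns, strictly increasing.
    """

    structure: Structure
    coords: np.ndarray
    times: np.ndarray = None  # type: ignore[assignment]
    topology: "ZipperTopology | None" = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (
            self.structure.n_atoms,
            3,
        ):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{self.structure.n_atoms} atoms"
            )
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.structure.with_coords(self.coords[i])

    def frames(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _atoms_from_array(arr: AtomArray) -> list[Atom]:
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize()
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                mass=mass_of_element(element),
                residue_position=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                coords=np.asarray(arr.coord[i], dtype=float),
            )
        )
    return atoms


def read_pdb(path: Union[str, Path]) -> Union[Structure, Trajectory]:
    """Read a PDB file; multi-MODEL files yield a Trajectory, single a Structure.

    Atom order is preserved as in the file.  MODEL blocks must contain the
    same atoms in the same order; otherwise a :class:`PDBFormatError` is
    raised.  Frame times are not stored in PDB; a loaded trajectory gets
    ``times = 0, 1, 2, ...`` (reassign after loading if needed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        if n_models == 1:
            arr = pdb_file.get_structure(model=1)
            return Structure(atoms=_atoms_from_array(arr))
        arr_stack: AtomArrayStack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise PDBFormatError(f"{path}: {exc}") from exc
    template = Structure(atoms=_atoms_from_array(arr_stack[0]))
    return Trajectory(structure=template, coords=np.asarray(arr_stack.coord, float))


def _array_from_structure(structure: Structure) -> AtomArray:
    n = structure.n_atoms
    arr = AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_position for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(path: Union[str, Path], obj: Union[Structure, Trajectory]) -> None:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks)."""
    pdb_file = PDBFile()
    if isinstance(obj, Trajectory):
        template = _array_from_structure(obj.structure)
        arrays = []
        for i in range(obj.n_frames):
            arr = template.copy()
            arr.coord = obj.coords[i]
            arrays.append(arr)
        pdb_file.set_structure(_stack(arrays))
    else:
        pdb_file.set_structure(_array_from_structure(obj))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Side-chain centers of mass
# ---------------------------------------------------------------------------


def is_sidechain(atom: Atom) -> bool:
    """Heavy side-chain atom: not backbone N/CA/C/O(/OXT) and not hydrogen."""
    return atom.name not in BACKBONE_ATOM_NAMES and atom.element.upper() != "H"


def sidechain_center_of_mass(
    structure: Structure, chain_id: str, residue_position: int
) -> np.ndarray:
    """Mass-weighted mean of a residue's heavy side-chain atoms (Angstrom).

    Hydrogens and the backbone N, CA, C, O are excluded.  Glycine has no
    side chain; its CA position is returned so that mutant analyses keep a
    well-defined contact point per residue.
    """
    side = [
        a
        for a in structure.atoms
        if a.chain_id == chain_id
        and a.residue_position == residue_position
        and is_sidechain(a)
    ]
    if not side:
        ca = [
            a
            for a in structure.atoms
            if a.chain_id == chain_id
            and a.residue_position == residue_position
            and a.name == "CA"
        ]
        if not ca:
            raise KeyError(
                f"chain {chain_id} residue {residue_position}: no side chain and no CA"
            )
        return ca[0].coords.copy()
    masses = np.array([a.mass for a in side])
    coords = np.array([a.coords for a in side])
    return masses @ coords / masses.sum()
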