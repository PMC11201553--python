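"""Molecular structures with a per-atom restraint-weight channel.

A :class:`Structure` is an ordered list of atoms with Cartesian
coordinates in Å.  Each atom additionally carries a ``restraint_weight``
in kcal/mol/Å² that encodes its role in a restrained optimization:

* ``-1``  — sentinel: the atom is *frozen* (static during optimization),
* ``0``   — free, unrestrained,
* ``> 0`` — harmonic positional restraint weight toward a reference
  position.

On disk the weight rides the PDB temperature-factor (B-factor) column,
so prepared pockets remain readable by any standard PDB tool.  Parsing
and formatting of the fixed-column PDB records is delegated to biotite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "read_xyz",
    "write_xyz",
    "element_from_atom_name",
    "FROZEN_SENTINEL",
]

#: restraint_weight value marking a frozen atom
FROZEN_SENTINEL: float = -1.0

# Recognized element symbols (all stable elements; docking inputs rarely
# go beyond the first few rows, but PDB files may contain e.g. Se, Zn).
_ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U""".split()
)
_ELEMENTS_UPPER = {e.upper(): e for e in _ELEMENTS}

# Two-letter elements accepted from a bare atom name.  "CA" is absent on
# purpose: in practice it is an alpha carbon; calcium must come from the
# element column.
_TWO_LETTER_IN_NAMES = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"}


def element_from_atom_name(atom_name: str) -> str:
    """Infer the element from a PDB atom name.

    Handles the common conventions: leading digits (``1HB``), primes
    (``O3'``), Greek-position suffixes (``CA``, ``ND1``) and the
    two-letter elements that actually occur in atom names.  Raises
    ``ValueError`` when no recognized element fits — a silent guess
    would corrupt every downstream energy evaluation.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    head = stripped[:2].upper()
    if head in _TWO_LETTER_IN_NAMES and head in _ELEMENTS_UPPER:
        # Two-letter matches are only taken when the name is exactly the
        # element symbol (ions are named like "ZN", "CL").
        if stripped.upper() == head:
            return _ELEMENTS_UPPER[head]
    one = stripped[0].upper()
    if one in _ELEMENTS_UPPER:
        return _ELEMENTS_UPPER[one]
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _normalize_element(symbol: str) -> str:
    sym = symbol.strip()
    if sym.upper() in _ELEMENTS_UPPER:
        return _ELEMENTS_UPPER[sym.upper()]
    raise ValueError(f"unrecognized element symbol {symbol!r}")


@dataclass(frozen=True)
class Atom:
    """One atom: element, position (Å), residue identity, restraint weight."""

    element: str
    coords: np.ndarray
    residue_name: str = "UNK"
    residue_id: int = 1
    chain_id: str = "A"
    atom_name: str = ""
    restraint_weight: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "element", _normalize_element(self.element))
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"coords must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", coords)
        if not math.isfinite(self.restraint_weight) or self.restraint_weight < -1:
            raise ValueError(
                f"restraint_weight must be >= -1 (-1 = frozen), got {self.restraint_weight}"
            )
        if not self.atom_name:
            object.__setattr__(self, "atom_name", self.element)


@dataclass
class Structure:
    """An ordered collection of atoms; atom order is stable and preserved."""

    atoms: list[Atom] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (a copy)."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def restraint_weights(self) -> np.ndarray:
        return np.array([a.restraint_weight for a in self.atoms], dtype=float)

    @property
    def frozen_mask(self) -> np.ndarray:
        """Boolean mask of atoms flagged frozen (weight == -1)."""
        return self.restraint_weights == FROZEN_SENTINEL

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}"
            )
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label if label is not None else self.label)

    def with_weights(self, weights: Sequence[float]) -> "Structure":
        if len(weights) != len(self.atoms):
            raise ValueError("weight array length does not match atom count")
        atoms = [replace(a, restraint_weight=float(w)) for a, w in zip(self.atoms, weights)]
        return Structure(atoms, self.label)

    def subset(self, indices: Sequence[int], label: str = "") -> "Structure":
        return Structure([self.atoms[i] for i in indices], label or self.label)

    def translated(self, shift: np.ndarray) -> "Structure":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def centroid(self) -> np.ndarray:
        """Unweighted geometric center."""
        if not self.atoms:
            raise ValueError("empty structure has no centroid")
        return self.coords.mean(axis=0)

    def residues(self) -> list[tuple[tuple[str, int], list[int]]]:
        """Group atom indices by (chain_id, residue_id), in first-seen order."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.chain_id, a.residue_id), []).append(i)
        return list(groups.items())


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _atom_array_to_structure(arr: bst.AtomArray, label: str) -> Structure:
    b_factor = (
        arr.get_annotation("b_factor")
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length())
    )
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip()
        name = str(arr.atom_name[i])
        if not elem:
            elem = element_from_atom_name(name)
        atoms.append(
            Atom(
                element=elem,
                coords=np.asarray(arr.coord[i], dtype=float),
                residue_name=str(arr.res_name[i]),
                residue_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                atom_name=name,
                restraint_weight=float(b_factor[i]),
            )
        )
    return Structure(atoms, label)


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every model of a PDB file as a list of Structures.

    A single-model file yields a one-element list.  Model order is
    preserved; for docked pose sets it defines the initial pose rank.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    structures = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, extra_fields=["b_factor"])
        if arr.array_length() == 0:
            raise ValueError(f"{path}: model {m} contains no atoms")
        structures.append(
            _atom_array_to_structure(arr, f"{path.stem}" if n_models == 1 else f"{path.stem}:{m}")
        )
    return structures


def read_pdb(path: str | Path) -> Structure | list[Structure]:
    """Read a PDB file; multi-model files yield a sequence of Structures."""
    models = read_pdb_models(path)
    return models[0] if len(models) == 1 else models


def _structure_to_atom_array(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_id for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in structure.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("b_factor", structure.restraint_weights)
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def write_pdb(structure: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one Structure (single model) or a sequence (MODEL/ENDMDL blocks).

    The restraint weight goes to the B-factor column with two decimals;
    ``-1.00`` marks frozen atoms.  Multi-model output requires identical
    atom annotations across models (the pose-set convention).
    """
    if isinstance(structure, Structure):
        if len(structure) == 0:
            raise ValueError("refusing to write an empty structure")
        array = _structure_to_atom_array(structure)
    else:
        models = list(structure)
        if not models or any(len(m) == 0 for m in models):
            raise ValueError("refusing to write empty models")
        template = _structure_to_atom_array(models[0])
        stack = bst.AtomArrayStack(len(models), len(models[0]))
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = np.stack([m.coords.astype(np.float32) for m in models])
        array = stack
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Structure:
    """Read a single-frame XYZ file (count header, element + 3 coords per line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed XYZ count header") from exc
    label = lines[1].strip() if len(lines) > 1 else ""
    atoms = []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed XYZ atom line {line!r}")
        atoms.append(Atom(element=parts[0], coords=[float(x) for x in parts[1:4]]))
    if len(atoms) != n:
        raise ValueError(f"{path}: header promises {n} atoms, found {len(atoms)}")
    return Structure(atoms, label)


def write_xyz(structure: Structure, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(structure)}\n{comment or structure.label}\n")
        for a in structure.atoms:
            x, y, z = a.coords
            fh.write(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def concatenate(parts: Iterable[Structure], label: str = "") -> Structure:
    """Concatenate structures preserving atom order (receptor-then-ligand)."""
    atoms: list[Atom] = []
    for p in parts:
        atoms.extend(p.atoms)
    return Structure(atoms, label)
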