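"""Columnar molecule/trajectory data model and elementary accessors.

A :class:`Molecule` is a columnar atom table plus one or more coordinate
frames and an optional bond graph. Atom identity throughout the library is the
0-based positional index — PDB serial numbers are carried as data but never
used as keys (they may repeat or overflow in real files).

Selections are plain sequences of strictly increasing, duplicate-free atom
indices; :func:`validate_selection` normalizes and checks them.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    FrameBoundsError,
    SelectionBoundsError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a circular import
    from .bonds import BondGraph

#: Text-valued AtomTable columns (stored as Python string lists).
TEXT_COLUMNS = (
    "name",
    "alt_loc",
    "resname",
    "chain",
    "insertion_code",
    "element",
    "record_kind",
)
#: Integer-valued columns (int64 arrays).
INT_COLUMNS = ("serial", "resseq")
#: Real-valued columns (float64 arrays).
REAL_COLUMNS = ("occupancy", "bfactor", "charge")

ALL_COLUMNS = TEXT_COLUMNS + INT_COLUMNS + REAL_COLUMNS


@dataclass
class AtomTable:
    """Column-oriented per-atom data. All columns share one length."""

    serial: np.ndarray
    name: list[str]
    alt_loc: list[str]
    resname: list[str]
    chain: list[str]
    resseq: np.ndarray
    insertion_code: list[str]
    occupancy: np.ndarray
    bfactor: np.ndarray
    element: list[str]
    charge: np.ndarray
    record_kind: list[str]

    @classmethod
    def empty(cls) -> "AtomTable":
        return cls.from_rows([])

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "AtomTable":
        """Build a table from per-atom dicts; missing fields get defaults."""
        rows = list(rows)
        defaults = {
            "serial": 0, "name": "", "alt_loc": "", "resname": "",
            "chain": "", "resseq": 0, "insertion_code": "",
            "occupancy": 1.0, "bfactor": 0.0, "element": "", "charge": 0.0,
            "record_kind": "ATOM",
        }
        cols: dict[str, list] = {k: [] for k in defaults}
        for row in rows:
            for k, dv in defaults.items():
                cols[k].append(row.get(k, dv))
        return cls(
            serial=np.asarray(cols["serial"], dtype=np.int64),
            name=[str(v) for v in cols["name"]],
            alt_loc=[str(v) for v in cols["alt_loc"]],
            resname=[str(v) for v in cols["resname"]],
            chain=[str(v) for v in cols["chain"]],
            resseq=np.asarray(cols["resseq"], dtype=np.int64),
            insertion_code=[str(v) for v in cols["insertion_code"]],
            occupancy=np.asarray(cols["occupancy"], dtype=np.float64),
            bfactor=np.asarray(cols["bfactor"], dtype=np.float64),
            element=[str(v) for v in cols["element"]],
            charge=np.asarray(cols["charge"], dtype=np.float64),
            record_kind=[str(v) for v in cols["record_kind"]],
        )

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def column(self, name: str):
        if name not in ALL_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)

    def take(self, indices: Sequence[int]) -> "AtomTable":
        idx = list(indices)
        return AtomTable(
            serial=self.serial[idx].copy(),
            name=[self.name[i] for i in idx],
            alt_loc=[self.alt_loc[i] for i in idx],
            resname=[self.resname[i] for i in idx],
            chain=[self.chain[i] for i in idx],
            resseq=self.resseq[idx].copy(),
            insertion_code=[self.insertion_code[i] for i in idx],
            occupancy=self.occupancy[idx].copy(),
            bfactor=self.bfactor[idx].copy(),
            element=[self.element[i] for i in idx],
            charge=self.charge[idx].copy(),
            record_kind=[self.record_kind[i] for i in idx],
        )

    def copy(self) -> "AtomTable":
        return self.take(range(self.n_atoms))

    @staticmethod
    def concat(a: "AtomTable", b: "AtomTable") -> "AtomTable":
        return AtomTable(
            serial=np.concatenate([a.serial, b.serial]),
            name=a.name + b.name,
            alt_loc=a.alt_loc + b.alt_loc,
            resname=a.resname + b.resname,
            chain=a.chain + b.chain,
            resseq=np.concatenate([a.resseq, b.resseq]),
            insertion_code=a.insertion_code + b.insertion_code,
            occupancy=np.concatenate([a.occupancy, b.occupancy]),
            bfactor=np.concatenate([a.bfactor, b.bfactor]),
            element=a.element + b.element,
            charge=np.concatenate([a.charge, b.charge]),
            record_kind=a.record_kind + b.record_kind,
        )

    def equals(self, other: "AtomTable") -> bool:
        if self.n_atoms != other.n_atoms:
            return False
        for col in TEXT_COLUMNS:
            if getattr(self, col) != getattr(other, col):
                return False
        for col in INT_COLUMNS:
            if not np.array_equal(getattr(self, col), getattr(other, col)):
                return False
        for col in REAL_COLUMNS:
            if not np.array_equal(getattr(self, col), getattr(other, col)):
                return False
        return True


@dataclass
class Molecule:
    """Atom table + coordinate frames (+ optional bonds, header remarks).

    ``frames`` is a list of ``(n_atoms, 3)`` float64 arrays in Å. ``extra``
    holds auxiliary per-atom text columns (e.g. AutoDock atom types from
    PDBQT input) keyed by column name.
    """

    atoms: AtomTable
    frames: list[np.ndarray]
    bonds: "BondGraph | None" = None
    remarks: list[str] = field(default_factory=list)
    extra: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=self.atoms.copy(),
            frames=[f.copy() for f in self.frames],
            bonds=_copy.deepcopy(self.bonds),
            remarks=list(self.remarks),
            extra={k: list(v) for k, v in self.extra.items()},
        )

    # Thin OO conveniences over the functional API.
    def get_frame(self, frame_index: int) -> np.ndarray:
        return get_frame(self, frame_index)

    def subset(self, sel: Sequence[int]) -> "Molecule":
        return copy_subset(self, sel)


def resolve_frame_index(mol: Molecule, frame_index: int) -> int:
    """Normalize a (possibly negative) frame index, raising on out-of-range."""
    n = mol.n_frames
    i = int(frame_index)
    if i < 0:
        i += n
    if not 0 <= i < n:
        raise FrameBoundsError(
            f"frame index {frame_index} out of range for {n} frame(s)"
        )
    return i


def validate_selection(sel: Sequence[int], n_atoms: int) -> list[int]:
    """Check that ``sel`` is strictly increasing, unique, and in-bounds.

    Returns the selection as a plain list of ints.
    """
    out: list[int] = []
    prev = -1
    for raw in sel:
        i = int(raw)
        if not 0 <= i < n_atoms:
            raise SelectionBoundsError(
                f"atom index {i} out of range for {n_atoms} atom(s)"
            )
        if i <= prev:
            raise SelectionBoundsError(
                "selection indices must be strictly increasing and unique"
            )
        out.append(i)
        prev = i
    return out


def copy_subset(mol: Molecule, sel: Sequence[int]) -> Molecule:
    """Deep-copied sub-molecule over the selected atoms.

    All frames are sliced consistently and bonds are restricted to
    intra-selection pairs with indices remapped to the new positions.
    """
    idx = validate_selection(sel, mol.n_atoms)
    sub_bonds = mol.bonds.subgraph(idx) if mol.bonds is not None else None
    return Molecule(
        atoms=mol.atoms.take(idx),
        frames=[f[idx].copy() for f in mol.frames],
        bonds=sub_bonds,
        remarks=list(mol.remarks),
        extra={k: [v[i] for i in idx] for k, v in mol.extra.items()},
    )


def get_frame(mol: Molecule, frame_index: int) -> np.ndarray:
    """Defensive copy of one frame's ``(n_atoms, 3)`` coordinates."""
    return mol.frames[resolve_frame_index(mol, frame_index)].copy()


def geometric_center(
    mol: Molecule, sel: Sequence[int], frame_index: int = 0
) -> np.ndarray:
    """Unweighted mean position of the selected atoms in one frame."""
    idx = validate_selection(sel, mol.n_atoms)
    if not idx:
        raise EmptySelectionError("geometric center of an empty selection")
    frame = mol.frames[resolve_frame_index(mol, frame_index)]
    return frame[idx].mean(axis=0)


def molecules_equal(a: Molecule, b: Molecule, coord_tol: float = 0.0) -> bool:
    """True iff all atom columns match exactly and coordinates within tol.

    Shape mismatches (atom or frame counts) yield False, never an error.
    """
    if coord_tol < 0:
        raise ValueError("coord_tol must be >= 0")
    if a.n_atoms != b.n_atoms or a.n_frames != b.n_frames:
        return False
    if not a.atoms.equals(b.atoms):
        return False
    for fa, fb in zip(a.frames, b.frames):
        if fa.shape != fb.shape:
            return False
        if fa.size and np.abs(fa - fb).max() > coord_tol:
            return False
    return True
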