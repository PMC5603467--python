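"""Deterministic synthetic molecules and trajectories.

Every generator is a pure function of its arguments (including the seed), so
tests, docs examples, and the acceptance suite run without any downloads.
Randomness goes through ``numpy.random.default_rng(seed)`` — no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AtomTable, Molecule
from .errors import ParameterError

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"))

#: Alphabets for randomized atom tables. Names map 1:1 to an element so the
#: generated chemistry stays self-consistent.
_NAME_POOL = (
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
    ("CG", "C"), ("OD1", "O"), ("ND2", "N"), ("SD", "S"), ("OG", "O"),
)
_RESNAME_POOL = ("ALA", "GLY", "SER", "LEU", "HIS", "ASP", "MET")
_CHAIN_POOL = ("A", "B", "C")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for :func:`make_random_molecule` (deterministic per seed)."""

    seed: int
    n_atoms: int = 50
    n_frames: int = 1
    box_size: float = 20.0
    atoms_per_residue: int = 4


def make_chain(n_residues: int, spacing: float = 1.5, chain_id: str = "A") -> Molecule:
    """Collinear backbone-like chain: N, CA, C per residue along +x.

    Consecutive atoms sit ``spacing`` Å apart, so with the default 1.5 Å the
    distance-based bond rule links them into a single path graph.
    """
    if n_residues < 1 or spacing <= 0:
        raise ParameterError("need n_residues >= 1 and spacing > 0")
    rows = []
    coords = []
    serial = 1
    for res in range(1, n_residues + 1):
        for name, element in _BACKBONE:
            rows.append({
                "serial": serial,
                "name": name,
                "resname": "ALA",
                "chain": chain_id,
                "resseq": res,
                "occupancy": 1.0,
                "bfactor": 0.0,
                "element": element,
                "record_kind": "ATOM",
            })
            coords.append([(serial - 1) * spacing, 0.0, 0.0])
            serial += 1
    return Molecule(
        atoms=AtomTable.from_rows(rows),
        frames=[np.asarray(coords, dtype=np.float64)],
    )


def make_two_domain_trajectory(schedule: Sequence[float]) -> Molecule:
    """Two single-atom chains whose gap follows ``schedule`` frame by frame.

    Chain A holds one static atom at the origin; chain B's atom sits at
    ``(0, 0, schedule[k])`` in frame ``k``. This makes contact-footprint
    fractions analytically predictable from the schedule alone.
    """
    schedule = list(schedule)
    if not schedule:
        raise ParameterError("schedule must be non-empty")
    rows = [
        {"serial": 1, "name": "CA", "resname": "ALA", "chain": "A",
         "resseq": 1, "element": "C", "record_kind": "ATOM"},
        {"serial": 2, "name": "CA", "resname": "ALA", "chain": "B",
         "resseq": 1, "element": "C", "record_kind": "ATOM"},
    ]
    frames = [
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(gap)]]) for gap in schedule
    ]
    return Molecule(atoms=AtomTable.from_rows(rows), frames=frames)


def make_random_molecule(spec: FixtureSpec | int, n_atoms: int | None = None) -> Molecule:
    """Seeded random molecule with realistic-looking columns.

    Accepts either a :class:`FixtureSpec` or a bare seed (with optional
    ``n_atoms``). Coordinates are uniform in a cube of ``box_size`` Å;
    occupancy/B-factor are 2-decimal values and charges small integers so the
    molecule survives a PDB round trip column-exactly.
    """
    if not isinstance(spec, FixtureSpec):
        spec = FixtureSpec(seed=int(spec), n_atoms=n_atoms or 50)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    rows = []
    for i in range(n):
        name, element = _NAME_POOL[rng.integers(len(_NAME_POOL))]
        resseq = i // spec.atoms_per_residue + 1
        rows.append({
            "serial": i + 1,
            "name": name,
            "alt_loc": "",
            "resname": _RESNAME_POOL[rng.integers(len(_RESNAME_POOL))],
            "chain": _CHAIN_POOL[rng.integers(len(_CHAIN_POOL))],
            "resseq": resseq,
            "insertion_code": "",
            "occupancy": round(float(rng.integers(0, 101)) / 100.0, 2),
            "bfactor": round(float(rng.integers(0, 10000)) / 100.0, 2),
            "element": element,
            "charge": float(rng.integers(-2, 3)),
            "record_kind": "ATOM" if rng.random() < 0.9 else "HETATM",
        })
    frames = [
        rng.uniform(0.0, spec.box_size, size=(n, 3)) for _ in range(spec.n_frames)
    ]
    return Molecule(atoms=AtomTable.from_rows(rows), frames=frames)


def make_random_cloud(seed: int, n_atoms: int, box_size: float = 20.0,
                      n_frames: int = 1) -> Molecule:
    """Random carbon cloud: minimal columns, random coordinates (for oracles)."""
    rng = np.random.default_rng(seed)
    rows = [
        {"serial": i + 1, "name": "C", "resname": "LIG", "chain": "A",
         "resseq": i + 1, "element": "C", "record_kind": "HETATM"}
        for i in range(n_atoms)
    ]
    frames = [rng.uniform(0.0, box_size, size=(n_atoms, 3)) for _ in range(n_frames)]
    return Molecule(atoms=AtomTable.from_rows(rows), frames=frames)
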