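"""Inter-domain contact-footprint analysis over a trajectory.

For two disjoint atom selections (the "domains"), each selected atom's
contact residence fraction is the fraction of trajectory frames in which it
lies within a cutoff (default 3.0 Å, inclusive) of any atom of the other
domain. Fractions are written into the PDB occupancy field (0.00–1.00) of a
single-frame annotated copy, ready for surface coloring in a viewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Molecule, validate_selection
from .errors import (
    AnnotationError,
    EmptySelectionError,
    SelectionOverlapError,
)
from .fileio import load_any, save_pdb
from .selections import select_atoms

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.0


@dataclass
class FootprintResult:
    """Per-atom contact residence fractions in [0, 1].

    ``fractions[i] * n_frames`` is always an integer (a frame count); atoms
    outside both selections have fraction 0.
    """

    fractions: np.ndarray
    n_frames: int
    cutoff: float
    sel_a: list[int]
    sel_b: list[int]


def contact_residence_fractions(
    mol: Molecule,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> FootprintResult:
    """Fraction of frames each selected atom spends within ``cutoff`` of the
    other selection.

    ``sel_a`` and ``sel_b`` must be disjoint and non-empty; all frames of
    ``mol`` are analyzed.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ia = validate_selection(sel_a, mol.n_atoms)
    ib = validate_selection(sel_b, mol.n_atoms)
    if not ia or not ib:
        raise EmptySelectionError("both domain selections must be non-empty")
    overlap = set(ia) & set(ib)
    if overlap:
        raise SelectionOverlapError(
            f"domain selections share atoms: {sorted(overlap)[:10]}"
        )
    counts = np.zeros(mol.n_atoms, dtype=np.int64)
    cutoff_sq = cutoff * cutoff
    arr_a = np.array(ia)
    arr_b = np.array(ib)
    for frame in mol.frames:
        diff = frame[arr_a][:, None, :] - frame[arr_b][None, :, :]
        close = (diff * diff).sum(axis=-1) <= cutoff_sq
        counts[arr_a] += close.any(axis=1)
        counts[arr_b] += close.any(axis=0)
    fractions = counts / mol.n_frames
    return FootprintResult(
        fractions=fractions,
        n_frames=mol.n_frames,
        cutoff=float(cutoff),
        sel_a=ia,
        sel_b=ib,
    )


def annotate_occupancy(
    mol: Molecule, result: FootprintResult, percent: bool = False
) -> Molecule:
    """Single-frame copy of ``mol`` with fractions in the occupancy column.

    Values are rounded to 2 decimals (the PDB field precision). With
    ``percent=True`` the 0–100 scale is stored instead.
    """
    if len(result.fractions) != mol.n_atoms:
        raise AnnotationError(
            f"result covers {len(result.fractions)} atoms, molecule has {mol.n_atoms}"
        )
    out = mol.copy()
    out.frames = [mol.frames[0].copy()]
    values = result.fractions * (100.0 if percent else 1.0)
    out.atoms.occupancy = np.round(values, 2)
    return out


def aggregate_per_residue(
    mol: Molecule, result: FootprintResult, rule: str = "max"
) -> dict[tuple[str, int, str], float]:
    """Aggregate atom fractions to residues keyed by (chain, resseq, icode).

    ``rule`` is ``"max"`` (default: a residue is in contact when any of its
    atoms is) or ``"mean"``.
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    groups: dict[tuple[str, int, str], list[float]] = {}
    at = mol.atoms
    for i in range(mol.n_atoms):
        key = (at.chain[i], int(at.resseq[i]), at.insertion_code[i])
        groups.setdefault(key, []).append(float(result.fractions[i]))
    agg = max if rule == "max" else (lambda vs: sum(vs) / len(vs))
    return {key: agg(vals) for key, vals in groups.items()}


def run_footprint(
    traj_path,
    criteria_a: Mapping[str, object],
    criteria_b: Mapping[str, object],
    cutoff: float = DEFAULT_CUTOFF,
    out_path=None,
    percent: bool = False,
) -> FootprintResult:
    """End-to-end pipeline: load trajectory, select the two domains, compute
    contact residence fractions, annotate occupancies, save a PDB.

    Fails fast (before any computation) when either criteria set selects no
    atoms or the cutoff is non-positive.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    mol = load_any(traj_path)
    sel_a = select_atoms(mol, criteria_a)
    sel_b = select_atoms(mol, criteria_b)
    if not sel_a or not sel_b:
        raise EmptySelectionError(
            f"domain criteria selected {len(sel_a)} and {len(sel_b)} atoms; "
            "both must be non-empty"
        )
    logger.info(
        "footprint: %d frames, |A|=%d, |B|=%d, cutoff=%.2f Å",
        mol.n_frames, len(sel_a), len(sel_b), cutoff,
    )
    result = contact_residence_fractions(mol, sel_a, sel_b, cutoff)
    if out_path is not None:
        annotated = annotate_occupancy(mol, result, percent=percent)
        save_pdb(annotated, out_path)
    return result
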