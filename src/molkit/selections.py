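"""Property-based and spatial atom selection, plus selection set algebra.

Criteria are per-column constraints combined by logical AND: text and integer
columns take a set of allowed values, real columns take an inclusive
``(low, high)`` interval. Spatial selections use closed balls (``<= cutoff``)
so a "within 3 Å" query includes atoms at exactly 3 Å.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    INT_COLUMNS,
    REAL_COLUMNS,
    TEXT_COLUMNS,
    Molecule,
    resolve_frame_index,
    validate_selection,
)
from .errors import CriteriaError, SelectionMismatchError


def select_atoms(mol: Molecule, criteria: Mapping[str, object]) -> list[int]:
    """Indices of atoms satisfying every criterion, in increasing order.

    Empty criteria select all atoms. Text values are compared exactly after
    whitespace trim (case-sensitive).
    """
    mask = np.ones(mol.n_atoms, dtype=bool)
    for column, constraint in criteria.items():
        if column in TEXT_COLUMNS:
            if isinstance(constraint, str):
                constraint = {constraint}
            allowed = {str(v).strip() for v in constraint}
            values = mol.atoms.column(column)
            col_mask = np.array([v.strip() in allowed for v in values], dtype=bool)
        elif column in INT_COLUMNS:
            if isinstance(constraint, (int, np.integer)):
                constraint = {int(constraint)}
            allowed_ints = {int(v) for v in constraint}
            values = mol.atoms.column(column)
            col_mask = np.array([int(v) in allowed_ints for v in values], dtype=bool)
        elif column in REAL_COLUMNS:
            try:
                low, high = constraint  # type: ignore[misc]
            except (TypeError, ValueError) as exc:
                raise CriteriaError(
                    f"real column {column!r} needs a (low, high) interval"
                ) from exc
            values = mol.atoms.column(column)
            col_mask = (values >= float(low)) & (values <= float(high))
        else:
            raise CriteriaError(f"unknown column {column!r}")
        mask &= col_mask
    return np.nonzero(mask)[0].tolist()


def select_atoms_near_other_selection(
    mol: Molecule,
    sel: Sequence[int],
    cutoff: float,
    frame_index: int = 0,
    include_selection: bool = False,
    method: str = "auto",
) -> list[int]:
    """Atoms within ``cutoff`` Å of any atom of ``sel`` in one frame.

    The seed selection itself is excluded unless ``include_selection``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    idx = validate_selection(sel, mol.n_atoms)
    coords = mol.frames[resolve_frame_index(mol, frame_index)]
    if not idx:
        return []
    if method == "auto":
        method = "kdtree" if mol.n_atoms > 500 else "pairs"
    if method == "pairs":
        seed = coords[idx]
        diff = coords[:, None, :] - seed[None, :, :]
        near = (diff * diff).sum(axis=-1) <= cutoff * cutoff
        hits = set(np.nonzero(near.any(axis=1))[0].tolist())
    elif method == "kdtree":
        tree = cKDTree(coords)
        hits = set()
        for lst in tree.query_ball_point(coords[idx], r=cutoff):
            hits.update(lst)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not include_selection:
        hits -= set(idx)
    return sorted(hits)


def select_close_atoms_from_different_molecules(
    a: Molecule,
    b: Molecule,
    cutoff: float,
    frame_a: int = 0,
    frame_b: int = 0,
) -> tuple[list[int], list[int]]:
    """Cross-molecule proximity: atoms of each molecule within ``cutoff`` of the other."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ca = a.frames[resolve_frame_index(a, frame_a)]
    cb = b.frames[resolve_frame_index(b, frame_b)]
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        return [], []
    diff = ca[:, None, :] - cb[None, :, :]
    close = (diff * diff).sum(axis=-1) <= cutoff * cutoff
    sel_a = np.nonzero(close.any(axis=1))[0].tolist()
    sel_b = np.nonzero(close.any(axis=0))[0].tolist()
    return sel_a, sel_b


def _check_operands(n_atoms: int, *sels: Sequence[int]) -> list[set[int]]:
    out = []
    for sel in sels:
        try:
            out.append(set(validate_selection(sel, n_atoms)))
        except Exception as exc:
            raise SelectionMismatchError(
                f"selection does not fit a molecule of {n_atoms} atoms: {exc}"
            ) from exc
    return out


def union(a: Sequence[int], b: Sequence[int], n_atoms: int) -> list[int]:
    sa, sb = _check_operands(n_atoms, a, b)
    return sorted(sa | sb)


def intersection(a: Sequence[int], b: Sequence[int], n_atoms: int) -> list[int]:
    sa, sb = _check_operands(n_atoms, a, b)
    return sorted(sa & sb)


def difference(a: Sequence[int], b: Sequence[int], n_atoms: int) -> list[int]:
    sa, sb = _check_operands(n_atoms, a, b)
    return sorted(sa - sb)


def invert(sel: Sequence[int], n_atoms: int) -> list[int]:
    (s,) = _check_operands(n_atoms, sel)
    return sorted(set(range(n_atoms)) - s)
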