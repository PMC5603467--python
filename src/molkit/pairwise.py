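"""Pairwise inter-molecule operations.

RMSD over an explicit atom pairing, a key-based pairing heuristic, optimal
rigid superposition (Kabsch via SVD with reflection correction), steric-clash
detection, minimum inter-molecular distance, and molecule merging.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import AtomTable, Molecule, resolve_frame_index
from .errors import (
    EmptyMoleculeError,
    EmptyPairingError,
    MergeShapeError,
    NoCorrespondenceError,
)

AtomPairing = list[tuple[int, int]]


def _paired_coords(
    a: Molecule, b: Molecule, pairing: AtomPairing, frame_a: int, frame_b: int
) -> tuple[np.ndarray, np.ndarray]:
    if not pairing:
        raise EmptyPairingError("pairing contains no atom pairs")
    ca = a.frames[resolve_frame_index(a, frame_a)]
    cb = b.frames[resolve_frame_index(b, frame_b)]
    ia = [p[0] for p in pairing]
    ib = [p[1] for p in pairing]
    if len(set(ia)) != len(ia) or len(set(ib)) != len(ib):
        raise ValueError("pairing repeats an atom index")
    return ca[ia], cb[ib]


def rmsd(
    a: Molecule,
    b: Molecule,
    pairing: AtomPairing | None = None,
    frame_a: int = 0,
    frame_b: int = 0,
) -> float:
    """Root-mean-square deviation over paired atoms; no superposition applied.

    ``pairing=None`` pairs atoms positionally (requires equal atom counts).
    """
    if pairing is None:
        if a.n_atoms != b.n_atoms:
            raise EmptyPairingError(
                "positional pairing needs equal atom counts; supply a pairing"
            )
        pairing = [(i, i) for i in range(a.n_atoms)]
    xa, xb = _paired_coords(a, b, pairing, frame_a, frame_b)
    return float(np.sqrt(((xa - xb) ** 2).sum(axis=1).mean()))


def pairing_heuristic(a: Molecule, b: Molecule) -> AtomPairing:
    """Pair atoms by exact (chain, resseq, insertion_code, name) key.

    Atoms whose key is non-unique on either side, or unmatched, are dropped.
    The pairing is sorted by A-index.
    """

    def keys(mol: Molecule) -> dict[tuple, list[int]]:
        table: dict[tuple, list[int]] = {}
        at = mol.atoms
        for i in range(mol.n_atoms):
            key = (
                at.chain[i].strip(),
                int(at.resseq[i]),
                at.insertion_code[i].strip(),
                at.name[i].strip(),
            )
            table.setdefault(key, []).append(i)
        return table

    ka, kb = keys(a), keys(b)
    pairs = sorted(
        (ia[0], kb[key][0])
        for key, ia in ka.items()
        if len(ia) == 1 and len(kb.get(key, ())) == 1
    )
    if not pairs:
        raise NoCorrespondenceError("no unique key matches between molecules")
    return pairs


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with ``R@x+t ≈ target``.

    Centers both point sets, takes the SVD of the cross-covariance, and flips
    the smallest singular direction if needed so det(R) = +1 (no reflections:
    molecules are chiral).
    """
    mov_c = moving.mean(axis=0)
    tgt_c = target.mean(axis=0)
    H = (moving - mov_c).T @ (target - tgt_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt_c - R @ mov_c
    return R, t


def align_other_to_this(
    ref: Molecule,
    other: Molecule,
    pairing: AtomPairing | None = None,
    frame_ref: int = 0,
    frame_other: int = 0,
) -> tuple[Molecule, float]:
    """Copy of ``other`` rigidly superposed onto ``ref`` over the paired atoms.

    The transform is fitted on the paired atoms only but moves *all* atoms
    (and all frames) of ``other``. Returns the moved copy and the
    post-alignment paired RMSD. With fewer than 3 non-collinear pairs the
    rotation is not unique; the SVD still returns one valid minimizer.
    """
    if pairing is None:
        pairing = pairing_heuristic(ref, other)
    x_ref, x_other = _paired_coords(ref, other, list(pairing), frame_ref, frame_other)
    R, t = kabsch(x_other, x_ref)
    moved = other.copy()
    for fi in range(moved.n_frames):
        moved.frames[fi] = moved.frames[fi] @ R.T + t
    final = rmsd(ref, moved, pairing, frame_ref, frame_other)
    return moved, final


def steric_clash_with_another_molecule(
    a: Molecule,
    b: Molecule,
    cutoff: float,
    frame_a: int = 0,
    frame_b: int = 0,
) -> tuple[bool, list[tuple[int, int]]]:
    """Whether any inter-molecule atom pair lies within ``cutoff`` Å.

    Returns the exhaustive, sorted list of clashing (a_index, b_index) pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ca = a.frames[resolve_frame_index(a, frame_a)]
    cb = b.frames[resolve_frame_index(b, frame_b)]
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        return False, []
    diff = ca[:, None, :] - cb[None, :, :]
    close = (diff * diff).sum(axis=-1) <= cutoff * cutoff
    ii, jj = np.nonzero(close)
    pairs = sorted(zip(ii.tolist(), jj.tolist()))
    return bool(pairs), pairs


def get_distance_to_another_molecule(
    a: Molecule, b: Molecule, frame_a: int = 0, frame_b: int = 0
) -> float:
    """Minimum inter-atomic distance over all cross pairs (Å)."""
    ca = a.frames[resolve_frame_index(a, frame_a)]
    cb = b.frames[resolve_frame_index(b, frame_b)]
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        raise EmptyMoleculeError("both molecules must contain atoms")
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=-1).min()))


def get_centroid_distance_to_another_molecule(
    a: Molecule, b: Molecule, frame_a: int = 0, frame_b: int = 0
) -> float:
    """Distance between the two geometric centers (alternative metric)."""
    ca = a.frames[resolve_frame_index(a, frame_a)]
    cb = b.frames[resolve_frame_index(b, frame_b)]
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        raise EmptyMoleculeError("both molecules must contain atoms")
    return float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))


def merge(a: Molecule, b: Molecule) -> Molecule:
    """Concatenate two molecules (``a`` first) frame by frame.

    Bonds of ``b`` are re-indexed by ``a.n_atoms``; serial numbers are kept
    verbatim, so duplicates are possible (atom identity stays positional).
    """
    if a.n_frames != b.n_frames:
        raise MergeShapeError(
            f"frame counts differ: {a.n_frames} vs {b.n_frames}"
        )
    n_total = a.n_atoms + b.n_atoms
    bonds = None
    if a.bonds is not None or b.bonds is not None:
        from .bonds import BondGraph

        bonds = BondGraph(n_total)
        if a.bonds is not None:
            for i, j in a.bonds.edges():
                bonds.add_bond(i, j)
        if b.bonds is not None:
            for i, j in b.bonds.edges():
                bonds.add_bond(i + a.n_atoms, j + a.n_atoms)
    extra: dict[str, list[str]] = {}
    for key in set(a.extra) | set(b.extra):
        extra[key] = (
            a.extra.get(key, [""] * a.n_atoms) + b.extra.get(key, [""] * b.n_atoms)
        )
    return Molecule(
        atoms=AtomTable.concat(a.atoms, b.atoms),
        frames=[
            np.concatenate([fa, fb], axis=0)
            for fa, fb in zip(a.frames, b.frames)
        ],
        bonds=bonds,
        remarks=list(a.remarks) + list(b.remarks),
        extra=extra,
    )
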