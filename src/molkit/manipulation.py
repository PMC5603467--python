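"""Rigid-body translation and rotation of molecular coordinates.

All operations mutate the molecule in place (pass ``copy=True`` for a
transformed copy) and accept ``frames="all"`` or a single frame index.

Euler angles use the extrinsic X-then-Y-then-Z convention: the combined
matrix is ``R = Rz(θz) @ Ry(θy) @ Rx(θx)`` with right-handed rotations about
the fixed coordinate axes. Angles are radians throughout the library; the CLI
offers ``--degrees``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Molecule, resolve_frame_index
from .errors import AtomBoundsError, DegenerateAxisError


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rotation_matrix_xyz(theta_x: float, theta_y: float, theta_z: float) -> np.ndarray:
    """Extrinsic XYZ rotation matrix ``Rz @ Ry @ Rx``."""
    cx, sx = np.cos(theta_x), np.sin(theta_x)
    cy, sy = np.cos(theta_y), np.sin(theta_y)
    cz, sz = np.cos(theta_z), np.sin(theta_z)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-zero) axis, right-hand rule."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(axis)
    if norm <= 1e-9:
        raise DegenerateAxisError("rotation axis has (near-)zero length")
    k = axis / norm
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _target_frames(mol: Molecule, frames) -> list[int]:
    if frames == "all":
        return list(range(mol.n_frames))
    return [resolve_frame_index(mol, frames)]


def _maybe_copy(mol: Molecule, copy: bool) -> Molecule:
    return mol.copy() if copy else mol


def translate(
    mol: Molecule, v: Sequence[float], frames="all", copy: bool = False
) -> Molecule:
    """Shift targeted frames by vector ``v`` (Å)."""
    mol = _maybe_copy(mol, copy)
    vec = np.asarray(v, dtype=float).reshape(3)
    for fi in _target_frames(mol, frames):
        mol.frames[fi] += vec
    return mol


def rotate_around_pivot_point(
    mol: Molecule,
    pivot: Sequence[float],
    angles: Sequence[float],
    frames="all",
    copy: bool = False,
) -> Molecule:
    """Rotate about a fixed point: ``x -> R(x - pivot) + pivot``."""
    mol = _maybe_copy(mol, copy)
    p = np.asarray(pivot, dtype=float).reshape(3)
    R = rotation_matrix_xyz(*(float(a) for a in angles))
    for fi in _target_frames(mol, frames):
        mol.frames[fi] = (mol.frames[fi] - p) @ R.T + p
    return mol


def rotate_around_pivot_atom(
    mol: Molecule,
    pivot_atom: int,
    angles: Sequence[float],
    frames="all",
    copy: bool = False,
    per_frame_pivot: bool = True,
) -> Molecule:
    """Rotate about an atom's own coordinates.

    With ``frames="all"`` each frame pivots about that atom's position in the
    same frame (set ``per_frame_pivot=False`` to pivot every frame about the
    frame-0 position).
    """
    mol = _maybe_copy(mol, copy)
    if not 0 <= int(pivot_atom) < mol.n_atoms:
        raise AtomBoundsError(
            f"pivot atom {pivot_atom} out of range for {mol.n_atoms} atoms"
        )
    R = rotation_matrix_xyz(*(float(a) for a in angles))
    fixed_pivot = mol.frames[0][int(pivot_atom)].copy()
    for fi in _target_frames(mol, frames):
        p = mol.frames[fi][int(pivot_atom)].copy() if per_frame_pivot else fixed_pivot
        mol.frames[fi] = (mol.frames[fi] - p) @ R.T + p
    return mol


def rotate_around_line(
    mol: Molecule,
    p1: Sequence[float],
    p2: Sequence[float],
    angle: float,
    frames="all",
    copy: bool = False,
) -> Molecule:
    """Rotate by ``angle`` about the axis through ``p1`` toward ``p2``."""
    mol = _maybe_copy(mol, copy)
    a = np.asarray(p1, dtype=float).reshape(3)
    b = np.asarray(p2, dtype=float).reshape(3)
    R = axis_angle_matrix(b - a, float(angle))
    for fi in _target_frames(mol, frames):
        mol.frames[fi] = (mol.frames[fi] - a) @ R.T + a
    return mol
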