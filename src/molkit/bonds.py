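"""Distance-based bond perception and bond-graph algorithms.

Two atoms i, j (i < j) are bonded iff

    min_dist < d(i, j) <= r_cov(element_i) + r_cov(element_j) + tolerance

using the bundled single-bond covalent radii. ``min_dist`` suppresses bonds
between overlapping/duplicated atoms. Two code paths produce identical graphs:
a vectorized all-pairs scan (reference) and a KD-tree neighbor search
(accelerated); both are exercised by the test suite against a pure-Python
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Molecule, resolve_frame_index, validate_selection
from .elements import covalent_radius
from .errors import InvalidBranchError

DEFAULT_TOLERANCE = 0.4
DEFAULT_MIN_DIST = 0.4


@dataclass
class BondGraph:
    """Undirected simple graph over atom indices ``0..n_atoms-1``."""

    n_atoms: int
    _adj: list[set[int]] = field(default_factory=list)

    def __post_init__(self):
        if not self._adj:
            self._adj = [set() for _ in range(self.n_atoms)]

    @classmethod
    def from_edges(cls, n_atoms: int, edges: Iterable[tuple[int, int]]) -> "BondGraph":
        g = cls(n_atoms)
        for i, j in edges:
            g.add_bond(i, j)
        return g

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed in a bond graph")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise IndexError(f"bond ({i},{j}) out of range for {self.n_atoms} atoms")
        self._adj[i].add(j)
        self._adj[j].add(i)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def adjacency(self) -> list[list[int]]:
        return [sorted(s) for s in self._adj]

    def edges(self) -> list[tuple[int, int]]:
        """All bonds as sorted (i, j) pairs with i < j."""
        return sorted(
            (i, j) for i in range(self.n_atoms) for j in self._adj[i] if i < j
        )

    @property
    def n_bonds(self) -> int:
        return sum(len(s) for s in self._adj) // 2

    def has_bond(self, i: int, j: int) -> bool:
        return j in self._adj[i]

    def subgraph(self, indices: Sequence[int]) -> "BondGraph":
        """Graph restricted to ``indices``, remapped to 0..len-1."""
        remap = {old: new for new, old in enumerate(indices)}
        g = BondGraph(len(remap))
        for old_i, new_i in remap.items():
            for old_j in self._adj[old_i]:
                new_j = remap.get(old_j)
                if new_j is not None and new_i < new_j:
                    g.add_bond(new_i, new_j)
        return g

    def offset(self, delta: int, n_atoms: int) -> "BondGraph":
        """Copy with every index shifted by ``delta`` into a graph of ``n_atoms``."""
        g = BondGraph(n_atoms)
        for i, j in self.edges():
            g.add_bond(i + delta, j + delta)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, BondGraph):
            return NotImplemented
        return self.n_atoms == other.n_atoms and self.edges() == other.edges()


def _radii(mol: Molecule) -> np.ndarray:
    return np.array([covalent_radius(e) for e in mol.atoms.element])


def create_bonds_by_distance(
    mol: Molecule,
    frame_index: int = 0,
    tolerance: float = DEFAULT_TOLERANCE,
    min_dist: float = DEFAULT_MIN_DIST,
    method: str = "auto",
) -> BondGraph:
    """Perceive bonds from interatomic distances in one frame.

    Parameters
    ----------
    method:
        ``"pairs"`` — vectorized all-pairs distance matrix (reference path);
        ``"kdtree"`` — KD-tree fixed-radius neighbor search (accelerated path);
        ``"auto"`` — kdtree for larger systems, pairs otherwise. Both paths
        yield identical graphs by construction.
    """
    if tolerance < 0 or min_dist < 0:
        raise ValueError("tolerance and min_dist must be >= 0")
    if method not in ("auto", "pairs", "kdtree"):
        raise ValueError(f"unknown method {method!r}")
    coords = mol.frames[resolve_frame_index(mol, frame_index)]
    n = mol.n_atoms
    if method == "auto":
        method = "kdtree" if n > 500 else "pairs"
    radii = _radii(mol) if n else np.empty(0)
    graph = BondGraph(n)
    if n < 2:
        return graph

    if method == "pairs":
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=-1))
        cut = radii[:, None] + radii[None, :] + tolerance
        bonded = (dist > min_dist) & (dist <= cut)
        ii, jj = np.nonzero(np.triu(bonded, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            graph.add_bond(i, j)
    else:
        tree = cKDTree(coords)
        r_max = 2.0 * radii.max() + tolerance
        for i, j in tree.query_pairs(r=r_max):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if min_dist < d <= radii[i] + radii[j] + tolerance:
                graph.add_bond(min(i, j), max(i, j))
    return graph


def constituent_molecule_selections(bonds: BondGraph) -> list[list[int]]:
    """Connected components as sorted selections, ordered by smallest member."""
    seen = [False] * bonds.n_atoms
    components: list[list[int]] = []
    for start in range(bonds.n_atoms):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in bonds._adj[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        components.append(sorted(comp))
    return components  # discovery order == order by smallest member


def select_atoms_from_same_molecule(
    bonds: BondGraph, sel: Sequence[int]
) -> list[int]:
    """Union of every connected component intersecting ``sel``."""
    idx = validate_selection(sel, bonds.n_atoms)
    if not idx:
        return []
    want = set(idx)
    out: set[int] = set()
    for comp in constituent_molecule_selections(bonds):
        if want.intersection(comp):
            out.update(comp)
    return sorted(out)


def select_all_atoms_bound_to_selection(
    bonds: BondGraph, sel: Sequence[int]
) -> list[int]:
    """Atoms adjacent to any member of ``sel``, excluding ``sel`` itself."""
    idx = set(validate_selection(sel, bonds.n_atoms))
    out: set[int] = set()
    for i in idx:
        out.update(bonds._adj[i])
    return sorted(out - idx)


def select_branch(bonds: BondGraph, root: int, away_from: int) -> list[int]:
    """Atoms reachable from ``root`` without crossing the root–away_from bond.

    ``root`` is always included. On cyclic graphs the traversal terminates via
    a visited set and may legitimately reach ``away_from`` through a cycle.
    """
    if not (0 <= root < bonds.n_atoms and 0 <= away_from < bonds.n_atoms):
        raise IndexError("root/away_from out of range")
    if not bonds.has_bond(root, away_from):
        raise InvalidBranchError(
            f"atoms {root} and {away_from} are not bonded; no branch to select"
        )
    visited = {root}
    stack = [root]
    while stack:
        i = stack.pop()
        for j in bonds._adj[i]:
            if i == root and j == away_from:
                continue  # the severed edge
            if j not in visited:
                visited.add(j)
                stack.append(j)
    return sorted(visited)
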