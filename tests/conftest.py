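import numpy as np
import pytest

from molkit.bonds import BondGraph
from molkit.core import AtomTable, Molecule
from molkit.fixtures import make_chain, make_two_domain_trajectory


@pytest.fixture
def chain2() -> Molecule:
    """6-atom collinear backbone chain, consecutive atoms 1.5 Å apart."""
    return make_chain(2, 1.5, "A")


@pytest.fixture
def two_chains() -> Molecule:
    """Two 3-atom chains, 50 Å apart: bonds {0-1,1-2} and {3-4,4-5}."""
    rows = [
        {"serial": i + 1, "name": "C", "resname": "LIG",
         "chain": "A" if i < 3 else "B", "resseq": 1 if i < 3 else 2,
         "element": "C", "record_kind": "ATOM"}
        for i in range(6)
    ]
    coords = np.array([
        [0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0],
        [50.0, 0, 0], [51.5, 0, 0], [53.0, 0, 0],
    ])
    mol = Molecule(atoms=AtomTable.from_rows(rows), frames=[coords])
    mol.bonds = BondGraph.from_edges(6, [(0, 1), (1, 2), (3, 4), (4, 5)])
    return mol


@pytest.fixture
def footprint_traj() -> Molecule:
    """The canonical 4-frame two-domain trajectory (gaps 2.0/2.5/2.9/5.0)."""
    return make_two_domain_trajectory([2.0, 2.5, 2.9, 5.0])


def simple_molecule(coords, elements=None, **overrides) -> Molecule:
    """Minimal molecule from raw coordinates (helper, not a fixture)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    elements = elements or ["C"] * n
    rows = []
    for i in range(n):
        row = {"serial": i + 1, "name": elements[i], "resname": "LIG",
               "chain": "A", "resseq": 1, "element": elements[i],
               "record_kind": "HETATM"}
        row.update({k: v[i] if isinstance(v, (list, tuple)) else v
                    for k, v in overrides.items()})
        rows.append(row)
    return Molecule(atoms=AtomTable.from_rows(rows), frames=[coords.copy()])
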