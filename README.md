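# molkit

A lightweight, columnar toolkit for 3D molecular structures and trajectories:

- **Data model** — `Molecule`: a column-oriented atom table (serial, name,
  alt-loc, residue, chain, occupancy, B-factor, element, charge, record kind)
  plus one or more coordinate frames (Å) and an optional bond graph. Atom
  identity is the 0-based positional index throughout.
- **File I/O** — fixed-column PDB v3.3 (single- and multi-frame via
  MODEL/ENDMDL), AutoDock PDBQT (partial charges + atom types), and **PYM**,
  a binary columnar container with bit-exact round trips for fast
  high-throughput load/save.
- **Bonds** — distance-based bond perception (covalent-radius sums + tolerance)
  with two interchangeable code paths (all-pairs reference, KD-tree
  accelerated), connected components, branch selection, neighbor expansion.
- **Selections** — property criteria (AND-combined per-column constraints),
  spatial proximity within and across molecules, and set algebra.
- **Manipulation** — translation, rotation about points, atoms, and lines
  (extrinsic XYZ Euler / Rodrigues axis-angle), all rigid.
- **Comparison** — pairwise RMSD, key-based pairing heuristic, Kabsch
  superposition (SVD, reflections excluded), steric clash, minimum distance,
  merge.
- **Footprint analysis** — per-atom inter-domain contact residence fractions
  over a trajectory (default 3.0 Å cutoff), written into PDB occupancy fields
  for downstream surface coloring.
- **Fixtures** — deterministic synthetic molecules and trajectories so every
  test and example runs offline.

## Library quick start

```python
import molkit
from molkit.selections import select_atoms
from molkit.footprint import contact_residence_fractions, annotate_occupancy

mol = molkit.load_pdb("trajectory.pdb")           # MODEL blocks -> frames
sel_a = select_atoms(mol, {"chain": {"A"}})
sel_b = select_atoms(mol, {"chain": {"C"}})
result = contact_residence_fractions(mol, sel_a, sel_b, cutoff=3.0)
molkit.save_pdb(annotate_occupancy(mol, result), "footprint.pdb")
```

## Command line

All functionality is under a single `molkit` entry point
(exit codes: 0 ok, 1 usage error, 2 data/format error):

```sh
molkit info protein.pdb
molkit convert protein.pdb protein.pym          # format sniffed by extension
molkit bonds protein.pdb --tolerance 0.4        # 'i j' pairs, one per line
molkit select protein.pdb --where "chain=A,name=CA" --near-sel 3.0
molkit transform in.pdb out.pdb --translate 1,0,0 \
    --rotate-line 0,0,0:0,0,1:90 --degrees
molkit rmsd a.pdb b.pdb --heuristic --align
molkit clash a.pdb b.pdb --cutoff 2.0
molkit mindist a.pdb b.pdb
molkit merge a.pdb b.pdb merged.pdb
molkit footprint traj.pdb --sel-a "chain=A" --sel-b "chain=B" \
    --cutoff 3.0 --out footprint.pdb
molkit fixtures make-traj --schedule 2.0,2.5,2.9,5.0 --out traj.pdb
```

## The PYM format

Binary, little-endian, columnar: a 15-byte header (`PYM1` magic, version,
atom/frame counts, column-flags bitmask), length-prefixed UTF-8 string
columns, int64/float64 numeric columns, then contiguous float64 coordinate
blocks per frame. Unlike text PDB, coordinates survive round trips bit-exactly.
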