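import numpy as np
import pytest

from molkit.bonds import BondGraph
from molkit.core import molecules_equal
from molkit.errors import (
    EmptyMoleculeError,
    EmptyPairingError,
    MergeShapeError,
    NoCorrespondenceError,
)
from molkit.fixtures import FixtureSpec, make_random_cloud, make_random_molecule
from molkit.manipulation import axis_angle_matrix, rotation_matrix_xyz
from molkit.pairwise import (
    align_other_to_this,
    get_centroid_distance_to_another_molecule,
    get_distance_to_another_molecule,
    kabsch,
    merge,
    pairing_heuristic,
    rmsd,
    steric_clash_with_another_molecule,
)

from conftest import simple_molecule


def apply_rigid(mol, R, t):
    out = mol.copy()
    for fi in range(out.n_frames):
        out.frames[fi] = out.frames[fi] @ R.T + np.asarray(t)
    return out


class TestRmsd:
    def test_identity_is_zero(self):
        mol = make_random_molecule(FixtureSpec(seed=1, n_atoms=10))
        assert rmsd(mol, mol.copy()) == 0.0

    def test_uniform_unit_displacement(self):
        a = simple_molecule([[0, 0, 0], [1, 1, 1], [2, 0, 2]])
        b = a.copy()
        b.frames[0] += np.array([0, 0, 1.0])
        assert rmsd(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_hand_summed_oracle(self):
        rng = np.random.default_rng(33)
        xa = rng.uniform(-5, 5, (3, 3))
        xb = rng.uniform(-5, 5, (3, 3))
        a = simple_molecule(xa)
        b = simple_molecule(xb)
        expected = (sum(
            float(np.dot(xa[k] - xb[k], xa[k] - xb[k])) for k in range(3)
        ) / 3) ** 0.5
        assert rmsd(a, b, [(0, 0), (1, 1), (2, 2)]) == pytest.approx(expected)

    def test_symmetric(self):
        a = make_random_cloud(seed=2, n_atoms=8)
        b = make_random_cloud(seed=3, n_atoms=8)
        pairing = [(i, i) for i in range(8)]
        reversed_pairing = [(j, i) for i, j in pairing]
        assert rmsd(a, b, pairing) == pytest.approx(rmsd(b, a, reversed_pairing))

    def test_empty_pairing(self):
        a = simple_molecule([[0, 0, 0]])
        with pytest.raises(EmptyPairingError):
            rmsd(a, a.copy(), [])


class TestPairingHeuristic:
    def _mol(self, names, resseqs, chains=None, serials=None):
        n = len(names)
        mol = simple_molecule(
            np.arange(3 * n, dtype=float).reshape(n, 3),
            name=list(names), resseq=list(resseqs),
            chain=list(chains) if chains else ["A"] * n,
        )
        if serials is not None:
            mol.atoms.serial[:] = serials
        return mol

    def test_renumbered_copy_pairs_fully(self):
        a = self._mol(["N", "CA", "C"], [1, 1, 1])
        b = self._mol(["N", "CA", "C"], [1, 1, 1], serials=[10, 20, 30])
        pairing = pairing_heuristic(a, b)
        assert pairing == [(0, 0), (1, 1), (2, 2)]
        assert rmsd(a, b, pairing) == 0.0

    def test_missing_residue_dropped(self):
        a = self._mol(["CA", "CA"], [1, 2])
        b = self._mol(["CA"], [1])
        assert pairing_heuristic(a, b) == [(0, 0)]

    def test_duplicate_key_dropped_on_both_sides(self):
        # Key multiset oracle: "CA"/res1 appears twice in a -> multiplicity 2
        # -> excluded even though b has it once.
        a = self._mol(["CA", "CA", "N"], [1, 1, 1])
        b = self._mol(["CA", "N"], [1, 1])
        assert pairing_heuristic(a, b) == [(2, 1)]

    def test_no_correspondence(self):
        a = self._mol(["CA"], [1])
        b = self._mol(["CB"], [2])
        with pytest.raises(NoCorrespondenceError):
            pairing_heuristic(a, b)


class TestAlignment:
    def test_exact_rigid_recovery(self):
        ref = make_random_molecule(FixtureSpec(seed=5, n_atoms=20))
        R = rotation_matrix_xyz(0, 0, np.pi / 2)
        other = apply_rigid(ref, R, (3, 4, 5))
        aligned, final = align_other_to_this(
            ref, other, [(i, i) for i in range(20)]
        )
        assert final < 1e-9
        np.testing.assert_allclose(aligned.frames[0], ref.frames[0], atol=1e-8)

    def test_identity_alignment(self):
        ref = make_random_molecule(FixtureSpec(seed=6, n_atoms=12))
        aligned, final = align_other_to_this(
            ref, ref.copy(), [(i, i) for i in range(12)]
        )
        assert final == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_kabsch_recovery_seeded(self, seed):
        rng = np.random.default_rng(seed)
        ref = make_random_cloud(seed=seed, n_atoms=30)
        R_true = axis_angle_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
        t_true = rng.uniform(-20, 20, 3)
        other = apply_rigid(ref, R_true, t_true)
        pairing = [(i, i) for i in range(30)]
        aligned, final = align_other_to_this(ref, other, pairing)
        assert final < 1e-8
        # the fitted rotation must invert the applied one
        R_fit, _ = kabsch(other.frames[0], ref.frames[0])
        assert np.linalg.norm(R_fit - R_true.T, ord="fro") < 1e-8

    def test_noisy_recovery(self):
        rng = np.random.default_rng(77)
        sigma = 0.1
        ref = make_random_cloud(seed=50, n_atoms=100)
        noisy = ref.copy()
        noisy.frames[0] = noisy.frames[0] + rng.normal(0, sigma, (100, 3))
        R_true = axis_angle_matrix(rng.normal(size=3), 1.0)
        other = apply_rigid(noisy, R_true, (5.0, -3.0, 2.0))
        aligned, final = align_other_to_this(
            ref, other, [(i, i) for i in range(100)]
        )
        expected = sigma * np.sqrt(3)
        assert expected / 2 < final < expected * 2
        R_fit, _ = kabsch(other.frames[0], ref.frames[0])
        assert np.linalg.norm(R_fit - R_true.T, ord="fro") < 1e-1

    def test_moves_all_atoms_not_just_paired(self):
        ref = make_random_cloud(seed=60, n_atoms=10)
        R = rotation_matrix_xyz(0.3, 0.2, 0.1)
        other = apply_rigid(ref, R, (1, 2, 3))
        pairing = [(i, i) for i in range(5)]  # fit on half the atoms
        aligned, final = align_other_to_this(ref, other, pairing)
        np.testing.assert_allclose(aligned.frames[0], ref.frames[0], atol=1e-8)

    def test_alignment_is_rigid_for_other(self):
        ref = make_random_cloud(seed=61, n_atoms=15)
        other = make_random_cloud(seed=62, n_atoms=15)
        before = other.frames[0].copy()
        aligned, _ = align_other_to_this(ref, other,
                                         [(i, i) for i in range(15)])
        def pd(c):
            d = c[:, None, :] - c[None, :, :]
            return np.sqrt((d * d).sum(-1))
        np.testing.assert_allclose(pd(aligned.frames[0]), pd(before), atol=1e-9)
        # never a reflection
        R_fit, _ = kabsch(other.frames[0], ref.frames[0])
        assert np.linalg.det(R_fit) == pytest.approx(1.0, abs=1e-9)


class TestStericClash:
    def test_threshold(self):
        a = simple_molecule([[0, 0, 0]])
        b = simple_molecule([[0, 0, 1.9]])
        has, pairs = steric_clash_with_another_molecule(a, b, cutoff=2.0)
        assert has and pairs == [(0, 0)]

    def test_far_apart(self):
        a = make_random_cloud(seed=7, n_atoms=10, box_size=5.0)
        b = make_random_cloud(seed=8, n_atoms=10, box_size=5.0)
        b.frames[0] += 100.0
        assert steric_clash_with_another_molecule(a, b, 2.0) == (False, [])

    def test_matches_cross_pair_oracle_and_symmetry(self):
        a = make_random_cloud(seed=9, n_atoms=25, box_size=8.0)
        b = make_random_cloud(seed=10, n_atoms=20, box_size=8.0)
        cutoff = 2.0
        expected = sorted(
            (i, j)
            for i in range(25)
            for j in range(20)
            if np.linalg.norm(a.frames[0][i] - b.frames[0][j]) <= cutoff
        )
        has_ab, pairs_ab = steric_clash_with_another_molecule(a, b, cutoff)
        has_ba, pairs_ba = steric_clash_with_another_molecule(b, a, cutoff)
        assert pairs_ab == expected
        assert has_ab == has_ba == bool(expected)
        assert sorted((j, i) for i, j in pairs_ab) == pairs_ba


class TestMinDistance:
    def test_single_pair(self):
        a = simple_molecule([[0, 0, 0]])
        b = simple_molecule([[0, 0, 4]])
        assert get_distance_to_another_molecule(a, b) == pytest.approx(4.0)

    def test_shared_coordinate_is_zero(self):
        a = simple_molecule([[1, 2, 3], [9, 9, 9]])
        b = simple_molecule([[1, 2, 3]])
        assert get_distance_to_another_molecule(a, b) == 0.0

    def test_matches_exhaustive_oracle(self):
        a = make_random_cloud(seed=11, n_atoms=30)
        b = make_random_cloud(seed=12, n_atoms=25)
        expected = min(
            float(np.linalg.norm(a.frames[0][i] - b.frames[0][j]))
            for i in range(30)
            for j in range(25)
        )
        assert get_distance_to_another_molecule(a, b) == pytest.approx(expected)

    def test_min_leq_any_true_clash_cutoff(self):
        a = make_random_cloud(seed=13, n_atoms=20)
        b = make_random_cloud(seed=14, n_atoms=20)
        dmin = get_distance_to_another_molecule(a, b)
        for cutoff in (1.0, 2.0, 5.0, 10.0):
            has, _ = steric_clash_with_another_molecule(a, b, cutoff)
            if has:
                assert dmin <= cutoff

    def test_empty_molecule(self):
        a = simple_molecule(np.empty((0, 3)))
        b = simple_molecule([[0, 0, 0]])
        with pytest.raises(EmptyMoleculeError):
            get_distance_to_another_molecule(a, b)

    def test_centroid_variant(self):
        a = simple_molecule([[0, 0, 0], [2, 0, 0]])
        b = simple_molecule([[11, 0, 0]])
        assert get_centroid_distance_to_another_molecule(a, b) == pytest.approx(10.0)


class TestMerge:
    def test_concatenation(self):
        a = make_random_molecule(FixtureSpec(seed=20, n_atoms=3))
        b = make_random_molecule(FixtureSpec(seed=21, n_atoms=2))
        out = merge(a, b)
        assert out.n_atoms == 5
        assert out.atoms.name[3] == b.atoms.name[0]
        assert int(out.atoms.serial[3]) == int(b.atoms.serial[0])
        np.testing.assert_array_equal(out.frames[0][3], b.frames[0][0])

    def test_merge_with_empty_is_identity(self):
        a = make_random_molecule(FixtureSpec(seed=22, n_atoms=4))
        empty = simple_molecule(np.empty((0, 3)))
        assert molecules_equal(merge(a, empty), a, 0.0)

    def test_bond_offset_reindexing(self):
        a = simple_molecule([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        b = simple_molecule([[10, 0, 0], [11, 0, 0]])
        b.bonds = BondGraph.from_edges(2, [(0, 1)])
        out = merge(a, b)
        assert out.bonds.edges() == [(3, 4)]

    def test_frame_count_mismatch(self):
        a = make_random_molecule(FixtureSpec(seed=23, n_atoms=3, n_frames=2))
        b = make_random_molecule(FixtureSpec(seed=24, n_atoms=3, n_frames=1))
        with pytest.raises(MergeShapeError):
            merge(a, b)
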