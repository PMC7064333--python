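import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pocketgate as pg


def _structure_from_points(points, names=None):
    atoms = []
    for i, p in enumerate(points):
        atoms.append(pg.Atom(i + 1, names[i] if names else "CA", "C", "GLY",
                             i + 1, "A", np.asarray(p, float)))
    return pg.Structure(atoms)


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
    return rot, rng.normal(0, 5, 3)


class TestAlignSequences:
    def test_identical_sequences(self):
        r = pg.align_sequences("ACDEF", "ACDEF")
        assert r.percent_identity == 100.0

    def test_four_of_five_columns(self):
        r = pg.align_sequences("ACDEF", "ACDEG")
        assert r.percent_identity == pytest.approx(80.0)

    def test_identity_symmetric(self):
        a, b = "ACDEFGHIKLMNPQRS", "ACDEFGWIKLMNPQRT"
        assert pg.align_sequences(a, b).percent_identity == \
               pytest.approx(pg.align_sequences(b, a).percent_identity)

    def test_rejects_nonstandard(self):
        with pytest.raises(ValueError):
            pg.align_sequences("ACDX", "ACDE")

    def test_pairs_strictly_increasing(self):
        r = pg.align_sequences("ACDEFGHIK", "ACDGHIK")
        ai = [p[0] for p in r.aligned_pairs]
        bi = [p[1] for p in r.aligned_pairs]
        assert ai == sorted(ai) and bi == sorted(bi)
        assert len(set(ai)) == len(ai) and len(set(bi)) == len(bi)


def brute_force_rmsd(ref, mov, n_steps=24):
    """Scan rotations from a quaternion grid (plus optimal translation)."""
    best = np.inf
    # coarse random quaternion sweep refined around the best hit
    rng = np.random.default_rng(0)
    quats = rng.normal(size=(n_steps ** 2, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    for _ in range(4):
        best_q = None
        for q in quats:
            r = Rotation.from_quat(q).as_matrix()
            val = np.sqrt(np.mean(np.sum((mov_c @ r.T - ref_c) ** 2, axis=1)))
            if val < best:
                best, best_q = val, q
        if best_q is None:
            break
        quats = best_q + rng.normal(scale=0.05, size=(n_steps ** 2, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    return best


class TestSuperpose:
    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 3, (10, 3))
        rot, t = _random_rigid(2)
        a = _structure_from_points(pts)
        b = _structure_from_points(pts @ rot.T + t)
        res = pg.superpose(a, b, [(i, i) for i in range(10)])
        assert res.rmsd < 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 2, (4, 3))
        mov = rng.normal(0, 2, (4, 3))
        a = _structure_from_points(ref)
        b = _structure_from_points(mov)
        res = pg.superpose(a, b, [(i, i) for i in range(4)])
        oracle = brute_force_rmsd(ref, mov)
        assert res.rmsd <= oracle + 1e-6
        assert res.rmsd == pytest.approx(oracle, rel=1e-3)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(4)
        pa = rng.normal(0, 2, (6, 3))
        pb = rng.normal(0, 2, (6, 3))
        a = _structure_from_points(pa)
        b = _structure_from_points(pb)
        pairs = [(i, i) for i in range(6)]
        assert pg.superpose(a, b, pairs).rmsd == \
               pytest.approx(pg.superpose(b, a, pairs).rmsd, abs=1e-9)

    def test_self_superposition_identity(self):
        rng = np.random.default_rng(5)
        a = _structure_from_points(rng.normal(0, 2, (5, 3)))
        res = pg.superpose(a, a, [(i, i) for i in range(5)])
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_degenerate_pairs_rejected(self):
        line = _structure_from_points([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            pg.superpose(line, line, [(i, i) for i in range(3)])
        with pytest.raises(ValueError, match="3"):
            pg.superpose(line, line, [(0, 0), (1, 1)])


def _displacement_fixture(shift):
    """Two copies of a rigid core with one probe residue moved by shift."""
    rng = np.random.default_rng(7)
    core = rng.normal(0, 4, (8, 3))
    probe = np.array([1.0, 1.0, 1.0])
    atoms_a, atoms_b = [], []
    for i, p in enumerate(core):
        atoms_a.append(pg.Atom(i + 1, "CA", "C", "GLY", i + 1, "A", p))
        atoms_b.append(pg.Atom(i + 1, "CA", "C", "GLY", i + 1, "A", p.copy()))
    atoms_a.append(pg.Atom(9, "CA", "C", "SER", 9, "A", probe))
    atoms_a.append(pg.Atom(10, "OG", "O", "SER", 9, "A", probe + [0.5, 0, 0]))
    atoms_b.append(pg.Atom(9, "CA", "C", "SER", 9, "A", probe + shift))
    atoms_b.append(pg.Atom(10, "OG", "O", "SER", 9, "A", probe + shift + [0.5, 0, 0]))
    return pg.Structure(atoms_a), pg.Structure(atoms_b)


class TestResidueDisplacement:
    def test_identical_structures_zero(self):
        a, _ = _displacement_fixture(np.zeros(3))
        pairs = [(i, i) for i in range(8)]
        assert pg.residue_displacement(a, a, pairs, ("A", 9)) == pytest.approx(0.0, abs=1e-9)

    def test_pythagorean_translation(self):
        a, b = _displacement_fixture(np.array([3.0, 4.0, 0.0]))
        pairs = [(i, i) for i in range(8)]
        assert pg.residue_displacement(a, b, pairs, ("A", 9)) == \
               pytest.approx(5.0, abs=1e-9)

    def test_invariant_to_rigid_premotion(self):
        a, b = _displacement_fixture(np.array([3.0, 4.0, 0.0]))
        rot, t = _random_rigid(8)
        b_moved = b.with_coords(b.coords @ rot.T + t)
        pairs = [(i, i) for i in range(8)]
        assert pg.residue_displacement(a, b_moved, pairs, ("A", 9)) == \
               pytest.approx(5.0, abs=1e-6)

    def test_ca_rule_for_gly_ala(self):
        a, b = _displacement_fixture(np.array([0.0, 0.0, 2.0]))
        pairs = [(i, i) for i in range(8)]
        d = pg.residue_displacement(a, b, pairs, ("A", 9), rule="ca")
        assert d == pytest.approx(2.0, abs=1e-9)

    def test_missing_probe_rejected(self):
        a, b = _displacement_fixture(np.zeros(3))
        pairs = [(i, i) for i in range(8)]
        with pytest.raises(KeyError):
            pg.residue_displacement(a, b, pairs, ("A", 99))


def test_ca_rmsd_by_alignment_on_mutated_copy():
    """Alignment-based pairing reproduces the known RMSD of a perturbed copy."""
    rng = np.random.default_rng(9)
    n = 20
    coords = rng.normal(0, 5, (n, 3))
    seq = "ACDEFGHIKLMNPQRSTVWY"
    three = {v: k for k, v in pg.io.THREE_TO_ONE.items() if len(k) == 3}
    atoms_a = [pg.Atom(i + 1, "CA", "C", three[seq[i]], i + 1, "A", coords[i])
               for i in range(n)]
    rot, t = _random_rigid(10)
    atoms_b = [pg.Atom(i + 1, "CA", "C", three[seq[i]], i + 1, "A",
                       coords[i] @ rot.T + t) for i in range(n)]
    a = pg.Structure(atoms_a)
    b = pg.Structure(atoms_b)
    assert pg.ca_rmsd(a, b) < 1e-6
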