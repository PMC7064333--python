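import numpy as np
import pytest
import scipy.integrate as si
from scipy.stats import vonmises

import pocketgate as pg
from pocketgate.divergence import TORSION_KINDS


class TestDihedral:
    def test_quarter_turn_sign_convention(self):
        assert pg.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)) == \
               pytest.approx(-90.0)

    def test_cis_is_zero(self):
        assert pg.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == \
               pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        assert abs(pg.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0))) == \
               pytest.approx(180.0)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 2, (6, 4, 3))
        vec = pg.dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        for k in range(6):
            assert vec[k] == pytest.approx(
                pg.dihedral(*pts[k]), abs=1e-9)


def binned_vonmises_kl(mu_p, mu_q, kappa, n_bins=30):
    """Quadrature oracle: KL of two von Mises laws after binning."""
    edges = np.radians(np.linspace(-180, 180, n_bins + 1))
    p = np.array([si.quad(lambda x: vonmises.pdf(x, kappa, loc=mu_p), lo, hi)[0]
                  for lo, hi in zip(edges[:-1], edges[1:])])
    q = np.array([si.quad(lambda x: vonmises.pdf(x, kappa, loc=mu_q), lo, hi)[0]
                  for lo, hi in zip(edges[:-1], edges[1:])])
    return float(np.sum(p * np.log(p / q)))


class TestKLDivergence:
    def test_self_divergence_below_pseudocount_floor(self):
        rng = np.random.default_rng(1)
        a = np.degrees(rng.vonmises(0, 4, 5000))
        assert pg.kl_divergence(a, a) <= 2e-3

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = np.degrees(rng.vonmises(rng.uniform(-np.pi, np.pi), 2, 500))
            b = np.degrees(rng.vonmises(rng.uniform(-np.pi, np.pi), 2, 500))
            assert pg.kl_divergence(a, b) >= 0.0

    def test_von_mises_pair_matches_quadrature(self):
        rng = np.random.default_rng(3)
        a = np.degrees(rng.vonmises(0.0, 4.0, 100_000))
        b = np.degrees(rng.vonmises(np.radians(60.0), 4.0, 100_000))
        est = pg.kl_divergence(a, b, n_bins=30)
        oracle = binned_vonmises_kl(0.0, np.radians(60.0), 4.0)
        assert est == pytest.approx(oracle, rel=0.05)

    def test_uniform_vs_point_mass(self):
        rng = np.random.default_rng(4)
        n_bins = 30
        uniform = rng.uniform(-180, 180, 10_000)
        point = np.full(10_000, 6.0)  # all mass in one bin
        d = pg.kl_divergence(point, uniform, n_bins=n_bins)
        assert d == pytest.approx(np.log(n_bins), rel=0.10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pg.kl_divergence(np.array([]), np.array([1.0]))


def _quad_structure():
    """Four-residue chain with full backbone for torsion extraction."""
    rng = np.random.default_rng(5)
    atoms = []
    serial = 0
    for seq in range(1, 5):
        base = np.array([3.8 * seq, 0.1 * seq ** 2, 0.0])
        for name, el, off in (("N", "N", [-1.2, 0.3, 0.1]),
                              ("CA", "C", [0, 0, 0]),
                              ("C", "C", [1.0, 1.0, 0.2]),
                              ("O", "O", [1.9, 1.0, 0.9]),
                              ("CB", "C", [0.4, -1.3, 0.8]),
                              ("OG", "O", [0.9, -2.2, 1.5])):
            serial += 1
            atoms.append(pg.Atom(serial, name, el, "SER", seq, "A",
                                 base + np.array(off)))
    return pg.Structure(atoms)


class TestExtractDihedrals:
    def test_terminal_and_interior_torsions(self):
        st = _quad_structure()
        traj = pg.Trajectory(st, np.repeat(st.coords[None], 8, axis=0))
        ens = pg.extract_dihedrals(traj, frames_per_block=4, n_blocks=2)
        assert ens.n_blocks == 2
        # first residue has no phi, last has no psi; all have chi1
        assert "phi" not in ens.angles[("A", 1)]
        assert "psi" not in ens.angles[("A", 4)]
        for key in ens.residues:
            assert "chi1" in ens.angles[key]

    def test_matches_direct_formula(self):
        st = _quad_structure()
        traj = pg.Trajectory(st, np.repeat(st.coords[None], 4, axis=0))
        ens = pg.extract_dihedrals(traj, frames_per_block=2, n_blocks=2)
        n = st.atom("A", 2, "N").position
        ca = st.atom("A", 2, "CA").position
        cb = st.atom("A", 2, "CB").position
        og = st.atom("A", 2, "OG").position
        expected = pg.dihedral(n, ca, cb, og)
        assert ens.angles[("A", 2)]["chi1"][0, 0] == pytest.approx(expected)

    def test_missing_backbone_residue_skipped(self):
        st = _quad_structure()
        atoms = [a for a in st.atoms if not (a.residue_seq == 3 and a.name == "CA")]
        st2 = pg.Structure(atoms)
        traj = pg.Trajectory(st2, np.repeat(st2.coords[None], 4, axis=0))
        ens = pg.extract_dihedrals(traj, frames_per_block=2, n_blocks=2)
        assert ("A", 3) not in ens.angles


class TestKLProfile:
    def test_exchangeable_ensembles_flag_nothing(self):
        p = pg.TorsionModelParams(n_residues=10, frames_per_block=800,
                                  n_blocks=4, seed=6)
        a, b, truth = pg.generate_torsion_ensembles(p)
        assert truth == set()
        prof = pg.kl_profile(a, b, n_bootstrap=100, seed=7)
        assert int(prof.significant.sum()) == 0

    def test_shifted_residues_detected(self):
        p = pg.TorsionModelParams(n_residues=12, shifted_residues=[5, 6, 7, 8],
                                  shift_deg=60.0, frames_per_block=2000,
                                  n_blocks=4, seed=8,
                                  components=[(-60.0, 8.0, 1.0)])
        a, b, truth = pg.generate_torsion_ensembles(p)
        prof = pg.kl_profile(a, b, n_bootstrap=100, seed=9)
        flagged = {i for i, s in enumerate(prof.significant) if s}
        assert flagged == truth
        # shifted residues dominate the ranking
        order = np.argsort(prof.kl)[::-1]
        assert set(order[:4]) == truth

    def test_block_order_invariance(self):
        p = pg.TorsionModelParams(n_residues=6, shifted_residues=[2],
                                  frames_per_block=500, n_blocks=4, seed=10)
        a, b, _ = pg.generate_torsion_ensembles(p)
        prof1 = pg.kl_profile(a, b, n_bootstrap=20, seed=11)
        for key in a.angles:
            for kind in a.angles[key]:
                a.angles[key][kind] = a.angles[key][kind][::-1].copy()
        prof2 = pg.kl_profile(a, b, n_bootstrap=20, seed=11)
        np.testing.assert_allclose(prof1.kl, prof2.kl)

    def test_seeded_reproducibility(self):
        p = pg.TorsionModelParams(n_residues=6, frames_per_block=400,
                                  n_blocks=4, seed=12)
        a, b, _ = pg.generate_torsion_ensembles(p)
        prof1 = pg.kl_profile(a, b, n_bootstrap=30, seed=13)
        prof2 = pg.kl_profile(a, b, n_bootstrap=30, seed=13)
        np.testing.assert_array_equal(prof1.bootstrap_null, prof2.bootstrap_null)
        np.testing.assert_array_equal(prof1.significant, prof2.significant)

    def test_requires_two_blocks(self):
        p = pg.TorsionModelParams(n_residues=4, frames_per_block=300,
                                  n_blocks=1, seed=14)
        a, b, _ = pg.generate_torsion_ensembles(p)
        with pytest.raises(ValueError):
            pg.kl_profile(a, b, n_bootstrap=10, seed=15)
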