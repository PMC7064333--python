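import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pocketgate as pg
from pocketgate.elements import vdw_radius

from conftest import gate_pocket_spec

SPHERE_V = 4.0 / 3.0 * np.pi * 5.0 ** 3  # 523.6 A^3


def test_empty_sphere_matches_analytic_volume():
    spec = pg.PocketSpec([(np.zeros(3), 5.0)], grid_spacing=0.5)
    v = pg.pocket_volume(None, spec)
    assert v == pytest.approx(SPHERE_V, rel=0.05)


def test_grid_refinement_converges():
    errors = []
    for spacing in (2.0, 1.0, 0.5):
        spec = pg.PocketSpec([(np.zeros(3), 5.0)], grid_spacing=spacing)
        errors.append(abs(pg.pocket_volume(None, spec) - SPHERE_V) / SPHERE_V)
    assert errors[2] < 0.05
    assert errors[2] <= errors[0]


def test_single_atom_occlusion_analytic_difference():
    spec = pg.PocketSpec([(np.zeros(3), 5.0)], grid_spacing=0.5,
                         exclusion_padding=1.09)
    atom = pg.Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3))
    st = pg.Structure([atom])
    removed = pg.pocket_volume(None, spec) - pg.pocket_volume(st, spec)
    r_excl = vdw_radius("C") + 1.09
    analytic = 4.0 / 3.0 * np.pi * r_excl ** 3
    assert removed == pytest.approx(analytic, rel=0.05)


def test_translation_invariance_exact():
    rng = np.random.default_rng(0)
    atoms = [pg.Atom(i + 1, "CA", "C", "ALA", i + 1, "A", rng.normal(0, 3, 3))
             for i in range(10)]
    st = pg.Structure(atoms)
    spec = pg.PocketSpec([(np.zeros(3), 6.0)], grid_spacing=1.0)
    v0 = pg.pocket_volume(st, spec)
    shift = np.array([13.7, -4.2, 8.9])
    moved = st.with_coords(st.coords + shift)
    spec_m = spec.shifted(np.eye(3), shift)
    assert pg.pocket_volume(moved, spec_m) == v0


def test_rotation_invariance_within_grid_error():
    rng = np.random.default_rng(1)
    atoms = [pg.Atom(i + 1, "CA", "C", "ALA", i + 1, "A", rng.normal(0, 3, 3))
             for i in range(10)]
    st = pg.Structure(atoms)
    spec = pg.PocketSpec([(np.zeros(3), 6.0)], grid_spacing=0.5)
    v0 = pg.pocket_volume(st, spec)
    rot = Rotation.random(random_state=5).as_matrix()
    moved = st.with_coords(st.coords @ rot.T)
    assert pg.pocket_volume(moved, spec.shifted(rot, np.zeros(3))) == \
           pytest.approx(v0, rel=0.03)


def test_closed_pocket_seed_returns_zero():
    # a carbon sitting on the seed excludes it: closed pocket
    st = pg.Structure([pg.Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3))])
    spec = pg.PocketSpec([(np.zeros(3), 2.0)], grid_spacing=0.5,
                         contiguity_seed=np.zeros(3))
    assert pg.pocket_volume(st, spec) == 0.0


class TestComDistance:
    def test_single_atom_residues(self):
        atoms = [pg.Atom(1, "CA", "C", "GLY", 1, "A", np.zeros(3)),
                 pg.Atom(2, "CA", "C", "GLY", 2, "A", np.array([7.0, 0, 0]))]
        st = pg.Structure(atoms)
        assert pg.com_distance(st, ("A", 1), ("A", 2)) == pytest.approx(7.0)

    def test_mass_weighting(self):
        atoms = [pg.Atom(1, "C1", "C", "LIG", 1, "A", np.zeros(3)),
                 pg.Atom(2, "C2", "C", "LIG", 1, "A", np.array([0, 0, 2.0])),
                 pg.Atom(3, "CA", "C", "GLY", 2, "A", np.zeros(3))]
        st = pg.Structure(atoms)
        assert pg.com_distance(st, ("A", 1), ("A", 2)) == pytest.approx(1.0)

    def test_unresolved_residue(self):
        st = pg.Structure([pg.Atom(1, "CA", "C", "GLY", 1, "A", np.zeros(3))])
        with pytest.raises(KeyError):
            pg.com_distance(st, ("A", 1), ("A", 9))


class TestVolumeDistanceSeries:
    def test_frozen_trajectory_constant(self, gate_pair):
        (params, traj, _), _ = gate_pair
        frozen = pg.Trajectory(traj.topology,
                               np.repeat(traj.frames[:1], 12, axis=0))
        series = pg.volume_distance_series(frozen, gate_pocket_spec(params),
                                           *params.distance_pair)
        assert np.ptp(series.volume) == 0.0
        assert np.ptp(series.distance) == pytest.approx(0.0, abs=1e-9)

    def test_gate_couples_volume_and_distance(self, gate_pair):
        (params, traj, truth), _ = gate_pair
        series = pg.volume_distance_series(traj, gate_pocket_spec(params),
                                           *params.distance_pair)
        r = np.corrcoef(series.volume, series.distance)[0, 1]
        assert r > 0.5
        open_m = (truth.state == "open").to_numpy()
        assert series.distance[open_m].mean() > series.distance[~open_m].mean()
        assert series.volume[open_m].mean() > series.volume[~open_m].mean()

    def test_requested_length(self, gate_pair):
        (params, traj, _), _ = gate_pair
        series = pg.volume_distance_series(traj, gate_pocket_spec(params),
                                           *params.distance_pair, n_frames=51)
        assert len(series.volume) == 51


def exhaustive_ranksum_p(a, b):
    """Two-sided p by enumerating all label assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    w_obs = ranks[: len(a)].sum()
    mu = len(a) * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), len(a)):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_samples_p_one(self):
        r = pg.ranksum_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0

    def test_extreme_separation_exact(self):
        r = pg.ranksum_test([1, 2, 3], [10, 11, 12])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 4)
            r = pg.ranksum_test(a, b)
            assert r.p_value == pytest.approx(exhaustive_ranksum_p(a, b), abs=1e-9)

    def test_normal_approx_close_to_enumeration(self):
        """At n=8 per group the asymptotic branch (with continuity
        correction) tracks the exhaustive-permutation p within 0.02."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.8, 1, 8)
            r = pg.ranksum_test(a, b)
            assert r.method == "asymptotic"
            assert abs(r.p_value - exhaustive_ranksum_p(a, b)) < 0.02

    def test_tied_samples_use_asymptotic_branch(self):
        r = pg.ranksum_test([1.0, 1.0, 2.0, 3.0], [2.5, 3.5, 4.0, 4.0])
        assert r.method == "asymptotic"
        assert 0.0 < r.p_value < 1.0

    def test_open_vs_closed_volumes_reject(self, gate_pair):
        (po, to, _), (pc, tc, _) = gate_pair
        so = pg.volume_distance_series(to, gate_pocket_spec(po),
                                       *po.distance_pair)
        sc = pg.volume_distance_series(tc, gate_pocket_spec(pc),
                                       *pc.distance_pair)
        r = pg.ranksum_test(so.volume, sc.volume)
        assert r.p_value < 0.001
        assert r.n_a == r.n_b == 251

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            pg.ranksum_test([1.0], [2.0, 3.0])
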