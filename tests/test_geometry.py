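import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from hexchan import (
    Trajectory,
    axis_angle,
    center_of_mass,
    fit_axis,
    kabsch_superpose,
    pair_distance_series,
    rmsd_series,
    rmsf_per_residue,
)
from hexchan.exceptions import SelectionError
from hexchan.structure_io import Topology
from hexchan.synthetic import ideal_helix


def _toy_trajectory(coords: np.ndarray) -> Trajectory:
    """Trajectory of anonymous carbon atoms from a (F, N, 3) array."""
    n = coords.shape[1]
    top = Topology(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n, dtype=object),
        residue_name=np.array(["ALA"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        residue_number=np.arange(1, n + 1),
        element=np.array(["C"] * n, dtype=object),
        mass=np.full(n, 12.011),
        het=np.zeros(n, dtype=bool),
    )
    return Trajectory(top, coords)


def _kabsch_oracle(mobile, reference):
    """Independent classic Kabsch: SVD of the cross-covariance matrix with
    determinant correction; returns the minimal proper-rotation RMSD."""
    mob = mobile - mobile.mean(0)
    ref = reference - reference.mean(0)
    u, _, vt = np.linalg.svd(mob.T @ ref)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    diff = ref - mob @ rot.T
    return float(np.sqrt((diff**2).sum() / len(mob)))


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        com = center_of_mass(np.array([[0.0, 0, 0], [0, 0, 2.0]]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(com, [0, 0, 1.0])

    def test_weighted_mean(self):
        # mass 12 at x=0, mass 16 at x=1 -> x = 16/28
        com = center_of_mass(np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.array([12.0, 16.0]))
        np.testing.assert_allclose(com[0], 16.0 / 28.0)

    def test_single_atom_identity(self):
        p = np.array([[1.5, -2.0, 3.0]])
        np.testing.assert_allclose(center_of_mass(p, np.array([14.0])), p[0])

    def test_empty_rejected(self):
        with pytest.raises(SelectionError):
            center_of_mass(np.empty((0, 3)), np.empty(0))


class TestKabsch:
    def test_identity_superposition(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd <= 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True)
        mob = rot.apply(ref) + np.array([5.0, 5.0, 5.0])
        res = kabsch_superpose(mob, ref)
        assert res.rmsd <= 1e-9
        np.testing.assert_allclose(res.apply(mob), ref, atol=1e-9)

    def test_mirror_image_cannot_reach_zero(self):
        """Reflections are forbidden: the best proper rotation for a chiral
        point set's mirror image has RMSD > 0, matching a rotation-grid scan."""
        pts = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [0, 2.0, 0], [1.0, 1.0, 4.0]]
        )
        mirror = pts * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(mirror, pts)
        assert np.isclose(np.linalg.det(res.rotation), 1.0)
        assert res.rmsd > 0.1
        # grid oracle: exhaustive proper rotations at 9 degree resolution
        best = np.inf
        ref_c = pts - pts.mean(0)
        mob_c = mirror - mirror.mean(0)
        for a in np.arange(0, 360, 9):
            for b in np.arange(0, 180, 9):
                for c in np.arange(0, 360, 9):
                    R = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_matrix()
                    diff = ref_c - mob_c @ R.T
                    best = min(best, np.sqrt((diff**2).sum() / len(pts)))
        assert res.rmsd <= best + 1e-9  # kabsch is optimal
        assert best - res.rmsd < 0.25  # and the coarse grid approaches it

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3))
        mob = ref + rng.normal(scale=0.3, size=(10, 3))
        res = kabsch_superpose(mob, ref)
        assert np.isclose(res.rmsd, _kabsch_oracle(mob, ref), atol=1e-9)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        frame = np.random.default_rng(3).normal(size=(5, 3))
        traj = _toy_trajectory(np.repeat(frame[None], 4, axis=0))
        np.testing.assert_allclose(rmsd_series(traj, np.arange(5)), 0.0, atol=1e-12)

    def test_rigid_rotation_removed(self):
        rng = np.random.default_rng(4)
        frame = rng.normal(size=(6, 3))
        frames = [
            Rotation.from_euler("z", k, degrees=True).apply(frame) for k in range(5)
        ]
        traj = _toy_trajectory(np.stack(frames))
        np.testing.assert_allclose(rmsd_series(traj, np.arange(6)), 0.0, atol=1e-9)

    def test_two_frame_value_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        f0 = rng.normal(size=(8, 3))
        f1 = f0 + rng.normal(scale=0.5, size=(8, 3))
        traj = _toy_trajectory(np.stack([f0, f1]))
        vals = rmsd_series(traj, np.arange(8))
        assert vals[0] <= 1e-12  # reference frame
        assert np.isclose(vals[1], _kabsch_oracle(f1, f0), atol=1e-9)

    def test_reference_out_of_range(self):
        traj = _toy_trajectory(np.zeros((2, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(IndexError):
            rmsd_series(traj, np.arange(4), reference_frame_index=5)


class TestRmsf:
    def test_static_trajectory_zero(self):
        frame = np.random.default_rng(6).normal(size=(7, 3))
        traj = _toy_trajectory(np.repeat(frame[None], 5, axis=0))
        np.testing.assert_allclose(rmsf_per_residue(traj, np.arange(7)), 0.0, atol=1e-12)

    def test_isotropic_jitter_gives_sigma_sqrt3(self):
        """Per-coordinate Gaussian jitter of s.d. sigma on a rigid structure
        yields RMSF -> sigma * sqrt(3) (E|dr|^2 = 3 sigma^2), up to the small
        deflation from fitting 6 rigid-body degrees of freedom."""
        rng = np.random.default_rng(7)
        sigma = 0.2
        base = ideal_helix(40)
        coords = base[None] + rng.normal(scale=sigma, size=(800, 40, 3))
        traj = _toy_trajectory(coords)
        rmsf = rmsf_per_residue(traj, np.arange(40))
        expected = sigma * np.sqrt(3.0)
        assert abs(rmsf.mean() - expected) / expected < 0.05

    def test_localized_jitter_stays_localized(self):
        rng = np.random.default_rng(8)
        base = ideal_helix(30)
        coords = np.repeat(base[None], 400, axis=0)
        coords[:, 15, :] += rng.normal(scale=0.5, size=(400, 3))
        traj = _toy_trajectory(coords)
        rmsf = rmsf_per_residue(traj, np.arange(30))
        assert rmsf[15] > 0.5
        others = np.delete(rmsf, 15)
        # alignment leakage bound: fitting 6 DOF over 30 atoms spreads at most
        # a ~ sqrt(6/(3*30)) fraction of the displacement onto other residues
        assert others.max() < 0.5 * np.sqrt(6.0 / 90.0) * 3

    def test_single_frame_rejected(self):
        traj = _toy_trajectory(np.zeros((1, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(ValueError):
            rmsf_per_residue(traj, np.arange(4))


class TestFitAxis:
    def test_collinear_points(self):
        fit = fit_axis(np.array([[0.0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]]))
        np.testing.assert_allclose(fit.direction, [0, 0, 1], atol=1e-12)
        assert fit.residual_rms < 1e-12

    def test_ideal_helix_axis_within_one_degree(self):
        # the TLS axis of a finite helix deviates from the nominal axis by an
        # amount that shrinks with length; a 28-residue TM-scale helix is
        # within 1 degree
        pts = ideal_helix(28)  # rise 1.5, 100 deg/res, radius 2.3
        fit = fit_axis(pts)
        angle = np.degrees(np.arccos(abs(fit.direction @ np.array([0, 0, 1.0]))))
        assert angle < 1.0
        assert fit.direction[2] > 0  # oriented N -> C

    def test_rotation_equivariance(self):
        pts = ideal_helix(28)
        rot = Rotation.from_euler("x", 30, degrees=True)
        d0 = fit_axis(pts).direction
        d1 = fit_axis(rot.apply(pts)).direction
        angle = np.degrees(np.arccos(np.clip(d1 @ rot.apply(d0), -1, 1)))
        assert angle < 1e-6

    def test_direction_flips_with_input_order(self):
        pts = ideal_helix(15)
        d_fwd = fit_axis(pts).direction
        d_rev = fit_axis(pts[::-1]).direction
        np.testing.assert_allclose(d_rev, -d_fwd, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_axis(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            fit_axis(np.array([[0.0, 0, 0], [1.0, 0, 0]]))


class TestAxisAngle:
    @pytest.mark.parametrize(
        "da,db,expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((0, 0, 1), (0, 1, 0), 90.0),
            ((0, 0, 1), (0, 0, -1), 180.0),
            ((0, 0, 1), (0, np.sin(np.radians(10)), np.cos(np.radians(10))), 10.0),
        ],
    )
    def test_angles(self, da, db, expected):
        a = fit_axis(np.outer([0, 1.0, 2.0], da))
        b = fit_axis(np.outer([0, 1.0, 2.0], db))
        assert np.isclose(axis_angle(a, b), expected, atol=1e-9)


class TestPairDistanceSeries:
    def test_three_four_five(self):
        coords = np.repeat(
            np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]]), 5, axis=0
        )
        traj = _toy_trajectory(coords)
        series = pair_distance_series(traj, [0], [1], mode="single")
        np.testing.assert_allclose(series.values, 5.0)

    def test_coincident_selections_zero(self):
        coords = np.zeros((3, 2, 3))
        traj = _toy_trajectory(coords)
        series = pair_distance_series(traj, [0, 1], [0, 1])
        np.testing.assert_allclose(series.values, 0.0)

    def test_empty_selection_rejected(self):
        traj = _toy_trajectory(np.zeros((2, 3, 3)) + np.arange(3)[None, :, None])
        with pytest.raises(SelectionError):
            pair_distance_series(traj, [], [0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    angles=st.tuples(*[st.floats(-180, 180) for _ in range(3)]),
    shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
)
def test_rigid_motion_invariance_and_equivariance(angles, shift):
    """Distances, angles and RMSD are invariant under a global rigid motion of
    every frame; fitted axes are equivariant."""
    rng = np.random.default_rng(9)
    coords = rng.normal(size=(3, 10, 3)) * 3.0
    rot = Rotation.from_euler("xyz", angles, degrees=True)
    moved = np.stack([rot.apply(f) + np.asarray(shift) for f in coords])
    t0, t1 = _toy_trajectory(coords), _toy_trajectory(moved)

    d0 = pair_distance_series(t0, [0, 1], [2, 3]).values
    d1 = pair_distance_series(t1, [0, 1], [2, 3]).values
    np.testing.assert_allclose(d0, d1, atol=1e-8)

    r0 = rmsd_series(t0, np.arange(10))
    r1 = rmsd_series(t1, np.arange(10))
    np.testing.assert_allclose(r0, r1, atol=1e-8)

    a0 = fit_axis(coords[0])
    a1 = fit_axis(moved[0])
    np.testing.assert_allclose(a1.direction, rot.apply(a0.direction), atol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_superposed_rmsd_never_exceeds_raw_rmsd(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(6, 3)) * 2
    b = rng.normal(size=(6, 3)) * 2
    res = kabsch_superpose(a, b)
    assert np.isclose(np.linalg.det(res.rotation), 1.0, atol=1e-9)
    raw = np.sqrt(((a - b) ** 2).sum() / len(a))
    assert res.rmsd <= raw + 1e-9
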