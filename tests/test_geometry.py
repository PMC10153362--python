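"""Kinematics: NeRF, frames, relative transforms, Kabsch, C2 operations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from specpair.geometry import (
    Frame,
    InternalCoordinate,
    RigidTransform,
    bond_angle,
    c2_apply,
    cartesian_to_internal,
    chain_from_internal,
    dihedral,
    frame_from_residue,
    kabsch,
    nerf_place,
    rotation_about_axis,
    transform_between,
)
from conftest import random_rotation


class TestNerf:
    def test_placed_atom_satisfies_internal_coordinates(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3)) * 3
            if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
                continue
            ic = InternalCoordinate(
                bond_length=float(rng.uniform(1.0, 2.0)),
                bond_angle=float(rng.uniform(30, 150)),
                dihedral=float(rng.uniform(-180, 180)),
            )
            d = nerf_place(a, b, c, ic)
            assert np.linalg.norm(d - c) == pytest.approx(ic.bond_length, abs=1e-9)
            assert bond_angle(b, c, d) == pytest.approx(ic.bond_angle, abs=1e-6)
            assert dihedral(a, b, c, d) == pytest.approx(ic.dihedral, abs=1e-6)

    def test_dihedral_sign_symmetry_and_planarity(self):
        a, b, c = np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.5, 0, 0])
        # +phi and -phi placements are mirror images across the a-b-c plane
        d_plus = nerf_place(a, b, c, InternalCoordinate(1.5, 109.5, 60.0))
        d_minus = nerf_place(a, b, c, InternalCoordinate(1.5, 109.5, -60.0))
        assert d_plus[:2] == pytest.approx(d_minus[:2], abs=1e-9)
        assert d_plus[2] == pytest.approx(-d_minus[2], abs=1e-9)
        # 0 (cis) and 180 (trans) placements are coplanar with a, b, c
        d0 = nerf_place(a, b, c, InternalCoordinate(1.5, 109.5, 0.0))
        d180 = nerf_place(a, b, c, InternalCoordinate(1.5, 109.5, 180.0))
        assert d0[2] == pytest.approx(0.0, abs=1e-9)
        assert d180[2] == pytest.approx(0.0, abs=1e-9)
        assert d0[1] == pytest.approx(-d180[1], abs=1e-9)

    def test_collinear_references_rejected(self):
        with pytest.raises(ValueError):
            nerf_place([0, 0, 0], [1, 0, 0], [2, 0, 0], InternalCoordinate(1.5, 100, 0))

    def test_round_trip_random_chains(self, rng):
        """internal -> cartesian -> internal reproduces a 10-atom chain to 1e-6."""
        for _ in range(10):
            coords = [np.zeros(3), np.array([1.5, 0, 0]), np.array([2.3, 1.2, 0])]
            for _ in range(7):
                ic = InternalCoordinate(
                    float(rng.uniform(1.2, 1.8)),
                    float(rng.uniform(60, 150)),
                    float(rng.uniform(-180, 180)),
                )
                coords.append(nerf_place(coords[-3], coords[-2], coords[-1], ic))
            coords = np.array(coords)
            ics = cartesian_to_internal(coords)
            rebuilt = chain_from_internal(coords[:3], ics)
            assert np.max(np.abs(rebuilt - coords)) < 1e-6

    def test_square_corner_dihedral_sign(self):
        # right-hand rule: looking down b->c, +90 puts d counterclockwise
        a = np.array([1.0, 0, 0])
        b = np.array([0.0, 0, 0])
        c = np.array([0.0, 1.0, 0])
        d_up = np.array([0.0, 1.0, 1.0])
        assert dihedral(a, b, c, d_up) == pytest.approx(-90.0, abs=1e-9)
        assert dihedral(a, b, c, [0.0, 1.0, -1.0]) == pytest.approx(90.0, abs=1e-9)

    def test_trans_zigzag_dihedrals_are_180(self):
        zig = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0], [4, 0, 0]], float)
        for ic in cartesian_to_internal(zig):
            assert abs(ic.dihedral) == pytest.approx(180.0, abs=1e-9)


class TestFramesAndTransforms:
    def _random_frame(self, rng):
        n, ca, c = rng.normal(size=(3, 3)) * 4
        if np.linalg.norm(np.cross(n - ca, c - ca)) < 1e-3:
            return self._random_frame(rng)
        return frame_from_residue(n, ca, c), (n, ca, c)

    def test_frame_translates_and_rotates_with_residue(self, rng):
        f, (n, ca, c) = self._random_frame(rng)
        shift = np.array([3.0, -2.0, 5.0])
        f2 = frame_from_residue(n + shift, ca + shift, c + shift)
        assert f2.origin == pytest.approx(f.origin + shift)
        assert f2.axes == pytest.approx(f.axes)
        R = random_rotation(rng)
        f3 = frame_from_residue(R @ n, R @ ca, R @ c)
        assert f3.axes == pytest.approx(R @ f.axes)

    def test_transform_between_reproduces_target_frame(self, rng):
        f1, _ = self._random_frame(rng)
        f2, _ = self._random_frame(rng)
        t = transform_between(f1, f2)
        moved = f1.transformed(t)
        assert moved.origin == pytest.approx(f2.origin, abs=1e-9)
        assert moved.axes == pytest.approx(f2.axes, abs=1e-9)

    def test_transform_invariant_under_joint_rigid_motion(self, rng):
        """The hashed quantity must not depend on the global pose of the pair."""
        for _ in range(10):
            f1, a1 = self._random_frame(rng)
            f2, a2 = self._random_frame(rng)
            t = transform_between(f1, f2)
            R = random_rotation(rng)
            shift = rng.normal(size=3) * 10
            g1 = frame_from_residue(*(R @ p + shift for p in a1))
            g2 = frame_from_residue(*(R @ p + shift for p in a2))
            t2 = transform_between(g1, g2)
            assert t2.rotation == pytest.approx(t.rotation, abs=1e-9)
            assert t2.translation == pytest.approx(t.translation, abs=1e-9)

    def test_transform_composition(self, rng):
        f1, _ = self._random_frame(rng)
        f2, _ = self._random_frame(rng)
        f3, _ = self._random_frame(rng)
        t13 = transform_between(f1, f2).compose(transform_between(f2, f3))
        ref = transform_between(f1, f3)
        assert t13.rotation == pytest.approx(ref.rotation, abs=1e-9)
        assert t13.translation == pytest.approx(ref.translation, abs=1e-9)


class TestKabsch:
    def test_identity_and_pure_rotation_recovered(self, rng):
        p = rng.normal(size=(10, 3)) * 5
        t, r = kabsch(p, p)
        assert r == pytest.approx(0.0, abs=1e-9)
        R = random_rotation(rng)
        q = p @ R.T + np.array([1.0, 2.0, 3.0])
        t2, r2 = kabsch(p, q)
        assert r2 == pytest.approx(0.0, abs=1e-7)
        assert t2.rotation == pytest.approx(R, abs=1e-7)

    def test_beats_random_rotation_brute_force(self, rng):
        """Kabsch RMSD must lower-bound a 1e5-sample random-rotation search."""
        p = rng.normal(size=(10, 3)) * 4
        q = p @ random_rotation(rng).T + rng.normal(size=(10, 3)) * 0.5
        _, r_kabsch = kabsch(p, q)
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        Rs = Rotation.random(100_000, random_state=7).as_matrix()
        rotated = np.einsum("kij,nj->kni", Rs, pc)
        rmsds = np.sqrt(np.mean(np.sum((rotated - qc) ** 2, axis=2), axis=1))
        assert r_kabsch <= rmsds.min() + 1e-12

    def test_never_worse_than_untransformed(self, rng):
        p = rng.normal(size=(8, 3)) * 3
        q = rng.normal(size=(8, 3)) * 3
        _, r = kabsch(p, q)
        raw = np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1)))
        assert r <= raw + 1e-12

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestC2:
    def test_point_on_axis_fixed_and_involution(self, rng):
        axis = np.array([0.0, 0.0, 1.0])
        pts = rng.normal(size=(12, 3)) * 6
        once = c2_apply(axis, np.zeros(3), pts)
        twice = c2_apply(axis, np.zeros(3), once)
        assert twice == pytest.approx(pts, abs=1e-9)
        on_axis = np.array([[0.0, 0.0, 3.7]])
        assert c2_apply(axis, np.zeros(3), on_axis) == pytest.approx(on_axis)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            c2_apply([0, 0, 0], [0, 0, 0], np.zeros((1, 3)))

    def test_rotation_about_axis_matches_scipy(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rotation_about_axis(axis, 73.0)
        ref = Rotation.from_rotvec(np.radians(73.0) * axis).as_matrix()
        assert R == pytest.approx(ref, abs=1e-12)


class TestRigidTransform:
    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_composes_to_identity(self, rng):
        R = random_rotation(rng)
        t = RigidTransform(R, rng.normal(size=3))
        ident = t.compose(t.inverse())
        assert ident.rotation == pytest.approx(np.eye(3), abs=1e-12)
        assert ident.translation == pytest.approx(np.zeros(3), abs=1e-12)
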