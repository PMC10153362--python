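"""Rigid-body kinematics shared by all higher-level modules.

Conventions
-----------
* Dihedral angles follow the IUPAC right-hand rule: looking down the
  b->c bond, a positive dihedral rotates the far bond clockwise.
* Residue frames are built from the backbone N, CA, C atoms with the
  origin at CA, x along CA->N, z along x cross (CA->C), y completing a
  right-handed set.  Any self-consistent convention would do for
  transform hashing; this one is fixed and documented here.
* ``transform_between(f1, f2)`` returns the relative transform expressed
  in f1's local coordinates, which makes it invariant under any common
  rigid motion of both frames -- the property the motif hash relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "InternalCoordinate",
    "Frame",
    "nerf_place",
    "cartesian_to_internal",
    "chain_from_internal",
    "bond_angle",
    "dihedral",
    "frame_from_residue",
    "transform_between",
    "kabsch",
    "c2_apply",
    "rotation_about_axis",
]

_ORTHO_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize near-zero vector")
    return v / n


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation in SO(3), translation in A)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self then other in self's moving frame: (self * other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class InternalCoordinate:
    """Bond length (A), bond angle and dihedral (degrees) relative to three predecessors."""

    bond_length: float
    bond_angle: float
    dihedral: float

    def __post_init__(self) -> None:
        if not (self.bond_length > 0):
            raise ValueError("bond_length must be positive")
        if not (0.0 < self.bond_angle < 180.0):
            raise ValueError("bond_angle must be in (0, 180) degrees")


@dataclass(frozen=True)
class Frame:
    """Orthonormal residue frame: origin plus 3x3 basis (columns = x, y, z axes)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, dtype=float)
        o = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "origin", o)

    def transformed(self, t: RigidTransform) -> "Frame":
        """Compose this frame with a local-coordinate transform (frame * t)."""
        return Frame(self.origin + self.axes @ t.translation, self.axes @ t.rotation)

    def moved(self, t: RigidTransform) -> "Frame":
        """Apply a global rigid motion to this frame."""
        return Frame(t.apply(self.origin), t.rotation @ self.axes)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(np.asarray(a, float) - b)
    v = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, IUPAC right-hand rule."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b0 = a - b
    b1 = _unit(c - b)
    b2 = d - c
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def nerf_place(a, b, c, ic: InternalCoordinate) -> np.ndarray:
    """Place atom d from three predecessors and internal coordinates (NeRF).

    The returned point satisfies |d - c| = bond_length, angle(b, c, d) =
    bond_angle and dihedral(a, b, c, d) = dihedral exactly (to floating
    precision).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    bc = c - b
    ab = b - a
    n_bc = np.linalg.norm(bc)
    if n_bc < 1e-9:
        raise ValueError("b and c coincide")
    bc_hat = bc / n_bc
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-9:
        raise ValueError("reference atoms a, b, c are collinear")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)

    theta = np.radians(ic.bond_angle)
    phi = np.radians(ic.dihedral)
    L = ic.bond_length
    # local displacement: -cos(theta) along bc, the rest rotated by the dihedral
    d_local = np.array(
        [-L * np.cos(theta), L * np.sin(theta) * np.cos(phi), L * np.sin(theta) * np.sin(phi)]
    )
    M = np.column_stack([bc_hat, m_hat, n_hat])
    return c + M @ d_local


def cartesian_to_internal(coords: np.ndarray) -> list[InternalCoordinate]:
    """Internal coordinates of a serial chain (atom i referenced to i-3, i-2, i-1).

    Inverse of sequential :func:`nerf_place` given the same first three atoms.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 4:
        raise ValueError("need an (n>=4, 3) coordinate array")
    out = []
    for i in range(3, len(coords)):
        a, b, c, d = coords[i - 3], coords[i - 2], coords[i - 1], coords[i]
        if np.linalg.norm(np.cross(b - a, c - b)) < 1e-9:
            raise ValueError(f"atoms {i-3}..{i-1} are collinear")
        out.append(
            InternalCoordinate(
                bond_length=float(np.linalg.norm(d - c)),
                bond_angle=bond_angle(b, c, d),
                dihedral=dihedral(a, b, c, d),
            )
        )
    return out


def chain_from_internal(first_three: np.ndarray, ics: list[InternalCoordinate]) -> np.ndarray:
    """Rebuild a serial chain from its first three atoms and internal coordinates."""
    coords = [np.asarray(p, float) for p in first_three]
    if len(coords) != 3:
        raise ValueError("need exactly three seed atoms")
    for ic in ics:
        coords.append(nerf_place(coords[-3], coords[-2], coords[-1], ic))
    return np.array(coords)


def frame_from_residue(n, ca, c) -> Frame:
    """Backbone frame: origin at CA, x along CA->N, z = x cross (CA->C), y = z cross x."""
    n, ca, c = (np.asarray(v, float) for v in (n, ca, c))
    x = _unit(n - ca)
    v = c - ca
    z = np.cross(x, v)
    if np.linalg.norm(z) < 1e-9:
        raise ValueError("N, CA, C are collinear")
    z = _unit(z)
    y = np.cross(z, x)
    return Frame(ca, np.column_stack([x, y, z]))


def transform_between(f1: Frame, f2: Frame) -> RigidTransform:
    """Relative transform from f1 to f2 expressed in f1's coordinates.

    ``f1.transformed(transform_between(f1, f2))`` reproduces f2; the result
    is invariant under any rigid motion applied jointly to both frames.
    """
    R = f1.axes.T @ f2.axes
    t = f1.axes.T @ (f2.origin - f1.origin)
    return RigidTransform(R, t)


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of p onto q (proper rotation only).

    Returns the transform T minimizing RMSD(T(p), q) and that minimum RMSD.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("point sets must be matching (n>=3, 3) arrays")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    T = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((T.apply(p) - q) ** 2, axis=1))))
    return T, rmsd


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle in degrees (Rodrigues)."""
    a = _unit(np.asarray(axis, float))
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def c2_apply(axis: np.ndarray, point_on_axis: np.ndarray, atoms: np.ndarray) -> np.ndarray:
    """180-degree rotation of coordinates about an axis through a given point."""
    a = np.asarray(axis, float)
    if np.linalg.norm(a) < 1e-9:
        raise ValueError("zero-length axis")
    a = _unit(a)
    p0 = np.asarray(point_on_axis, float)
    R = 2.0 * np.outer(a, a) - np.eye(3)
    pts = np.asarray(atoms, float)
    return (pts - p0) @ R.T + p0
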