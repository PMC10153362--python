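"""Two-component octahedral (and tetrahedral) nanocage assembly.

A C2-symmetric component (e.g. a chlorophyll-binding special-pair dimer)
is placed on the two-fold axes of the point group and a C3-symmetric
homotrimer on the three-fold axes; sampling the rotation about, and
translation along, those axes generates closely packed cage models:
for the octahedral group, 12 dimers on the edges and 8 trimers on the
vertices, i.e. 24 chromophores and 48 protein chains when each dimer
protomer carries one chromophore.

Component convention: a component Structure must have its internal
symmetry axis along global z through the origin (the fixture builders
below produce this); ``place_and_expand`` verifies the internal symmetry
before expanding by the group's coset representatives.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chem import Atom, Chain, Residue, Structure, compute_sasa
from .geometry import RigidTransform, rotation_about_axis, kabsch

__all__ = [
    "SymmetryArchitecture",
    "ComponentPose",
    "CageModel",
    "architecture",
    "place_and_expand",
    "score_dock",
    "sample_docks",
    "make_c2_component",
    "make_c3_component",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    group = [np.eye(3)]

    def known(R):
        return any(np.allclose(R, G, atol=1e-9) for G in group)

    frontier = [np.eye(3)]
    while frontier:
        new = []
        for G in frontier:
            for g in generators:
                H = g @ G
                if not known(H):
                    group.append(H)
                    new.append(H)
        frontier = new
    return group


@dataclass
class SymmetryArchitecture:
    """Point-group rotations plus the two component slots (order, axis, copies)."""

    group: str
    rotations: list[np.ndarray]
    c2_axis: np.ndarray
    c3_axis: np.ndarray

    @property
    def n_c2_copies(self) -> int:
        return len(self.rotations) // 2

    @property
    def n_c3_copies(self) -> int:
        return len(self.rotations) // 3


def architecture(group: str = "O") -> SymmetryArchitecture:
    """Rotation group and component axes for octahedral (O) or tetrahedral (T)."""
    if group == "O":
        gens = [
            rotation_about_axis([0, 0, 1], 90.0),
            rotation_about_axis([1, 1, 1], 120.0),
        ]
        c2 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)  # edge (2-fold) axis
        c3 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)  # vertex (3-fold) axis
        order = 24
    elif group == "T":
        gens = [
            rotation_about_axis([0, 0, 1], 180.0),
            rotation_about_axis([1, 1, 1], 120.0),
        ]
        c2 = np.array([0.0, 0.0, 1.0])
        c3 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        order = 12
    else:
        raise ValueError(f"unsupported point group {group!r}")
    rots = _closure(gens)
    if len(rots) != order:
        raise RuntimeError(f"group closure produced {len(rots)} != {order} rotations")
    return SymmetryArchitecture(group, rots, c2, c3)


@dataclass(frozen=True)
class ComponentPose:
    """Spin about the component's own symmetry axis and translation along it."""

    rotation_deg: float = 0.0
    translation: float = 0.0


@dataclass
class CageModel:
    structure: Structure
    n_c2_copies: int
    n_c3_copies: int
    chromophore_count: int
    scores: dict = field(default_factory=dict)


def _axis_alignment(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking global z onto the given unit axis."""
    z = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else rotation_about_axis([1, 0, 0], 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _component_coords(s: Structure) -> np.ndarray:
    return s.coordinates()


def verify_internal_symmetry(s: Structure, order: int, tol: float = 1e-3) -> None:
    """Check chains permute onto themselves under rotation by 360/order about z."""
    R = rotation_about_axis([0, 0, 1], 360.0 / order)
    chains = [
        np.array([a.position for r in c.residues for a in r.atoms]) for c in s.chains
    ]
    for coords in chains:
        rotated = coords @ R.T
        if not any(
            c.shape == rotated.shape and np.allclose(c, rotated, atol=tol)
            for c in chains
        ):
            raise ValueError("component lacks the required internal symmetry")


def _transform_structure(s: Structure, R: np.ndarray, t: np.ndarray, chain_ids) -> list[Chain]:
    out = []
    for chain, cid in zip(s.chains, chain_ids):
        residues = []
        for res in chain.residues:
            atoms = [
                Atom(a.name, a.element, R @ a.position + t, a.radius)
                for a in res.atoms
            ]
            residues.append(Residue(res.name, res.seqid, atoms, hetero=res.hetero))
        out.append(Chain(cid, residues))
    return out


def _expand_component(
    arch: SymmetryArchitecture,
    component: Structure,
    axis: np.ndarray,
    order: int,
    pose: ComponentPose,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Coset-representative (R, t) placements of a posed component."""
    A = _axis_alignment(axis)
    spin = rotation_about_axis([0, 0, 1], pose.rotation_deg)
    R0 = A @ spin
    t0 = A @ np.array([0.0, 0.0, pose.translation])
    seen: list[np.ndarray] = []
    placements = []
    probe = _component_coords(component)
    for G in arch.rotations:
        R = G @ R0
        t = G @ t0
        coords = probe @ R.T + t
        # order-invariant key: the stabilizer permutes atoms between copies
        rounded = np.round(coords, 5)
        key = rounded[np.lexsort(rounded.T)]
        if any(np.allclose(key, s, atol=1e-4) for s in seen):
            continue
        seen.append(key)
        placements.append((R, t))
    expected = len(arch.rotations) // order
    if len(placements) != expected:  # pragma: no cover - sanity guard
        raise RuntimeError(
            f"expected {expected} unique placements, got {len(placements)}"
        )
    return placements


def place_and_expand(
    arch: SymmetryArchitecture,
    c2_component: Structure,
    c3_component: Structure,
    pose2: ComponentPose = ComponentPose(),
    pose3: ComponentPose = ComponentPose(),
    chromophore_resname: str = "CLA",
) -> CageModel:
    """Align components axis-to-axis, pose them, and expand to the full cage."""
    verify_internal_symmetry(c2_component, 2)
    verify_internal_symmetry(c3_component, 3)
    placements2 = _expand_component(arch, c2_component, arch.c2_axis, 2, pose2)
    placements3 = _expand_component(arch, c3_component, arch.c3_axis, 3, pose3)

    chains: list[Chain] = []
    cid_iter = iter(_CHAIN_IDS)

    def next_ids(n):
        return [next(cid_iter) for _ in range(n)]

    for R, t in placements2:
        chains.extend(
            _transform_structure(c2_component, R, t, next_ids(len(c2_component.chains)))
        )
    for R, t in placements3:
        chains.extend(
            _transform_structure(c3_component, R, t, next_ids(len(c3_component.chains)))
        )
    structure = Structure(chains)
    n_chromo = sum(
        1
        for c in structure.chains
        for r in c.residues
        if r.name == chromophore_resname
    )
    return CageModel(
        structure=structure,
        n_c2_copies=len(placements2),
        n_c3_copies=len(placements3),
        chromophore_count=n_chromo,
    )


def _backbone(chain: Chain) -> np.ndarray:
    return np.array(
        [
            a.position
            for r in chain.residues
            if not r.hetero
            for a in r.atoms
            if a.name in ("N", "CA", "C", "O")
        ]
    ).reshape(-1, 3)


def score_dock(
    cage: CageModel,
    clash_cutoff: float = 2.8,
    contact_cutoff: float = 8.0,
    area_bounds: tuple[float, float] = (1000.0, 1600.0),
    max_clash: int = 3,
    sasa_points: int = 240,
) -> dict:
    """Score the unique C2-C3 interface of an expanded cage.

    Reports backbone clash count, CA-level contact count and buried
    interface area (SASA of the two partners minus SASA of the pair) for
    the first C2 copy against its closest C3 copy, plus pass/fail flags
    against the clash and area bounds.  Scores are invariant under global
    rigid motion of the cage.
    """
    n2 = cage.n_c2_copies
    c2_chains_per = 0
    # chains are ordered: all C2 copies first, then C3 copies
    total2 = 0
    # infer chains per c2 copy from chain count arithmetic
    n3 = cage.n_c3_copies
    n_chains = len(cage.structure.chains)
    per2 = (n_chains - n3 * _chains_per_c3(cage)) // n2 if n2 else 0
    per3 = _chains_per_c3(cage)

    c2_first = cage.structure.chains[:per2]
    c3_copies = [
        cage.structure.chains[n2 * per2 + i * per3 : n2 * per2 + (i + 1) * per3]
        for i in range(n3)
    ]
    bb2 = np.vstack([_backbone(c) for c in c2_first])
    best = None
    for copy in c3_copies:
        bb3 = np.vstack([_backbone(c) for c in copy])
        d, _ = cKDTree(bb3).query(bb2, k=1)
        contacts = int(np.sum(d < contact_cutoff))
        clashes = int(np.sum(d < clash_cutoff))
        if best is None or contacts > best[0]:
            best = (contacts, clashes, copy)
    contacts, clashes, partner = best

    if contacts == 0:
        area = 0.0
    else:
        atoms2 = [a for c in c2_first for r in c.residues for a in r.atoms]
        atoms3 = [a for c in partner for r in c.residues for a in r.atoms]
        s2 = compute_sasa(atoms2, n_points=sasa_points).sum()
        s3 = compute_sasa(atoms3, n_points=sasa_points).sum()
        s23 = compute_sasa(atoms2 + atoms3, n_points=sasa_points).sum()
        area = float(s2 + s3 - s23)

    lo, hi = area_bounds
    return {
        "clash_count": clashes,
        "contact_count": contacts,
        "interface_area": area,
        "pass_clash": clashes < max_clash,
        "pass_area": lo < area < hi,
        "pass": clashes < max_clash and lo < area < hi,
    }


def _chains_per_c3(cage: CageModel) -> int:
    return 3  # C3 homotrimer convention used throughout


def sample_docks(
    arch: SymmetryArchitecture,
    c2_component: Structure,
    c3_component: Structure,
    rotation_grid: list[float],
    translation_grid: list[float],
    **score_kw,
) -> list[dict]:
    """Exhaustive grid over (pose2 x pose3); returns scored poses in order."""
    if not rotation_grid or not translation_grid:
        raise ValueError("grids must be non-empty")
    results = []
    poses = [
        ComponentPose(r, t) for r, t in itertools.product(rotation_grid, translation_grid)
    ]
    for pose2, pose3 in itertools.product(poses, poses):
        cage = place_and_expand(arch, c2_component, c3_component, pose2, pose3)
        scores = score_dock(cage, **score_kw)
        results.append({"pose2": pose2, "pose3": pose3, **scores})
    return results


# ---------------------------------------------------------------------------
# Synthetic component builders (fixtures)


def _helix_chain_at(offset: np.ndarray, spin_deg: float, chain_id: str, n_res: int,
                    chromophore: bool) -> Chain:
    from .matching import build_ideal_helix

    helix = build_ideal_helix(n_res)
    R = rotation_about_axis([0, 0, 1], spin_deg)
    # orient the helix roughly along z before offsetting
    ca = np.array([r["CA"] for r in helix])
    axis_dir = ca[-1] - ca[0]
    align = _axis_alignment(axis_dir / np.linalg.norm(axis_dir)).T  # helix axis -> z
    center = ca.mean(axis=0)
    residues = []
    for i, r in enumerate(helix, start=1):
        atoms = [
            Atom(n, "O" if n == "O" else ("N" if n == "N" else "C"),
                 R @ (align @ (p - center) + offset))
            for n, p in r.items()
        ]
        residues.append(Residue("ALA", i, atoms))
    if chromophore:
        from .chem import build_ideal_chlorin

        chl = build_ideal_chlorin("Zn")
        shift = RigidTransform(R, R @ (offset + np.array([4.0, 0.0, 0.0])))
        placed = chl.transformed(shift)
        residues.append(placed.to_residue(name="CLA", seqid=n_res + 1))
    return Chain(chain_id, residues)


def make_c2_component(n_res: int = 18, radius: float = 6.0, with_chromophore: bool = True) -> Structure:
    """Toy C2 helical homodimer (axis = z through origin), optionally with one
    chlorin per protomer."""
    chains = []
    for k in range(2):
        chains.append(
            _helix_chain_at(np.array([radius, 0.0, 0.0]), 180.0 * k, "AB"[k], n_res,
                            with_chromophore)
        )
    return Structure(chains)


def make_c3_component(n_res: int = 18, radius: float = 7.0) -> Structure:
    """Toy C3 helical homotrimer (axis = z through origin)."""
    chains = []
    for k in range(3):
        chains.append(
            _helix_chain_at(np.array([radius, 0.0, 0.0]), 120.0 * k, "ABC"[k], n_res,
                            False)
        )
    return Structure(chains)
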