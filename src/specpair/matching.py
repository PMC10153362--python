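"""Scan C2-homodimeric scaffolds for cross-chain residue pairs that hit
the motif hash table; rebuild and clash-check chlorin-dimer placements.

Residue pairing is index-to-index across the two chains (i in chain A
with i in chain B), the natural pairing for C2 homodimers.  Scaffold
side chains are ignored: only backbone clashes are authoritative, since
pocket side chains would be redesigned around an accepted placement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chem import Atom, Chain, Residue, Structure, ligand_burial
from .geometry import (
    Frame,
    RigidTransform,
    c2_apply,
    frame_from_residue,
    InternalCoordinate,
    nerf_place,
    transform_between,
)
from .hashing import MotifRecord, TransformHashTable
from .motif import HIS_HEAVY_ATOMS, HisChlMotif

logger = logging.getLogger(__name__)

__all__ = [
    "Scaffold",
    "Placement",
    "enumerate_symmetric_pairs",
    "match_scaffold",
    "backbone_clash_check",
    "rank_placements",
    "make_planted_scaffold",
    "build_ideal_helix",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Scaffold:
    """A two-chain C2 homodimer with an optional designable-position mask."""

    structure: Structure
    chain_a: str = "A"
    chain_b: str = "B"
    mask: set[int] | None = None  # residue indices excluded from matching

    def __post_init__(self) -> None:
        a = self.structure.chain(self.chain_a)
        b = self.structure.chain(self.chain_b)
        if len(a.residues) != len(b.residues):
            raise ValueError("C2 scaffold chains must have equal length")

    def backbone_coordinates(self, exempt: set[int] | None = None) -> np.ndarray:
        pts = []
        for cid in (self.chain_a, self.chain_b):
            for res in self.structure.chain(cid).residues:
                if exempt and res.seqid in exempt:
                    continue
                pts.extend(
                    a.position for a in res.atoms if a.name in BACKBONE_ATOMS
                )
        return np.array(pts)


@dataclass
class Placement:
    """A rebuilt motif anchored at one symmetric residue pair of a scaffold."""

    residue_index: int
    record: MotifRecord
    motif: HisChlMotif
    backbone_clash_count: int
    ligand_burial: float
    accepted: bool

    def report_row(self) -> dict:
        return {
            "residue_index": self.residue_index,
            "ligation": self.record.ligation_nitrogen,
            "chi1": self.record.chi1,
            "chi2": self.record.chi2,
            "ligation_dihedral": self.record.ligation_dihedral,
            "clash_count": self.backbone_clash_count,
            "burial": round(self.ligand_burial, 4),
            "accepted": self.accepted,
        }


def _residue_frame(res: Residue) -> Frame | None:
    try:
        return frame_from_residue(
            res.atom("N").position, res.atom("CA").position, res.atom("C").position
        )
    except KeyError:
        return None


def enumerate_symmetric_pairs(s: Scaffold) -> list[tuple[int, RigidTransform]]:
    """Cross-chain frame transform of each unmasked residue pair (i, i)."""
    out = []
    chain_a = s.structure.chain(s.chain_a)
    chain_b = s.structure.chain(s.chain_b)
    by_id_b = {r.seqid: r for r in chain_b.residues}
    for res_a in chain_a.residues:
        if s.mask and res_a.seqid in s.mask:
            continue
        res_b = by_id_b.get(res_a.seqid)
        if res_b is None:
            continue
        fa = _residue_frame(res_a)
        fb = _residue_frame(res_b)
        if fa is None or fb is None:
            logger.warning("skipping residue %d: incomplete backbone", res_a.seqid)
            continue
        out.append((res_a.seqid, transform_between(fa, fb)))
    return out


def backbone_clash_check(
    motif_coords: np.ndarray,
    backbone_coords: np.ndarray,
    cutoff: float = 2.5,
) -> int:
    """Number of motif heavy atoms within ``cutoff`` of any backbone heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(backbone_coords) == 0 or len(motif_coords) == 0:
        return 0
    d, _ = cKDTree(backbone_coords).query(motif_coords, k=1)
    return int(np.sum(d < cutoff))


def _anchor_transform(frame_from: Frame, frame_to: Frame) -> RigidTransform:
    R = frame_to.axes @ frame_from.axes.T
    t = frame_to.origin - R @ frame_from.origin
    return RigidTransform(R, t)


def match_scaffold(
    s: Scaffold,
    table: TransformHashTable,
    clash_cutoff: float = 2.5,
    neighbor_cells: bool = False,
    compute_burial: bool = True,
) -> list[Placement]:
    """Query every symmetric residue pair against the table and rebuild hits.

    Each hit is anchored by mapping the motif's first-histidine N-CA-C
    frame onto the chain-A residue frame; the placement is accepted when
    no motif heavy atom clashes with non-host backbone.
    """
    chain_a = s.structure.chain(s.chain_a)
    by_id_a = {r.seqid: r for r in chain_a.residues}
    placements: list[Placement] = []
    for seqid, t in enumerate_symmetric_pairs(s):
        records = table.query(t, neighbor_cells=neighbor_cells)
        if not records:
            continue
        fa = _residue_frame(by_id_a[seqid])
        backbone = s.backbone_coordinates(exempt={seqid})
        for record in records:
            motif = record.rebuild()
            moved = motif.transformed(_anchor_transform(motif.his1_frame(), fa))
            lig_coords = np.vstack(
                [
                    [a.position for a in moved.chlorin.all_atoms()],
                    [a.position for a in moved.chlorin_2.all_atoms()],
                ]
            )
            clashes = backbone_clash_check(lig_coords, backbone, clash_cutoff)
            burial = 0.0
            if compute_burial and clashes == 0:
                lig_atoms = [*moved.chlorin.all_atoms(), *moved.chlorin_2.all_atoms()]
                scaffold_atoms = [
                    Atom("X", "C", p) for p in s.backbone_coordinates()
                ]
                burial = ligand_burial(lig_atoms, lig_atoms + scaffold_atoms)
            placements.append(
                Placement(
                    residue_index=seqid,
                    record=record,
                    motif=moved,
                    backbone_clash_count=clashes,
                    ligand_burial=burial,
                    accepted=clashes == 0,
                )
            )
    return placements


def rank_placements(
    placements: list[Placement],
    max_clash: int = 0,
    min_burial: float = 0.0,
) -> list[Placement]:
    """Filter on clash count and ligand burial; order by (clash asc, burial desc)."""
    survivors = [
        p
        for p in placements
        if p.backbone_clash_count <= max_clash and p.ligand_burial >= min_burial
    ]
    return sorted(
        survivors, key=lambda p: (p.backbone_clash_count, -p.ligand_burial)
    )


# ---------------------------------------------------------------------------
# Planted-scaffold fixture generator


def build_ideal_helix(n_residues: int, phi: float = -57.0, psi: float = -47.0):
    """Ideal alpha-helix backbone: list of per-residue dicts N/CA/C/O."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = np.radians(180.0 - 111.0)
    c0 = ca0 + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords = [n0, ca0, c0]
    for _ in range(n_residues - 1):
        a, b, c = coords[-3], coords[-2], coords[-1]
        coords.append(nerf_place(a, b, c, InternalCoordinate(1.329, 116.2, psi)))  # N
        a, b, c = coords[-3], coords[-2], coords[-1]
        coords.append(nerf_place(a, b, c, InternalCoordinate(1.458, 121.7, 180.0)))  # CA
        a, b, c = coords[-3], coords[-2], coords[-1]
        coords.append(nerf_place(a, b, c, InternalCoordinate(1.525, 111.0, phi)))  # C
    residues = []
    for i in range(n_residues):
        n, ca, c = coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]
        o = nerf_place(n, ca, c, InternalCoordinate(1.231, 120.5, 133.0))
        residues.append({"N": n, "CA": ca, "C": c, "O": o})
    return residues


def _helix_chain(residues, chain_id: str, res_name: str = "ALA") -> Chain:
    out = []
    for i, res in enumerate(residues, start=1):
        atoms = [
            Atom(name, "O" if name == "O" else ("N" if name == "N" else "C"), pos)
            for name, pos in res.items()
        ]
        out.append(Residue(res_name, i, atoms))
    return Chain(chain_id, out)


def make_planted_scaffold(
    motif: HisChlMotif,
    n_residues: int = 50,
    seed: int = 0,
    clash_cutoff: float = 2.5,
) -> Scaffold:
    """Two-chain helical scaffold with one cross-chain residue pair realizing
    the motif's His-pair transform exactly.

    Chain A consists of a short host helix whose central residue's N-CA-C
    frame coincides with the motif's first-histidine frame, plus a decoy
    helical segment placed (seeded) well away from the binding site; chain
    B is the exact C2 copy of chain A about the motif's two-fold axis, so
    the scaffold is perfectly C2 and the planted pair hashes to the
    motif's key.  Host helix length shrinks until the surrounding backbone
    clears the chlorin footprint; if even the minimal host clashes, the
    graft is impossible and an error is raised.

    The motif must be in its canonical dimer frame (C2 axis = global z),
    as produced by :func:`specpair.motif.build_motif`.
    """
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    rng = np.random.default_rng(seed)

    motif_coords = motif.all_coordinates()
    # footprint that must stay clear of backbone: both chlorins + His side chains
    side_chain = ("CB", "CG", "ND1", "CD2", "CE1", "NE2")
    footprint = np.vstack(
        [
            [a.position for a in motif.chlorin.all_atoms()],
            [a.position for a in motif.chlorin_2.all_atoms()],
            [motif.his_atoms[n] for n in side_chain],
            [motif.his_atoms_2[n] for n in side_chain],
        ]
    )
    f1 = motif.his1_frame()

    host_a = None
    # host segment spans residues [i-a, i+b]; asymmetric spans let the helix
    # extend only on the side that clears the chlorin dimer
    for a, b in ((7, 7), (7, 1), (1, 7), (5, 5), (5, 1), (1, 5),
                 (3, 3), (3, 1), (1, 3), (2, 2), (1, 1)):
        helix = build_ideal_helix(a + b + 1)
        res = helix[a]
        f_can = frame_from_residue(res["N"], res["CA"], res["C"])
        move = _anchor_transform(f_can, f1)
        moved = [{n: move.apply(p) for n, p in r.items()} for r in helix]
        all_pts = np.array([p for r in moved for p in r.values()])
        nonhost = np.array(
            [p for j, r in enumerate(moved) if abs(j - a) > 1 for p in r.values()]
        ).reshape(-1, 3)
        mirror_nonhost = (
            c2_apply(np.array([0.0, 0.0, 1.0]), np.zeros(3), nonhost)
            if len(nonhost)
            else nonhost
        )
        if backbone_clash_check(footprint, nonhost, clash_cutoff) > 0:
            continue
        if backbone_clash_check(footprint, mirror_nonhost, clash_cutoff) > 0:
            continue
        mirror_all = c2_apply(np.array([0.0, 0.0, 1.0]), np.zeros(3), all_pts)
        d, _ = cKDTree(mirror_all).query(all_pts, k=1)
        if float(d.min()) < 1.8:
            continue
        host_a = moved
        break
    if host_a is None:
        raise ValueError(
            "impossible graft: motif transform incompatible with backbone continuity"
        )

    # decoy helical segment, placed far from the site in a seeded direction
    n_decoy = n_residues - len(host_a)
    decoy_a: list[dict] = []
    if n_decoy >= 2:
        decoy = build_ideal_helix(n_decoy)
        for _ in range(50):
            direction = rng.normal(size=3)
            direction[2] = abs(direction[2]) + 0.5  # keep clear of the C2 axis image
            direction /= np.linalg.norm(direction)
            R = _random_rotation(rng)
            offset = 60.0 * direction
            cand = [
                {n: R @ p + offset for n, p in r.items()} for r in decoy
            ]
            pts = np.array([p for r in cand for p in r.values()])
            mirror = c2_apply(np.array([0.0, 0.0, 1.0]), np.zeros(3), pts)
            env = np.vstack(
                [
                    motif_coords,
                    np.array([p for r in host_a for p in r.values()]),
                    mirror,
                ]
            )
            d, _ = cKDTree(env).query(pts, k=1)
            if float(d.min()) >= 4.0:
                decoy_a = cand
                break
        else:  # pragma: no cover - 60 A offsets essentially always clear
            raise ValueError("could not place decoy segment")

    chain_a_res = host_a + decoy_a
    axis = np.array([0.0, 0.0, 1.0])
    chain_b_res = [
        {n: c2_apply(axis, np.zeros(3), p) for n, p in r.items()} for r in chain_a_res
    ]
    structure = Structure(
        [_helix_chain(chain_a_res, "A"), _helix_chain(chain_b_res, "B")]
    )
    return Scaffold(structure)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR with sign fix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q
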