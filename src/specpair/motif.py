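"""C2-symmetric histidine-chlorin dimer motif enumeration.

A motif is one half (histidine + metal-ligated chlorin) plus its exact
C2 duplicate.  Halves are built with ideal covalent geometry by NeRF
from the histidine backbone outward; the chlorin is attached through
the axial metal-N(His) bond on one ring face, the way (B)Chls are
pentacoordinated in native special pairs.  The builder works in the
"dimer frame": the C2 axis is global z, chlorin 1 is posed by the dimer
geometry parameters, and chlorin 2 / histidine 2 follow by the 180-degree
rotation, so emitted motifs are C2-exact by construction.

Dimer geometry parameterization (our choice; see docs/methods.md):
``mm_distance`` separates the two metals along x, ``slip`` offsets them
along y, ``tilt_deg`` rotates each ring about x (so the inter-plane angle
is set by the C2 relation), ``azimuth_deg`` spins each ring about its own
normal.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chem import Atom, ChlorinTemplate, build_ideal_chlorin
from .geometry import (
    Frame,
    InternalCoordinate,
    RigidTransform,
    frame_from_residue,
    nerf_place,
    rotation_about_axis,
    c2_apply,
)

__all__ = [
    "DimerGeometry",
    "MotifGrid",
    "HisChlMotif",
    "build_his_residue",
    "build_motif",
    "enumerate_conformers",
    "clash_filter",
    "save_motifs",
    "load_motifs",
    "write_motif_pdb",
]

C2_AXIS = np.array([0.0, 0.0, 1.0])
_C2 = RigidTransform(np.diag([-1.0, -1.0, 1.0]), np.zeros(3))

HIS_HEAVY_ATOMS = ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2")


def build_his_residue(chi1: float, chi2: float) -> dict[str, np.ndarray]:
    """Histidine heavy atoms with ideal covalent geometry in a local frame.

    chi1 = dihedral(N, CA, CB, CG); chi2 = dihedral(CA, CB, CG, ND1);
    the imidazole ring is planar.
    """
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    ang = math.radians(180.0 - 111.0)
    c = ca + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    atoms = {"N": n, "CA": ca, "C": c}
    atoms["O"] = nerf_place(n, ca, c, InternalCoordinate(1.231, 120.5, 133.0))
    atoms["CB"] = nerf_place(c, n, ca, InternalCoordinate(1.530, 110.5, 122.6))
    atoms["CG"] = nerf_place(n, ca, atoms["CB"], InternalCoordinate(1.500, 113.8, chi1))
    atoms["ND1"] = nerf_place(ca, atoms["CB"], atoms["CG"], InternalCoordinate(1.380, 122.7, chi2))
    atoms["CD2"] = nerf_place(
        ca, atoms["CB"], atoms["CG"], InternalCoordinate(1.360, 131.0, chi2 + 180.0)
    )
    atoms["CE1"] = nerf_place(
        atoms["CB"], atoms["CG"], atoms["ND1"], InternalCoordinate(1.320, 109.3, 180.0)
    )
    atoms["NE2"] = nerf_place(
        atoms["CB"], atoms["CG"], atoms["CD2"], InternalCoordinate(1.370, 107.2, 180.0)
    )
    return atoms


@dataclass(frozen=True)
class DimerGeometry:
    """Relative placement of the two chlorins (metal separation, slip, tilt, spin)."""

    mm_distance: float = 7.6
    slip: float = 0.0
    tilt_deg: float = 0.0
    azimuth_deg: float = 0.0


@dataclass
class MotifGrid:
    """Cartesian grid of internal coordinates enumerated into conformers."""

    chi1_values: list[float] = field(default_factory=lambda: [-60.0, 60.0, 180.0])
    chi2_values: list[float] = field(default_factory=lambda: [-90.0, -60.0, 60.0, 90.0])
    ligation_dihedral_values: list[float] = field(
        default_factory=lambda: [0.0, 90.0, 180.0, 270.0]
    )
    dimer_geometry_values: list[DimerGeometry] = field(
        default_factory=lambda: [
            # pi-stacked, native-special-pair-like: metal-metal ~7.6 A
            DimerGeometry(6.7, 3.5, 90.0, 0.0),
            # closer stacking, SP2-like
            DimerGeometry(5.5, 3.8, 90.0, 0.0),
            # side-by-side coplanar
            DimerGeometry(12.0, 0.0, 0.0, 0.0),
        ]
    )
    ligation_modes: tuple[str, ...] = ("epsilon", "delta")
    metal_his_distance: float = 2.1

    def __post_init__(self) -> None:
        if not (
            self.chi1_values
            and self.chi2_values
            and self.ligation_dihedral_values
            and self.dimer_geometry_values
            and self.ligation_modes
        ):
            raise ValueError("all grid dimensions must be non-empty")
        for m in self.ligation_modes:
            if m not in {"epsilon", "delta"}:
                raise ValueError(f"unknown ligation mode {m!r}")

    @property
    def size(self) -> int:
        return (
            len(self.chi1_values)
            * len(self.chi2_values)
            * len(self.ligation_dihedral_values)
            * len(self.dimer_geometry_values)
            * len(self.ligation_modes)
        )


@dataclass
class HisChlMotif:
    """One His-chlorin half plus its exact C2 duplicate, with build parameters."""

    his_atoms: dict[str, np.ndarray]
    his_atoms_2: dict[str, np.ndarray]
    chlorin: ChlorinTemplate
    chlorin_2: ChlorinTemplate
    ligation_nitrogen: str
    chi_angles: tuple[float, float]
    ligation_dihedral: float
    metal_his_distance: float
    dimer_geometry: DimerGeometry
    metal: str = "Zn"

    @property
    def ligating_atom_name(self) -> str:
        return "NE2" if self.ligation_nitrogen == "epsilon" else "ND1"

    def his1_frame(self) -> Frame:
        return frame_from_residue(self.his_atoms["N"], self.his_atoms["CA"], self.his_atoms["C"])

    def his2_frame(self) -> Frame:
        return frame_from_residue(
            self.his_atoms_2["N"], self.his_atoms_2["CA"], self.his_atoms_2["C"]
        )

    def half_coordinates(self, half: int) -> np.ndarray:
        his = self.his_atoms if half == 1 else self.his_atoms_2
        chl = self.chlorin if half == 1 else self.chlorin_2
        pts = [his[name] for name in HIS_HEAVY_ATOMS]
        pts.extend(a.position for a in chl.all_atoms())
        return np.array(pts)

    def all_coordinates(self) -> np.ndarray:
        return np.vstack([self.half_coordinates(1), self.half_coordinates(2)])

    def transformed(self, t: RigidTransform) -> "HisChlMotif":
        """Rigidly move the whole motif (both halves) by a global transform."""
        return HisChlMotif(
            his_atoms={k: t.apply(v) for k, v in self.his_atoms.items()},
            his_atoms_2={k: t.apply(v) for k, v in self.his_atoms_2.items()},
            chlorin=self.chlorin.transformed(t),
            chlorin_2=self.chlorin_2.transformed(t),
            ligation_nitrogen=self.ligation_nitrogen,
            chi_angles=self.chi_angles,
            ligation_dihedral=self.ligation_dihedral,
            metal_his_distance=self.metal_his_distance,
            dimer_geometry=self.dimer_geometry,
            metal=self.metal,
        )

    def build_params(self) -> dict:
        """Compact parameter record sufficient to rebuild this motif exactly."""
        return {
            "ligation_nitrogen": self.ligation_nitrogen,
            "chi1": self.chi_angles[0],
            "chi2": self.chi_angles[1],
            "ligation_dihedral": self.ligation_dihedral,
            "metal_his_distance": self.metal_his_distance,
            "geometry": asdict(self.dimer_geometry),
            "metal": self.metal,
        }


def _pose_transform(geom: DimerGeometry) -> RigidTransform:
    R = rotation_about_axis([1.0, 0.0, 0.0], geom.tilt_deg) @ rotation_about_axis(
        [0.0, 0.0, 1.0], geom.azimuth_deg
    )
    t = np.array([-geom.mm_distance / 2.0, -geom.slip / 2.0, 0.0])
    return RigidTransform(R, t)


def build_motif(
    chi1: float,
    chi2: float,
    ligation_dihedral: float,
    geometry: DimerGeometry,
    ligation_nitrogen: str = "epsilon",
    metal_his_distance: float = 2.1,
    metal: str = "Zn",
) -> HisChlMotif:
    """Construct one C2-symmetric His-chlorin dimer motif.

    The histidine is oriented so that the ligating-nitrogen lone pair (the
    in-plane bisector of its two ring neighbours) points at the metal along
    the ring normal; ``ligation_dihedral`` rotates the imidazole about the
    metal-N axis relative to the chlorin Qy axis.
    """
    if ligation_nitrogen not in {"epsilon", "delta"}:
        raise ValueError(f"unknown ligation mode {ligation_nitrogen!r}")

    pose = _pose_transform(geometry)
    chl1 = build_ideal_chlorin(metal).transformed(pose)
    normal1 = pose.rotation @ np.array([0.0, 0.0, 1.0])
    metal_pos = chl1.metal.position

    his_local = build_his_residue(chi1, chi2)
    if ligation_nitrogen == "epsilon":
        nl_name, nbr1, nbr2 = "NE2", "CE1", "CD2"
    else:
        nl_name, nbr1, nbr2 = "ND1", "CE1", "CG"
    nl = his_local[nl_name]
    u1 = his_local[nbr1] - nl
    u2 = his_local[nbr2] - nl
    bis = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
    e1 = bis / np.linalg.norm(bis)  # lone-pair direction, N -> metal
    ref = u1 - (u1 @ e1) * e1
    e2 = ref / np.linalg.norm(ref)
    e3 = np.cross(e1, e2)

    f1 = -normal1  # N sits on the +normal face, bond points back at the metal
    qy = chl1.qy_axis - (chl1.qy_axis @ normal1) * normal1
    qy = qy / np.linalg.norm(qy)
    f2 = rotation_about_axis(normal1, ligation_dihedral) @ qy
    f2 = f2 - (f2 @ f1) * f1
    f2 = f2 / np.linalg.norm(f2)
    f3 = np.cross(f1, f2)

    R = np.column_stack([f1, f2, f3]) @ np.column_stack([e1, e2, e3]).T
    n_target = metal_pos + metal_his_distance * normal1
    t = n_target - R @ nl
    move = RigidTransform(R, t)
    his1 = {name: move.apply(pos) for name, pos in his_local.items()}

    his2 = {name: c2_apply(C2_AXIS, np.zeros(3), pos) for name, pos in his1.items()}
    chl2 = chl1.transformed(_C2)

    return HisChlMotif(
        his_atoms=his1,
        his_atoms_2=his2,
        chlorin=chl1,
        chlorin_2=chl2,
        ligation_nitrogen=ligation_nitrogen,
        chi_angles=(chi1, chi2),
        ligation_dihedral=ligation_dihedral,
        metal_his_distance=metal_his_distance,
        dimer_geometry=geometry,
        metal=metal,
    )


def rebuild_motif(params: dict) -> HisChlMotif:
    """Rebuild a motif from the compact parameter record (inverse of build_params)."""
    geom = DimerGeometry(**params["geometry"])
    return build_motif(
        chi1=params["chi1"],
        chi2=params["chi2"],
        ligation_dihedral=params["ligation_dihedral"],
        geometry=geom,
        ligation_nitrogen=params["ligation_nitrogen"],
        metal_his_distance=params["metal_his_distance"],
        metal=params.get("metal", "Zn"),
    )


def enumerate_conformers(grid: MotifGrid, metal: str = "Zn") -> list[HisChlMotif]:
    """Enumerate the full grid of C2-symmetric conformers (no filtering)."""
    motifs = []
    for chi1, chi2, dih, geom, mode in itertools.product(
        grid.chi1_values,
        grid.chi2_values,
        grid.ligation_dihedral_values,
        grid.dimer_geometry_values,
        grid.ligation_modes,
    ):
        motifs.append(
            build_motif(
                chi1, chi2, dih, geom, mode, grid.metal_his_distance, metal=metal
            )
        )
    return motifs


_HIS_NONRING = ("N", "CA", "C", "O", "CB")


def clash_filter(motifs: list[HisChlMotif], cutoff: float = 2.8) -> list[HisChlMotif]:
    """Drop motifs with steric clashes closer than ``cutoff`` A.

    Two checks per motif: (1) minimum heavy-atom distance between the two
    halves, and (2) minimum distance between each histidine's
    backbone/CB atoms and its own chlorin.  The designed imidazole-metal
    ligation contact (the ligating nitrogen and the atoms bonded through
    it) is excluded by construction: only non-imidazole His atoms enter
    the intra-half check.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    from scipy.spatial import cKDTree

    kept = []
    for m in motifs:
        h1 = m.half_coordinates(1)
        h2 = m.half_coordinates(2)
        d, _ = cKDTree(h2).query(h1, k=1)
        if float(np.min(d)) < cutoff:
            continue
        chl = np.array([a.position for a in m.chlorin.all_atoms()])
        his_nonring = np.array([m.his_atoms[n] for n in _HIS_NONRING])
        d_intra, _ = cKDTree(chl).query(his_nonring, k=1)
        if float(np.min(d_intra)) < cutoff:
            continue
        kept.append(m)
    return kept


def save_motifs(motifs: list[HisChlMotif], path: str | Path) -> None:
    """One JSON record per line: the compact rebuild parameters."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(json.dumps(m.build_params()) + "\n")


def load_motifs(path: str | Path) -> list[HisChlMotif]:
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                motifs.append(rebuild_motif(json.loads(line)))
    return motifs


def motif_to_structure(m: HisChlMotif):
    """Motif as a two-chain Structure (His + chlorin per chain) for writing."""
    from .chem import Chain, Residue, Structure

    chains = []
    for half, cid in ((1, "A"), (2, "B")):
        his = m.his_atoms if half == 1 else m.his_atoms_2
        chl = m.chlorin if half == 1 else m.chlorin_2
        his_res = Residue(
            "HIS",
            1,
            [Atom(nm, "N" if nm.startswith("N") else ("O" if nm == "O" else "C"), his[nm])
             for nm in HIS_HEAVY_ATOMS],
        )
        chl_res = chl.to_residue(name="CLA", seqid=2)
        chains.append(Chain(cid, [his_res, chl_res]))
    return Structure(chains)


def write_motif_pdb(motifs: list[HisChlMotif], path: str | Path) -> None:
    """Multi-model PDB of a motif library for visual inspection."""
    import gemmi

    st = gemmi.Structure()
    st.name = "motifs"
    from .chem import write_structure  # noqa: F401  (shared conventions)

    for i, m in enumerate(motifs, start=1):
        model = gemmi.Model(str(i))
        s = motif_to_structure(m)
        for chain in s.chains:
            ch = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                r = gemmi.Residue()
                r.name = res.name
                r.seqid = gemmi.SeqId(res.seqid, " ")
                r.het_flag = "H" if res.hetero else "A"
                for atom in res.atoms:
                    a = gemmi.Atom()
                    a.name = atom.name
                    a.element = gemmi.Element(atom.element)
                    a.pos = gemmi.Position(*atom.position)
                    r.add_atom(a)
                ch.add_residue(r)
            model.add_chain(ch)
        st.add_model(model)
    st.write_pdb(str(path))
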