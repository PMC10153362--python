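"""Chlorin chemistry and structure handling.

Provides the idealized metal-chlorin template used for motif building, a
light-weight Structure container backed by gemmi for PDB/mmCIF I/O, the
24-atom tetrapyrrole selection convention used in all ring-ring RMSD
comparisons, Shrake-Rupley solvent accessibility, and Beer-Lambert
utilities.

Tetrapyrrole atom ordering
--------------------------
Ring-atom names follow the chemical-component convention for
chlorophylls: pyrrole nitrogens ``NA NB NC ND``, pyrrole carbons
``C1A..C4A`` through ``C1D..C4D``, methine bridge carbons
``CHA CHB CHC CHD``.  The canonical selection order is, for each ring X
in A, B, C, D: ``NX, C1X, C2X, C3X, C4X``; followed by the four methine
carbons -- 24 atoms per monomer, 48 per dimer.  The central metal is
never part of the selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ChlorinTemplate",
    "TetrapyrroleSelection",
    "TETRAPYRROLE_ATOM_ORDER",
    "BONDI_RADII",
    "load_structure",
    "write_structure",
    "build_ideal_chlorin",
    "select_tetrapyrrole",
    "compute_sasa",
    "ligand_burial",
    "concentration_from_absorbance",
]

# Bondi van der Waals radii (A); 1.7 fallback for unlisted elements
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "FE": 1.80, "NA": 2.27, "K": 2.75,
}


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element.strip().upper(), 1.70)


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    radius: float | None = None
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.radius is None:
            self.radius = vdw_radius(self.element)
        if not (self.radius > 0):
            raise ValueError(f"non-positive vdW radius for atom {self.name}")


@dataclass
class Residue:
    name: str
    seqid: int
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.seqid} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seqid for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"residue indices not strictly increasing in chain {self.chain_id}")


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain identifiers must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def all_atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.all_atoms()])


def load_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    First altloc kept; first model only; coordinates in Angstrom.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb")
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path} as {fmt}: {exc}") from exc
    st.remove_alternative_conformations()  # keep first altloc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        for res in ch:
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                )
                for at in res
            ]
            residues.append(
                Residue(res.name, res.seqid.num, atoms, hetero=res.het_flag == "H")
            )
        if residues:
            chains.append(Chain(ch.name, residues))
    structure = Structure(chains)
    if not structure.all_atoms():
        raise ValueError(f"{path}: structure contains no atoms")
    return structure


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> None:
    """Write PDB or mmCIF. Chlorin/metal (hetero) residues become HETATM records."""
    import gemmi

    path = Path(path)
    fmt = format or ("mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb")
    st = gemmi.Structure()
    st.name = "specpair"
    model = gemmi.Model("1")
    for chain in structure.chains:
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
                a.occ = atom.occupancy
                a.b_iso = atom.b_factor
                r.add_atom(a)
            ch.add_residue(r)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    elif fmt == "pdb":
        st.write_pdb(str(path))
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# Ideal chlorin template

_RINGS = ("A", "B", "C", "D")

TETRAPYRROLE_ATOM_ORDER: tuple[str, ...] = tuple(
    name for X in _RINGS for name in (f"N{X}", f"C1{X}", f"C2{X}", f"C3{X}", f"C4{X}")
) + tuple(f"CH{X}" for X in _RINGS)


@dataclass
class ChlorinTemplate:
    """Idealized planar metal-chlorin macrocycle.

    ``ring_atoms`` hold the 24 tetrapyrrole atoms in the canonical order;
    ``qy_axis`` is the in-plane unit vector of the Qy transition dipole
    (default convention: through the NA-NC nitrogen pair).
    """

    ring_atoms: list[Atom]
    metal: Atom
    qy_axis: np.ndarray
    substituent_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.qy_axis = np.asarray(self.qy_axis, dtype=float).reshape(3)
        n_n = sum(1 for a in self.ring_atoms if a.element == "N")
        n_c = sum(1 for a in self.ring_atoms if a.element == "C")
        if len(self.ring_atoms) != 24 or n_n != 4 or n_c != 20:
            raise ValueError("ring_atoms must contain 4 N and 20 C (24 atoms)")

    def ring_coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.ring_atoms])

    def ring_center(self) -> np.ndarray:
        return self.ring_coordinates().mean(axis=0)

    def ring_normal(self) -> np.ndarray:
        """Unit normal of the best-fit ring plane (SVD), sign toward +z of build frame."""
        coords = self.ring_coordinates()
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        return vt[2]

    def all_atoms(self) -> list[Atom]:
        return [*self.ring_atoms, self.metal, *self.substituent_atoms]

    def transformed(self, t: RigidTransform) -> "ChlorinTemplate":
        def move(atom: Atom) -> Atom:
            return replace(atom, position=t.apply(atom.position))

        return ChlorinTemplate(
            ring_atoms=[move(a) for a in self.ring_atoms],
            metal=move(self.metal),
            qy_axis=t.rotation @ self.qy_axis,
            substituent_atoms=[move(a) for a in self.substituent_atoms],
        )

    def to_residue(self, name: str = "CLA", seqid: int = 1) -> Residue:
        atoms = [replace(a, position=a.position.copy()) for a in (*self.ring_atoms, self.metal)]
        return Residue(name, seqid, atoms, hetero=True)


def build_ideal_chlorin(metal: str = "Zn", qy_convention: str = "NA-NC") -> ChlorinTemplate:
    """Construct a planar, four-fold symmetric metal-chlorin macrocycle.

    Pyrrole nitrogens sit at 90-degree intervals 2.05 A from the metal
    (origin); each pyrrole is a regular pentagon with 1.40 A sides; methine
    carbons bridge adjacent pyrroles with 1.40 A bonds.  The ring lies in
    the z=0 plane, so the ring normal is +z.
    """
    metal = metal.capitalize()
    if metal not in {"Zn", "Mg"}:
        raise ValueError(f"unsupported metal {metal!r} (expected Zn or Mg)")

    metal_n = 2.05  # metal-nitrogen distance, A
    side = 1.40  # pyrrole C-C / C-N bond length, A
    circum = side / (2.0 * math.sin(math.pi / 5.0))  # pentagon circumradius
    pent_center_r = metal_n + circum

    ring_atoms: list[Atom] = []
    ring_dirs = {}
    for k, X in enumerate(_RINGS):
        phi = math.radians(90.0 * k)  # ring A at +x, B at +y, C at -x, D at -y
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        v = np.array([-math.sin(phi), math.cos(phi), 0.0])
        ring_dirs[X] = u
        center = pent_center_r * u
        # pentagon vertices: N points toward the metal (angle 180 deg from u)
        names = (f"N{X}", f"C1{X}", f"C2{X}", f"C3{X}", f"C4{X}")
        # vertex angular offsets (deg) around the pentagon center, N at 180
        offsets = {f"N{X}": 180.0, f"C1{X}": 180.0 - 72.0, f"C4{X}": 180.0 + 72.0,
                   f"C2{X}": 180.0 - 144.0, f"C3{X}": 180.0 + 144.0}
        for nm in names:
            ang = math.radians(offsets[nm])
            pos = center + circum * (math.cos(ang) * u + math.sin(ang) * v)
            ring_atoms.append(Atom(nm, "N" if nm.startswith("N") else "C", pos))

    by_name = {a.name: a for a in ring_atoms}
    # methine CHX bridges C1 of ring X and C4 of the next ring, on the bisector
    for k, X in enumerate(_RINGS):
        Y = _RINGS[(k + 1) % 4]
        p1 = by_name[f"C1{X}"].position
        p2 = by_name[f"C4{Y}"].position
        mid = 0.5 * (p1 + p2)
        u = mid / np.linalg.norm(mid)
        half = 0.5 * np.linalg.norm(p2 - p1)
        if half >= side:
            raise RuntimeError("inconsistent macrocycle geometry")
        out = math.sqrt(side**2 - half**2)
        pos = mid + out * u
        ring_atoms.append(Atom(f"CH{X}", "C", pos))

    order = {nm: i for i, nm in enumerate(TETRAPYRROLE_ATOM_ORDER)}
    ring_atoms.sort(key=lambda a: order[a.name])

    if qy_convention == "NA-NC":
        qy = by_name["NC"].position - by_name["NA"].position
    elif qy_convention == "NB-ND":
        qy = by_name["ND"].position - by_name["NB"].position
    else:
        raise ValueError(f"unknown qy_convention {qy_convention!r}")
    qy = qy / np.linalg.norm(qy)

    metal_atom = Atom(metal.upper(), metal, np.zeros(3))
    return ChlorinTemplate(ring_atoms=ring_atoms, metal=metal_atom, qy_axis=qy)


@dataclass
class TetrapyrroleSelection:
    """Ordered ring-atom coordinates (24 per monomer) with provenance labels."""

    atom_positions: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float)
        n = len(self.atom_positions)
        if n % 24 != 0 or n == 0:
            raise ValueError("selection size must be a positive multiple of 24")
        if len(self.labels) != n:
            raise ValueError("labels must match atom count")

    @property
    def n_monomers(self) -> int:
        return len(self.atom_positions) // 24


def select_tetrapyrrole(
    structure: Structure,
    chlorin_residues: list[tuple[str, int]],
    name_map: dict[str, str] | None = None,
) -> TetrapyrroleSelection:
    """Extract the 24 tetrapyrrole ring atoms per chlorin residue, in canonical order.

    ``chlorin_residues`` is a list of (chain_id, seqid).  ``name_map``
    translates canonical ring-atom names to the names used in the file
    (some depositions name ring atoms differently); metals are excluded.
    """
    positions = []
    labels = []
    for chain_id, seqid in chlorin_residues:
        chain = structure.chain(chain_id)
        res = next((r for r in chain.residues if r.seqid == seqid), None)
        if res is None:
            raise KeyError(f"no residue {seqid} in chain {chain_id}")
        for canonical in TETRAPYRROLE_ATOM_ORDER:
            actual = (name_map or {}).get(canonical, canonical)
            if not res.has_atom(actual):
                raise KeyError(
                    f"residue {res.name} {chain_id}:{seqid} is missing ring atom "
                    f"{actual!r} (canonical {canonical!r})"
                )
            positions.append(res.atom(actual).position)
            labels.append(f"{chain_id}:{seqid}:{canonical}")
    return TetrapyrroleSelection(np.array(positions), labels)


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley via biotite) and Beer-Lambert


def compute_sasa(
    atoms: list[Atom], probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Deterministic for a fixed Fibonacci point set; total SASA is the sum
    of the returned per-atom areas.
    """
    import biotite.structure as struc

    if not atoms:
        raise ValueError("empty atom set")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.position for a in atoms], dtype=np.float32)
    arr.element = np.array([a.element.upper() for a in atoms], dtype="U2")
    arr.atom_name = np.array([a.name for a in atoms], dtype="U6")
    arr.res_name = np.full(len(atoms), "LIG", dtype="U5")
    arr.res_id = np.ones(len(atoms), dtype=int)
    arr.chain_id = np.full(len(atoms), "A", dtype="U4")
    radii = np.array([a.radius for a in atoms], dtype=np.float64)
    areas = struc.sasa(
        arr,
        probe_radius=probe_radius,
        ignore_ions=False,
        point_number=n_points,
        vdw_radii=radii,
    )
    return np.asarray(areas, dtype=float)


def ligand_burial(
    ligand_atoms: list[Atom],
    complex_atoms: list[Atom],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Fraction of ligand SASA buried in the complex (the DSasa design filter).

    Ligand atoms are matched to complex atoms by coordinates; they must be
    a subset of the complex.
    """
    free = compute_sasa(ligand_atoms, probe_radius, n_points)
    sasa_free = float(free.sum())
    if sasa_free <= 0:
        raise ValueError("ligand has zero free SASA")
    complex_coords = np.array([a.position for a in complex_atoms])
    lig_idx = []
    for a in ligand_atoms:
        d2 = np.sum((complex_coords - a.position) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] > 1e-12:
            raise ValueError(f"ligand atom {a.name} not found in complex")
        lig_idx.append(j)
    in_complex = compute_sasa(complex_atoms, probe_radius, n_points)
    sasa_bound = float(in_complex[lig_idx].sum())
    return (sasa_free - sasa_bound) / sasa_free


def concentration_from_absorbance(
    absorbance: float, epsilon: float, path: float = 1.0
) -> float:
    """Beer-Lambert: molar concentration c = A / (epsilon * l)."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if epsilon <= 0 or path <= 0:
        raise ValueError("epsilon and path length must be positive")
    return absorbance / (epsilon * path)
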