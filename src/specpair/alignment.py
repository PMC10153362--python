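"""Pairwise special-pair structural comparison.

Chlorin-dimer geometries are compared on the 24 tetrapyrrole ring atoms
per monomer (48 per dimer): ring substituents and the central metal are
excluded, which ignores rotameric differences of peripheral groups and
Mg-vs-Zn placement.  The monomer pairing ambiguity (which chlorin of one
dimer maps to which of the other) is resolved by trying both assignments
and reporting the smaller RMSD; the in-plane ring correspondence is fixed
by chemical identity (ring A-D labels), never by geometric search.
"""

from __future__ import annotations

import numpy as np

from .chem import TetrapyrroleSelection
from .geometry import RigidTransform, kabsch

__all__ = ["compare_pairs", "compare_selections"]


def compare_selections(
    sel1: TetrapyrroleSelection, sel2: TetrapyrroleSelection
) -> tuple[float, RigidTransform]:
    """48-atom tetrapyrrole RMSD between two chlorin dimers (or 24-atom monomers).

    Returns (rmsd, transform mapping sel1 onto sel2).  For dimers both
    monomer assignments are tried and the minimum reported.
    """
    p = sel1.atom_positions
    q = sel2.atom_positions
    if len(p) != len(q):
        raise ValueError("selections must have equal atom counts")
    if len(p) not in (24, 48):
        raise ValueError("expected a chlorin monomer (24 atoms) or dimer (48)")
    if len(p) == 24:
        t, r = kabsch(p, q)
        return r, t
    swapped = np.vstack([q[24:], q[:24]])
    t1, r1 = kabsch(p, q)
    t2, r2 = kabsch(p, swapped)
    return (r1, t1) if r1 <= r2 else (r2, t2)


def compare_pairs(
    structure1,
    selection1: list[tuple[str, int]],
    structure2,
    selection2: list[tuple[str, int]],
    name_map1: dict[str, str] | None = None,
    name_map2: dict[str, str] | None = None,
) -> tuple[float, RigidTransform]:
    """Tetrapyrrole RMSD between chlorin dimers of two structures.

    ``selection*`` are lists of (chain_id, seqid) of the chlorin residues
    (two per structure for a dimer comparison).
    """
    from .chem import select_tetrapyrrole

    s1 = select_tetrapyrrole(structure1, selection1, name_map1)
    s2 = select_tetrapyrrole(structure2, selection2, name_map2)
    return compare_selections(s1, s2)
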