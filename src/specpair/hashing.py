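"""6-D rigid-transform hashing for motif lookup.

The relative transform between the N-CA-C frames of the two ligating
histidines is discretized into an integer key of a multi-value hash
table; the value is a compact record from which the full His-chlorin
complex is rebuilt.  Binning is half-open (``floor(x / bin)``) on the
three translation components and on intrinsic z-y-x Euler angles of the
rotation, so bin-boundary false negatives are possible by construction;
an optional neighbour-cell query over the 27 adjacent translation cells
mitigates this (off by default).

Key packing: the six bin indices are packed into one 64-bit integer with
fixed field widths (translation 3 x 12 bits, Euler angles 3 x 9 bits);
out-of-range translations yield the ``OUT_OF_RANGE`` sentinel rather
than wrapping around.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, transform_between
from .motif import HisChlMotif, rebuild_motif

__all__ = [
    "BinSpec",
    "MotifRecord",
    "TransformHashTable",
    "OUT_OF_RANGE",
    "hash_transform",
    "build_table",
    "query",
]

OUT_OF_RANGE = -1

_T_BITS = 12  # signed translation bins per axis
_A_BITS = 9   # Euler-angle bins per axis


@dataclass(frozen=True)
class BinSpec:
    """Bin widths of the 6-D discretization (A and degrees), half-open cells."""

    translation_bin: float = 1.0
    rotation_bin: float = 15.0
    scheme: str = "euler_zyx"
    translation_range: float = 512.0  # |t| per axis beyond which keys are out of range

    def __post_init__(self) -> None:
        if self.translation_bin <= 0 or self.rotation_bin <= 0:
            raise ValueError("bin widths must be positive")
        if self.scheme != "euler_zyx":
            raise ValueError(f"unknown binning scheme {self.scheme!r}")


@dataclass(frozen=True)
class MotifRecord:
    """Compact motif rebuild record stored as a hash-table value."""

    ligation_nitrogen: str
    chi1: float
    chi2: float
    ligation_dihedral: float
    metal_his_distance: float
    geometry: dict
    metal: str = "Zn"

    def rebuild(self) -> HisChlMotif:
        return rebuild_motif(
            {
                "ligation_nitrogen": self.ligation_nitrogen,
                "chi1": self.chi1,
                "chi2": self.chi2,
                "ligation_dihedral": self.ligation_dihedral,
                "metal_his_distance": self.metal_his_distance,
                "geometry": dict(self.geometry),
                "metal": self.metal,
            }
        )

    @classmethod
    def from_motif(cls, m: HisChlMotif) -> "MotifRecord":
        p = m.build_params()
        return cls(
            ligation_nitrogen=p["ligation_nitrogen"],
            chi1=p["chi1"],
            chi2=p["chi2"],
            ligation_dihedral=p["ligation_dihedral"],
            metal_his_distance=p["metal_his_distance"],
            geometry=tuple(sorted(p["geometry"].items())),
            metal=p["metal"],
        )


def _bin_indices(t: RigidTransform, bins: BinSpec) -> tuple[int, ...] | None:
    trans = t.translation
    if np.any(np.abs(trans) >= bins.translation_range):
        return None
    t_idx = tuple(int(math.floor(x / bins.translation_bin)) for x in trans)
    # intrinsic z-y-x Euler angles in degrees: yaw/roll in [-180, 180), pitch in [-90, 90]
    ang = Rotation.from_matrix(t.rotation).as_euler("ZYX", degrees=True)
    a_idx = tuple(int(math.floor(a / bins.rotation_bin)) for a in ang)
    return t_idx + a_idx


def _pack(indices: tuple[int, ...]) -> int:
    key = 0
    for idx, bits in zip(indices, (_T_BITS,) * 3 + (_A_BITS,) * 3):
        lo, hi = -(1 << (bits - 1)), (1 << (bits - 1)) - 1
        if not (lo <= idx <= hi):
            return OUT_OF_RANGE
        key = (key << bits) | (idx - lo)
    return key


def hash_transform(t: RigidTransform, bins: BinSpec) -> int:
    """Deterministic 64-bit key of a binned 6-D transform (or OUT_OF_RANGE)."""
    indices = _bin_indices(t, bins)
    if indices is None:
        return OUT_OF_RANGE
    return _pack(indices)


@dataclass
class TransformHashTable:
    """Multi-value map from binned His-pair transforms to motif rebuild records."""

    bins: BinSpec = field(default_factory=BinSpec)
    _table: dict[int, list[MotifRecord]] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self._table.values())

    @property
    def n_keys(self) -> int:
        return len(self._table)

    def insert(self, t: RigidTransform, record: MotifRecord) -> int:
        key = hash_transform(t, self.bins)
        if key == OUT_OF_RANGE:
            raise ValueError("transform translation outside configured range")
        self._table.setdefault(key, []).append(record)
        return key

    def query(self, t: RigidTransform, neighbor_cells: bool = False) -> list[MotifRecord]:
        """Records stored under this transform's bin (insertion order).

        With ``neighbor_cells=True`` the 27 adjacent translation cells are
        also searched, mitigating bin-boundary false negatives.
        """
        indices = _bin_indices(t, self.bins)
        if indices is None:
            return []
        if not neighbor_cells:
            return list(self._table.get(_pack(indices), []))
        out: list[MotifRecord] = []
        for d in itertools.product((-1, 0, 1), repeat=3):
            shifted = tuple(i + di for i, di in zip(indices[:3], d)) + indices[3:]
            out.extend(self._table.get(_pack(shifted), []))
        return out

    def save(self, path: str | Path) -> None:
        doc = {
            "binspec": asdict(self.bins),
            "entries": [
                {"key": k, "records": [asdict(r) for r in recs]}
                for k, recs in self._table.items()
            ],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "TransformHashTable":
        doc = json.loads(Path(path).read_text())
        bins = BinSpec(**doc["binspec"])
        table = cls(bins=bins)
        for entry in doc["entries"]:
            recs = []
            for r in entry["records"]:
                r = dict(r)
                r["geometry"] = tuple(tuple(kv) for kv in r["geometry"])
                recs.append(MotifRecord(**r))
            table._table[int(entry["key"])] = recs
        return table


def build_table(motifs: list[HisChlMotif], bins: BinSpec | None = None) -> TransformHashTable:
    """Hash every motif's His-pair transform into a multi-value table."""
    if not motifs:
        raise ValueError("motif list is empty")
    table = TransformHashTable(bins=bins or BinSpec())
    for m in motifs:
        t = transform_between(m.his1_frame(), m.his2_frame())
        table.insert(t, MotifRecord.from_motif(m))
    return table


def query(table: TransformHashTable, t: RigidTransform, **kw) -> list[MotifRecord]:
    return table.query(t, **kw)
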