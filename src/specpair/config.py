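"""Structured run configuration shared by the command-line tools.

A config file is a JSON document; unknown keys are rejected so typos
fail loudly.  Every default is owned by one module and mirrored here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

__all__ = ["RunConfig"]

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    """Tool-wide defaults (module owner in the trailing comment)."""

    version: int = CONFIG_VERSION
    seed: int = 0
    translation_bin: float = 1.0        # hashing: translation bin width, A
    rotation_bin: float = 15.0          # hashing: Euler-angle bin width, deg
    motif_clash_cutoff: float = 2.8     # motif: inter-half heavy-atom cutoff, A
    backbone_clash_cutoff: float = 2.5  # matching: ligand-backbone cutoff, A
    metal_his_distance: float = 2.1     # motif: axial metal-N(His) bond, A
    probe_radius: float = 1.4           # chem: SASA probe radius, A
    sasa_points: int = 960              # chem: Shrake-Rupley sphere points
    qy_dipole_debye: float = 4.6        # exciton: Qy transition dipole, D
    qy_site_nm: float = 669.0           # exciton: monomer Qy band position, nm
    fwhm_q: float = 350.0               # exciton: Q-band Gaussian FWHM, cm^-1
    fwhm_soret: float = 1150.0          # exciton: Soret Gaussian FWHM, cm^-1
    global_shift_ev: float = -0.25      # exciton: empirical spectral shift, eV
    screening: float = 1.0              # exciton: coupling screening factor
    cage_contact_cutoff: float = 8.0    # cage: backbone contact distance, A
    cage_area_bounds: tuple[float, float] = (1000.0, 1600.0)  # cage: interface SASA, A^2

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cage_area_bounds" in doc:
            doc["cage_area_bounds"] = tuple(doc["cage_area_bounds"])
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
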