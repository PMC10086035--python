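"""In-memory containers for atomistic structures and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AtomisticStructure:
    """An all-atom structure: positions plus per-atom physical properties.

    Positions are in Angstrom, masses in amu, charges in elementary charge
    units.  Atom ids are implicit: atom ``i`` is row ``i`` of every array.
    """

    positions: np.ndarray          # (n, 3) float64, A
    masses: np.ndarray             # (n,) amu
    charges: np.ndarray            # (n,) e
    vdw_radii: np.ndarray          # (n,) A
    hydrophobic: np.ndarray        # (n,) bool
    names: np.ndarray = None       # (n,) str
    residue_ids: np.ndarray = None  # (n,) int
    chain_ids: np.ndarray = None   # (n,) str
    elements: np.ndarray = None    # (n,) str

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        n = len(self.positions)
        if n == 0:
            raise ValueError("empty structure: no atoms")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.charges = np.asarray(self.charges, dtype=np.float64)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=np.float64)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        for arr, fill in (("names", "X"), ("chain_ids", "A"), ("elements", "C")):
            if getattr(self, arr) is None:
                setattr(self, arr, np.full(n, fill, dtype=object))
            else:
                setattr(self, arr, np.asarray(getattr(self, arr), dtype=object))
        if self.residue_ids is None:
            self.residue_ids = np.zeros(n, dtype=np.int64)
        else:
            self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        for name in ("masses", "charges", "vdw_radii", "hydrophobic",
                     "names", "residue_ids", "chain_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != n_atoms {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class Trajectory:
    """Frames of particle positions aligned to a structure's atom/bead ids."""

    xyz: np.ndarray                # (n_frames, n_particles, 3) A
    timestep_ps: float = 0.0       # frame stride metadata

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"trajectory must be (n_frames, n, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_particles(self) -> int:
        return self.xyz.shape[1]
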