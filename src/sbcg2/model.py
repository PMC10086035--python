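"""Coarse-grained model containers: beads, topology and harmonic parameters.

Harmonic terms follow the CHARMM convention U = K (x - x0)^2 (no 1/2), with
bond K in kcal mol^-1 A^-2 and angle K in kcal mol^-1 rad^-2.  The force
constant of every term is tied to the displacement variance it came from by
Boltzmann inversion, K = kB*T / (2*D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB


def _base36(i: int) -> str:
    digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i == 0:
        return "0"
    out = ""
    while i:
        i, r = divmod(i, 36)
        out = digits[r] + out
    return out


def bead_type_label(index: int) -> str:
    """Default per-bead CHARMM atom type: every bead gets its own type."""
    return "B" + _base36(index)


@dataclass
class CGBead:
    """One CG bead and the atomic domain (Voronoi cell) it represents."""

    position: np.ndarray       # (3,) A, mass-weighted COM of its domain
    mass: float                # amu
    charge: float              # e
    lj_epsilon: float = 0.0    # kcal/mol
    radius: float = 0.0        # A, radius of gyration of the domain
    domain: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    type_label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.domain = np.asarray(self.domain, dtype=np.int64)
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")
        if self.radius < 0:
            raise ValueError("bead radius must be non-negative")


@dataclass
class CGModel:
    """Beads plus the bond/angle topology connecting them.

    Bonds are stored as sorted unique pairs (i < j); angles as triples
    (i, j, k) with j the vertex and i < k.
    """

    beads: list
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    eps_max: float = 0.0

    def __post_init__(self):
        self.bonds = [self._norm_bond(b) for b in self.bonds]
        if len(set(self.bonds)) != len(self.bonds):
            raise ValueError("duplicate bonds")
        self.angles = [self._norm_angle(a) for a in self.angles]
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("duplicate angles")
        bond_set = set(self.bonds)
        for (i, j, k) in self.angles:
            if self._norm_bond((i, j)) not in bond_set or self._norm_bond((j, k)) not in bond_set:
                raise ValueError(f"angle ({i},{j},{k}) flanks are not both bonds")

    @staticmethod
    def _norm_bond(b):
        i, j = int(b[0]), int(b[1])
        if i == j:
            raise ValueError("self-bond")
        return (i, j) if i < j else (j, i)

    @staticmethod
    def _norm_angle(a):
        i, j, k = int(a[0]), int(a[1]), int(a[2])
        if len({i, j, k}) != 3:
            raise ValueError("degenerate angle")
        return (i, j, k) if i < k else (k, j, i)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=np.float64)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=np.float64)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=np.float64)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads], dtype=np.float64)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([b.lj_epsilon for b in self.beads], dtype=np.float64)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def type_labels(self) -> list:
        return [b.type_label or bead_type_label(i) for i, b in enumerate(self.beads)]


@dataclass
class BondParam:
    k: float          # kcal mol^-1 A^-2
    b0: float         # A, equilibrium = <r>
    variance: float = 0.0   # A^2, the D it came from


@dataclass
class AngleParam:
    k: float          # kcal mol^-1 rad^-2
    theta0: float     # rad, equilibrium = <theta>
    variance: float = 0.0   # rad^2


@dataclass
class ParameterSet:
    """Per-term harmonic parameters keyed by bead-index tuples."""

    bonds: dict = field(default_factory=dict)     # (i,j) -> BondParam
    angles: dict = field(default_factory=dict)    # (i,j,k) -> AngleParam
    temperature: float = 298.0

    def __post_init__(self):
        for p in list(self.bonds.values()) + list(self.angles.values()):
            if p.k <= 0:
                raise ValueError("force constants must be positive")

    @property
    def kB(self) -> float:
        return KB

    def covers(self, model: CGModel) -> bool:
        return (all(b in self.bonds for b in model.bonds)
                and all(a in self.angles for a in model.angles))

    def missing_terms(self, model: CGModel) -> list:
        out = [("bond", b) for b in model.bonds if b not in self.bonds]
        out += [("angle", a) for a in model.angles if a not in self.angles]
        return out
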