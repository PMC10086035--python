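"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical features the method cares about —
compact protein-like point clouds with masses, zero-sum partial charges and
a hydrophobicity label; multi-copy rigid assemblies of an identical subunit;
equilibrium harmonic bond/angle samples with exactly known force constants;
and random voxel grids.  They make no attempt at realistic protein geometry
(no rotamers, no secondary structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .model import CGModel, ParameterSet
from .structure import AtomisticStructure, Trajectory
from .grid import VolumetricGrid

_SHAPES = ("blob", "two-domain", "helix-like")


@dataclass
class FixtureSpec:
    n_atoms: int
    shape: str = "blob"
    charge_scale: float = 0.25      # e
    hydrophobic_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if not 0 <= self.hydrophobic_fraction <= 1:
            raise ValueError("hydrophobic fraction must be in [0, 1]")


def make_structure(spec: FixtureSpec) -> AtomisticStructure:
    """Generate a protein-like atom cloud; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    if spec.shape == "blob":
        positions = rng.normal(0.0, 10.0, size=(n, 3))
    elif spec.shape == "two-domain":
        # two isotropic Gaussians with centers 20 A apart, compact enough
        # that the within/between-domain distance modes stay separable
        centers = np.array([[-10.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        which = rng.integers(0, 2, size=n)
        positions = centers[which] + rng.normal(0.0, 3.0, size=(n, 3))
    else:  # helix-like: points on a helix of radius 8 A, pitch 15 A/turn
        t = np.linspace(0.0, 4.0 * np.pi, n)
        positions = np.column_stack([
            8.0 * np.cos(t), 8.0 * np.sin(t), 15.0 * t / (2.0 * np.pi),
        ]) + rng.normal(0.0, 1.0, size=(n, 3))

    masses = rng.uniform(12.0, 32.0, size=n)
    if spec.charge_scale > 0:
        charges = rng.normal(0.0, spec.charge_scale, size=n)
        charges -= charges.mean()        # zero-sum by construction
    else:
        charges = np.zeros(n)
    hydrophobic = rng.random(n) < spec.hydrophobic_fraction
    elements = np.where(hydrophobic, "C", "N").astype(object)
    radii = np.where(hydrophobic, 1.70, 1.55)
    return AtomisticStructure(
        positions=positions, masses=masses, charges=charges,
        vdw_radii=radii, hydrophobic=hydrophobic,
        names=np.array([f"A{i % 100}" for i in range(n)], dtype=object),
        residue_ids=np.arange(n) // 4,
        elements=elements,
    )


def make_assembly(monomer: AtomisticStructure, transforms) -> AtomisticStructure:
    """Concatenate rigid copies of a monomer.

    ``transforms`` is a list of (R, t) pairs — a 3x3 rotation matrix and a
    translation vector — or 4x4 affine matrices.  Chain ids are relabeled
    per copy so subunits are distinguishable.
    """
    if len(transforms) < 1:
        raise ValueError("need at least one transform")
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    parts = []
    for c, tr in enumerate(transforms):
        if isinstance(tr, np.ndarray) and tr.shape == (4, 4):
            R, t = tr[:3, :3], tr[:3, 3]
        else:
            R, t = np.asarray(tr[0], dtype=float), np.asarray(tr[1], dtype=float)
        pos = monomer.positions @ R.T + t
        parts.append((pos, chains[c % len(chains)]))
    n = monomer.n_atoms
    k = len(transforms)
    return AtomisticStructure(
        positions=np.vstack([p for p, _ in parts]),
        masses=np.tile(monomer.masses, k),
        charges=np.tile(monomer.charges, k),
        vdw_radii=np.tile(monomer.vdw_radii, k),
        hydrophobic=np.tile(monomer.hydrophobic, k),
        names=np.tile(monomer.names, k),
        residue_ids=np.tile(monomer.residue_ids, k),
        chain_ids=np.concatenate([np.full(n, c, dtype=object) for _, c in parts]),
        elements=np.tile(monomer.elements, k),
    )


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix (unit-normalized axis)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _placement_order(n_beads: int, bonds):
    """BFS tree order over the bond graph; errors on cycles."""
    adjacency = {i: [] for i in range(n_beads)}
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    parent = {}
    order = []
    seen = set()
    for root in range(n_beads):
        if root in seen:
            continue
        parent[root] = None
        seen.add(root)
        queue = [root]
        while queue:
            u = queue.pop(0)
            order.append(u)
            for v in sorted(adjacency[u]):
                if v == parent[u]:
                    continue
                if v in seen:
                    raise ValueError("cyclic bond topology: exact harmonic "
                                     "sampling requires a tree (use cg_sim "
                                     "toy MD for cyclic models)")
                parent[v] = u
                seen.add(v)
                queue.append(v)
    return order, parent


def make_harmonic_trajectory(model: CGModel, true_params: ParameterSet,
                             T: float = 298.0, n_frames: int = 1000,
                             seed: int = 0) -> Trajectory:
    """Draw i.i.d. equilibrium frames of a harmonic tree topology.

    Each frame is built by sequential placement: every bond length is drawn
    Normal(b0, sqrt(kB*T/(2*K_b))) and every parameterized angle
    (grandparent, parent, child) is drawn Normal(theta0, sqrt(kB*T/(2*K_a)))
    with a uniform azimuth, so each term's Boltzmann target is exact and
    terms are uncoupled by construction.  Angle parameters that cannot be
    realized this way (e.g. between two children of the same parent) are an
    error.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    missing = true_params.missing_terms(model)
    if missing:
        raise ValueError(f"unparameterized terms: {missing[:3]}")
    order, parent = _placement_order(model.n_beads, model.bonds)

    controlled = set()
    for child in order:
        p = parent[child]
        g = parent.get(p) if p is not None else None
        if g is not None:
            a = (g, p, child) if g < child else (child, p, g)
            controlled.add(a)
    unrealizable = [a for a in true_params.angles if a not in controlled]
    if set(true_params.angles) and unrealizable:
        raise ValueError(
            f"angle terms not realizable by sequential placement: {unrealizable[:3]}")

    rng = np.random.default_rng(seed)
    n = model.n_beads
    xyz = np.zeros((n_frames, n, 3))
    bond_sd = {b: np.sqrt(KB * T / (2.0 * p.k)) for b, p in true_params.bonds.items()}
    angle_sd = {a: np.sqrt(KB * T / (2.0 * p.k)) for a, p in true_params.angles.items()}

    # vectorized over frames: every bead is placed for all frames at once
    for child in order:
        p = parent[child]
        if p is None:
            continue
        bkey = (p, child) if p < child else (child, p)
        bp = true_params.bonds[bkey]
        r = rng.normal(bp.b0, bond_sd[bkey], size=n_frames)
        g = parent.get(p)
        akey = None
        if g is not None:
            akey = (g, p, child) if g < child else (child, p, g)
            if akey not in true_params.angles:
                akey = None
        if akey is None:
            u = rng.normal(size=(n_frames, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            xyz[:, child] = xyz[:, p] + r[:, None] * u
        else:
            ap = true_params.angles[akey]
            theta = rng.normal(ap.theta0, angle_sd[akey], size=n_frames)
            phi = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
            axis = xyz[:, p] - xyz[:, g]
            axis /= np.linalg.norm(axis, axis=1, keepdims=True)
            # orthonormal frame around the parent-grandparent axis
            ref = np.where((np.abs(axis[:, 0]) > 0.9)[:, None],
                           [0.0, 1.0, 0.0], [1.0, 0.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(axis, e1)
            direction = (np.cos(np.pi - theta)[:, None] * axis
                         + np.sin(np.pi - theta)[:, None]
                         * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
            xyz[:, child] = xyz[:, p] + r[:, None] * direction
    return Trajectory(xyz=xyz)


def make_random_grid(counts=(32, 32, 32), w: float = 1.0, seed: int = 0,
                     origin=(0.0, 0.0, 0.0)) -> VolumetricGrid:
    """I.i.d. standard-normal voxels; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return VolumetricGrid(values=rng.standard_normal(tuple(counts)),
                          width=w, origin=np.asarray(origin, dtype=float))


def make_chain_model(n_beads: int, bond_length: float = 5.0,
                     mass: float = 60.0) -> CGModel:
    """A straight CG chain 0-1-...-(n-1): handy harmonic-test scaffold."""
    from .model import CGBead
    beads = [CGBead(position=np.array([bond_length * i, 0.0, 0.0]),
                    mass=mass, charge=0.0, radius=2.0,
                    domain=np.array([i]))
             for i in range(n_beads)]
    bonds = [(i, i + 1) for i in range(n_beads - 1)]
    angles = [(i, i + 1, i + 2) for i in range(n_beads - 2)]
    return CGModel(beads=beads, bonds=bonds, angles=angles)
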