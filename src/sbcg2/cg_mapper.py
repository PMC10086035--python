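"""Map atomistic properties onto a coarse-grained bead model.

Atoms are partitioned into the Voronoi cells of the converged bead
positions (each atom goes to its nearest bead).  Each bead then inherits
the summed mass and charge of its cell, a Lennard-Jones well depth derived
from the cell's hydrophobic fraction of solvent-accessible surface area,

    eps_j = eps_max * (sasa_hydrophobic / sasa_total)^2,

and a radius equal to the mass-weighted radius of gyration of the cell
about the bead position.  Bonds come from the learned TRN connectivity and
angles are enumerated exhaustively from the bonds.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .model import CGBead, CGModel, bead_type_label
from .structure import AtomisticStructure


def assign_cells(structure: AtomisticStructure, bead_positions) -> np.ndarray:
    """Nearest-bead (Voronoi) assignment; ties go to the lowest bead index."""
    bead_positions = np.atleast_2d(np.asarray(bead_positions, dtype=np.float64))
    if len(bead_positions) < 1:
        raise ValueError("need at least one bead position")
    # argmin returns the first (lowest-index) minimiser, which is the tie rule
    return cdist(structure.positions, bead_positions).argmin(axis=1)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def compute_sasa(structure: AtomisticStructure, probe_radius: float = 1.4,
                 n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    Each atom's accessible sphere (radius r_vdw + probe) is sampled with a
    golden-spiral point set; a point is exposed if it lies outside every
    neighbor's accessible sphere.  Area = exposed fraction * 4 pi R^2.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    pos = structure.positions
    radii = structure.vdw_radii + probe_radius
    n = len(pos)
    unit = _sphere_points(n_points)
    tree = cKDTree(pos)
    areas = np.empty(n)
    for i in range(n):
        pts = pos[i] + radii[i] * unit
        neighbors = np.array([j for j in
                              tree.query_ball_point(pos[i], radii[i] + radii.max())
                              if j != i], dtype=np.int64)
        if len(neighbors) == 0:
            areas[i] = 4.0 * np.pi * radii[i] ** 2
            continue
        d2 = cdist(pos[neighbors], pts, "sqeuclidean")
        exposed = np.all(d2 > (radii[neighbors] ** 2)[:, None], axis=0)
        areas[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def map_properties(structure: AtomisticStructure, assignment: np.ndarray,
                   eps_max: float = 0.5, sasa: np.ndarray = None,
                   probe_radius: float = 1.4, n_points: int = 960) -> list:
    """Build CG beads from a Voronoi assignment (one bead per cell).

    Mass and charge are conserved sums over each cell; position is the
    mass-weighted center of mass; the bead radius is the mass-weighted
    radius of gyration about that position.  ``sasa`` (per-atom areas on
    the *full* structure) is computed if not supplied.  Cells whose total
    SASA is zero (fully buried domains) get eps = 0.
    """
    assignment = np.asarray(assignment, dtype=np.int64)
    if len(assignment) != structure.n_atoms:
        raise ValueError("assignment must cover every atom")
    n_beads = int(assignment.max()) + 1
    counts = np.bincount(assignment, minlength=n_beads)
    if np.any(counts == 0):
        raise ValueError(f"empty Voronoi cell(s): {np.nonzero(counts == 0)[0].tolist()}")
    if sasa is None:
        sasa = compute_sasa(structure, probe_radius=probe_radius, n_points=n_points)

    beads = []
    for j in range(n_beads):
        cell = np.nonzero(assignment == j)[0]
        m = structure.masses[cell]
        com = (m[:, None] * structure.positions[cell]).sum(axis=0) / m.sum()
        dr2 = np.einsum("ij,ij->i", structure.positions[cell] - com,
                        structure.positions[cell] - com)
        r_gyr = float(np.sqrt((m * dr2).sum() / m.sum()))
        sasa_tot = float(sasa[cell].sum())
        sasa_hyd = float(sasa[cell][structure.hydrophobic[cell]].sum())
        eps = eps_max * (sasa_hyd / sasa_tot) ** 2 if sasa_tot > 0 else 0.0
        beads.append(CGBead(
            position=com, mass=float(m.sum()),
            charge=float(structure.charges[cell].sum()),
            lj_epsilon=eps, radius=r_gyr, domain=cell,
            type_label=bead_type_label(j),
        ))
    return beads


def build_topology(edges, beads, eps_max: float = 0.5) -> CGModel:
    """Bonds from learned edges; angles enumerated exhaustively.

    An angle (i, j, k) exists for every pair of bonds (i, j), (j, k) —
    i.e. all neighbor pairs around every vertex j.
    """
    bonds = sorted({(min(i, j), max(i, j)) for i, j in edges})
    neighbors = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    angles = []
    for j, nbrs in sorted(neighbors.items()):
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))
    return CGModel(beads=list(beads), bonds=bonds, angles=sorted(angles),
                   eps_max=eps_max)


def geometric_equilibria(model: CGModel):
    """Equilibrium bond lengths / vertex angles from the static geometry.

    Placeholders until Boltzmann inversion overwrites them with atomistic
    trajectory means.  Returns ({bond: b0}, {angle: theta0}).
    """
    pos = model.positions
    b0 = {(i, j): float(np.linalg.norm(pos[j] - pos[i])) for i, j in model.bonds}
    theta0 = {}
    for (i, j, k) in model.angles:
        a = pos[i] - pos[j]
        b = pos[k] - pos[j]
        c = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0)
        theta0[(i, j, k)] = float(np.arccos(c))
    return b0, theta0


def transfer_map(monomer_model: CGModel, monomer_structure: AtomisticStructure,
                 assembly_structure: AtomisticStructure) -> CGModel:
    """Copy a monomer's mapping, topology and properties onto each subunit.

    The assembly must be k identical copies of the monomer, concatenated in
    order; per-subunit bead positions are recomputed as the mass-weighted
    COM of the corresponding atom domains.  Inter-subunit bonds are never
    created.
    """
    n_mono = monomer_structure.n_atoms
    n_asm = assembly_structure.n_atoms
    if n_asm % n_mono != 0:
        raise ValueError(f"assembly atom count {n_asm} is not a multiple of "
                         f"monomer count {n_mono}")
    k = n_asm // n_mono
    for c in range(k):
        sl = slice(c * n_mono, (c + 1) * n_mono)
        names = assembly_structure.names[sl]
        resids = assembly_structure.residue_ids[sl]
        bad = np.nonzero((names != monomer_structure.names)
                         | (resids != monomer_structure.residue_ids))[0]
        if len(bad):
            i = int(bad[0])
            raise ValueError(
                f"subunit {c} mismatch at atom {i}: "
                f"{names[i]}/{resids[i]} != "
                f"{monomer_structure.names[i]}/{monomer_structure.residue_ids[i]}")

    nb = monomer_model.n_beads
    beads, bonds, angles = [], [], []
    for c in range(k):
        off_atoms = c * n_mono
        for j, bead in enumerate(monomer_model.beads):
            cell = bead.domain + off_atoms
            m = assembly_structure.masses[cell]
            com = (m[:, None] * assembly_structure.positions[cell]).sum(axis=0) / m.sum()
            beads.append(CGBead(
                position=com, mass=bead.mass, charge=bead.charge,
                lj_epsilon=bead.lj_epsilon, radius=bead.radius,
                domain=cell, type_label=bead.type_label or bead_type_label(j),
            ))
        bonds += [(i + c * nb, j + c * nb) for i, j in monomer_model.bonds]
        angles += [(i + c * nb, j + c * nb, kk + c * nb)
                   for i, j, kk in monomer_model.angles]
    return CGModel(beads=beads, bonds=bonds, angles=angles,
                   eps_max=monomer_model.eps_max)


def transfer_parameters(monomer_params, n_copies: int, n_beads: int):
    """Replicate a monomer ParameterSet across ``n_copies`` subunits."""
    from .model import ParameterSet, BondParam, AngleParam
    bonds, angles = {}, {}
    for c in range(n_copies):
        off = c * n_beads
        for (i, j), p in monomer_params.bonds.items():
            bonds[(i + off, j + off)] = BondParam(p.k, p.b0, p.variance)
        for (i, j, k), p in monomer_params.angles.items():
            angles[(i + off, j + off, k + off)] = AngleParam(p.k, p.theta0, p.variance)
    return ParameterSet(bonds=bonds, angles=angles,
                        temperature=monomer_params.temperature)


def add_site_beads(model: CGModel, positions, charge: float, radius: float,
                   mass: float, lj_epsilon: float = 0.0) -> CGModel:
    """Append unbonded cofactor/ion beads (e.g. an IP6 bead of -12 e, 5 A).

    Ion "clump" beads carry clump_size * unit charge and mass; the clump
    size is the caller's choice (default elsewhere: 5).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    if positions.size == 0:
        return model
    n0 = model.n_beads
    beads = list(model.beads)
    for s, p in enumerate(positions):
        beads.append(CGBead(position=p, mass=mass, charge=charge,
                            lj_epsilon=lj_epsilon, radius=radius,
                            domain=np.empty(0, dtype=np.int64),
                            type_label=bead_type_label(n0 + s)))
    return CGModel(beads=beads, bonds=list(model.bonds),
                   angles=list(model.angles), eps_max=model.eps_max)


def make_ion_clump_properties(unit_charge: float = 1.0, clump_size: int = 5,
                              ion_mass: float = 30.0):
    """Charge and mass of a clumped-ion bead: clump_size x the single ion."""
    return clump_size * unit_charge, clump_size * ion_mass
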