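"""Readers and writers for every on-disk format the pipeline touches.

PDB structures are parsed with biotite; trajectories are plain-text XYZ or
CHARMM-style binary DCD (via mdtraj's low-level reader); CG force fields are
CHARMM RTF/PRM text; volumetric maps are OpenDX scalar grids.

CG-specific PDB convention: bead radius is stored in the B-factor column and
bead charge in the occupancy column (the standard columns carry no meaning
for CG beads, so they are reused; this convention is our own).
"""

from __future__ import annotations

import math
import os

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .constants import ELEMENT_MASSES, ELEMENT_VDW, HYDROPHOBIC_ELEMENTS
from .grid import VolumetricGrid
from .model import CGBead, CGModel, BondParam, AngleParam, ParameterSet
from .structure import AtomisticStructure, Trajectory


# ---------------------------------------------------------------------------
# PDB structures


def read_charge_table(path) -> dict:
    """Two- or three-column whitespace table of partial charges.

    Lines are either ``atom_name charge`` or ``res_name atom_name charge``;
    '#' starts a comment.
    """
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 2:
                table[parts[0]] = float(parts[1])
            elif len(parts) == 3:
                table[(parts[0], parts[1])] = float(parts[2])
            else:
                raise ValueError(f"malformed charge-table line: {line!r}")
    return table


def read_structure(path, charge_table=None, hydrophobic_rule=None) -> AtomisticStructure:
    """Read an atomistic PDB file (ATOM/HETATM records, first altloc kept).

    Masses and vdW radii come from the element; charges from ``charge_table``
    (a path or a dict as returned by :func:`read_charge_table`) and default
    to zero.  ``hydrophobic_rule`` is a callable (element, res_name,
    atom_name) -> bool; the default flags carbon and sulfur.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pdb = PDBFile.read(path)
    try:
        arr = pdb.get_structure(model=1, altloc="first")
    except Exception as err:
        raise ValueError(f"no atoms parseable from {path}: {err}") from None
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in {path}")

    elements = np.array([e.upper() for e in arr.element], dtype=object)
    unknown = sorted({e for e in elements if e not in ELEMENT_MASSES})
    if unknown:
        raise ValueError(f"unknown element(s) {unknown}; extend the mass table")
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    radii = np.array([ELEMENT_VDW[e] for e in elements])

    if isinstance(charge_table, (str, os.PathLike)):
        charge_table = read_charge_table(charge_table)
    charges = np.zeros(len(elements))
    if charge_table:
        for i, (res, name) in enumerate(zip(arr.res_name, arr.atom_name)):
            if (res, name) in charge_table:
                charges[i] = charge_table[(res, name)]
            elif name in charge_table:
                charges[i] = charge_table[name]

    if hydrophobic_rule is None:
        hydrophobic = np.array([e in HYDROPHOBIC_ELEMENTS for e in elements])
    else:
        hydrophobic = np.array([
            bool(hydrophobic_rule(e, r, n))
            for e, r, n in zip(elements, arr.res_name, arr.atom_name)
        ])

    return AtomisticStructure(
        positions=arr.coord,
        masses=masses,
        charges=charges,
        vdw_radii=radii,
        hydrophobic=hydrophobic,
        names=arr.atom_name.astype(object),
        residue_ids=arr.res_id,
        chain_ids=arr.chain_id.astype(object),
        elements=elements,
    )


def write_cg_structure(model: CGModel, path) -> None:
    """Write one ATOM record per bead (radius -> B-factor, charge -> occupancy)."""
    if model.n_beads < 1:
        raise ValueError("cannot write an empty CG model")
    if model.n_beads > 99999:
        raise ValueError("more than 99,999 beads: PDB serial overflow "
                         "(assemblies this large are out of scope)")
    labels = model.type_labels()
    with open(path, "w") as fh:
        fh.write("REMARK   generated by sbcg2; B-factor = bead radius (A), "
                 "occupancy = bead charge (e)\n")
        for i, bead in enumerate(model.beads):
            x, y, z = bead.position
            name = labels[i][:4]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} CGB A{(i % 9999) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{bead.charge:6.2f}{bead.radius:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("END\n")


def read_cg_structure(path) -> CGModel:
    """Read a bead PDB written by :func:`write_cg_structure` (no topology)."""
    pdb = PDBFile.read(path)
    arr = pdb.get_structure(model=1, altloc="first",
                            extra_fields=["b_factor", "occupancy"])
    if arr.array_length() == 0:
        raise ValueError(f"no beads in {path}")
    beads = [
        CGBead(position=arr.coord[i], mass=1.0, charge=float(arr.occupancy[i]),
               radius=float(arr.b_factor[i]), type_label=str(arr.atom_name[i]))
        for i in range(arr.array_length())
    ]
    return CGModel(beads=beads)


# ---------------------------------------------------------------------------
# CHARMM topology (RTF) and parameter (PRM) files


def write_charmm_files(model: CGModel, params: ParameterSet, rtf_path, prm_path) -> None:
    """Emit a CHARMM-compatible RTF/PRM pair for a CG model.

    Each bead gets its own atom type (sub-nanometer models are heterogeneous),
    so every bond/angle term maps to exactly one typed parameter line.
    Harmonic convention is CHARMM's U = K (x - x0)^2; angle equilibria are
    written in degrees, force constants in kcal/mol/rad^2.
    """
    missing = params.missing_terms(model)
    if missing:
        kind, term = missing[0]
        raise ValueError(f"missing parameter for {kind} {term}")
    labels = model.type_labels()

    with open(rtf_path, "w") as fh:
        fh.write("* Coarse-grained topology generated by sbcg2\n*\n36  1\n\n")
        for i, bead in enumerate(model.beads):
            fh.write(f"MASS  {i + 1:5d} {labels[i]:<8s} {bead.mass:12.5f}\n")
        fh.write("\nRESI CGM  {:.3f}\n".format(model.total_charge))
        for i, bead in enumerate(model.beads):
            fh.write(f"ATOM {labels[i]:<8s} {labels[i]:<8s} {bead.charge:10.6f}\n")
        for (i, j) in model.bonds:
            fh.write(f"BOND {labels[i]:<8s} {labels[j]:<8s}\n")
        fh.write("\nEND\n")

    with open(prm_path, "w") as fh:
        fh.write("* Coarse-grained parameters generated by sbcg2\n*\n\nBONDS\n")
        for (i, j) in model.bonds:
            p = params.bonds[(i, j)]
            fh.write(f"{labels[i]:<8s} {labels[j]:<8s} {p.k:14.6f} {p.b0:12.6f}\n")
        fh.write("\nANGLES\n")
        for (i, j, k) in model.angles:
            p = params.angles[(i, j, k)]
            fh.write(f"{labels[i]:<8s} {labels[j]:<8s} {labels[k]:<8s} "
                     f"{p.k:14.6f} {math.degrees(p.theta0):12.6f}\n")
        fh.write("\nNONBONDED\n")
        for i, bead in enumerate(model.beads):
            # CHARMM convention: epsilon is written negative; Rmin/2 = radius
            fh.write(f"{labels[i]:<8s} 0.0 {-bead.lj_epsilon:14.6f} "
                     f"{bead.radius:12.6f}\n")
        fh.write("\nEND\n")


def read_charmm_prm(path, model: CGModel, temperature: float = 298.0) -> ParameterSet:
    """Parse a PRM written by :func:`write_charmm_files` back into a ParameterSet."""
    label_to_index = {lab: i for i, lab in enumerate(model.type_labels())}
    bonds, angles = {}, {}
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.split("!")[0].strip()
            if not line or line.startswith("*"):
                continue
            upper = line.upper()
            if upper in ("BONDS", "ANGLES", "NONBONDED", "END"):
                section = upper
                continue
            parts = line.split()
            if section == "BONDS":
                i, j = label_to_index[parts[0]], label_to_index[parts[1]]
                key = (i, j) if i < j else (j, i)
                bonds[key] = BondParam(k=float(parts[2]), b0=float(parts[3]))
            elif section == "ANGLES":
                i, j, k = (label_to_index[p] for p in parts[:3])
                key = (i, j, k) if i < k else (k, j, i)
                angles[key] = AngleParam(k=float(parts[3]),
                                         theta0=math.radians(float(parts[4])))
    return ParameterSet(bonds=bonds, angles=angles, temperature=temperature)


# ---------------------------------------------------------------------------
# Trajectories: XYZ (text) and DCD (binary, CHARMM-style)


def write_trajectory(traj: Trajectory, path) -> None:
    path = str(path)
    if path.endswith(".dcd"):
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(path, "w") as fh:
            fh.write(traj.xyz.astype(np.float32))
    else:
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_particles}\nframe {f}\n")
                for x, y, z in traj.xyz[f]:
                    fh.write(f"P {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(path, structure=None, n_particles: int = None) -> Trajectory:
    """Read XYZ or DCD; particle count must match ``structure`` if given."""
    path = str(path)
    if path.endswith(".dcd"):
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(path) as fh:
            xyz, _, _ = fh.read()
        xyz = np.asarray(xyz, dtype=np.float64)
    else:
        frames = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i].strip())
            coords = [list(map(float, lines[i + 2 + k].split()[1:4]))
                      for k in range(n)]
            frames.append(coords)
            i += 2 + n
        xyz = np.asarray(frames, dtype=np.float64)
    if xyz.ndim != 3:
        raise ValueError(f"no frames read from {path}")
    expect = None
    if structure is not None:
        expect = structure.n_atoms if hasattr(structure, "n_atoms") else structure.n_beads
    elif n_particles is not None:
        expect = n_particles
    if expect is not None and xyz.shape[1] != expect:
        raise ValueError(f"trajectory has {xyz.shape[1]} particles, expected {expect}")
    return Trajectory(xyz=xyz)


# ---------------------------------------------------------------------------
# OpenDX scalar maps (orthorhombic only)


def write_map(grid: VolumetricGrid, path) -> None:
    n1, n2, n3 = grid.counts
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar map written by sbcg2\n")
        fh.write(f"object 1 class gridpositions counts {n1} {n2} {n3}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.width:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {grid.width:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {grid.width:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {n1} {n2} {n3}\n")
        fh.write(f"object 3 class array type double rank 0 items {n1 * n2 * n3} data follows\n")
        flat = grid.values.reshape(-1)
        for start in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.9g}" for v in flat[start:start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_map(path) -> VolumetricGrid:
    counts = origin = None
    deltas = []
    data = []
    n_items = None
    reading = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if reading:
                if stripped and (stripped[0].isdigit() or stripped[0] in "+-."):
                    data.extend(float(t) for t in stripped.split())
                    if n_items is not None and len(data) >= n_items:
                        reading = False
                else:
                    reading = False
                continue
            if stripped.startswith("#") or not stripped:
                continue
            if "gridpositions" in stripped:
                counts = tuple(int(t) for t in stripped.split()[-3:])
            elif stripped.startswith("origin"):
                origin = np.array([float(t) for t in stripped.split()[1:4]])
            elif stripped.startswith("delta"):
                deltas.append([float(t) for t in stripped.split()[1:4]])
            elif "data follows" in stripped:
                n_items = int(stripped.split("items")[1].split()[0])
                reading = True
    if counts is None or origin is None or len(deltas) != 3:
        missing = ("origin" if origin is None else
                   "counts" if counts is None else "deltas")
        raise ValueError(f"malformed OpenDX file {path}: missing {missing}")
    deltas = np.asarray(deltas)
    if not np.allclose(deltas, np.diag(np.diag(deltas))):
        raise ValueError("non-orthorhombic OpenDX deltas are unsupported")
    diag = np.diag(deltas)
    if not np.allclose(diag, diag[0], rtol=1e-9):
        raise ValueError("anisotropic voxel widths are unsupported")
    values = np.asarray(data, dtype=np.float64)
    if len(values) != counts[0] * counts[1] * counts[2]:
        raise ValueError("OpenDX data length does not match counts")
    return VolumetricGrid(values=values.reshape(counts), width=float(diag[0]),
                          origin=origin)


# ---------------------------------------------------------------------------
# Full CG models as JSON (beads with domains + topology)


def save_model(model: CGModel, path) -> None:
    import json
    payload = {
        "eps_max": model.eps_max,
        "beads": [{
            "position": bead.position.tolist(),
            "mass": bead.mass, "charge": bead.charge,
            "lj_epsilon": bead.lj_epsilon, "radius": bead.radius,
            "domain": bead.domain.tolist(), "type_label": bead.type_label,
        } for bead in model.beads],
        "bonds": [list(b) for b in model.bonds],
        "angles": [list(a) for a in model.angles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> CGModel:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    beads = [CGBead(position=np.array(b["position"]), mass=b["mass"],
                    charge=b["charge"], lj_epsilon=b["lj_epsilon"],
                    radius=b["radius"], domain=np.array(b["domain"], dtype=np.int64),
                    type_label=b["type_label"])
             for b in payload["beads"]]
    return CGModel(beads=beads, bonds=[tuple(b) for b in payload["bonds"]],
                   angles=[tuple(a) for a in payload["angles"]],
                   eps_max=payload.get("eps_max", 0.0))


# ---------------------------------------------------------------------------
# FSC curves: two-column text (spatial frequency 1/A, zeta)


def write_fsc(curve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# spatial_frequency_invA  fsc\n")
        for f, z in zip(curve.frequencies, curve.zeta):
            fh.write(f"{f:.8f} {z:.8f}\n")


def write_edge_list(bonds, path) -> None:
    with open(path, "w") as fh:
        for i, j in bonds:
            fh.write(f"{i} {j}\n")


def read_edge_list(path) -> list:
    with open(path) as fh:
        return [tuple(int(t) for t in line.split()[:2])
                for line in fh if line.strip()]
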