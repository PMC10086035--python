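"""Bond/angle force constants by iterative Boltzmann inversion.

A harmonic term with CHARMM convention U = K (r - r0)^2 in a Boltzmann
ensemble at temperature T has displacement variance D = kB*T / (2K), so a
measured variance inverts to K = kB*T / (2D) with equilibrium value <r>.
Because bonds and angles are strongly coupled in sub-nanometer CG models,
the directly inverted constants do not reproduce the reference when
simulated; they are refined iteratively: simulate, re-invert, and move the
applied constants toward reproducing the reference set, scaled by
hyperparameters m (bonds) and n (angles).  Redundant angle degrees of
freedom are pruned first: for each bead only its strongest (highest
reference K) incident angle is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .constants import KB
from .model import AngleParam, BondParam, CGModel, ParameterSet
from .structure import Trajectory


def map_trajectory_to_cg(aa_traj: Trajectory, model: CGModel,
                         structure) -> Trajectory:
    """Per frame, place each bead at the mass-weighted COM of its domain."""
    n_beads = model.n_beads
    xyz = np.empty((aa_traj.n_frames, n_beads, 3))
    masses = structure.masses
    for j, bead in enumerate(model.beads):
        cell = bead.domain
        m = masses[cell]
        xyz[:, j, :] = np.einsum("fij,i->fj", aa_traj.xyz[:, cell, :], m) / m.sum()
    return Trajectory(xyz=xyz, timestep_ps=aa_traj.timestep_ps)


def measure_bonds(traj: Trajectory, bonds) -> dict:
    """Per-frame bond lengths (A), one array per bond."""
    out = {}
    for (i, j) in bonds:
        d = traj.xyz[:, j, :] - traj.xyz[:, i, :]
        out[(i, j)] = np.sqrt(np.einsum("fk,fk->f", d, d))
    return out


def measure_angles(traj: Trajectory, angles) -> dict:
    """Per-frame vertex angles (rad, in [0, pi]), one array per angle."""
    out = {}
    for (i, j, k) in angles:
        a = traj.xyz[:, i, :] - traj.xyz[:, j, :]
        b = traj.xyz[:, k, :] - traj.xyz[:, j, :]
        cos = np.einsum("fk,fk->f", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        out[(i, j, k)] = np.arccos(np.clip(cos, -1.0, 1.0))
    return out


def boltzmann_invert(cg_traj: Trajectory, model: CGModel,
                     T: float = 298.0) -> ParameterSet:
    """Invert per-term displacement variances into harmonic force constants."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if cg_traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a variance")
    bonds, angles = {}, {}
    degenerate = []
    for key, samples in measure_bonds(cg_traj, model.bonds).items():
        D = float(samples.var())
        if D == 0.0:
            degenerate.append(("bond", key))
            continue
        bonds[key] = BondParam(k=KB * T / (2.0 * D), b0=float(samples.mean()),
                               variance=D)
    for key, samples in measure_angles(cg_traj, model.angles).items():
        D = float(samples.var())
        if D == 0.0:
            degenerate.append(("angle", key))
            continue
        angles[key] = AngleParam(k=KB * T / (2.0 * D),
                                 theta0=float(samples.mean()), variance=D)
    if degenerate:
        raise ValueError(f"degenerate (frozen) terms with zero variance: {degenerate}")
    return ParameterSet(bonds=bonds, angles=angles, temperature=T)


def rmse(params: ParameterSet, reference: ParameterSet):
    """(bond RMSE, angle RMSE) of force constants over matched terms."""
    db = [params.bonds[k].k - reference.bonds[k].k
          for k in params.bonds if k in reference.bonds]
    da = [params.angles[k].k - reference.angles[k].k
          for k in params.angles if k in reference.angles]
    bond_rmse = float(np.sqrt(np.mean(np.square(db)))) if db else 0.0
    angle_rmse = float(np.sqrt(np.mean(np.square(da)))) if da else 0.0
    return bond_rmse, angle_rmse


@dataclass
class RefinementState:
    """One step of the iterative refinement loop."""

    applied: ParameterSet               # parameters used in the CG simulation
    reference: ParameterSet             # all-atom-derived targets
    measured: ParameterSet = None       # inversion of the latest CG run
    iteration: int = 0
    m: float = 0.3                      # bond scaling hyperparameter
    n: float = 0.3                      # angle scaling hyperparameter
    bond_rmse_history: list = field(default_factory=list)
    angle_rmse_history: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.m <= 1 and 0 <= self.n <= 1):
            raise ValueError("m, n must lie in [0, 1]")


def refine_step(state: RefinementState, verbatim: bool = False) -> RefinementState:
    """Produce the next applied parameter set from the measured one.

    Default (corrective) update:  K_applied += m * (K_ref - K_measured),
    which is a fixed point exactly when the simulation reproduces the
    reference.  ``verbatim=True`` instead applies the update
    K_{i+1} = K_i - m (K_ref - K_i) literally; note that form moves away
    from the reference and is kept only for comparison.
    """
    if state.measured is None:
        raise ValueError("measured parameters for this iteration are missing")
    for term in list(state.applied.bonds) + list(state.applied.angles):
        cont = (state.measured.bonds if len(term) == 2 else state.measured.angles)
        if term not in cont:
            raise ValueError(f"missing measured term {term}")

    def _update(key, applied_p, ref_p, meas_p, scale, cls):
        if verbatim:
            k_new = meas_p.k - scale * (ref_p.k - meas_p.k)
        else:
            k_new = applied_p.k + scale * (ref_p.k - meas_p.k)
        k_new = max(k_new, 1e-6)   # keep constants positive
        return cls(k=k_new, b0=getattr(applied_p, "b0", None),
                   variance=applied_p.variance) if cls is BondParam else \
            cls(k=k_new, theta0=applied_p.theta0, variance=applied_p.variance)

    new_bonds = {k: _update(k, state.applied.bonds[k], state.reference.bonds[k],
                            state.measured.bonds[k], state.m, BondParam)
                 for k in state.applied.bonds}
    new_angles = {k: _update(k, state.applied.angles[k], state.reference.angles[k],
                             state.measured.angles[k], state.n, AngleParam)
                  for k in state.applied.angles}
    b_rmse, a_rmse = rmse(state.measured, state.reference)
    return RefinementState(
        applied=ParameterSet(bonds=new_bonds, angles=new_angles,
                             temperature=state.applied.temperature),
        reference=state.reference, measured=None,
        iteration=state.iteration + 1, m=state.m, n=state.n,
        bond_rmse_history=state.bond_rmse_history + [b_rmse],
        angle_rmse_history=state.angle_rmse_history + [a_rmse],
    )


def prune_angles(model: CGModel, reference_params: ParameterSet) -> CGModel:
    """Keep, for each bead, only its strongest incident angle parameter.

    An angle is incident on all three of its beads; the retained set is the
    union over beads of the argmax-K_a incident angle, with exact K ties
    broken by lexicographically smallest angle tuple.  The retained count
    is therefore at most n_beads.
    """
    for a in model.angles:
        if a not in reference_params.angles:
            raise ValueError(f"angle {a} has no reference force constant")
    retained = set()
    for bead in range(model.n_beads):
        incident = [a for a in model.angles if bead in a]
        if not incident:
            continue
        best = max(incident, key=lambda a: (reference_params.angles[a].k,
                                            tuple(-x for x in a)))
        retained.add(best)
    return CGModel(beads=list(model.beads), bonds=list(model.bonds),
                   angles=sorted(retained), eps_max=model.eps_max)


def mn_grid(lo: float = 0.1, hi: float = 0.9, stride: float = 0.1):
    """The (m, n) hyperparameter grid; default 0.1..0.9 by 0.1 -> 81 pairs."""
    vals = np.round(np.arange(lo, hi + stride / 2, stride), 10)
    return [(float(m), float(n)) for m, n in product(vals, vals)]


def sweep_mn(model: CGModel, reference_params: ParameterSet, measure,
             grid=None, applied: ParameterSet = None):
    """Evaluate one refinement iteration per (m, n) pair.

    ``measure`` is a callable (ParameterSet -> ParameterSet) that runs a CG
    simulation with the applied parameters and Boltzmann-inverts the
    resulting trajectory.  Returns (table, best_pair); the table rows are
    dicts with m, n and the post-iteration total RMSE (bonds + angles).
    """
    if grid is None:
        grid = mn_grid()
    if len(grid) == 0:
        raise ValueError("empty (m, n) grid")
    if applied is None:
        applied = reference_params
    table = []
    for (m, n) in grid:
        state = RefinementState(applied=applied, reference=reference_params,
                                m=m, n=n)
        state.measured = measure(state.applied)
        nxt = refine_step(state)
        nxt.measured = measure(nxt.applied)
        b_rmse, a_rmse = rmse(nxt.measured, reference_params)
        table.append({"m": m, "n": n, "rmse": b_rmse + a_rmse,
                      "bond_rmse": b_rmse, "angle_rmse": a_rmse})
    best = min(table, key=lambda row: row["rmse"])
    return table, (best["m"], best["n"])
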