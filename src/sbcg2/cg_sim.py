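"""Langevin dynamics on the CG Hamiltonian, time-step selection, counter-ions.

The potential is CHARMM-convention harmonic bonds and angles,
U = K (x - x0)^2, plus Lennard-Jones (per-bead well depths from the SASA
mapping, R_min,ij = r_i + r_j, eps_ij geometric mean) and cutoff Coulomb
with a dielectric and a CHARMM-style energy switching function — a toy
engine by design: no PME, no periodic images by default.

Integration is BAOAB-discretized Langevin dynamics at temperature T with
friction gamma (ps^-1); with gamma = 0 it reduces to velocity Verlet.  The
integration time step is chosen from the fastest bond vibration,
tau = 1 / max_i nu_i with nu_i = (1/2pi) sqrt(K_b,i / mu_i) converted from
(kcal/mol/A^2, amu) to fs^-1 via the AKMA time unit (~48.89 fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import AKMA_TIME_FS, COULOMB, KB, MD_ACC
from .model import CGModel, ParameterSet
from .structure import Trajectory


class DivergenceError(RuntimeError):
    pass


@dataclass
class SimConfig:
    timestep_fs: float = 10.0
    gamma_ps: float = 2.0            # Langevin friction, ps^-1
    temperature: float = 298.0       # K
    cutoff: float = 30.0             # A
    switch: float = 25.0             # A
    pairlist: float = 35.0           # A
    dielectric: float = 80.0
    seed: int = 0
    n_steps: int = 1000
    save_interval: int = 10          # frames & log cadence
    minimize_steps: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("time step must be positive")
        if self.gamma_ps < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.switch <= self.cutoff <= self.pairlist:
            raise ValueError("need 0 < switch <= cutoff <= pairlist")


@dataclass
class FrequencySpectrum:
    bonds: list                      # (i, j) per entry
    frequencies_fs: np.ndarray       # nu_i, fs^-1
    reduced_masses: np.ndarray       # mu_i, amu
    force_constants: np.ndarray      # K_b,i

    @property
    def max_frequency(self) -> float:
        return float(self.frequencies_fs.max())


def vibrational_spectrum(model: CGModel, params: ParameterSet) -> FrequencySpectrum:
    """Per-bond harmonic frequency nu = (1/2pi) sqrt(K/mu), in fs^-1."""
    masses = model.masses
    if np.any(masses <= 0):
        raise ValueError("zero or negative bead mass")
    bonds, nus, mus, ks = [], [], [], []
    for (i, j) in model.bonds:
        if (i, j) not in params.bonds:
            raise ValueError(f"bond {(i, j)} has no parameters")
        K = params.bonds[(i, j)].k
        if K <= 0:
            raise ValueError(f"bond {(i, j)} has non-positive K")
        mu = masses[i] * masses[j] / (masses[i] + masses[j])
        # sqrt(K/mu) is rad per AKMA time unit; AKMA_TIME_FS converts to fs
        nu = np.sqrt(K / mu) / (2.0 * np.pi * AKMA_TIME_FS)
        bonds.append((i, j))
        nus.append(nu)
        mus.append(mu)
        ks.append(K)
    if not bonds:
        raise ValueError("model has no bonds")
    return FrequencySpectrum(bonds=bonds, frequencies_fs=np.asarray(nus),
                             reduced_masses=np.asarray(mus),
                             force_constants=np.asarray(ks))


def select_timestep(spectrum: FrequencySpectrum, safety_factor: float = 1.0) -> float:
    """tau = safety_factor / max nu — the fastest oscillation period (fs)."""
    return safety_factor / spectrum.max_frequency


# ---------------------------------------------------------------------------
# Forces


def _exclusions(model: CGModel) -> set:
    """1-2 and 1-3 pairs (bonded and angle-flanking) excluded from nonbonded."""
    excl = set(model.bonds)
    for (i, j, k) in model.angles:
        excl.add((min(i, k), max(i, k)))
    return excl


def _switch_factor(r, switch, cutoff):
    """CHARMM energy switching function and its derivative wrt r."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    sel = (r > switch) & (r < cutoff)
    if np.any(sel):
        c2, s2, r2 = cutoff**2, switch**2, r[sel] ** 2
        denom = (c2 - s2) ** 3
        s[sel] = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / denom
        ds[sel] = (2.0 * (c2 - r2) * (-2.0 * r[sel]) * (c2 + 2.0 * r2 - 3.0 * s2)
                   + (c2 - r2) ** 2 * 4.0 * r[sel]) / denom
    s[r >= cutoff] = 0.0
    return s, ds


class _ForceField:
    """Vectorized force/energy evaluation for one CG model."""

    def __init__(self, model: CGModel, params: ParameterSet, config: SimConfig):
        missing = params.missing_terms(model)
        if missing:
            raise ValueError(f"unparameterized term: {missing[0]}")
        self.config = config
        self.n = model.n_beads
        self.masses = model.masses
        self.charges = model.charges
        self.radii = model.radii
        self.epsilons = model.epsilons
        self.bond_idx = np.array(model.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_k = np.array([params.bonds[b].k for b in model.bonds])
        self.bond_b0 = np.array([params.bonds[b].b0 for b in model.bonds])
        self.angle_idx = np.array(model.angles, dtype=np.int64).reshape(-1, 3)
        self.angle_k = np.array([params.angles[a].k for a in model.angles])
        self.angle_t0 = np.array([params.angles[a].theta0 for a in model.angles])
        self.excl = _exclusions(model)
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self._pairlist_ref = None

    def rebuild_pairlist(self, pos):
        tree = cKDTree(pos)
        raw = tree.query_pairs(self.config.pairlist, output_type="ndarray")
        if len(raw):
            keep = [(i, j) not in self.excl for i, j in raw]
            self.pairs = raw[np.asarray(keep, dtype=bool)]
        else:
            self.pairs = raw
        self._pairlist_ref = pos.copy()

    def maybe_rebuild(self, pos):
        if self._pairlist_ref is None:
            self.rebuild_pairlist(pos)
            return
        margin = (self.config.pairlist - self.config.cutoff) / 2.0
        disp = np.abs(pos - self._pairlist_ref).max()
        if disp > margin:
            self.rebuild_pairlist(pos)

    def evaluate(self, pos):
        """Return (forces kcal/mol/A, potential energy kcal/mol)."""
        F = np.zeros_like(pos)
        energy = 0.0

        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            rij = pos[j] - pos[i]
            r = np.linalg.norm(rij, axis=1)
            dr = r - self.bond_b0
            energy += float((self.bond_k * dr**2).sum())
            # dU/dr = 2 K dr; force on i points along +rij when stretched
            fmag = (2.0 * self.bond_k * dr / r)[:, None] * rij
            np.add.at(F, i, fmag)
            np.add.at(F, j, -fmag)

        if len(self.angle_idx):
            ia, ja, ka = (self.angle_idx[:, 0], self.angle_idx[:, 1],
                          self.angle_idx[:, 2])
            a = pos[ia] - pos[ja]
            b = pos[ka] - pos[ja]
            la = np.linalg.norm(a, axis=1)
            lb = np.linalg.norm(b, axis=1)
            cos = np.clip(np.einsum("ij,ij->i", a, b) / (la * lb), -1.0, 1.0)
            theta = np.arccos(cos)
            sin = np.sqrt(np.clip(1.0 - cos**2, 1e-12, None))
            dtheta = theta - self.angle_t0
            energy += float((self.angle_k * dtheta**2).sum())
            dU = 2.0 * self.angle_k * dtheta
            # dtheta/dxi = (cos*a_hat - b_hat) / (la * sin); symmetric for k
            a_hat = a / la[:, None]
            b_hat = b / lb[:, None]
            Fi = -(dU / (la * sin))[:, None] * (cos[:, None] * a_hat - b_hat)
            Fk = -(dU / (lb * sin))[:, None] * (cos[:, None] * b_hat - a_hat)
            np.add.at(F, ia, Fi)
            np.add.at(F, ka, Fk)
            np.add.at(F, ja, -(Fi + Fk))

        if len(self.pairs):
            i, j = self.pairs[:, 0], self.pairs[:, 1]
            rij = pos[j] - pos[i]
            r = np.linalg.norm(rij, axis=1)
            within = r < self.config.cutoff
            if np.any(within):
                i, j, rij, r = i[within], j[within], rij[within], r[within]
                s, ds = _switch_factor(r, self.config.switch, self.config.cutoff)
                eps = np.sqrt(self.epsilons[i] * self.epsilons[j])
                rmin = self.radii[i] + self.radii[j]
                x6 = (rmin / r) ** 6
                u_lj = eps * (x6**2 - 2.0 * x6)
                du_lj = eps * 12.0 * (x6 - x6**2) / r
                u_el = COULOMB * self.charges[i] * self.charges[j] / (
                    self.config.dielectric * r)
                du_el = -u_el / r
                u = u_lj + u_el
                du = du_lj + du_el
                energy += float((u * s).sum())
                fmag = ((du * s + u * ds) / r)[:, None] * rij
                np.add.at(F, i, fmag)
                np.add.at(F, j, -fmag)

        if not np.all(np.isfinite(F)):
            bad = np.nonzero(~np.isfinite(F).all(axis=1))[0]
            raise DivergenceError(f"non-finite force on bead(s) {bad.tolist()}")
        return F, energy


def kinetic_temperature(velocities, masses) -> float:
    """Instantaneous kinetic temperature from <KE> = (3/2) N kB T."""
    ke = 0.5 * float((masses * np.einsum("ij,ij->i", velocities, velocities)).sum())
    ke_kcal = ke / MD_ACC
    return 2.0 * ke_kcal / (3.0 * len(masses) * KB)


def run_md(model: CGModel, params: ParameterSet, config: SimConfig,
           initial_positions=None, warn=None):
    """BAOAB Langevin dynamics; returns (Trajectory, log dict of series).

    The log holds per-``save_interval`` arrays: step, potential and kinetic
    energy (kcal/mol) and kinetic temperature (K).  Deterministic per seed.
    Warns (via ``warn`` callable or warnings module) when the time step
    exceeds the spectral stability rule tau = 1/max nu.
    """
    ff = _ForceField(model, params, config)
    try:
        spectrum = vibrational_spectrum(model, params)
        tau_max = select_timestep(spectrum)
        if config.timestep_fs > tau_max:
            message = (f"time step {config.timestep_fs} fs exceeds the "
                       f"fastest bond period {tau_max:.2f} fs")
            if warn is not None:
                warn(message)
            else:
                import warnings
                warnings.warn(message, stacklevel=2)
    except ValueError:
        pass  # bond-free models have no spectral constraint

    rng = np.random.default_rng(config.seed)
    pos = (model.positions if initial_positions is None
           else np.array(initial_positions, dtype=np.float64))
    masses = model.masses
    n = len(masses)
    dt = config.timestep_fs
    gamma_fs = config.gamma_ps * 1e-3
    kT = KB * config.temperature
    sigma_v = np.sqrt(kT * MD_ACC / masses)[:, None]   # A/fs per bead

    vel = sigma_v * rng.standard_normal((n, 3))
    c1 = np.exp(-gamma_fs * dt)
    c2 = np.sqrt(1.0 - c1**2)

    ff.rebuild_pairlist(pos)
    F, _ = ff.evaluate(pos)

    n_saved = config.n_steps // config.save_interval
    frames = np.empty((n_saved, n, 3))
    log = {"step": np.empty(n_saved, dtype=np.int64),
           "potential": np.empty(n_saved), "kinetic": np.empty(n_saved),
           "temperature": np.empty(n_saved)}
    isave = 0
    for step in range(config.n_steps):
        vel += 0.5 * dt * MD_ACC * F / masses[:, None]
        pos += 0.5 * dt * vel
        if gamma_fs > 0:
            vel = c1 * vel + c2 * sigma_v * rng.standard_normal((n, 3))
        pos += 0.5 * dt * vel
        ff.maybe_rebuild(pos)
        try:
            F, potential = ff.evaluate(pos)
        except DivergenceError as err:
            raise DivergenceError(f"step {step + 1}: {err}") from None
        vel += 0.5 * dt * MD_ACC * F / masses[:, None]

        if (step + 1) % config.save_interval == 0 and isave < n_saved:
            frames[isave] = pos
            ke = 0.5 * float((masses * np.einsum("ij,ij->i", vel, vel)).sum()) / MD_ACC
            log["step"][isave] = step + 1
            log["potential"][isave] = potential
            log["kinetic"][isave] = ke
            log["temperature"][isave] = 2.0 * ke / (3.0 * n * KB)
            isave += 1

    traj = Trajectory(xyz=frames, timestep_ps=dt * config.save_interval * 1e-3)
    return traj, log


# ---------------------------------------------------------------------------
# Counter-ionization on a Coulombic grid potential


def counterionize(model: CGModel, ion_bead_charge: float, grid_w: float = 2.0,
                  min_distance: float = 5.0, padding: float = 15.0):
    """Greedy counter-ion placement at extrema of the Coulomb potential.

    Repeats until the remaining net charge is smaller in magnitude than one
    ion bead: compute the softened Coulomb potential on a voxel grid from
    all current charges, place a counter-charged bead at the minimum
    (cations) or maximum (anions) allowed voxel, and update the potential
    incrementally.  Voxels within ``min_distance`` of any particle are
    disallowed.  Returns (positions, charges) of the placed ions.
    """
    net = model.total_charge
    q_ion = abs(ion_bead_charge)
    if q_ion == 0:
        raise ValueError("ion charge must be nonzero")
    if abs(net) < q_ion:
        return np.empty((0, 3)), np.empty(0)

    pos = model.positions
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    counts = np.maximum(np.ceil((hi - lo) / grid_w).astype(int) + 1, 2)
    axes = [lo[d] + grid_w * np.arange(counts[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    voxels = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def add_potential(phi, allowed, p, q):
        d = np.linalg.norm(voxels - p, axis=1)
        allowed &= d >= min_distance
        phi += COULOMB * q / np.maximum(d, min_distance)
        return phi, allowed

    phi = np.zeros(len(voxels))
    allowed = np.ones(len(voxels), dtype=bool)
    for p, q in zip(pos, model.charges):
        phi, allowed = add_potential(phi, allowed, p, q)

    placed_pos, placed_q = [], []
    remaining = net
    while abs(remaining) >= q_ion:
        if not allowed.any():
            raise RuntimeError("no allowed voxel left for ion placement; "
                               "increase the grid padding")
        q_bead = -np.sign(remaining) * q_ion
        masked = np.where(allowed, phi, np.inf if q_bead > 0 else -np.inf)
        idx = int(masked.argmin() if q_bead > 0 else masked.argmax())
        p_bead = voxels[idx]
        placed_pos.append(p_bead)
        placed_q.append(q_bead)
        phi, allowed = add_potential(phi, allowed, p_bead, q_bead)
        remaining += q_bead
    return np.asarray(placed_pos), np.asarray(placed_q)
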