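"""Topology-representing network: learn bead positions and connectivity.

Bead positions are learned by neural-gas weight adaptation: at each
presentation an atom position v is drawn uniformly, all units are ranked by
distance to v, and every weight moves by eps * exp(-rank/lambda) * (v - w).
Connectivity is learned by competitive Hebbian adaptation: the two units
nearest to v are connected, connection ages are incremented for the winner's
other links, and links past an age threshold are removed.  The converged
edge set is a subgraph of the Delaunay triangulation of the weights.

High granularity (down to one atom per bead) is made possible by an
exclusive initialization: each unit starts at a *distinct* atom position,
so no two units are reflexively identical and winner selection is never
degenerate (ties that remain are broken deterministically by unit index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AtomisticStructure


@dataclass
class TRNSchedule:
    """Annealing schedule; quantities interpolate exponentially over t_max.

    Defaults: learning rate eps decays 0.3 -> 0.005, neighborhood range
    lambda decays 0.3 -> 0.01, and the Hebbian age threshold is a constant
    2*N_beads presentations.  ``t_max`` defaults to 200 presentations per
    atom.  Note the deliberately *narrow* lambda: exclusive initialization
    already draws the units from the data distribution itself, so the wide
    neighborhood ranges of classic neural gas (which are needed to unfold a
    random initialization) only collapse the density-matched start and
    leave dead units at high granularity.  A sub-unit lambda preserves it.
    """

    eps_initial: float = 0.3
    eps_final: float = 0.005
    lambda_initial: float = 0.3
    lambda_final: float = 0.01
    age_threshold_initial: float = None   # default 2 * n_beads (constant)
    age_threshold_final: float = None
    t_max: int = None                 # default 200 * n_atoms

    def resolved(self, n_beads: int, n_atoms: int) -> "TRNSchedule":
        lam_i = self.lambda_initial
        age_i = self.age_threshold_initial if self.age_threshold_initial is not None \
            else 2.0 * n_beads
        age_f = self.age_threshold_final if self.age_threshold_final is not None else age_i
        t_max = self.t_max if self.t_max is not None else 200 * n_atoms
        return TRNSchedule(self.eps_initial, self.eps_final, lam_i,
                           self.lambda_final, age_i, age_f, t_max)


def _interp(xi: float, xf: float, frac: float) -> float:
    """Exponential interpolation x(t) = xi * (xf/xi)^(t/t_max)."""
    return xi * (xf / xi) ** frac


@dataclass
class TRNState:
    weights: np.ndarray               # (N, 3) A
    connectivity: np.ndarray          # (N, N) symmetric, zero diagonal
    ages: np.ndarray                  # (N, N) ages; meaningful where C > 0
    schedule: TRNSchedule
    rng: np.random.Generator

    @property
    def n_beads(self) -> int:
        return len(self.weights)


@dataclass
class TRNResult:
    weights: np.ndarray
    edges: list                       # unique (i, j), i < j
    presentations: int
    max_last_epoch_displacement: float   # A, over the final n_atoms presentations
    eps_trace: np.ndarray = field(default=None)
    lambda_trace: np.ndarray = field(default=None)


def initialize_exclusive(structure: AtomisticStructure, n_beads: int,
                         seed: int = 0,
                         schedule: TRNSchedule = None) -> TRNState:
    """Place each unit at a distinct atom position, without replacement.

    Duplicate atom coordinates reduce the usable capacity: the network can
    hold at most as many units as there are distinct positions.
    """
    n_atoms = structure.n_atoms
    if not 1 <= n_beads <= n_atoms:
        raise ValueError(f"n_beads must be in [1, {n_atoms}], got {n_beads}")
    rng = np.random.default_rng(seed)
    positions = structure.positions
    unique_pos, first_idx = np.unique(positions.round(decimals=9), axis=0,
                                      return_index=True)
    if n_beads > len(unique_pos):
        raise ValueError(
            f"only {len(unique_pos)} distinct atom positions; cannot place "
            f"{n_beads} exclusive units")
    chosen = rng.choice(first_idx, size=n_beads, replace=False)
    weights = positions[chosen].copy()
    n = n_beads
    return TRNState(
        weights=weights,
        connectivity=np.zeros((n, n)),
        ages=np.zeros((n, n)),
        schedule=(schedule or TRNSchedule()),
        rng=rng,
    )


def adapt(state: TRNState, structure: AtomisticStructure,
          log_every: int = 0) -> TRNResult:
    """Run the TRN for t_max presentations and return the converged network.

    Each presentation: draw an atom uniformly; rank all units by distance
    (exact ties broken by lower unit index); evolve every weight by the
    neural-gas rule; Hebb-connect the two nearest units (refreshing the
    connection age if it exists); age the winner's other connections and
    drop those past the age threshold.  The loop is bounded: there is no
    data-dependent stopping rule.
    """
    sched = state.schedule.resolved(state.n_beads, structure.n_atoms)
    W = state.weights
    C = state.connectivity
    ages = state.ages
    rng = state.rng
    atoms = structure.positions
    n_atoms = len(atoms)
    t_max = int(sched.t_max)
    n = state.n_beads

    n_epoch_records = max(t_max // max(n_atoms, 1), 1)
    eps_trace, lam_trace = [], []
    last_epoch_start = max(t_max - n_atoms, 0)
    w_epoch_ref = None

    sample_idx = rng.integers(0, n_atoms, size=t_max)
    for t in range(t_max):
        frac = t / max(t_max - 1, 1)
        eps = _interp(sched.eps_initial, sched.eps_final, frac)
        lam = _interp(sched.lambda_initial, sched.lambda_final, frac)
        age_threshold = _interp(sched.age_threshold_initial,
                                sched.age_threshold_final, frac)
        if t % max(n_atoms, 1) == 0:
            eps_trace.append(eps)
            lam_trace.append(lam)
        if t == last_epoch_start:
            w_epoch_ref = W.copy()

        v = atoms[sample_idx[t]]
        delta = v - W
        d2 = np.einsum("ij,ij->i", delta, delta)
        order = np.argsort(d2, kind="stable")     # ties -> lower index first
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(n)
        W += (eps * np.exp(-ranks / lam))[:, None] * delta

        if n >= 2:
            i, j = int(order[0]), int(order[1])
            C[i, j] = C[j, i] = 1.0
            ages[i, j] = ages[j, i] = 0.0
            # age the winner's other connections, remove the stale ones
            row = C[i] > 0
            row[j] = False
            ages[i, row] += 1.0
            ages[row, i] += 1.0
            stale = row & (ages[i] > age_threshold)
            if stale.any():
                C[i, stale] = C[stale, i] = 0.0
                ages[i, stale] = ages[stale, i] = 0.0

    max_disp = float(np.abs(W - w_epoch_ref).max()) if w_epoch_ref is not None else 0.0
    ii, jj = np.nonzero(np.triu(C, k=1))
    edges = [(int(a), int(b)) for a, b in zip(ii, jj)]
    return TRNResult(weights=W.copy(), edges=edges, presentations=t_max,
                     max_last_epoch_displacement=max_disp,
                     eps_trace=np.asarray(eps_trace),
                     lambda_trace=np.asarray(lam_trace))


def coarse_grain(structure: AtomisticStructure, n_beads: int, seed: int = 0,
                 schedule: TRNSchedule = None) -> TRNResult:
    """Convenience wrapper: exclusive initialization followed by adaptation."""
    state = initialize_exclusive(structure, n_beads, seed=seed, schedule=schedule)
    return adapt(state, structure)
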