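# Methods

This note records the models implemented in `sbcg2`, the defaults chosen
where the design was open, and what the synthetic test conditions do and do
not demonstrate.

## Units

Length Å, mass amu, charge e, energy kcal/mol, temperature K, time fs.
`kB = 0.0019872041 kcal/mol/K`; Coulomb constant `332.0636 kcal·Å/mol/e²`.
With these units an acceleration `F/m` carries the factor
`4.184e-4 Å/fs²` per (kcal/mol/Å)/amu, equivalently the AKMA time unit
`sqrt(amu·Å²/(kcal/mol)) = 48.8882 fs`; the unit test for the vibrational
spectrum re-derives this factor from SI definitions.

## Topology-representing network

Bead positions are neural-gas weights; connectivity is competitive Hebbian.
Per presentation: draw an atom uniformly, rank all units by distance (exact
ties broken by lowest unit index, which keeps winner selection well defined),
move every weight by `eps*exp(-rank/lambda)*(v-w)`, connect the two nearest
units with age zero (refreshing an existing link also resets its age), age
the winner's other links and delete those past the threshold.  The loop
runs a fixed `t_max` presentations — the per-epoch maximum weight
displacement is reported as a convergence diagnostic but never used as a
stopping rule.  Connection strengths are binary: only the support of the
connectivity matrix is consumed downstream.

**Initialization.**  Each unit starts at a *distinct* atom position, drawn
without replacement.  Coincident atoms reduce capacity accordingly and are
rejected with an error rather than silently collapsing two units onto one
reflexive state.

**Schedule defaults** (exponential interpolation
`x(t) = x_i (x_f/x_i)^(t/t_max)`): `eps` 0.3 → 0.005, `lambda` 0.3 → 0.01,
age threshold constant `2*N_beads`, `t_max = 200 * n_atoms`.  The narrow
neighborhood range is deliberate and differs from classic neural-gas
practice (`lambda_i ~ N/2`): a wide neighborhood exists to unfold a *random*
initialization, but exclusive initialization already draws the units from
the data distribution itself, and the early wide-lambda phase only collapses
that density-matched start toward the cloud center, stranding dead units.
Measured on 300-atom/300-bead fixtures: `lambda_i = 0.2*N` leaves ~50–70
empty Voronoi cells; `lambda_i = 0.3` leaves zero across all seeds tried
while preserving the Delaunay-subgraph property of the learned edges.  All
schedule quantities are config-exposed.

## Property mapping

Atoms map to their nearest weight (ties to the lowest bead index).  Bead
position is the mass-weighted center of mass of its cell; mass and charge
are cell sums (conserved to machine precision); the bead radius is the
mass-weighted radius of gyration about the bead position.  The LJ well
depth is `eps_max*(sasa_hydrophob/sasa_tot)²`, with `eps = 0` for fully
buried cells.  SASA uses Shrake–Rupley sampling with a 1.4 Å probe and 960
golden-spiral points per atom (cross-checked in the tests against a
10⁴-point self-oracle and against biotite's independent implementation).
Hydrophobicity defaults to the element rule {C, S}; a callable hook allows
residue- or name-based rules.

Assemblies: a monomer mapping is transferred to each identical subunit by
recomputing bead centers from the subunit's atom domains and copying
topology and parameters with an index offset; atom name/residue mismatches
abort with the first offending atom.  Inter-subunit bonds are never
created.  Ion/cofactor beads (e.g. an IP6-like bead: −12 e, 5 Å radius)
append as unbonded beads; clumped-ion beads default to charge and mass of
five single ions per bead — the clump size is config because single-ion
(±1 e) granularity is equally defensible.

## Charge density and FSC

Each particle contributes a Gaussian of standard deviation equal to its vdW
radius, truncated at 3 sigma and discretely normalized so each particle's
voxel sum times `w³` equals its charge exactly ("normalized, additively
distributed").  Default voxel width 0.5 Å, padding 5 Å.

The voxel↔Cartesian transform is the 4×4 affine with diagonal
`L_d/(N_d−1)`, `L_d = w·N_d`, and the grid origin as translation.
Resampling maps reference voxel indices through this transform pair and
interpolates trilinearly (`scipy.ndimage.map_coordinates`, order 1) with
zero outside the source extent; lattice-coincident grids round-trip
bit-exactly and constant fields are fixed points.

FSC uses `numpy.fft.fftn`; shells are concentric bins of width one
reciprocal voxel, `1/(N1·w)` Å⁻¹ with `N1 = max(N)`, giving `N1//2` bins up
to Nyquist — the bin-count rule `N1/(2w)` is read with the shell width in
voxel units, the only dimensionally consistent reading.  `zeta` is the real
part of the normalized cross-correlation; shells where both spectra vanish
are defined as 0 and flagged.  The FFT path is verified per shell against a
brute-force (non-FFT, separable matrix) DFT oracle to RMSE ≤ 1e-7.
Resolution is `1/r*` at the first crossing below the threshold, linearly
interpolated in `(r, zeta)`; a curve that never crosses reports the Nyquist
resolution `2w` with a flag.  In granularity scans, CG beads are cast with
`sigma = max(r_gyr, mass-weighted mean vdW radius of the domain)` so
single-atom domains keep their atomic width instead of a zero-width spike.

## Boltzmann inversion and refinement

`K = kB·T/(2D)`, `D = <r²> − <r>²`, equilibrium `<r>`; angles are vertex
angles in `[0, pi]` radians (no periodic wrap; the models carry no
dihedrals).  Frozen terms (zero variance) are an error, not a silent
`K = inf`.

The refinement update is the corrective form
`K_applied,i+1 = K_applied,i + m·(K_ref − K_measured,i)` (separately `n`
for angles), whose fixed point is exactly "the simulation reproduces the
reference".  A verbatim alternative `K_{i+1} = K_i − m(K_ref − K_i)` is
kept behind a flag for comparison; as written it moves away from the
reference, and the surrounding description of scaling parameters by their
error supports the corrective reading.  RMSE is tracked on force constants
only, bonds and angles separately (their units differ).

Pruning retains, per bead, the single incident angle with the highest
*reference* force constant (ties: lexicographically smallest triple), so
the retained set is a per-bead argmax union of size ≤ `N_beads`, and one
strong angle may be shared by several beads.

The (m, n) hyperparameter sweep enumerates 0.1–0.9 at stride 0.1 → 81
pairs, each evaluated by one refinement iteration against a caller-supplied
measurement callback (a short CG run + inversion in production; an exact
harmonic sampler in the fast tests).

## Synthetic fixtures

Structures are Gaussian blobs (sigma 10 Å), two-domain mixtures (centers
20 Å apart, sigma 3 Å — compact enough that the within/between-domain
distance modes separate), or jittered helices; masses uniform in 12–32 amu,
charges zero-sum by construction, hydrophobic flags Bernoulli.  These are
point-statistics stand-ins: they have no covalent geometry, secondary
structure or realistic packing, so passing tests demonstrates algorithmic
correctness (conservation, convergence, recovery), not chemical realism on
real proteins.

Harmonic reference trajectories are drawn frame-i.i.d. by sequential
placement on a tree topology: each bond length `Normal(b0, sqrt(kBT/2K))`,
each (grandparent, parent, child) angle `Normal(theta0, sqrt(kBT/2K))` with
uniform azimuth.  This makes every term's Boltzmann target *exact* and
uncoupled — the ideal inversion oracle.  It cannot realize cyclic
topologies or sibling angles (two children of one parent); those raise an
error and are sampled with the toy MD engine instead.

## Langevin engine

BAOAB splitting; `gamma = 0` reduces to velocity Verlet (the tests verify
no secular energy drift over 100 periods).  Velocities are initialized from
Maxwell–Boltzmann.  Nonbonded terms: LJ with `R_min,ij = r_i + r_j`,
`eps_ij = sqrt(eps_i·eps_j)`; Coulomb over a dielectric (default 80,
implicit-solvent screening); CHARMM energy switching between the switch and
cutoff distances; 1–2 and 1–3 exclusions; Verlet pair list rebuilt when any
displacement exceeds `(pairlist − cutoff)/2`.  No periodic boundaries
(finite assemblies) and no reciprocal-space electrostatics — cutoff
("truncated") electrostatics is a stated scope limit of this engine, not an
approximation of PME.

`tau = 1/max(nu)` is the spectral rule as such; for *accurate* sampling the
CLI and tests run at 1/20 of the fastest period, since kinetic-temperature
discretization bias grows as `(omega·tau)²` (at 1/10 of the period the
measured mean temperature sits ~2 % low, at 1/20 within ~1 %).
Reported temperature is kinetic, from `<KE> = (3/2)·N·kB·T`.

Counter-ionization computes the softened Coulomb potential (`r` clamped at
the minimum approach distance) on a grid with 15 Å default padding, places
each counter-ion bead at the extremal allowed voxel (minimum potential for
cations, maximum for anions), updates the potential incrementally, and
repeats until the remaining net charge is smaller than one ion bead — for
a net charge divisible by the ion charge, exactly `|net|/|q_ion|`
placements.

## Problem sizes in the test and acceptance runs

Chosen to exercise every code path at desk scale: 150–300-atom fixtures,
≤300 beads, 32³ FSC grids, 10⁵-frame exact-sampler trajectories,
1.5×10⁵-step one-bond MD runs, 10⁴-step refinement measurements, 20-seed
convergence sweeps.  The full acceptance script completes in ~2 minutes on
one CPU.

## Known limitations

- The engine is a validation tool, not a production MD code: single CPU,
  dense pair lists, no PME, no constraints, NVT only.
- Bead typing emits one CHARMM type per bead; models beyond ~46k beads
  would exhaust the 4-character base-36 label space, and bead counts beyond
  99,999 exceed PDB serials (both error out).
- `eps_max` is a user choice; nothing in the pipeline calibrates it.
- FSC-based granularity selection inherits the usual caveats of threshold
  metrics; both 0.143 and 0.5 crossings are reported.
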