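"""Charge-density grids and Fourier shell correlation for granularity selection.

Particle charges are cast to a voxel lattice as additively-distributed
normalized Gaussians whose widths (standard deviations) equal the particle
van der Waals radii.  Two grids on a common lattice are compared by shell-
binned normalized cross-correlation of their discrete Fourier transforms,

    zeta(r) = Re[ sum F1 F2* / sqrt(sum |F1|^2 * sum |F2|^2) ],

with N_bins = N1/2 spherical shells of one reciprocal-voxel width reaching
the Nyquist frequency 1/(2w).  The spatial frequency at which zeta first
drops below a chosen threshold (0.5 "half", 0.143 "gold") defines the
effective resolution of a coarse model relative to its atomistic reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import FSCCurve, VolumetricGrid


def cast_density(positions, charges, radii, w: float = 0.5,
                 padding: float = 5.0, truncation_sigmas: float = 3.0,
                 origin=None, counts=None) -> VolumetricGrid:
    """Cast charged particles to a Gaussian-smoothed charge-density grid.

    Each particle contributes q * G(x; sigma = vdW radius), evaluated on the
    voxels within ``truncation_sigmas`` * sigma and normalized so the
    discrete integral of each contribution is exactly q (in e; grid values
    are e/A^3).  ``origin``/``counts`` pin the lattice explicitly, e.g. to
    reuse a reference lattice.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    charges = np.asarray(charges, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if len(positions) < 1:
        raise ValueError("need at least one particle")
    if np.any(radii <= 0):
        raise ValueError("all particle radii must be positive")
    if w <= 0:
        raise ValueError("voxel width must be positive")

    if origin is None:
        lo = (positions - radii[:, None]).min(axis=0) - padding
        hi = (positions + radii[:, None]).max(axis=0) + padding
        origin = np.floor(lo / w) * w
        counts = np.maximum(np.ceil((hi - origin) / w).astype(int) + 1, 2)
    else:
        origin = np.asarray(origin, dtype=np.float64)
        counts = np.asarray(counts, dtype=int)

    values = np.zeros(tuple(counts))
    for p, q, sigma in zip(positions, charges, radii):
        reach = truncation_sigmas * sigma
        lo_idx = np.maximum(np.floor((p - reach - origin) / w).astype(int), 0)
        hi_idx = np.minimum(np.ceil((p + reach - origin) / w).astype(int) + 1,
                            counts)
        if np.any(lo_idx >= hi_idx):
            continue
        axes = [origin[d] + w * np.arange(lo_idx[d], hi_idx[d]) for d in range(3)]
        gs = [np.exp(-((ax - p[d]) ** 2) / (2.0 * sigma ** 2))
              for d, ax in enumerate(axes)]
        kernel = gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        total = kernel.sum()
        if total <= 0:
            continue
        values[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] += (
            q / (total * w**3)) * kernel
    return VolumetricGrid(values=values, width=w, origin=origin)


def resample(cg_grid: VolumetricGrid, reference_grid: VolumetricGrid) -> VolumetricGrid:
    """Resample a CG grid onto the reference lattice by trilinear interpolation.

    Every reference voxel index is mapped to Cartesian space with the
    reference transform, then into fractional CG voxel coordinates with the
    inverse CG transform; values are trilinearly interpolated there and
    zero is assigned outside the CG extent.
    """
    if cg_grid.same_lattice(reference_grid):
        return VolumetricGrid(values=cg_grid.values.copy(),
                              width=reference_grid.width,
                              origin=reference_grid.origin.copy())
    n1, n2, n3 = reference_grid.counts
    idx = np.indices((n1, n2, n3), dtype=np.float64).reshape(3, -1).T
    xyz = reference_grid.voxel_to_cartesian(idx)
    v_cg = cg_grid.cartesian_to_voxel(xyz)
    vals = ndimage.map_coordinates(cg_grid.values, v_cg.T, order=1,
                                   mode="constant", cval=0.0)
    return VolumetricGrid(values=vals.reshape(n1, n2, n3),
                          width=reference_grid.width,
                          origin=reference_grid.origin.copy())


def _shell_index(counts, w: float):
    """Radial shell index per DFT frequency and the shell geometry.

    Frequencies along axis d are k_d / (N_d * w) (1/A, signed); shells are
    concentric bins of width 1/(N1 * w) where N1 = max(N), giving
    N_bins = N1 // 2 shells up to Nyquist.
    """
    n1 = max(counts)
    n_bins = n1 // 2
    delta = 1.0 / (n1 * w)
    freqs = np.meshgrid(*[np.fft.fftfreq(nd, d=w) for nd in counts],
                        indexing="ij")
    radius = np.sqrt(freqs[0] ** 2 + freqs[1] ** 2 + freqs[2] ** 2)
    shell = np.floor(radius / delta).astype(np.int64)
    return shell, n_bins, delta


def fsc(grid1: VolumetricGrid, grid2: VolumetricGrid) -> FSCCurve:
    """Fourier shell correlation between two grids on the same lattice."""
    if not grid1.same_lattice(grid2):
        raise ValueError("grids are on different lattices: resample() first")
    F1 = np.fft.fftn(grid1.values)
    F2 = np.fft.fftn(grid2.values)
    shell, n_bins, delta = _shell_index(grid1.counts, grid1.width)
    keep = shell < n_bins
    s = shell[keep].ravel()
    num = np.bincount(s, weights=(F1 * np.conj(F2)).real[keep].ravel(),
                      minlength=n_bins)
    d1 = np.bincount(s, weights=(np.abs(F1) ** 2)[keep].ravel(), minlength=n_bins)
    d2 = np.bincount(s, weights=(np.abs(F2) ** 2)[keep].ravel(), minlength=n_bins)
    denom = np.sqrt(d1 * d2)
    # shells with (near-)zero power in either grid carry no signal: for a
    # zero-net-charge density the DC shell is pure roundoff, so an absolute
    # == 0 test is not enough
    empty = denom <= 1e-12 * max(denom.max(), 1e-300)
    zeta = np.where(empty, 0.0, num / np.where(empty, 1.0, denom))
    zeta = np.clip(zeta, -1.0, 1.0)  # guard rounding at |zeta| = 1
    freqs = (np.arange(n_bins) + 0.5) * delta
    return FSCCurve(frequencies=freqs, zeta=zeta, n_bins=n_bins,
                    voxel_width=grid1.width, empty_shells=empty)


@dataclass
class Resolution:
    resolution: float        # A
    crossing_frequency: float  # 1/A (Nyquist if no crossing)
    crossed: bool


def resolution_at(curve: FSCCurve, threshold: float) -> Resolution:
    """Resolution 1/r* at the first crossing of zeta below ``threshold``.

    The crossing is linearly interpolated between adjacent shells; a curve
    that never crosses reports the Nyquist resolution 2w with
    ``crossed=False``.  Shells flagged as empty (no signal in either grid,
    e.g. the DC shell of a zero-net-charge density) carry no correlation
    information and are skipped.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if len(curve) == 0:
        raise ValueError("empty FSC curve")
    keep = ~curve.empty_shells
    z = curve.zeta[keep]
    f = curve.frequencies[keep]
    if len(z) == 0:
        return Resolution(resolution=2.0 * curve.voxel_width,
                          crossing_frequency=1.0 / (2.0 * curve.voxel_width),
                          crossed=False)
    below = np.nonzero(z < threshold)[0]
    if len(below) == 0:
        nyq = 1.0 / (2.0 * curve.voxel_width)
        return Resolution(resolution=2.0 * curve.voxel_width,
                          crossing_frequency=nyq, crossed=False)
    i = int(below[0])
    if i == 0:
        r_star = f[0]
    else:
        z0, z1 = z[i - 1], z[i]
        r_star = f[i - 1] + (z0 - threshold) / (z0 - z1) * (f[i] - f[i - 1])
    return Resolution(resolution=1.0 / r_star, crossing_frequency=float(r_star),
                      crossed=True)


def granularity_scan(structure, bead_counts, seed: int = 0, eps_max: float = 0.5,
                     w: float = 0.5, schedule=None, sasa=None,
                     sub_nm_threshold: float = 10.0):
    """Resolution vs granularity table driving model selection.

    For each bead count: learn a TRN model, map properties, cast the CG and
    atomistic charge densities on the reference lattice, and evaluate the
    effective resolution at the 0.143 (gold) and 0.500 (half) metrics.
    Returns (rows, best) where ``best`` is the smallest bead count whose
    half-metric resolution is below ``sub_nm_threshold`` (None if none is).

    CG beads are cast with sigma = max(r_gyr, mass-weighted mean vdW radius
    of the domain) so single-atom domains keep their atomic width.
    """
    from . import cg_mapper, trn

    ref = cast_density(structure.positions, structure.charges,
                       structure.vdw_radii, w=w)
    if sasa is None:
        sasa = cg_mapper.compute_sasa(structure)
    rows = []
    for n_beads in bead_counts:
        result = trn.coarse_grain(structure, n_beads, seed=seed, schedule=schedule)
        assignment = cg_mapper.assign_cells(structure, result.weights)
        beads = cg_mapper.map_properties(structure, assignment, eps_max=eps_max,
                                         sasa=sasa)
        sigmas = []
        for b in beads:
            m = structure.masses[b.domain]
            mean_vdw = float((m * structure.vdw_radii[b.domain]).sum() / m.sum())
            sigmas.append(max(b.radius, mean_vdw))
        cg_own = cast_density(np.array([b.position for b in beads]),
                              np.array([b.charge for b in beads]),
                              np.array(sigmas), w=w)
        cg = resample(cg_own, ref)
        curve = fsc(ref, cg)
        rows.append({
            "n_beads": n_beads,
            "resolution_gold": resolution_at(curve, 0.143).resolution,
            "resolution_half": resolution_at(curve, 0.500).resolution,
        })
    best = None
    for row in rows:
        if row["resolution_half"] < sub_nm_threshold:
            best = row["n_beads"]
            break
    return rows, best
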