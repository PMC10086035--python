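"""Volumetric charge-density grids and Fourier-shell-correlation curves.

A grid stores one scalar per voxel on an orthorhombic lattice with counts
N = (N1, N2, N3), voxel width w (A) and Cartesian origin C (A).  The
physical extents are L_d = w * N_d, and the voxel -> Cartesian mapping is
the 4x4 affine transform with diagonal L_d / (N_d - 1) and translation C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class VolumetricGrid:
    values: np.ndarray        # (N1, N2, N3) float64
    width: float              # voxel width w, A
    origin: np.ndarray        # (3,) A

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("grid values must be 3-D")
        if min(self.values.shape) < 2:
            raise ValueError("grids need at least 2 voxels per axis")
        if self.width <= 0:
            raise ValueError("voxel width must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def counts(self) -> tuple:
        return self.values.shape

    @property
    def extents(self) -> np.ndarray:
        """Physical extents L_d = w * N_d, in A."""
        return self.width * np.asarray(self.values.shape, dtype=np.float64)

    @property
    def transform(self) -> np.ndarray:
        """The 4x4 voxel -> Cartesian matrix M."""
        N = np.asarray(self.values.shape, dtype=np.float64)
        M = np.eye(4)
        M[0, 0], M[1, 1], M[2, 2] = self.extents / (N - 1)
        M[:3, 3] = self.origin
        return M

    @property
    def inverse_transform(self) -> np.ndarray:
        return np.linalg.inv(self.transform)

    def voxel_to_cartesian(self, voxels: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(voxels, dtype=np.float64))
        hom = np.hstack([v, np.ones((len(v), 1))])
        return (self.transform @ hom.T).T[:, :3]

    def cartesian_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        hom = np.hstack([x, np.ones((len(x), 1))])
        return (self.inverse_transform @ hom.T).T[:, :3]

    def same_lattice(self, other: "VolumetricGrid", tol: float = 1e-9) -> bool:
        return (self.counts == other.counts
                and abs(self.width - other.width) <= tol
                and np.allclose(self.origin, other.origin, atol=tol))

    def integral(self) -> float:
        """Sum of voxel values times voxel volume (total charge, e)."""
        return float(self.values.sum() * self.width**3)


@dataclass
class FSCCurve:
    """Shell-binned correlation trace: spatial frequency (1/A) vs zeta."""

    frequencies: np.ndarray     # shell midpoints, 1/A
    zeta: np.ndarray            # correlation per shell, dimensionless
    n_bins: int
    voxel_width: float          # w of the underlying maps, A
    empty_shells: np.ndarray = None   # bool flags: zero-denominator shells

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.zeta = np.asarray(self.zeta, dtype=np.float64)
        if self.empty_shells is None:
            self.empty_shells = np.zeros(len(self.zeta), dtype=bool)
        if len(self.frequencies) != len(self.zeta):
            raise ValueError("frequency/zeta length mismatch")
        if np.any(self.zeta > 1 + 1e-6) or np.any(self.zeta < -1 - 1e-6):
            raise ValueError("zeta out of [-1, 1]")

    def __len__(self) -> int:
        return len(self.zeta)
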