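"""Reciprocal-space intensity volumes and trilinear gridding.

One gather/scatter pair implements every interpolation in the package:
slicing model snapshots out of a volume (expansion / rendering) and
inserting snapshots back by local averaging (compression / merging).  The
two share the same corner-weight computation, so scatter is the exact
adjoint of gather.

The volume lives on an L^3 Cartesian lattice with odd L, voxel spacing
``voxel_spacing`` (reciprocal length), and q = 0 at the central voxel, so
Friedel symmetry I(q) = I(-q) maps the lattice onto itself exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntensityVolume",
    "trilinear_gather",
    "trilinear_scatter",
    "friedel_symmetrize",
]


@dataclass
class IntensityVolume:
    """Non-negative intensities on an L^3 lattice centered at q = 0."""

    values: np.ndarray
    voxel_spacing: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("values must be a cubic L^3 array")
        if self.values.shape[0] % 2 == 0:
            raise ValueError("L must be odd (central voxel at q = 0)")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def q_extent(self) -> float:
        """Largest |q| component representable on the lattice."""
        return (self.L // 2) * self.voxel_spacing

    def voxel_q_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1D q coordinates along each axis."""
        c = np.arange(self.L) - self.L // 2
        q = c * self.voxel_spacing
        return q, q, q

    def to_index(self, q_points: np.ndarray) -> np.ndarray:
        """Map q-space points (n, 3) to fractional lattice indices (n, 3)."""
        return np.asarray(q_points, dtype=float) / self.voxel_spacing + self.L // 2


def _corner_weights(idx: np.ndarray, L: int):
    """8 corner flat-indices and weights for fractional indices (n, 3).

    Points whose interpolation cube is not fully inside the lattice are
    flagged out of bounds (zero weight everywhere).
    """
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    inside = np.all((i0 >= 0) & (i0 <= L - 2), axis=1)
    i0c = np.clip(i0, 0, L - 2)
    flat = []
    wts = []
    for dx in (0, 1):
        wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            for dz in (0, 1):
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = wx * wy * wz
                flat.append(((i0c[:, 0] + dx) * L + (i0c[:, 1] + dy)) * L + i0c[:, 2] + dz)
                wts.append(np.where(inside, w, 0.0))
    return np.stack(flat), np.stack(wts), inside


def trilinear_gather(values: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of ``values`` (L^3) at fractional indices.

    Returns (interpolated values, inside mask); out-of-bounds points get 0.
    """
    L = values.shape[0]
    flat, wts, inside = _corner_weights(idx, L)
    v = values.ravel()
    out = np.einsum("cn,cn->n", wts, v[flat])
    return out, inside


def trilinear_scatter(
    idx: np.ndarray, data: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint of :func:`trilinear_gather`: spread ``data`` onto the lattice.

    Returns (weighted sum, weight sum), both L^3 arrays; divide to get the
    locally averaged volume.
    """
    flat, wts, _ = _corner_weights(idx, L)
    n3 = L * L * L
    acc = np.zeros(n3)
    wacc = np.zeros(n3)
    d = np.asarray(data, dtype=float).ravel()
    for c in range(8):
        acc += np.bincount(flat[c], weights=wts[c] * d, minlength=n3)
        wacc += np.bincount(flat[c], weights=wts[c], minlength=n3)
    return acc.reshape(L, L, L), wacc.reshape(L, L, L)


def friedel_symmetrize(values: np.ndarray) -> np.ndarray:
    """Average a (odd-L) volume with its inversion image: exact I(q) = I(-q)."""
    return 0.5 * (values + values[::-1, ::-1, ::-1])
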