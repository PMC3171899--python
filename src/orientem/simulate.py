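"""Synthetic diffraction data: Gaussian-blob phantoms and noisy snapshot sets.

The simulator is the package's test bed.  A phantom is a sum of Gaussian
density blobs inside a sphere of diameter D; its continuous diffraction
intensity has a closed form,

    I(q) = | sum_j w_j (2 pi s_j^2)^(3/2) exp(-2 pi^2 s_j^2 |q|^2)
                   exp(-2 pi i q . c_j) |^2,

evaluated directly on the volume lattice (no FFT), which makes analytic
oracles available for every interpolation step downstream.

Snapshots are Ewald-sphere slices of the phantom at hidden uniform-random
orientations, globally rescaled so the *expected* total photon count per
snapshot equals ``mean_photons``, then Poisson-sampled per pixel, with an
optional zero-mean Gaussian background (clipped at zero).  The regime of
interest is ~100 photons per snapshot on a ~10^4-pixel detector, i.e.
~10^-2 photons per pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .detector import DetectorGeometry, pixel_q_coordinates, q_max
from .geometry import quat_to_matrix, random_orientation
from .volumes import IntensityVolume, friedel_symmetrize, trilinear_gather

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianBlobPhantom",
    "make_phantom",
    "render_slice",
    "SnapshotSet",
    "simulate_dataset",
    "required_L",
]


@dataclass
class GaussianBlobPhantom:
    """Analytic description of a blob phantom (centers, widths, weights)."""

    centers: np.ndarray  # (n_blobs, 3), real space
    widths: np.ndarray  # (n_blobs,)
    weights: np.ndarray  # (n_blobs,)
    diameter: float

    def intensity(self, q_points: np.ndarray) -> np.ndarray:
        """Closed-form diffraction intensity at q-space points (n, 3)."""
        q = np.atleast_2d(q_points)
        q2 = np.sum(q * q, axis=1)
        amp = np.zeros(len(q), dtype=complex)
        for c, s, w in zip(self.centers, self.widths, self.weights):
            form = w * (2.0 * math.pi * s * s) ** 1.5 * np.exp(-2.0 * math.pi ** 2 * s * s * q2)
            amp += form * np.exp(-2j * math.pi * (q @ c))
        return np.abs(amp) ** 2


def make_phantom(
    n_blobs: int = 8,
    box_diameter: float = 1.0,
    seed: int = 0,
    L: int = 49,
    voxel_spacing: float | None = None,
    blob_width: float | None = None,
) -> tuple[IntensityVolume, GaussianBlobPhantom]:
    """Random Gaussian-blob phantom and its intensity volume.

    Blob centers are uniform in a sphere of diameter ``box_diameter``; widths
    default to D/30 (features near the resolution scale, so speckle carries
    orientational information out to the detector edge); weights are uniform
    in [0.5, 1.5].  The lattice spacing defaults to the oversampled Shannon
    spacing 1/(2D).  Deterministic for a fixed seed.
    """
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    if L < 8:
        raise ValueError("L must be >= 8")
    if L % 2 == 0:
        L += 1
    D = box_diameter
    rng = np.random.default_rng(seed)
    # rejection-free uniform-in-ball: direction x radius^(1/3)
    u = rng.standard_normal((n_blobs, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = 0.5 * D * 0.8 * rng.random(n_blobs) ** (1.0 / 3.0)  # keep blobs off the surface
    centers = u * radii[:, None]
    base_w = D / 30.0 if blob_width is None else blob_width
    widths = base_w * (0.8 + 0.4 * rng.random(n_blobs))
    weights = 0.5 + rng.random(n_blobs)
    phantom = GaussianBlobPhantom(centers=centers, widths=widths, weights=weights, diameter=D)

    spacing = 1.0 / (2.0 * D) if voxel_spacing is None else voxel_spacing
    c = (np.arange(L) - L // 2) * spacing
    qx, qy, qz = np.meshgrid(c, c, c, indexing="ij")
    pts = np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=-1)
    values = phantom.intensity(pts).reshape(L, L, L)
    values = friedel_symmetrize(values)  # exact to rounding; real density
    return IntensityVolume(values=values, voxel_spacing=spacing), phantom


def required_L(geom: DetectorGeometry, voxel_spacing: float, margin: int = 2) -> int:
    """Smallest odd L whose lattice contains every rotated detector pixel."""
    half = math.ceil(q_max(geom) / voxel_spacing) + margin
    return 2 * half + 1


def render_slice(vol: IntensityVolume, quat: np.ndarray, geom: DetectorGeometry) -> np.ndarray:
    """Model snapshot at orientation ``quat``: the Ewald-sphere slice of ``vol``.

    Pixel q-vectors are rotated by ``quat`` and the volume is interpolated
    trilinearly.  Out-of-bounds pixels are set to zero and counted in a log
    message.  Output is non-negative.
    """
    pix = pixel_q_coordinates(geom)
    rot = pix @ quat_to_matrix(np.asarray(quat, dtype=float)).T
    vals, inside = trilinear_gather(vol.values, vol.to_index(rot))
    n_out = int(np.sum(~inside))
    if n_out:
        logger.warning("render_slice: %d of %d pixels fell outside the volume", n_out, len(pix))
    return np.clip(vals, 0.0, None)


@dataclass
class SnapshotSet:
    """N snapshots of p pixels each, with optional hidden true orientations."""

    counts: np.ndarray  # (N, p)
    geometry: DetectorGeometry
    true_orientations: np.ndarray | None = None  # (N, 4)
    mean_photons: float | None = None
    intensity_scale: float | None = None  # counts = scale * volume intensity
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be (N, p)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1] != self.geometry.p:
            raise ValueError("counts width does not match geometry pixel count")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def p(self) -> int:
        return self.counts.shape[1]


def simulate_dataset(
    vol: IntensityVolume,
    geom: DetectorGeometry,
    N: int,
    mean_photons: float,
    seed: int = 0,
    orientations: np.ndarray | None = None,
    background_sigma: float = 0.0,
    noise_model: str = "poisson",
) -> SnapshotSet:
    """Seeded noisy snapshot set from an intensity volume.

    Orientations are uniform on SO(3) unless supplied.  One global scale
    factor maps volume intensity to expected counts so that the mean *expected*
    total count per snapshot equals ``mean_photons``; per-snapshot totals then
    fluctuate Poissonically.  ``noise_model='none'`` returns the noise-free
    expected counts (useful for oracles).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if mean_photons <= 0:
        raise ValueError("mean_photons must be positive")
    rng = np.random.default_rng(seed)
    if orientations is None:
        quats = random_orientation(rng, N)
    else:
        quats = np.atleast_2d(np.asarray(orientations, dtype=float))
        if len(quats) != N:
            raise ValueError("orientations length must equal N")

    expected = np.empty((N, geom.p))
    for n in range(N):
        expected[n] = render_slice(vol, quats[n], geom)
    scale = mean_photons / float(np.mean(expected.sum(axis=1)))
    rates = expected * scale

    if noise_model == "poisson":
        counts = rng.poisson(rates).astype(float)
    elif noise_model == "none":
        counts = rates.copy()
    else:
        raise ValueError("noise_model must be 'poisson' or 'none'")
    if background_sigma > 0:
        counts = np.clip(counts + rng.normal(0.0, background_sigma, counts.shape), 0.0, None)

    return SnapshotSet(
        counts=counts,
        geometry=geom,
        true_orientations=quats,
        mean_photons=mean_photons,
        intensity_scale=scale,
        provenance={
            "seed": seed,
            "N": N,
            "mean_photons": mean_photons,
            "background_sigma": background_sigma,
            "noise_model": noise_model,
            "background_model": "zero-mean Gaussian, clipped at zero",
        },
    )
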