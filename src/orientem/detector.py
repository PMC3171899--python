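"""Detector geometry: mapping pixels to reciprocal space on the Ewald sphere.

A snapshot is a vector of ``p = n_fast * n_slow`` photon counts.  Each pixel
center is mapped to a scattering vector ``q = (s_hat - z_hat) / wavelength``
with ``s_hat`` the unit vector from the sample to the pixel and ``z_hat`` the
beam direction ("curved" mode, exact Ewald construction).  "flat" mode keeps
only the small-angle transverse components (``q_z = 0``), which gives planar
slices with closed forms, convenient for toy problems.

Pixel centers sit at half-integer offsets from the detector corner; indices
are 0-based; the fast axis is x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectorGeometry", "pixel_q_coordinates", "shannon_pixel_check", "shannon_geometry"]


@dataclass
class DetectorGeometry:
    n_fast: int
    n_slow: int
    pixel_size: float
    distance: float
    wavelength: float
    beam_center: tuple[float, float] | None = None  # (fast, slow), pixel units
    curvature_mode: str = "curved"
    beamstop_radius: float = 0.0  # pixels; 0 disables the central mask

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise ValueError("pixel counts must be >= 1")
        for name in ("pixel_size", "distance", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.curvature_mode not in ("curved", "flat"):
            raise ValueError("curvature_mode must be 'curved' or 'flat'")
        if self.beam_center is None:
            self.beam_center = (self.n_fast / 2.0, self.n_slow / 2.0)

    @property
    def p(self) -> int:
        return self.n_fast * self.n_slow

    def mask(self) -> np.ndarray:
        """Boolean mask of live pixels, flattened; False inside the beamstop."""
        if self.beamstop_radius <= 0:
            return np.ones(self.p, dtype=bool)
        i = np.arange(self.n_fast) + 0.5 - self.beam_center[0]
        j = np.arange(self.n_slow) + 0.5 - self.beam_center[1]
        jj, ii = np.meshgrid(j, i, indexing="ij")
        return (ii ** 2 + jj ** 2 > self.beamstop_radius ** 2).ravel()

    def to_dict(self) -> dict:
        return {
            "n_fast": self.n_fast,
            "n_slow": self.n_slow,
            "pixel_size": self.pixel_size,
            "distance": self.distance,
            "wavelength": self.wavelength,
            "beam_center": list(self.beam_center),
            "curvature_mode": self.curvature_mode,
            "beamstop_radius": self.beamstop_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorGeometry":
        d = dict(d)
        bc = d.get("beam_center")
        if bc is not None:
            d["beam_center"] = tuple(float(v) for v in bc)
        return cls(**d)


def pixel_q_coordinates(geom: DetectorGeometry) -> np.ndarray:
    """Reciprocal-space coordinates of every pixel center, shape (p, 3).

    Pure function of the geometry; row order is slow-major (row ``j`` of the
    detector, then fast index ``i``), matching ``counts.reshape(n_slow, n_fast)``.
    """
    cf, cs = geom.beam_center
    x = (np.arange(geom.n_fast) + 0.5 - cf) * geom.pixel_size
    y = (np.arange(geom.n_slow) + 0.5 - cs) * geom.pixel_size
    yy, xx = np.meshgrid(y, x, indexing="ij")
    if geom.curvature_mode == "flat":
        qx = xx / (geom.wavelength * geom.distance)
        qy = yy / (geom.wavelength * geom.distance)
        qz = np.zeros_like(qx)
    else:
        norm = np.sqrt(xx ** 2 + yy ** 2 + geom.distance ** 2)
        qx = xx / norm / geom.wavelength
        qy = yy / norm / geom.wavelength
        qz = (geom.distance / norm - 1.0) / geom.wavelength
    return np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=-1)


def q_max(geom: DetectorGeometry) -> float:
    """Largest |q| over the detector (set by the corner pixels)."""
    return float(np.max(np.linalg.norm(pixel_q_coordinates(geom), axis=1)))


def shannon_pixel_check(geom: DetectorGeometry, object_diameter: float) -> dict:
    """Check that the pixel raster oversamples the diffraction speckle.

    A compact object of diameter D produces intensity speckles of width
    ``1/D`` in reciprocal space; Shannon–Nyquist sampling requires a pixel
    q-spacing of at most ``1/(2D)``.  Returns the measured central spacing,
    the required spacing, their ratio, and a pass flag (ratio <= 1).
    """
    qs = pixel_q_coordinates(geom).reshape(geom.n_slow, geom.n_fast, 3)
    jc, ic = geom.n_slow // 2, geom.n_fast // 2
    spacing = float(np.linalg.norm(qs[jc, ic] - qs[jc, ic - 1])) if geom.n_fast > 1 else 0.0
    required = 1.0 / (2.0 * object_diameter)
    ratio = spacing / required
    return {"pixel_q_spacing": spacing, "required_spacing": required,
            "ratio": ratio, "pass": bool(ratio <= 1.0 + 1e-9)}


def shannon_geometry(
    n: int = 32,
    object_diameter: float = 1.0,
    distance: float = 1.0,
    wavelength: float | None = None,
    curvature_mode: str = "curved",
) -> DetectorGeometry:
    """Square detector whose central pixel q-spacing equals 1/(2D).

    The default wavelength ``D/32`` keeps the corner scattering angle modest
    (about 20 degrees for n = 32) so Ewald curvature is present but mild.
    """
    if wavelength is None:
        wavelength = object_diameter / 32.0
    pixel_size = wavelength * distance / (2.0 * object_diameter)
    return DetectorGeometry(
        n_fast=n, n_slow=n, pixel_size=pixel_size, distance=distance,
        wavelength=wavelength, curvature_mode=curvature_mode,
    )
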