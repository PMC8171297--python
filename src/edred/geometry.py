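"""Experiment geometry and detector <-> reciprocal-space mapping.

Conventions used throughout the package (stated once, here):

* pixel indices are 0-based and refer to pixel centers;
* ``x`` is the fast axis (last array dimension), ``y`` the slow axis, so an
  image is indexed ``image[y, x]``;
* the nominal detector center of an ``(ny, nx)`` detector is
  ``(nx / 2, ny / 2)`` in (x, y) order;
* scattering-vector lengths are reported as ``1/d`` in 1/Angstrom;
* the beam travels along +z in the laboratory frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants


@dataclass
class Geometry:
    """Still-diffraction camera geometry.

    Parameters
    ----------
    camera_length : float
        Effective camera length L in mm.
    pixel_size : float
        Pixel pitch p in mm.
    wavelength : float
        Electron de Broglie wavelength in Angstrom.
    detector_shape : tuple of int
        ``(ny, nx)`` detector size in pixels.
    ellipticity : tuple of float
        ``(eta, theta)``: axis ratio (major/minor, >= 1) and major-axis
        angle in rad of the residual elliptical distortion of the
        diffraction pattern.
    """

    camera_length: float = 2000.0
    pixel_size: float = 0.055
    wavelength: float = 0.0251
    detector_shape: tuple[int, int] = (1024, 1024)
    ellipticity: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.camera_length <= 0 or self.pixel_size <= 0 or self.wavelength <= 0:
            raise ValueError("camera_length, pixel_size and wavelength must be positive")
        eta, _ = self.ellipticity
        if eta < 1:
            raise ValueError("ellipticity axis ratio must be >= 1 (major/minor)")

    @property
    def detector_center(self) -> tuple[float, float]:
        """Nominal center (x, y) in px."""
        ny, nx = self.detector_shape
        return (nx / 2.0, ny / 2.0)

    # -- radius <-> scattering vector -------------------------------------

    def r_to_q(self, r_px, paraxial: bool = True):
        """Convert radius on the detector (px) to 1/d (1/A).

        The paraxial (small-angle) form is ``1/d = r p / (L lambda)``; the
        exact form uses ``1/d = 2 sin(theta_B)/lambda`` with
        ``tan(2 theta_B) = r p / L``.  For electron diffraction the two
        differ by well below 0.1% over the detector.
        """
        r_px = np.asarray(r_px, dtype=float)
        if paraxial:
            return r_px * self.pixel_size / (self.camera_length * self.wavelength)
        two_theta = np.arctan(r_px * self.pixel_size / self.camera_length)
        return 2.0 * np.sin(two_theta / 2.0) / self.wavelength

    def q_to_r(self, q, paraxial: bool = True):
        """Convert 1/d (1/A) to radius on the detector (px)."""
        q = np.asarray(q, dtype=float)
        if paraxial:
            return q * self.camera_length * self.wavelength / self.pixel_size
        two_theta = 2.0 * np.arcsin(np.clip(q * self.wavelength / 2.0, -1.0, 1.0))
        return np.tan(two_theta) * self.camera_length / self.pixel_size

    def pixel_to_q(self, x, y, center=None, paraxial: bool = True):
        """Map detector coordinates to scattering-vector components.

        Returns ``(qx, qy, qabs)`` with components along the detector axes,
        all in 1/A.  Coordinates are expected to be ellipticity-corrected.
        """
        if center is None:
            center = self.detector_center
        dx = np.asarray(x, dtype=float) - center[0]
        dy = np.asarray(y, dtype=float) - center[1]
        scale = self.pixel_size / (self.camera_length * self.wavelength)
        qx, qy = dx * scale, dy * scale
        qabs = self.r_to_q(np.hypot(dx, dy), paraxial=paraxial)
        return qx, qy, qabs


def electron_wavelength(accel_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron, in Angstrom.

    ``lambda = h / sqrt(2 m_e e V (1 + e V / (2 m_e c^2)))`` for an
    accelerating voltage V; at 200 kV this gives 0.0251 A.
    """
    if accel_kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    ev = accel_kv * 1e3 * constants.e
    mc2 = constants.m_e * constants.c**2
    p = np.sqrt(2.0 * constants.m_e * ev * (1.0 + ev / (2.0 * mc2)))
    return constants.h / p * 1e10
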