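"""Physical and sampling parameters shared by every propagator.

All lengths are held in nanometres internally.  The wavenumber is
``k = 2*pi*n/lambda`` with ``n`` the refractive index of the propagation
medium, and the pupil cut-off is ``s_max = NA/n_i`` with ``n_i`` the index
of the immersion medium.  The default configuration uses a single
homogeneous medium (``n_sample == n_immersion``); stratified-layer effects
enter only through the correction factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["OpticalSetup", "SamplingGrid", "derived_quantities"]


@dataclass(frozen=True)
class OpticalSetup:
    """Physical constants of the focusing system.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective (dimensionless).  Must satisfy
        ``0 <= na < n_immersion`` so that ``s_max = na/n_immersion < 1`` and
        the axial direction cosine ``sz = sqrt(1 - sx**2 - sy**2)`` stays
        real and strictly positive on the pupil disk.
    wavelength : float
        Vacuum wavelength in nm.
    n_sample : float
        Refractive index of the propagation medium (enters the wavenumber).
    n_immersion : float
        Refractive index of the immersion medium (sets the cut-off).
    focal_length : float
        Focal length f in mm; only enters the constant prefactor
        ``-i f k / (2 pi)`` common to all propagators.
    polarisation : tuple of complex
        Jones vector (ex, ey) of the incident field; normalised to unit
        modulus on construction.
    """

    na: float
    wavelength: float
    n_sample: float = 1.0
    n_immersion: float = 1.0
    focal_length: float = 3.0
    polarisation: tuple = (1.0 + 0.0j, 0.0 + 0.0j)

    def __post_init__(self):
        if not self.na >= 0:
            raise ValueError(f"na must be >= 0, got {self.na}")
        if not self.na < self.n_immersion:
            raise ValueError(
                f"na must be < n_immersion (got na={self.na}, "
                f"n_immersion={self.n_immersion}); otherwise sz is not real "
                "on the pupil disk"
            )
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.n_sample < 1 or self.n_immersion < 1:
            raise ValueError("refractive indices must be >= 1")
        jones = np.asarray(self.polarisation, dtype=complex)
        if jones.shape != (2,):
            raise ValueError("polarisation must be a 2-vector (ex, ey)")
        norm = float(np.linalg.norm(jones))
        if norm == 0:
            raise ValueError("polarisation vector must be non-zero")
        object.__setattr__(self, "polarisation", tuple(jones / norm))

    @property
    def jones(self) -> np.ndarray:
        return np.asarray(self.polarisation, dtype=complex)


@dataclass(frozen=True)
class SamplingGrid:
    """Discretisation of the pupil and of the focal region.

    ``pupil_size`` is the number of samples per pupil axis (Cartesian) or
    the number of theta samples (spherical); it must be odd so one sample
    sits exactly on the optical axis and so the composite Simpson rule sees
    an even interval count.  ``out_size`` is odd for the same reason: one
    output pixel sits exactly at rho = 0.
    """

    pupil_size: int = 513
    out_size: int = 201
    pixel_size: float = 20.0
    z_planes: tuple = (0.0,)

    def __post_init__(self):
        if self.pupil_size < 3 or self.pupil_size % 2 == 0:
            raise ValueError(
                f"pupil_size must be odd and >= 3, got {self.pupil_size}"
            )
        if self.out_size < 1 or self.out_size % 2 == 0:
            raise ValueError(f"out_size must be odd, got {self.out_size}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "z_planes", tuple(float(z) for z in self.z_planes))

    @property
    def n_z(self) -> int:
        return len(self.z_planes)

    def output_coords(self) -> np.ndarray:
        """Centred focal-plane sample positions (nm), one axis."""
        m = np.arange(self.out_size) - (self.out_size - 1) / 2
        return m * self.pixel_size


def derived_quantities(setup: OpticalSetup) -> tuple[float, float, float]:
    """Return ``(k, s_max, theta_max)`` for a validated setup.

    k = 2*pi*n_sample/wavelength (rad/nm), s_max = na/n_immersion,
    theta_max = arcsin(s_max) (rad, measured in the immersion medium).
    """
    k = 2.0 * math.pi * setup.n_sample / setup.wavelength
    s_max = setup.na / setup.n_immersion
    theta_max = math.asin(s_max)
    return k, s_max, theta_max
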