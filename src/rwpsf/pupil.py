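"""Sampled incident / far fields on Cartesian pupil grids or spherical theta-lines.

A pupil field lives either on an ``N x N`` Cartesian grid over the direction
cosines ``(sx, sy)`` in ``[-s_max, s_max]**2`` (hard-masked to the disk
``sx**2 + sy**2 <= s_max**2``), or — for axisymmetric fields — on a 1D line
of polar angles ``theta`` in ``[0, theta_max]``.  Channels: 1 for scalar
fields, 3 for the (x, y, z) components of a vectorial field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .optical_config import OpticalSetup, SamplingGrid, derived_quantities

__all__ = [
    "PupilField",
    "pupil_coords",
    "uniform_pupil",
    "apply_polarisation",
    "is_axisymmetric",
    "cartesian_to_spherical_profile",
]

#: default relative tolerance for the axisymmetry check (programmatic pupils
#: are symmetric up to rounding)
AXISYM_TOL = 1e-9


@dataclass
class PupilField:
    """A sampled pupil / far field.

    values : complex ndarray
        ``(channels, N, N)`` for the Cartesian parameterisation (first image
        axis is sy, second is sx), or ``(channels, n_theta)`` for the
        spherical one.
    """

    parameterisation: str  # "cartesian" | "spherical"
    values: np.ndarray
    s_max: float
    theta_max: float
    axisymmetric: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.parameterisation == "cartesian":
            if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
                raise ValueError("cartesian pupil values must be (channels, N, N)")
        elif self.parameterisation == "spherical":
            if self.values.ndim != 2:
                raise ValueError("spherical pupil values must be (channels, n_theta)")
            if not self.axisymmetric:
                raise ValueError("spherical parameterisation requires axisymmetric=True")
        else:
            raise ValueError(f"unknown parameterisation {self.parameterisation!r}")
        if self.channels not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {self.channels}")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Samples per axis (cartesian) or along theta (spherical)."""
        return self.values.shape[-1]

    def copy_with(self, values: np.ndarray) -> "PupilField":
        return replace(self, values=np.asarray(values, dtype=complex))


def pupil_coords(n: int, s_max: float):
    """Cartesian pupil-grid coordinates and the disk mask.

    Returns ``(sx, sy, mask)`` as 2D arrays; ``sx`` varies along the last
    axis, ``sy`` along the first.  Samples follow
    ``s_i = -s_max + i * (2 s_max / (N-1))`` so the centre sample of an odd
    grid is exactly on axis.  The mask is a hard binary disk
    (``sx**2 + sy**2 <= s_max**2``).
    """
    s = np.linspace(-s_max, s_max, n)
    sx, sy = np.meshgrid(s, s, indexing="xy")
    mask = sx**2 + sy**2 <= s_max**2 + 1e-15 * s_max**2
    return sx, sy, mask


def theta_line(n_theta: int, theta_max: float) -> np.ndarray:
    """Uniform theta samples on [0, theta_max]."""
    return np.linspace(0.0, theta_max, n_theta)


def uniform_pupil(
    setup: OpticalSetup, grid: SamplingGrid, parameterisation: str = "cartesian"
) -> PupilField:
    """Unit-amplitude, zero-phase scalar pupil (the canonical circular aperture)."""
    _, s_max, theta_max = derived_quantities(setup)
    if parameterisation == "cartesian":
        _, _, mask = pupil_coords(grid.pupil_size, s_max)
        values = mask.astype(complex)[None]
        return PupilField("cartesian", values, s_max, theta_max, axisymmetric=True)
    if parameterisation == "spherical":
        values = np.ones((1, grid.pupil_size), dtype=complex)
        return PupilField("spherical", values, s_max, theta_max, axisymmetric=True)
    raise ValueError(f"unknown parameterisation {parameterisation!r}")


def apply_polarisation(scalar_pupil: PupilField, jones, tol: float = 1e-9) -> PupilField:
    """Turn a 1-channel pupil into a 3-channel incident field (ex*p, ey*p, 0).

    The z channel of the incident field is zero by construction; the
    vectorial basis change later populates it.  Circular polarisation is
    ``(1, 1j)/sqrt(2)``.
    """
    if scalar_pupil.channels != 1:
        raise ValueError("apply_polarisation expects a 1-channel scalar pupil")
    jones = np.asarray(jones, dtype=complex)
    if jones.shape != (2,):
        raise ValueError("jones must be a 2-vector")
    if abs(np.linalg.norm(jones) - 1.0) > tol:
        raise ValueError("jones vector must be normalised to |jones| = 1")
    p = scalar_pupil.values[0]
    values = np.stack([jones[0] * p, jones[1] * p, np.zeros_like(p)])
    return scalar_pupil.copy_with(values)


def is_axisymmetric(pupil: PupilField, tol: float = AXISYM_TOL) -> bool:
    """True if the pupil depends only on radius.

    For every radial bin the spread (standard deviation over the angle) of
    the complex values must stay below ``tol`` times the maximum amplitude.
    """
    if pupil.parameterisation == "spherical":
        return True
    n = pupil.n
    sx, sy, mask = pupil_coords(n, pupil.s_max)
    r = np.hypot(sx, sy)
    # group by *equal* radius: symmetric samples of the centred grid share
    # their radius up to last-ulp rounding, which the quantisation absorbs
    bins = np.round(r / pupil.s_max * 1e10).astype(np.int64)
    vmax = np.abs(pupil.values).max()
    if vmax == 0:
        return True
    for ch in range(pupil.channels):
        vals = pupil.values[ch][mask]
        b = bins[mask]
        order = np.argsort(b, kind="stable")
        vals, b = vals[order], b[order]
        starts = np.searchsorted(b, np.unique(b))
        for lo, hi in zip(starts, np.append(starts[1:], len(b))):
            seg = vals[lo:hi]
            if seg.size > 1 and np.std(seg) > tol * vmax:
                return False
    return True


def cartesian_to_spherical_profile(
    pupil: PupilField, n_theta: int, tol: float = AXISYM_TOL
) -> PupilField:
    """Resample an axisymmetric Cartesian pupil onto a theta-line.

    The radial profile is read off the central row of the grid (sx >= 0,
    sy = 0) and interpolated linearly in sin(theta) at
    ``sin(theta_j) = s_max * sin(theta_j)/s_max`` — i.e. linear in the
    radial direction cosine.
    """
    if pupil.parameterisation != "cartesian":
        raise ValueError("input must be a cartesian pupil")
    if not is_axisymmetric(pupil, tol):
        raise ValueError("pupil is not axisymmetric; spherical profile undefined")
    n = pupil.n
    centre = (n - 1) // 2
    s_radial = np.linspace(0.0, pupil.s_max, centre + 1)
    theta = theta_line(n_theta, pupil.theta_max)
    sin_t = np.sin(theta)
    profiles = []
    for ch in range(pupil.channels):
        radial = pupil.values[ch][centre, centre:]
        re = np.interp(sin_t, s_radial, radial.real)
        im = np.interp(sin_t, s_radial, radial.imag)
        profiles.append(re + 1j * im)
    return PupilField(
        "spherical",
        np.stack(profiles),
        pupil.s_max,
        pupil.theta_max,
        axisymmetric=True,
    )
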