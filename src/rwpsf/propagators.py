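"""The four focal-field propagators of the Richards-Wolf framework.

The focal field is the angular superposition

    E(rho) = -i f k / (2 pi) * integral over the aperture solid angles of
             e_inf(s) * exp(+i k s . rho) dOmega

evaluated in one of two parameterisations of the same integral:

* **Cartesian** — direction cosines ``(sx, sy)``, ``dOmega = dsx dsy / sz``:
  per z-plane a sized 2D Fourier transform of ``e_inf * exp(i k sz z) / sz``.
  Fully general (any pupil).
* **Spherical** — polar angle ``theta`` only, valid for axisymmetric pupils:
  the azimuthal integral is done analytically and leaves 1D Bessel-kernel
  integrals over ``[0, theta_max]`` (J0 for the scalar model; J0/J1/J2 for
  the vectorial one).

Scalar propagators take ``e_inf = e_inc`` (1 channel); vectorial ones apply
the cylindrical-to-spherical basis change first (3 channels).  Output layout
is always ``(z, channel, x, y)`` where the last axis is x (columns) and the
second-to-last is y (rows, increasing upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .numerics import QuadratureRule, bessel_j, integrate_1d, sized_ft_2d
from .optical_config import OpticalSetup, SamplingGrid, derived_quantities
from .pupil import PupilField, pupil_coords, theta_line

__all__ = [
    "FocalField",
    "far_field_from_incident",
    "vectorial_far_field",
    "scalar_cartesian",
    "scalar_spherical",
    "vectorial_cartesian",
    "vectorial_spherical",
    "intensity",
]

_MM_TO_NM = 1.0e6


@dataclass
class FocalField:
    """Complex focal field stack with layout (z, channel, x, y)."""

    data: np.ndarray
    pixel_size: float
    z_planes: tuple
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("focal field data must be 4D (z, channel, x, y)")
        if self.data.shape[1] not in (1, 3):
            raise ValueError("channel dimension must be 1 (scalar) or 3 (vectorial)")
        if self.data.shape[0] != len(self.z_planes):
            raise ValueError("first axis must match the number of z planes")

    @property
    def channels(self) -> int:
        return self.data.shape[1]


def _prefactor(setup: OpticalSetup, k: float) -> complex:
    """Common constant -i f k / (2 pi), f converted from mm to nm."""
    return -1j * setup.focal_length * _MM_TO_NM * k / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# Vectorial basis change (cylindrical incident field -> spherical far field)


def far_field_from_incident(einc, theta, phi, q_s=1.0, q_p=1.0):
    """Cylindrical-to-spherical basis change of the incident field.

    ``einc`` is a 3-channel stack (x, y, z components; the z channel must be
    zero — a transverse incident beam).  ``theta``/``phi`` give the ray
    direction per sample; ``q_s``/``q_p`` are the Fresnel transmission
    products (scalars or same-shaped arrays, default 1).  At ``theta = 0``
    with unit coefficients the far field equals the incident field; for
    ``q_s = q_p = 1`` the map is a rotation (it preserves the 3-vector norm).
    """
    einc = np.asarray(einc, dtype=complex)
    if einc.shape[0] != 3:
        raise ValueError("einc must have 3 channels")
    if np.any(einc[2] != 0):
        raise ValueError("incident field must be transverse (zero z channel)")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cos_2p, sin_2p = np.cos(2 * phi), np.sin(2 * phi)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    ex, ey = einc[0], einc[1]
    out_x = (
        (q_s * (1 - cos_2p) + q_p * (1 + cos_2p) * cos_t) * ex
        + (-q_s + q_p * cos_t) * sin_2p * ey
    ) / 2.0
    out_y = (
        (-q_s + q_p * cos_t) * sin_2p * ex
        + (q_s * (1 + cos_2p) + q_p * (1 - cos_2p) * cos_t) * ey
    ) / 2.0
    out_z = (-2.0 * q_p * cos_p * sin_t * ex - 2.0 * q_p * sin_p * sin_t * ey) / 2.0
    return np.stack([out_x, out_y, out_z])


def vectorial_far_field(pupil: PupilField, q_s=1.0, q_p=1.0) -> PupilField:
    """Apply the basis change on a 3-channel Cartesian pupil's own grid."""
    if pupil.parameterisation != "cartesian":
        raise ValueError("vectorial_far_field expects a cartesian pupil")
    if pupil.channels != 3:
        raise ValueError("apply a polarisation first (3 channels required)")
    sx, sy, mask = pupil_coords(pupil.n, pupil.s_max)
    r = np.clip(np.hypot(sx, sy), 0.0, 1.0)
    theta = np.arcsin(r)
    phi = np.arctan2(sy, sx)
    out = far_field_from_incident(pupil.values, theta, phi, q_s, q_p)
    out *= mask[None]
    return pupil.copy_with(out)


# ---------------------------------------------------------------------------
# Cartesian propagators


def _cartesian_field(pupil: PupilField, setup: OpticalSetup, grid: SamplingGrid):
    k, s_max, _ = derived_quantities(setup)
    n = pupil.n
    sx, sy, mask = pupil_coords(n, s_max)
    sz = np.sqrt(np.clip(1.0 - sx**2 - sy**2, 0.0, None))
    sz_safe = np.where(mask, sz, 1.0)  # sz >= sqrt(1 - s_max^2) > 0 on the disk
    ds = 2.0 * s_max / (n - 1)
    scale = _prefactor(setup, k) * ds * ds
    m = grid.out_size
    planes = []
    base = np.where(mask, pupil.values / sz_safe, 0.0)
    for z in grid.z_planes:
        kernel = base * np.where(mask, np.exp(1j * k * sz * z), 0.0)
        out = sized_ft_2d(kernel, ds, -s_max, grid.pixel_size, m, k)
        planes.append(scale * out)
    return np.stack(planes)


def scalar_cartesian(
    pupil: PupilField, setup: OpticalSetup, grid: SamplingGrid
) -> FocalField:
    """Scalar focal field via the sized 2D Fourier transform of e/sz."""
    if pupil.parameterisation != "cartesian" or pupil.channels != 1:
        raise ValueError("scalar_cartesian expects a 1-channel cartesian pupil")
    data = _cartesian_field(pupil, setup, grid)
    return FocalField(
        data,
        grid.pixel_size,
        grid.z_planes,
        {"propagator": "scalar_cartesian", "setup": setup},
    )


def vectorial_cartesian(
    pupil3: PupilField, setup: OpticalSetup, grid: SamplingGrid
) -> FocalField:
    """Vectorial focal field: one sized transform per far-field component.

    ``pupil3`` must already be the far field (pass the polarised incident
    pupil through :func:`vectorial_far_field` first).
    """
    if pupil3.parameterisation != "cartesian" or pupil3.channels != 3:
        raise ValueError("vectorial_cartesian expects a 3-channel cartesian pupil")
    data = _cartesian_field(pupil3, setup, grid)
    return FocalField(
        data,
        grid.pixel_size,
        grid.z_planes,
        {"propagator": "vectorial_cartesian", "setup": setup},
    )


# ---------------------------------------------------------------------------
# Spherical propagators


def _radial_layout(grid: SamplingGrid):
    """Unique radii of the output grid and the inverse scatter map."""
    coords = grid.output_coords()
    x, y = np.meshgrid(coords, coords, indexing="xy")
    r = np.hypot(x, y)
    r_unique, inverse = np.unique(r, return_inverse=True)
    return x, y, r_unique, inverse.reshape(r.shape)


def scalar_spherical(
    pupil: PupilField,
    setup: OpticalSetup,
    grid: SamplingGrid,
    rule: QuadratureRule | None = None,
) -> FocalField:
    """Scalar focal field via the 1D Bessel (J0) integral.

    ``E(rho, z) = -i f k * int_0^theta_max e(theta) J0(k rho sin th)
    exp(i k z cos th) sin th dtheta``; evaluated at the sorted unique radii
    of the output grid and scattered onto the image by radial symmetry, one
    z-plane at a time.
    """
    if pupil.parameterisation != "spherical" or pupil.channels != 1:
        raise ValueError("scalar_spherical expects a 1-channel spherical profile")
    if rule is None:
        rule = QuadratureRule("simpson", pupil.n)
    if rule.n_points != pupil.n:
        raise ValueError("rule.n_points must match the pupil theta sampling")
    k, _, theta_max = derived_quantities(setup)
    theta = theta_line(pupil.n, theta_max)
    h = theta_max / (pupil.n - 1)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    _, _, r_unique, inverse = _radial_layout(grid)
    j0 = bessel_j(0, k * r_unique[:, None] * sin_t[None, :])
    base = pupil.values[0] * sin_t  # (n_theta,)
    pref = 2.0 * np.pi * _prefactor(setup, k)  # -i f k
    m = grid.out_size
    planes = []
    for z in grid.z_planes:
        integrand = j0 * (base * np.exp(1j * k * z * cos_t))[None, :]
        e_radial = pref * integrate_1d(integrand, h, rule, axis=-1)
        planes.append(e_radial[inverse][None])
    data = np.stack(planes).reshape(grid.n_z, 1, m, m)
    return FocalField(
        data,
        grid.pixel_size,
        grid.z_planes,
        {"propagator": "scalar_spherical", "setup": setup, "rule": rule.name},
    )


def vectorial_spherical(
    pupil3: PupilField,
    setup: OpticalSetup,
    grid: SamplingGrid,
    rule: QuadratureRule | None = None,
    q_s=1.0,
    q_p=1.0,
) -> FocalField:
    """Vectorial focal field from the six radial Bessel integrals.

    For each transverse incident component ``a`` in {x, y} with radial
    profile ``e_a(theta)``:

        I0a = int e_a sin th (q_s + q_p cos th)   J0(k rho sin th) exp(i k z cos th) dth
        I1a = int e_a q_p sin^2 th                J1(k rho sin th) exp(i k z cos th) dth
        I2a = int e_a sin th (q_p cos th - q_s)   J2(k rho sin th) exp(i k z cos th) dth

    (``q_s = q_p = 1`` recovers the bare kernels ``(cos th + 1)``,
    ``sin^2 th`` and ``(cos th - 1)``), assembled as

        Ex = -(i f k / 2) (I0x - I2x cos 2phi - I2y sin 2phi)
        Ey = -(i f k / 2) (-I2x sin 2phi + I0y + I2y cos 2phi)
        Ez = -(i f k / 2) (-2i I1x cos phi - 2i I1y sin phi)

    with ``phi`` the focal-plane azimuth measured from +x.
    """
    if pupil3.parameterisation != "spherical" or pupil3.channels != 3:
        raise ValueError("vectorial_spherical expects a 3-channel spherical profile")
    if np.any(pupil3.values[2] != 0):
        raise ValueError("incident profile must be transverse (zero z channel)")
    if rule is None:
        rule = QuadratureRule("simpson", pupil3.n)
    if rule.n_points != pupil3.n:
        raise ValueError("rule.n_points must match the pupil theta sampling")
    k, _, theta_max = derived_quantities(setup)
    n_t = pupil3.n
    theta = theta_line(n_t, theta_max)
    h = theta_max / (n_t - 1)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    q_s = np.broadcast_to(np.asarray(q_s, dtype=complex), theta.shape)
    q_p = np.broadcast_to(np.asarray(q_p, dtype=complex), theta.shape)
    kern0 = sin_t * (q_s + q_p * cos_t)
    kern1 = q_p * sin_t**2
    kern2 = sin_t * (q_p * cos_t - q_s)

    x, y, r_unique, inverse = _radial_layout(grid)
    phi = np.arctan2(y, x)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    cos_2p, sin_2p = np.cos(2 * phi), np.sin(2 * phi)
    arg = k * r_unique[:, None] * sin_t[None, :]
    j = [bessel_j(0, arg), bessel_j(1, arg), bessel_j(2, arg)]
    kerns = [kern0, kern1, kern2]
    pref = 2.0 * np.pi * _prefactor(setup, k) / 2.0  # -i f k / 2
    m = grid.out_size
    planes = []
    for z in grid.z_planes:
        defocus = np.exp(1j * k * z * cos_t)
        integrals = np.empty((3, 2, r_unique.size), dtype=complex)
        for order in range(3):
            for a in range(2):  # 0: x profile, 1: y profile
                integrand = j[order] * (pupil3.values[a] * kerns[order] * defocus)[None, :]
                integrals[order, a] = integrate_1d(integrand, h, rule, axis=-1)
        i0x, i0y = integrals[0, 0][inverse], integrals[0, 1][inverse]
        i1x, i1y = integrals[1, 0][inverse], integrals[1, 1][inverse]
        i2x, i2y = integrals[2, 0][inverse], integrals[2, 1][inverse]
        ex = pref * (i0x - i2x * cos_2p - i2y * sin_2p)
        ey = pref * (-i2x * sin_2p + i0y + i2y * cos_2p)
        ez = pref * (-2j * i1x * cos_p - 2j * i1y * sin_p)
        planes.append(np.stack([ex, ey, ez]))
    data = np.stack(planes).reshape(grid.n_z, 3, m, m)
    return FocalField(
        data,
        grid.pixel_size,
        grid.z_planes,
        {"propagator": "vectorial_spherical", "setup": setup, "rule": rule.name},
    )


def intensity(focal: FocalField, mode: str = "intensity") -> np.ndarray:
    """Channel-summed |E|^2 (or its square root in ``mode='amplitude'``)."""
    i = np.sum(np.abs(focal.data) ** 2, axis=1)
    if mode == "intensity":
        return i
    if mode == "amplitude":
        return np.sqrt(i)
    raise ValueError("mode must be 'intensity' or 'amplitude'")
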