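"""Amplitude and phase correction factors applied to pupils before propagation.

Covers refractive-index-mismatch (Gibson-Lanni) spherical aberration,
Zernike / custom / vortex phase masks, the apodisation factor of the
plane-to-sphere basis change, Gaussian beam envelopes, and Fresnel
transmission products through stratified media.  All factors are sampled on
the pupil's own parameterisation and composed multiplicatively as
``a(s) * exp(1j * W(s))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pupil import PupilField, pupil_coords

__all__ = [
    "LayeredMedium",
    "AberrationSpec",
    "gibson_lanni_phase",
    "immersion_thickness_from_focus",
    "zernike_polynomial",
    "zernike_phase",
    "vortex_phase",
    "half_moon_phase",
    "apodisation",
    "gaussian_envelope",
    "fresnel_coefficients",
    "apply_corrections",
]


@dataclass(frozen=True)
class LayeredMedium:
    """Stratified sample / glass / immersion stack, actual and design values.

    Indices ``n_s, n_i, n_g`` and thicknesses ``t_s, t_i, t_g`` (nm) describe
    the actual sample, immersion and glass layers; the starred counterparts
    are the design conditions the objective was corrected for.  ``t_i`` may
    be None, in which case it is obtained from the focusing condition (the
    immersion thickness is tuned experimentally to focus an emitter at depth
    ``t_s``).
    """

    n_s: float = 1.33
    n_i: float = 1.5
    n_g: float = 1.5
    t_s: float = 0.0
    t_g: float = 170_000.0
    t_i: float | None = None
    n_i_star: float = 1.5
    n_g_star: float = 1.5
    t_i_star: float = 150_000.0
    t_g_star: float = 170_000.0

    def __post_init__(self):
        for name in ("n_s", "n_i", "n_g", "n_i_star", "n_g_star"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("t_s", "t_g", "t_i_star", "t_g_star"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved_t_i(self) -> float:
        return self.t_i if self.t_i is not None else immersion_thickness_from_focus(self)


@dataclass
class AberrationSpec:
    """Zernike coefficients plus an optional free-form phase mask.

    ``zernike_coeffs`` is a list of ``(osa_index, coefficient)`` pairs; the
    coefficients are in radians unless ``unit='waves'`` (then multiplied by
    2*pi).  ``custom_phase`` is a 2D phase map in radians on the pupil grid.
    """

    zernike_coeffs: list = field(default_factory=list)
    custom_phase: np.ndarray | None = None
    unit: str = "radians"

    def __post_init__(self):
        if self.unit not in ("radians", "waves"):
            raise ValueError("unit must be 'radians' or 'waves'")

    def scale(self) -> float:
        return 2.0 * math.pi if self.unit == "waves" else 1.0


def immersion_thickness_from_focus(medium: LayeredMedium) -> float:
    """Immersion thickness t_i implied by the focusing condition.

    The immersion gap is adjusted until a point emitter at depth ``t_s``
    comes into focus, which fixes
    ``t_i = t_s + n_i * (-t_s/n_s - t_g/n_g + t_g*/n_g* + t_i*/n_i*)``.
    """
    m = medium
    if min(m.n_s, m.n_g, m.n_g_star, m.n_i_star) <= 0:
        raise ValueError("all refractive indices must be non-zero")
    return m.t_s + m.n_i * (
        -m.t_s / m.n_s - m.t_g / m.n_g + m.t_g_star / m.n_g_star + m.t_i_star / m.n_i_star
    )


def gibson_lanni_phase(
    medium: LayeredMedium, wavelength: float, sin_theta: np.ndarray
) -> np.ndarray:
    """Spherical-aberration phase of a mismatched stratified stack (radians).

    W = (2*pi/lambda) * [ t_s*sqrt(n_s^2 - n_i^2 sin^2 th)
                        + t_i*sqrt(n_i^2 - n_i^2 sin^2 th)
                        - t_i*.sqrt(n_i*^2 - n_i^2 sin^2 th)
                        + t_g*sqrt(n_g^2 - n_i^2 sin^2 th)
                        - t_g*.sqrt(n_g*^2 - n_i^2 sin^2 th) ]

    where ``theta`` is the ray angle in the immersion medium.  Supercritical
    angles into a lower-index layer make a square-root argument negative;
    the complex continuation is kept (the imaginary part of W becomes an
    evanescent amplitude decay) rather than clipped.
    """
    m = medium
    sin2 = np.asarray(sin_theta, dtype=complex) ** 2
    ni2s = m.n_i**2 * sin2
    t_i = m.resolved_t_i()
    w = (
        m.t_s * np.sqrt(m.n_s**2 - ni2s)
        + t_i * np.sqrt(m.n_i**2 - ni2s)
        - m.t_i_star * np.sqrt(m.n_i_star**2 - ni2s)
        + m.t_g * np.sqrt(m.n_g**2 - ni2s)
        - m.t_g_star * np.sqrt(m.n_g_star**2 - ni2s)
    )
    w = (2.0 * math.pi / wavelength) * w
    if np.all(np.abs(w.imag) < 1e-12 * (1 + np.abs(w.real))):
        return w.real
    return w


# ---------------------------------------------------------------------------
# Zernike and free-form phase masks


def _osa_to_nm(j: int) -> tuple[int, int]:
    """OSA/ANSI single index -> (radial order n, azimuthal frequency m)."""
    if j < 0:
        raise ValueError("OSA index must be >= 0")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def zernike_polynomial(j: int, rho: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal Zernike polynomial Z_j (OSA/ANSI indexing) on the unit disk.

    Normalised so that (1/pi) * integral over the unit disk of Z_i*Z_j is
    the identity.  Values outside rho > 1 are returned as evaluated (callers
    mask to the pupil disk).
    """
    n, m = _osa_to_nm(j)
    am = abs(m)
    rho = np.asarray(rho, dtype=float)
    radial = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
        radial += c * rho ** (n - 2 * k)
    norm = math.sqrt(2.0 * (n + 1)) if m != 0 else math.sqrt(n + 1.0)
    if m > 0:
        return norm * radial * np.cos(am * phi)
    if m < 0:
        return norm * radial * np.sin(am * phi)
    return norm * radial


def zernike_phase(spec: AberrationSpec, n: int, s_max: float) -> np.ndarray:
    """Phase map W = sum_k c_k Z_k + W0 (radians) on the Cartesian pupil grid.

    The pupil radius ``s_max`` maps to the unit radius of the Zernike disk.
    """
    sx, sy, _ = pupil_coords(n, s_max)
    rho = np.hypot(sx, sy) / s_max
    phi = np.arctan2(sy, sx)
    w = np.zeros((n, n))
    for j, c in spec.zernike_coeffs:
        w += spec.scale() * c * zernike_polynomial(int(j), rho, phi)
    if spec.custom_phase is not None:
        cp = np.asarray(spec.custom_phase, dtype=float)
        if cp.shape != (n, n):
            raise ValueError(
                f"custom_phase shape {cp.shape} does not match pupil grid ({n}, {n})"
            )
        w = w + cp
    return w


def vortex_phase(n: int, s_max: float, charge: int) -> np.ndarray:
    """Azimuthal phase ramp W = charge * phi, wrapped to [0, 2*pi).

    Charge 1 produces the donut beam used in STED depletion.
    """
    sx, sy, _ = pupil_coords(n, s_max)
    phi = np.arctan2(sy, sx)
    return np.mod(charge * phi, 2.0 * math.pi)


def half_moon_phase(n: int, s_max: float) -> np.ndarray:
    """Pi phase step across the pupil: W = pi for sx > 0, else 0."""
    sx, _, _ = pupil_coords(n, s_max)
    return math.pi * (sx > 0)


# ---------------------------------------------------------------------------
# Amplitude factors


def apodisation(sin_theta: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Energy-conservation amplitude factor A = (cos theta)^exponent.

    The default exponent 1 gives A = cos(theta); the classic Richards-Wolf
    choice sqrt(cos theta) is available via ``exponent=0.5``.  The exponent
    is explicit precisely because both conventions circulate — nothing is
    substituted silently.
    """
    cos_t = np.sqrt(np.clip(1.0 - np.asarray(sin_theta, float) ** 2, 0.0, None))
    return cos_t**exponent


def gaussian_envelope(sin_theta: np.ndarray, s_env: float) -> np.ndarray:
    """Gaussian beam envelope A = exp(-sin^2 theta / s_env^2)."""
    if not s_env > 0:
        raise ValueError("s_env must be > 0")
    return np.exp(-np.asarray(sin_theta, float) ** 2 / s_env**2)


def fresnel_coefficients(indices, theta_1):
    """Amplitude transmission products (q_s, q_p) through a layer stack.

    ``indices`` is the ordered list of layer refractive indices
    ``[n_1, ..., n_L]``; ``theta_1`` is the incidence angle (radians, scalar
    or array) in the first medium.  Angles in deeper layers follow Snell's
    law ``n_m sin th_m = n_{m+1} sin th_{m+1}``; a supercritical transition
    yields a complex cos(theta) and the evanescent (complex) coefficients
    are returned rather than clipped.  A single layer gives the empty
    product q_s = q_p = 1.
    """
    indices = list(indices)
    theta_1 = np.asarray(theta_1, dtype=float)
    q_s = np.ones(theta_1.shape, dtype=complex)
    q_p = np.ones(theta_1.shape, dtype=complex)
    sin_1 = np.sin(theta_1)
    for n_m, n_next in zip(indices[:-1], indices[1:]):
        sin_m = indices[0] * sin_1 / n_m
        sin_next = indices[0] * sin_1 / n_next
        cos_m = np.sqrt((1.0 + 0.0j) - sin_m**2)
        cos_next = np.sqrt((1.0 + 0.0j) - sin_next**2)
        q_s = q_s * 2.0 * n_m * cos_m / (n_m * cos_m + n_next * cos_next)
        q_p = q_p * 2.0 * n_m * cos_m / (n_next * cos_m + n_m * cos_next)
    if np.all(np.abs(q_s.imag) < 1e-14) and np.all(np.abs(q_p.imag) < 1e-14):
        return q_s.real, q_p.real
    return q_s, q_p


def apply_corrections(
    pupil: PupilField, amplitude_factors=(), phase_factors=()
) -> PupilField:
    """Multiply a pupil by amplitude factors and phase factors.

    ``values <- values * prod(a) * exp(1j * sum(W))``.  Factors are combined
    into a single product before application, so any ordering is
    bit-identical.  Each factor must be sampled on the pupil's own
    parameterisation (grid-shaped for cartesian, line-shaped for spherical).
    """
    shape = pupil.values.shape[1:]
    total = np.ones(shape, dtype=complex)
    for a in amplitude_factors:
        a = np.asarray(a)
        if a.shape != shape:
            raise ValueError(f"amplitude factor shape {a.shape} != pupil shape {shape}")
        total = total * a
    w_sum = np.zeros(shape, dtype=complex)
    for w in phase_factors:
        w = np.asarray(w)
        if w.shape != shape:
            raise ValueError(f"phase factor shape {w.shape} != pupil shape {shape}")
        w_sum = w_sum + w
    if np.any(w_sum != 0):
        total = total * np.exp(1j * w_sum)
    return pupil.copy_with(pupil.values * total[None])
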