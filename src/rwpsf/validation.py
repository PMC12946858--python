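"""Airy-disk accuracy benchmark and convergence-order estimation.

The Fourier transform of a perfect unit-modulus circular aperture is the
Airy pattern ``F(rho) = 2 J1(rho) / rho``.  Multiplying the uniform pupil by
an extra ``cos(theta) = sz`` amplitude factor cancels the ``1/sz`` kernel of
the propagation integral (a paraxial reduction), so both scalar propagators
then compute a plain aperture transform whose exact value is known
analytically — any residual is pure discretisation error.  Refining the
sampling and fitting the log-log slope of that error against the step size
recovers the order of the underlying quadrature: first order for the left
Riemann rule, fourth order for composite Simpson, and between first and
second order for the Cartesian route (limited by the pixelated disk edge).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .corrections import apodisation, apply_corrections
from .numerics import QuadratureRule, bessel_j
from .optical_config import OpticalSetup, SamplingGrid, derived_quantities
from .propagators import scalar_cartesian, scalar_spherical
from .pupil import pupil_coords, theta_line, uniform_pupil

__all__ = ["ConvergenceReport", "airy_disk", "l2_error", "airy_benchmark"]

#: error floor below which points are excluded from the slope fit
ERROR_FLOOR = 1e-12


@dataclass
class ConvergenceReport:
    """(step size, L2 error) series plus the fitted convergence order."""

    step_sizes: np.ndarray
    errors: np.ndarray
    fitted_order: float
    propagator: str
    rule: str | None = None
    n_points: list = dc_field(default_factory=list)

    def __post_init__(self):
        self.step_sizes = np.asarray(self.step_sizes, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if np.any(np.diff(self.step_sizes) >= 0):
            raise ValueError("step sizes must be strictly decreasing")
        if np.any(self.errors <= 0):
            raise ValueError("errors must be positive")

    def rounds_to(self, order: int) -> bool:
        return abs(self.fitted_order - order) < 0.5

    def to_json(self, path):
        payload = {
            "propagator": self.propagator,
            "rule": self.rule,
            "n_points": list(self.n_points),
            "step_sizes": self.step_sizes.tolist(),
            "errors": self.errors.tolist(),
            "fitted_order": self.fitted_order,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def plot(self, path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        label = self.propagator + (f" ({self.rule})" if self.rule else "")
        ax.loglog(self.step_sizes, self.errors, "o-", label=label)
        ax.loglog(
            self.step_sizes,
            self.errors[0] * (self.step_sizes / self.step_sizes[0]) ** self.fitted_order,
            "k--",
            label=f"slope {self.fitted_order:.2f}",
        )
        ax.set_xlabel("step size h")
        ax.set_ylabel(r"L2 error $\delta$")
        ax.legend()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def airy_disk(rho: np.ndarray) -> np.ndarray:
    """Analytic Airy amplitude 2 J1(rho)/rho with the series limit 1 at 0."""
    rho = np.asarray(rho, dtype=float)
    out = np.ones_like(rho)
    nz = rho != 0
    out[nz] = 2.0 * bessel_j(1, rho[nz]) / rho[nz]
    return out


def l2_error(field: np.ndarray, reference: np.ndarray, normalise: bool = True) -> float:
    """delta = ||E - F||_2, by default after rescaling both to unit peak.

    Peak normalisation removes the constant ``-i f k`` prefactor (the
    analytic reference has peak 1); only the error shape matters for the
    order fit.  Pass ``normalise=False`` for the raw difference norm.
    """
    field = np.asarray(field)
    reference = np.asarray(reference)
    if field.shape != reference.shape:
        raise ValueError(f"shape mismatch: {field.shape} vs {reference.shape}")
    if normalise:
        # divide by the complex value at the peak so the constant (complex)
        # prefactor drops out entirely, phase included
        field = field / field.flat[int(np.argmax(np.abs(field)))]
        reference = reference / reference.flat[int(np.argmax(np.abs(reference)))]
    return float(np.linalg.norm(field - reference))


def _fit_order(h: np.ndarray, err: np.ndarray) -> float:
    """Log-log slope over the densest decade of h, above the error floor."""
    keep = (err > ERROR_FLOOR) & (h <= 10.0 * h.min())
    if keep.sum() < 2:
        raise ValueError("not enough usable points to fit a convergence order")
    slope, _ = np.polyfit(np.log(h[keep]), np.log(err[keep]), 1)
    return float(slope)


def _radial_slice(plane: np.ndarray) -> np.ndarray:
    """Centre-to-edge 1D line through the middle of an odd square image."""
    centre = (plane.shape[0] - 1) // 2
    return plane[centre, centre:]


def airy_benchmark(
    propagator: str,
    n_points,
    setup: OpticalSetup,
    grid: SamplingGrid,
    rule_name: str = "simpson",
) -> ConvergenceReport:
    """Convergence of a scalar propagator against the analytic Airy disk.

    ``propagator`` is ``"spherical"`` (with ``rule_name`` riemann/simpson;
    ``n_points`` are theta sample counts) or ``"cartesian"`` (``n_points``
    are pupil grid sizes; the quadrature is the pixel sum itself).  For each
    sampling density the focal plane at z = 0 of the cos(theta)-apodised
    uniform pupil is computed, peak-normalised, and compared on a radial
    line against ``airy_disk`` at the dimensionless radii
    ``rho_airy = k * s_max * rho_physical``.
    """
    if propagator not in ("spherical", "cartesian"):
        raise ValueError("propagator must be 'spherical' or 'cartesian'")
    n_points = sorted(int(n) for n in n_points)
    if len(n_points) < 3:
        raise ValueError("need at least 3 sampling densities to fit a slope")
    k, s_max, theta_max = derived_quantities(setup)
    coords = grid.output_coords()
    radii = coords[(grid.out_size - 1) // 2:]
    reference = airy_disk(k * s_max * radii)

    steps, errors = [], []
    for n in n_points:
        g = SamplingGrid(
            pupil_size=n,
            out_size=grid.out_size,
            pixel_size=grid.pixel_size,
            z_planes=(0.0,),
        )
        if propagator == "spherical":
            pupil = uniform_pupil(setup, g, "spherical")
            sin_t = np.sin(theta_line(n, theta_max))
            pupil = apply_corrections(pupil, amplitude_factors=[apodisation(sin_t)])
            rule = QuadratureRule(rule_name, n)
            focal = scalar_spherical(pupil, setup, g, rule)
            steps.append(theta_max / (n - 1))
        else:
            pupil = uniform_pupil(setup, g, "cartesian")
            sx, sy, _ = pupil_coords(n, s_max)
            sin_grid = np.clip(np.hypot(sx, sy), 0.0, 1.0)
            pupil = apply_corrections(pupil, amplitude_factors=[apodisation(sin_grid)])
            focal = scalar_cartesian(pupil, setup, g)
            steps.append(2.0 * s_max / (n - 1))
        line = _radial_slice(focal.data[0, 0])
        errors.append(l2_error(line, reference))

    h = np.asarray(steps)  # decreasing, since n_points is sorted ascending
    err = np.asarray(errors)
    order = _fit_order(h, err)
    return ConvergenceReport(
        step_sizes=h,
        errors=err,
        fitted_order=order,
        propagator=f"scalar_{propagator}",
        rule=rule_name if propagator == "spherical" else None,
        n_points=n_points,
    )
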