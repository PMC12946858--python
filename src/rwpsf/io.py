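"""Persistence, configuration and the end-to-end pipeline.

Field stacks are written either as multi-page float32 TIFF (pages ordered
z-major then channel, pixel size recorded in the resolution tags) or as an
uncompressed ``.npz`` archive that round-trips the complex data bit-exactly.
A :class:`RunConfig` mirrors every CLI flag and can be loaded from a YAML
file; :func:`run_from_config` drives pupil construction, corrections,
propagation, normalisation and saving.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .corrections import (
    AberrationSpec,
    LayeredMedium,
    apodisation,
    gaussian_envelope,
    gibson_lanni_phase,
    half_moon_phase,
    vortex_phase,
    zernike_phase,
    apply_corrections,
    _osa_to_nm,
)
from .numerics import QuadratureRule
from .optical_config import OpticalSetup, SamplingGrid, derived_quantities
from .propagators import (
    FocalField,
    intensity,
    scalar_cartesian,
    scalar_spherical,
    vectorial_cartesian,
    vectorial_far_field,
    vectorial_spherical,
)
from .pupil import apply_polarisation, pupil_coords, theta_line, uniform_pupil

__all__ = [
    "RunConfig",
    "save_stack",
    "load_stack",
    "load_pupil_mask",
    "normalise",
    "run_from_config",
]

logger = logging.getLogger("rwpsf")

_POLARISATIONS = {
    "circular": (1.0 / math.sqrt(2), 1j / math.sqrt(2)),
    "linear_x": (1.0, 0.0),
    "linear_y": (0.0, 1.0),
}


def save_stack(field: FocalField, path, format: str = "npz", mode: str = "complex"):
    """Write a focal-field stack to disk.

    ``format='npz'`` stores the complex array plus metadata verbatim
    (bit-exact round trip via :func:`load_stack`).  ``format='tiff'`` writes
    multi-page 32-bit float images, pages ordered z-major then channel, with
    the pixel size recorded in the TIFF resolution tags (pixels per
    centimetre); complex data must first be reduced with ``mode`` set to
    ``'amplitude'`` or ``'intensity'``.
    """
    path = Path(path)
    if format == "npz":
        np.savez(
            path,
            data=field.data,
            pixel_size=field.pixel_size,
            z_planes=np.asarray(field.z_planes),
            propagator=str(field.metadata.get("propagator", "")),
        )
        return path
    if format != "tiff":
        raise ValueError("format must be 'tiff' or 'npz'")
    if mode == "complex":
        raise ValueError(
            "TIFF stores real pages; use mode='amplitude' or 'intensity', "
            "or format='npz' for the complex field"
        )
    stack = intensity(field, mode=mode)  # (z, x, y)
    pages = stack[:, None].astype(np.float32)  # single channel per z
    if mode == "amplitude" and field.channels == 3:
        # keep per-channel amplitudes for vectorial fields
        pages = np.abs(field.data).astype(np.float32)
    pages = pages.reshape(-1, pages.shape[-2], pages.shape[-1])
    px_cm = 1.0e7 / field.pixel_size  # pixels per cm, pixel_size in nm
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        resolution=(px_cm, px_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_nm": field.pixel_size, "z_planes_nm": list(field.z_planes)},
    )
    return path


def load_stack(path) -> FocalField:
    """Load an ``.npz`` archive written by :func:`save_stack`."""
    with np.load(path, allow_pickle=False) as archive:
        return FocalField(
            data=archive["data"],
            pixel_size=float(archive["pixel_size"]),
            z_planes=tuple(archive["z_planes"].tolist()),
            metadata={"propagator": str(archive["propagator"])},
        )


def load_pupil_mask(path) -> np.ndarray:
    """Read a single-page float TIFF mask interpreted on the pupil grid."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("pupil masks must be single-page 2D TIFF images")
    return np.asarray(arr, dtype=float)


def normalise(field: FocalField, mode: str = "none") -> FocalField:
    """Rescale a focal field: 'none', 'max' (peak |E| = 1) or 'energy'
    (total channel-summed |E|^2 = 1)."""
    if mode == "none":
        return field
    if mode == "max":
        scale = np.abs(field.data).max()
    elif mode == "energy":
        scale = math.sqrt(float(np.sum(np.abs(field.data) ** 2)))
    else:
        raise ValueError("normalisation must be 'none', 'max' or 'energy'")
    data = field.data / scale if scale > 0 else field.data
    return FocalField(data, field.pixel_size, field.z_planes, dict(field.metadata))


@dataclass
class RunConfig:
    """Everything needed for one end-to-end PSF computation."""

    # optics
    na: float = 1.3
    wavelength: float = 632.0
    n_sample: float = 1.5
    n_immersion: float = 1.5
    focal_length: float = 3.0
    polarisation: str = "circular"
    # model
    propagator: str = "vectorial"  # scalar | vectorial
    parameterisation: str = "cartesian"  # cartesian | spherical
    quadrature: str = "simpson"  # riemann | simpson (spherical only)
    # sampling
    pupil_size: int = 513
    out_size: int = 201
    pixel_size: float = 20.0
    z_planes: tuple = (0.0,)
    # corrections
    gibson_lanni: bool = False
    medium: dict = dc_field(default_factory=dict)  # LayeredMedium overrides
    zernike: list = dc_field(default_factory=list)  # [index, coeff] pairs
    zernike_unit: str = "radians"
    vortex_charge: int = 0
    half_moon: bool = False
    custom_phase_tiff: str | None = None
    apodisation: bool = False
    apodisation_exponent: float = 1.0
    gaussian_s_env: float | None = None
    # output
    output: str | None = None
    format: str = "npz"  # tiff | npz
    mode: str = "complex"  # complex | amplitude | intensity
    normalisation: str = "none"  # none | max | energy

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.z_planes, (int, float)):
            cfg.z_planes = (float(cfg.z_planes),)
        cfg.z_planes = tuple(float(z) for z in cfg.z_planes)
        return cfg

    def jones(self):
        if self.polarisation in _POLARISATIONS:
            return np.asarray(_POLARISATIONS[self.polarisation], dtype=complex)
        raise ValueError(
            f"polarisation must be one of {sorted(_POLARISATIONS)}, "
            f"got {self.polarisation!r}"
        )

    def validate(self) -> list[str]:
        """Return all configuration problems at once (empty list if valid)."""
        errors = []
        if self.propagator not in ("scalar", "vectorial"):
            errors.append(f"propagator must be scalar|vectorial, got {self.propagator!r}")
        if self.parameterisation not in ("cartesian", "spherical"):
            errors.append(
                f"parameterisation must be cartesian|spherical, got "
                f"{self.parameterisation!r}"
            )
        if self.quadrature not in ("riemann", "simpson"):
            errors.append(f"quadrature must be riemann|simpson, got {self.quadrature!r}")
        if self.polarisation not in _POLARISATIONS:
            errors.append(f"unknown polarisation preset {self.polarisation!r}")
        if self.format not in ("tiff", "npz"):
            errors.append(f"format must be tiff|npz, got {self.format!r}")
        if self.mode not in ("complex", "amplitude", "intensity"):
            errors.append(f"mode must be complex|amplitude|intensity, got {self.mode!r}")
        if self.normalisation not in ("none", "max", "energy"):
            errors.append(f"normalisation must be none|max|energy")
        if self.format == "tiff" and self.mode == "complex":
            errors.append("TIFF output requires mode amplitude or intensity")
        if self.parameterisation == "spherical":
            # the theta-line carries no azimuthal information: refuse any
            # correction that breaks axisymmetry
            non_radial = [j for j, _ in self.zernike if _osa_to_nm(int(j))[1] != 0]
            if non_radial:
                errors.append(
                    "spherical parameterisation only admits radial (m=0) Zernike "
                    f"terms; non-radial OSA indices: {non_radial}"
                )
            if self.vortex_charge != 0:
                errors.append("vortex phase requires the cartesian parameterisation")
            if self.half_moon:
                errors.append("half-moon phase requires the cartesian parameterisation")
            if self.custom_phase_tiff is not None:
                errors.append("custom phase masks require the cartesian parameterisation")
        try:
            OpticalSetup(
                na=self.na,
                wavelength=self.wavelength,
                n_sample=self.n_sample,
                n_immersion=self.n_immersion,
                focal_length=self.focal_length,
            )
        except ValueError as exc:
            errors.append(str(exc))
        try:
            SamplingGrid(
                pupil_size=self.pupil_size,
                out_size=self.out_size,
                pixel_size=self.pixel_size,
                z_planes=self.z_planes,
            )
        except ValueError as exc:
            errors.append(str(exc))
        return errors


def _build_corrections(cfg: RunConfig, setup: OpticalSetup, grid: SamplingGrid):
    """Amplitude and phase factor lists on the configured parameterisation."""
    k, s_max, theta_max = derived_quantities(setup)
    if cfg.parameterisation == "cartesian":
        sx, sy, mask = pupil_coords(grid.pupil_size, s_max)
        sin_t = np.clip(np.hypot(sx, sy), 0.0, 1.0)
    else:
        sin_t = np.sin(theta_line(grid.pupil_size, theta_max))
    amplitudes, phases = [], []
    if cfg.apodisation:
        amplitudes.append(apodisation(sin_t, cfg.apodisation_exponent))
    if cfg.gaussian_s_env is not None:
        amplitudes.append(gaussian_envelope(sin_t, cfg.gaussian_s_env))
    if cfg.gibson_lanni:
        medium = LayeredMedium(**{**{"n_i": setup.n_immersion}, **cfg.medium})
        phases.append(gibson_lanni_phase(medium, setup.wavelength, sin_t))
    if cfg.parameterisation == "cartesian":
        spec = AberrationSpec(
            zernike_coeffs=[(int(j), float(c)) for j, c in cfg.zernike],
            custom_phase=(
                load_pupil_mask(cfg.custom_phase_tiff)
                if cfg.custom_phase_tiff
                else None
            ),
            unit=cfg.zernike_unit,
        )
        if spec.zernike_coeffs or spec.custom_phase is not None:
            phases.append(zernike_phase(spec, grid.pupil_size, s_max))
        if cfg.vortex_charge:
            phases.append(vortex_phase(grid.pupil_size, s_max, cfg.vortex_charge))
        if cfg.half_moon:
            phases.append(half_moon_phase(grid.pupil_size, s_max))
    elif cfg.zernike:
        spec = AberrationSpec(
            zernike_coeffs=[(int(j), float(c)) for j, c in cfg.zernike],
            unit=cfg.zernike_unit,
        )
        # radial-only terms evaluated on the theta line
        phases.append(
            sum(
                spec.scale() * c * _radial_zernike(int(j), sin_t / s_max)
                for j, c in spec.zernike_coeffs
            )
        )
    return amplitudes, phases


def _radial_zernike(j: int, rho: np.ndarray) -> np.ndarray:
    from .corrections import zernike_polynomial

    n, m = _osa_to_nm(j)
    if m != 0:
        raise ValueError(f"OSA index {j} is not a radial term")
    return zernike_polynomial(j, rho, np.zeros_like(rho))


def run_from_config(cfg: RunConfig) -> FocalField:
    """Build pupil -> apply corrections -> propagate -> normalise -> save."""
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    setup = OpticalSetup(
        na=cfg.na,
        wavelength=cfg.wavelength,
        n_sample=cfg.n_sample,
        n_immersion=cfg.n_immersion,
        focal_length=cfg.focal_length,
        polarisation=tuple(cfg.jones()),
    )
    grid = SamplingGrid(
        pupil_size=cfg.pupil_size,
        out_size=cfg.out_size,
        pixel_size=cfg.pixel_size,
        z_planes=cfg.z_planes,
    )
    logger.info("resolved configuration: %s", asdict(cfg))
    pupil = uniform_pupil(setup, grid, cfg.parameterisation)
    amplitudes, phases = _build_corrections(cfg, setup, grid)
    pupil = apply_corrections(pupil, amplitudes, phases)
    rule = QuadratureRule(cfg.quadrature, grid.pupil_size)
    if cfg.propagator == "scalar":
        if cfg.parameterisation == "cartesian":
            field = scalar_cartesian(pupil, setup, grid)
        else:
            field = scalar_spherical(pupil, setup, grid, rule)
    else:
        pupil = apply_polarisation(pupil, setup.jones)
        if cfg.parameterisation == "cartesian":
            field = vectorial_cartesian(vectorial_far_field(pupil), setup, grid)
        else:
            field = vectorial_spherical(pupil, setup, grid, rule)
    logger.info("dispatched propagator: %s", field.metadata["propagator"])
    field = normalise(field, cfg.normalisation)
    if cfg.output:
        save_stack(field, cfg.output, format=cfg.format, mode=cfg.mode)
        logger.info("wrote %s (%s, %s)", cfg.output, cfg.format, cfg.mode)
    return field
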