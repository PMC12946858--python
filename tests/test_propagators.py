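import numpy as np
import pytest

from rwpsf import (
    OpticalSetup,
    QuadratureRule,
    SamplingGrid,
    apply_polarisation,
    far_field_from_incident,
    intensity,
    scalar_cartesian,
    scalar_spherical,
    uniform_pupil,
    vectorial_cartesian,
    vectorial_far_field,
    vectorial_spherical,
)
from rwpsf.corrections import apply_corrections, half_moon_phase, vortex_phase
from rwpsf.propagators import FocalField

CIRCULAR = (1 / np.sqrt(2), 1j / np.sqrt(2))


class TestBasisChange:
    def test_identity_on_axis(self):
        einc = np.array([[0.3 + 0.1j], [0.7 - 0.2j], [0.0]])
        out = far_field_from_incident(einc, np.array([0.0]), np.array([1.234]))
        assert np.allclose(out, einc, atol=1e-15)

    def test_x_polarised_meridional_plane(self):
        # einc = (1, 0, 0) at phi = 0 maps to (cos th, 0, -sin th)
        theta = np.array([0.7])
        einc = np.array([[1.0], [0.0], [0.0]], dtype=complex)
        out = far_field_from_incident(einc, theta, np.array([0.0]))
        expected = np.array([[np.cos(0.7)], [0.0], [-np.sin(0.7)]])
        assert np.allclose(out, expected, atol=1e-15)

    def test_norm_preserved_for_unit_fresnel(self):
        # with q_s = q_p = 1 the basis change is a rotation
        theta, phi = np.meshgrid(np.linspace(0, 1.4, 41), np.linspace(0, 2 * np.pi, 37))
        einc = np.stack(
            [
                np.full(theta.shape, 0.6 + 0.3j),
                np.full(theta.shape, -0.2 + 0.7j),
                np.zeros(theta.shape, dtype=complex),
            ]
        )
        out = far_field_from_incident(einc, theta, phi)
        norm_in = np.sum(np.abs(einc) ** 2, axis=0)
        norm_out = np.sum(np.abs(out) ** 2, axis=0)
        assert np.abs(norm_out - norm_in).max() < 1e-12

    def test_rejects_longitudinal_incident_field(self):
        einc = np.array([[1.0], [0.0], [0.5]], dtype=complex)
        with pytest.raises(ValueError):
            far_field_from_incident(einc, np.array([0.1]), np.array([0.0]))


class TestScalarPropagators:
    def test_zero_pupil_zero_field(self, low_na_setup, small_grid):
        p = uniform_pupil(low_na_setup, small_grid, "cartesian")
        f = scalar_cartesian(p.copy_with(np.zeros_like(p.values)), low_na_setup, small_grid)
        assert np.all(f.data == 0)
        assert f.data.shape == (1, 1, 31, 31)

    def test_axial_intensity_symmetry(self, low_na_setup):
        # unaberrated PSF intensity is symmetric under z -> -z
        grid = SamplingGrid(pupil_size=129, out_size=31, pixel_size=80.0,
                            z_planes=(-600.0, 600.0))
        f = scalar_cartesian(uniform_pupil(low_na_setup, grid, "cartesian"),
                             low_na_setup, grid)
        i = intensity(f)
        assert np.linalg.norm(i[0] - i[1]) / np.linalg.norm(i[0]) < 1e-8

    def test_spherical_output_radially_symmetric_bit_identical(self, low_na_setup):
        grid = SamplingGrid(pupil_size=201, out_size=31, pixel_size=80.0)
        f = scalar_spherical(uniform_pupil(low_na_setup, grid, "spherical"),
                             low_na_setup, grid)
        plane = f.data[0, 0]
        # equal radii get the exact same complex value: compare the four
        # quadrant reflections bitwise
        assert np.array_equal(plane, plane[::-1, :])
        assert np.array_equal(plane, plane[:, ::-1])
        assert np.array_equal(plane, plane.T)

    def test_cross_parameterisation_agreement(self, low_na_setup):
        gc = SamplingGrid(pupil_size=257, out_size=41, pixel_size=80.0,
                          z_planes=(0.0, 400.0))
        gs = SamplingGrid(pupil_size=501, out_size=41, pixel_size=80.0,
                          z_planes=(0.0, 400.0))
        fc = scalar_cartesian(uniform_pupil(low_na_setup, gc, "cartesian"),
                              low_na_setup, gc)
        fs = scalar_spherical(uniform_pupil(low_na_setup, gs, "spherical"),
                              low_na_setup, gs)
        err = np.linalg.norm(fc.data - fs.data) / np.linalg.norm(fs.data)
        assert err < 5e-3

    def test_linearity_in_pupil(self, low_na_setup, small_grid):
        p = uniform_pupil(low_na_setup, small_grid, "cartesian")
        rng = np.random.default_rng(3)
        v1 = p.values * rng.normal(size=p.values.shape)
        v2 = p.values * rng.normal(size=p.values.shape)
        f12 = scalar_cartesian(p.copy_with(2.0 * v1 - 0.5 * v2), low_na_setup, small_grid)
        f1 = scalar_cartesian(p.copy_with(v1), low_na_setup, small_grid)
        f2 = scalar_cartesian(p.copy_with(v2), low_na_setup, small_grid)
        assert np.allclose(f12.data, 2.0 * f1.data - 0.5 * f2.data, rtol=1e-11, atol=1e-8)

    def test_defocus_phase_additivity(self, low_na_setup):
        # exp(ik sz z1) * exp(ik sz z2) == exp(ik sz (z1+z2)) inside one run
        g12 = SamplingGrid(pupil_size=65, out_size=31, pixel_size=80.0, z_planes=(900.0,))
        p = uniform_pupil(low_na_setup, g12, "cartesian")
        from rwpsf.optical_config import derived_quantities
        from rwpsf.pupil import pupil_coords
        k, s_max, _ = derived_quantities(low_na_setup)
        sx, sy, mask = pupil_coords(65, s_max)
        sz = np.sqrt(np.clip(1 - sx**2 - sy**2, 0, None))
        pre = p.copy_with(p.values * np.exp(1j * k * sz * 400.0))
        g2 = SamplingGrid(pupil_size=65, out_size=31, pixel_size=80.0, z_planes=(500.0,))
        direct = scalar_cartesian(p, low_na_setup, g12)
        split = scalar_cartesian(pre, low_na_setup, g2)
        assert np.allclose(direct.data, split.data, rtol=1e-12)

    def test_rule_mismatch_rejected(self, low_na_setup):
        grid = SamplingGrid(pupil_size=101, out_size=31, pixel_size=80.0)
        p = uniform_pupil(low_na_setup, grid, "spherical")
        with pytest.raises(ValueError):
            scalar_spherical(p, low_na_setup, grid, QuadratureRule("simpson", 51))


class TestVectorialPropagators:
    def test_zero_pupil_zero_field(self, high_na_setup, small_grid):
        p = apply_polarisation(uniform_pupil(high_na_setup, small_grid, "cartesian"), CIRCULAR)
        p = vectorial_far_field(p)
        f = vectorial_cartesian(p.copy_with(np.zeros_like(p.values)), high_na_setup, small_grid)
        assert np.all(f.data == 0)
        assert f.data.shape == (1, 3, 31, 31)

    def test_low_na_crosstalk_negligible(self):
        # x-polarised input at tiny NA leaves y and z channels empty
        setup = OpticalSetup(na=0.05, wavelength=632.0, polarisation=(1.0, 0.0))
        grid = SamplingGrid(pupil_size=65, out_size=31, pixel_size=600.0)
        p = vectorial_far_field(
            apply_polarisation(uniform_pupil(setup, grid, "cartesian"), (1.0, 0.0))
        )
        f = vectorial_cartesian(p, setup, grid)
        energy = np.sum(np.abs(f.data) ** 2, axis=(0, 2, 3))
        assert energy[1] < 1e-3 * energy[0]
        assert energy[2] < 1e-3 * energy[0]

    def test_circular_polarisation_radially_symmetric_intensity(self, high_na_setup):
        grid = SamplingGrid(pupil_size=129, out_size=41, pixel_size=40.0)
        p = vectorial_far_field(
            apply_polarisation(uniform_pupil(high_na_setup, grid, "cartesian"), CIRCULAR)
        )
        i = intensity(vectorial_cartesian(p, high_na_setup, grid))[0]
        rot = np.rot90(i)
        assert np.abs(i - rot).max() / i.max() < 1e-6

    def test_on_axis_longitudinal_field_vanishes(self, high_na_setup):
        # J1(0) = J2(0) = 0 forces Ez(rho=0) = 0
        grid = SamplingGrid(pupil_size=201, out_size=31, pixel_size=40.0)
        p = apply_polarisation(uniform_pupil(high_na_setup, grid, "spherical"), CIRCULAR)
        f = vectorial_spherical(p, high_na_setup, grid)
        centre = (31 - 1) // 2
        assert abs(f.data[0, 2, centre, centre]) < 1e-12 * np.abs(f.data).max()

    def test_cross_parameterisation_agreement(self, high_na_setup):
        gc = SamplingGrid(pupil_size=257, out_size=41, pixel_size=20.0)
        gs = SamplingGrid(pupil_size=501, out_size=41, pixel_size=20.0)
        pc = vectorial_far_field(
            apply_polarisation(uniform_pupil(high_na_setup, gc, "cartesian"), CIRCULAR)
        )
        fc = vectorial_cartesian(pc, high_na_setup, gc)
        ps = apply_polarisation(uniform_pupil(high_na_setup, gs, "spherical"), CIRCULAR)
        fs = vectorial_spherical(ps, high_na_setup, gs)
        err = np.linalg.norm(fc.data - fs.data) / np.linalg.norm(fs.data)
        assert err < 1e-2

    def test_low_na_reduces_to_scalar(self):
        setup = OpticalSetup(na=0.2, wavelength=632.0, polarisation=CIRCULAR)
        grid = SamplingGrid(pupil_size=301, out_size=41, pixel_size=200.0)
        ps = uniform_pupil(setup, grid, "spherical")
        i_scalar = intensity(scalar_spherical(ps, setup, grid))
        i_vect = intensity(vectorial_spherical(apply_polarisation(ps, CIRCULAR), setup, grid))
        i_scalar /= i_scalar.max()
        i_vect /= i_vect.max()
        assert np.linalg.norm(i_scalar - i_vect) / np.linalg.norm(i_vect) < 0.01


class TestEngineeredPsfs:
    def test_half_moon_lobes_split_along_x(self, high_na_setup):
        # a pi step across sx makes the pupil odd in sx: the focal field has
        # a null on the x = 0 column and two lobes on the x axis
        grid = SamplingGrid(pupil_size=129, out_size=41, pixel_size=40.0)
        p = uniform_pupil(high_na_setup, grid, "cartesian")
        p = apply_corrections(p, phase_factors=[half_moon_phase(129, p.s_max)])
        p3 = vectorial_far_field(apply_polarisation(p, (1.0, 0.0)))
        f = vectorial_cartesian(p3, high_na_setup, grid)
        centre = 20
        # the dominant x channel (the z channel partially refills the null
        # at high NA) has a dark x = 0 column and bright lobes along x
        ix = np.abs(f.data[0, 0]) ** 2
        assert ix[:, centre].max() < 1e-3 * ix.max()
        assert ix[centre].argmax() != centre
        # total intensity still splits along x, not y
        i = intensity(f)[0]
        assert i[centre].max() > 2.0 * i[:, centre].max()

    def test_donut_dark_centre(self, high_na_setup):
        grid = SamplingGrid(pupil_size=129, out_size=41, pixel_size=40.0)
        p = uniform_pupil(high_na_setup, grid, "cartesian")
        p = apply_corrections(p, phase_factors=[vortex_phase(129, p.s_max, 1)])
        p3 = vectorial_far_field(apply_polarisation(p, CIRCULAR))
        i = intensity(vectorial_cartesian(p3, high_na_setup, grid))[0]
        assert i[20, 20] < 0.02 * i.max()


class TestFocalFieldAndIntensity:
    def test_layout_validation(self):
        with pytest.raises(ValueError):
            FocalField(np.zeros((1, 2, 5, 5)), 10.0, (0.0,))
        with pytest.raises(ValueError):
            FocalField(np.zeros((2, 1, 5, 5)), 10.0, (0.0,))

    def test_intensity_values(self):
        f = FocalField(np.full((1, 1, 2, 2), 3 + 4j), 10.0, (0.0,))
        assert np.allclose(intensity(f), 25.0)
        assert np.allclose(intensity(f, mode="amplitude"), 5.0)

    def test_channel_symmetry(self):
        a = np.zeros((1, 3, 2, 2), complex)
        b = np.zeros((1, 3, 2, 2), complex)
        a[:, 0] = 1.0
        b[:, 1] = 1.0
        fa = FocalField(a, 10.0, (0.0,))
        fb = FocalField(b, 10.0, (0.0,))
        assert np.array_equal(intensity(fa), intensity(fb))
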