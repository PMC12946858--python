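# rwpsf

Scalar and vectorial point-spread-function (PSF) simulation for high-NA
microscopy, built on the Richards–Wolf diffraction integral.

Accurate PSF models are the backbone of localisation microscopy,
deconvolution and PSF engineering.  At high numerical aperture the paraxial
Airy model fails: the electric field must be treated as a vector, and
aberrations from refractive-index mismatch between sample, coverslip and
immersion medium dominate the focal volume.  `rwpsf` computes the focused
field

```
E(ρ) = -i f k / (2π) ∫∫_Ω e∞(s) exp(i k s·ρ) dΩ
```

where `e∞(s)` is the far field on the Gaussian reference sphere,
`s = (sinθ cosφ, sinθ sinφ, cosθ)` runs over the aperture cone
(`s_max = NA/n_i`), `k = 2πn/λ`, and `ρ = (x, y, z)` is the focal-region
position.  The same integral is evaluated in two interchangeable
parameterisations:

* **Cartesian** (`sx, sy`): a sized 2D Fourier transform per z-plane,
  implemented with a chirp-Z (Bluestein) transform so that the focal-plane
  pixel size is arbitrary.  Works for any pupil, including vortex,
  half-moon and Zernike phase masks.
* **Spherical** (`θ`): for axisymmetric pupils the azimuthal integral is
  analytic and leaves 1D Bessel-kernel integrals (J0 for the scalar model;
  J0/J1/J2 for the vectorial one), integrated with a composite Simpson (or
  left-Riemann) rule.

The scalar model takes `e∞ = e_inc`; the vectorial model first applies the
cylindrical-to-spherical basis change (with optional Fresnel transmission
products `q_s`, `q_p` for stratified media).  Correction factors —
Gibson–Lanni index-mismatch phase, Zernike/vortex/custom masks,
apodisation `cosᵞθ`, Gaussian envelopes — multiply any pupil before
propagation.  Output stacks have layout `(z, channel, x, y)` with 1 channel
for scalar and 3 (Ex, Ey, Ez) for vectorial fields.

## Worked example

A high-NA (1.3, oil immersion) circularly polarised PSF at focus and
500 nm defocus:

```python
import numpy as np
from rwpsf import (OpticalSetup, SamplingGrid, uniform_pupil,
                   apply_polarisation, vectorial_far_field,
                   vectorial_cartesian, intensity)

setup = OpticalSetup(na=1.3, wavelength=632.0, n_sample=1.5,
                     n_immersion=1.5,
                     polarisation=(1/np.sqrt(2), 1j/np.sqrt(2)))
grid = SamplingGrid(pupil_size=513, out_size=201, pixel_size=20.0,
                    z_planes=(0.0, 500.0))
pupil = vectorial_far_field(
    apply_polarisation(uniform_pupil(setup, grid, "cartesian"), setup.jones))
field = vectorial_cartesian(pupil, setup, grid)
psf = intensity(field) / intensity(field).max()
```

This prints (via the obvious `print` statements):

```
stack shape (z, channel, x, y): (2, 3, 201, 201)
lateral FWHM: 264.0 nm
peak intensity ratio z=500nm vs focus: 0.266
longitudinal (Ez) energy fraction at focus: 0.223
```

The 264 nm full-width at half-maximum sits near the λ/(2·NA) diffraction
limit (243 nm), slightly broadened by the vectorial crosstalk: at NA 1.3 a
fifth of the focal energy lives in the longitudinal component Ez, which the
scalar model ignores entirely.

The same computation from the shell, plus the accuracy benchmark:

```sh
rwpsf generate --na 1.3 --propagator vectorial --output psf.npz
rwpsf benchmark --rule simpson
# scalar_spherical [simpson]: fitted order 4.001 (errors 1.17e-05 -> 1.09e-11)
rwpsf benchmark --rule riemann
# scalar_spherical [riemann]: fitted order 1.001 (errors 3.70e-02 -> 1.15e-03)
rwpsf gallery --outdir gallery   # donut, half-moon, astigmatic, ... TIFFs
```

The fitted orders confirm the first-order behaviour of the Riemann rule and
the fourth-order behaviour of composite Simpson on the analytic Airy-disk
oracle.

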