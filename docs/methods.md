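# Methods

## Model

`rwpsf` evaluates the Richards–Wolf (vectorial Debye) integral: the focal
field is a superposition of plane waves over the aperture cone,

    E(ρ) = -i f k/(2π) ∫∫_Ω a(s) e^{iW(s)} e∞(s) e^{+i k s·ρ} dΩ,

with `k = 2π n/λ` the wavenumber in the propagation medium, `f` the focal
length (entering only the constant prefactor), `s_max = NA/n_i` the pupil
cut-off and `a(s)`, `W(s)` multiplicative amplitude/phase corrections.  The
model assumes an aplanatic system in the Debye regime (large Fresnel
number); polarisation effects of the focusing element are captured by the
cylindrical-to-spherical basis change, partial interface transmission by
Fresnel products `q_s`, `q_p`.  By default a single homogeneous medium is
assumed (`n_sample = n_immersion`); stratified-layer physics enters only
through the Gibson–Lanni phase and the Fresnel coefficients.  Defocus is
angular-spectrum propagation, `exp(i k z cosθ)`, exact in a homogeneous
medium.

Two discretisations of the same integral are provided.

**Cartesian.**  With `dΩ = dsx dsy / sz`, each z-plane is a 2D Fourier-type
sum of `e∞ · exp(i k sz z)/sz` over the pupil grid.  The division by
`sz = √(1-sx²-sy²)` is safe because the constructor enforces `NA < n_i`, so
`sz ≥ √(1-s_max²) > 0` on the disk — no regularisation is applied.  The sum
is evaluated by a sized (chirp-Z/Bluestein) transform: one chirp
multiplication, a linear convolution done with FFTs zero-padded to the next
power of two ≥ N+M−1, and a final chirp — three FFTs per axis, O(n log n),
with the focal pixel size completely decoupled from the pupil sampling.
The transform is exact (machine precision against the direct double sum);
all Cartesian discretisation error comes from representing the pupil on a
finite grid.

**Spherical.**  For axisymmetric pupils the azimuthal integral is done
analytically, leaving 1D integrals over θ ∈ [0, θ_max] with Bessel kernels:
`J0` alone in the scalar case, and per incident component the three
integrals with kernels `sinθ(q_s + q_p cosθ)J0`, `q_p sin²θ J1`,
`sinθ(q_p cosθ − q_s)J2` in the vectorial case (reducing to the familiar
`(1+cosθ)`, `sin²θ`, `(cosθ−1)` kernels at `q_s = q_p = 1`).  The integrals
are evaluated at the sorted unique radii of the output grid and scattered
onto the image, which is bit-identical to per-pixel evaluation and makes
the radial symmetry of scalar outputs exact by construction.

Absolute scales of the two routes agree by construction: the spherical
prefactor `-i f k` is the Cartesian `-i f k/(2π)` with the 2π of the
analytic φ-integration absorbed.  This was verified numerically on the
uniform pupil (no constant-ratio mismatch).

## Conventions

* Sign: `exp(+i k s·ρ)` (inverse-transform convention), fixed in
  `numerics` and used everywhere.
* Lengths in nanometres internally (f converted from mm), avoiding
  underflow in `k·ρ` products; the CLI reports µm in summaries.
* Output layout `(z, channel, x, y)`: last axis is x (columns),
  second-to-last y (rows, y increasing with row index; display with
  `origin="lower"` to see y up).  Focal azimuth φ is measured from +x,
  counter-clockwise.  The half-moon fixture (π step across `sx > 0`) pins
  this: its x-channel null column is x = 0.
* Positive z is toward the far side of the focus; unaberrated PSFs are
  z-symmetric so only the relative sign matters.
* Pupil grid: `s_i = -s_max + i·2 s_max/(N-1)`, N odd, centre sample
  exactly on axis; the disk edge is a hard binary mask (`s² ≤ s_max²`).
  Edge smoothing is deliberately absent — it would contaminate the
  convergence-order benchmark, which relies on a perfect circular aperture.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| wavelength | 632 nm | HeNe line, common in calibration |
| NA presets | 0.5 (air) / 1.3 (oil, n_i = 1.5) | canonical low/high-aperture regimes; 1.3 is the package default since vectorial modelling is its point |
| pixel size | 20 nm | 201-pixel image spans ±2 µm ≈ 6.7 Airy radii at NA 1.3, ~6× oversampling of the λ/(4NA) Nyquist pitch |
| pupil sampling | 513² Cartesian / 1001 θ-samples | odd (Simpson needs an even interval count; centre sample on axis); resolves the aperture well while keeping a plane under 0.3 s |
| image size | 201 × 201 | standard single-plane benchmark size |
| polarisation | circular (1, i)/√2 | rotationally symmetric vectorial PSFs |
| apodisation exponent | 1 (A = cosθ) | kept explicit and configurable because both cosθ and the classic aplanatic √cosθ circulate; nothing is substituted silently |
| Zernike units | radians (OSA/ANSI single index, orthonormal) | unambiguous; `--waves` multiplies by 2π |
| Gaussian envelope fixture | s_env = s_max | filling factor 1 (beam waist matched to aperture) |

Gibson–Lanni: the immersion thickness `t_i`, hard to measure, defaults to
the focusing condition
`t_i = t_s + n_i(−t_s/n_s − t_g/n_g + t_g*/n_g* + t_i*/n_i*)` — the
grouping fixed by the requirement that fully matched conditions return
`t_i = t_i*`.  Supercritical angles (square-root arguments going negative
in the layer phases or in Snell transmission) are kept complex: the
imaginary phase part is a physical evanescent decay, and clipping would
introduce discontinuities.

## Accuracy benchmark

Multiplying the uniform pupil by an extra `cosθ` amplitude cancels the
`1/sz` kernel, reducing both scalar propagators to a plain transform of the
circular aperture whose analytic value is the Airy amplitude `2J1(ρ̂)/ρ̂`
at `ρ̂ = k s_max ρ`.  The in-focus plane is computed at several sampling
densities, peak-normalised (dividing by the complex peak value so the
`-i f k` prefactor cancels exactly), compared on a 1D radial line (the
fitted order is extent-invariant), and the log-log slope of δ = ‖E − F_AD‖₂
vs step size is fitted by least squares over the densest decade of h,
discarding points below a 1e-12 floor where double precision flattens the
slope.  Measured: left-Riemann 1.00, composite Simpson 4.00, Cartesian
pixel sum 1.29 (the pixelated disk edge limits it to between first and
second order).  "Rounds to N" means |slope − N| < 0.5.

## Cross-parameterisation equivalence

The central claim — both parameterisations compute the same integral — is
tested on uniform and Gaussian-envelope circularly polarised pupils at the
default sampling (513²/1001/201²).  The residual is pure quadrature error
of the slower-converging route.  Two regimes behave differently:

* NA 0.5: complex-field relative L2 agreement is ~5×10⁻⁴ for the hard-edged
  disk; asserted < 10⁻³.
* NA 1.3: the Cartesian route's aperture-edge error reaches ~2×10⁻³ on the
  complex field at the default pupil grid (decreasing ≈ h^1.4 under
  refinement: 5.0×10⁻³ / 2.0×10⁻³ / 7.2×10⁻⁴ at N = 257/513/1025, and an
  order of magnitude smaller for smooth pupils).  The edge error lives
  mostly in the phase of the weak outer rings, so the PSF itself —
  channel-summed intensity, the physically observed quantity — agrees to
  ~3×10⁻⁴; asserted < 10⁻³, together with monotone decrease of the field
  error under refinement.

The low-NA reduction of the vectorial to the scalar model is quantified on
peak-normalised intensities: 0.7% relative L2 at NA 0.2 versus 18% at
NA 1.3, where a fifth of the focal energy sits in Ez.

## Degenerate inputs and numerical edges

* `NA = 0` is legal (empty aperture, zero field); `NA ≥ n_i` is rejected at
  construction (complex `sz`).
* Simpson with an even sample count raises — no silent fallback to a
  lower-order rule.
* `airy_disk` uses the series limit 1 at ρ = 0; `J2` comes from
  `scipy.special` (the three-term recurrence is unstable near 0 and is kept
  only as a test identity).
* Axisymmetry detection groups pupil samples by exact radius (quantised at
  1e-10 relative to absorb last-ulp asymmetry of the centred grid) and
  demands relative spread < 1e-9 per radius — programmatic pupils are
  symmetric to rounding, so the check is a hard gate for the spherical
  route rather than a statistical test.
* The pipeline contains no randomness; repeated runs are bit-identical.

## Limitations

* Emission (dipole) PSFs via reciprocity, tilted interfaces and absorbing
  layers are out of scope; Fresnel products cover transmission only.
* No dispersion or multi-wavelength support.
* The spherical route requires axisymmetric pupils; non-radial Zernike
  terms, vortex and half-moon masks are rejected there at config
  validation.
* Wall-clock performance is hardware-dependent and not part of the test
  surface; accuracy, not speed, is benchmarked.
* All checks run on synthetic pupils; experimental pupils (phase retrieval,
  amplitude maps from measurements) can be imported as TIFF masks but no
  retrieval machinery is provided.
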