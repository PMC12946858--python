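"""Quadrature rules, Bessel functions and the sized (chirp-Z) Fourier transform.

Sign convention: the focal field is a superposition of plane waves
``exp(+1j * k * s . rho)`` — an *inverse*-transform convention.  It is fixed
here once and used by every propagator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = ["QuadratureRule", "integrate_1d", "bessel_j", "sized_ft_1d", "sized_ft_2d"]


@dataclass(frozen=True)
class QuadratureRule:
    """Composite quadrature over a uniform grid on [0, theta_max].

    ``riemann`` is the left rule (first order); ``simpson`` the composite
    Simpson rule (fourth order), which requires an odd sample count (even
    number of intervals).
    """

    name: str = "simpson"
    n_points: int = 1001

    def __post_init__(self):
        if self.name not in ("riemann", "simpson"):
            raise ValueError(f"unknown rule {self.name!r}")
        if self.n_points < 2:
            raise ValueError("need at least 2 quadrature points")
        if self.name == "simpson" and self.n_points % 2 == 0:
            raise ValueError(
                "composite Simpson rule requires an odd sample count "
                f"(even interval count); got {self.n_points}"
            )


def integrate_1d(samples: np.ndarray, h: float, rule: QuadratureRule, axis: int = -1):
    """Integrate uniformly sampled values with the given composite rule.

    ``samples`` may be any-dimensional; integration runs along ``axis``.
    """
    f = np.asarray(samples)
    n = f.shape[axis]
    if rule.name == "riemann":
        # left rule: h * sum f_i, i = 0..n-2
        sl = [slice(None)] * f.ndim
        sl[axis] = slice(0, n - 1)
        return h * f[tuple(sl)].sum(axis=axis)
    if n % 2 == 0:
        raise ValueError("composite Simpson rule requires an odd sample count")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    shape = [1] * f.ndim
    shape[axis] = n
    return (h / 3.0) * (f * w.reshape(shape)).sum(axis=axis)


def bessel_j(order: int, x) -> np.ndarray:
    """Bessel function of the first kind, orders 0..2."""
    x = np.asarray(x, dtype=float)
    if order == 0:
        return special.j0(x)
    if order == 1:
        return special.j1(x)
    if order == 2:
        return special.jv(2, x)
    raise ValueError(f"order must be 0, 1 or 2, got {order}")


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def sized_ft_1d(
    x: np.ndarray,
    alpha: float,
    phase0: np.ndarray | None,
    out_size: int,
    axis: int = -1,
) -> np.ndarray:
    """Bluestein evaluation of ``X_m = sum_n x_n exp(1j * alpha * n * m')``.

    ``m' = m - (out_size - 1)/2`` centres the output on the axis.  ``alpha``
    is an arbitrary real phase increment per index pair (not tied to
    ``2*pi/N``), which is what makes the output sampling free.  ``phase0``
    (shape ``(out_size,)``) is an optional extra per-output phase applied at
    the end.  Implemented as one chirp multiplication, a linear convolution
    carried out with FFTs zero-padded to the next power of two at least
    ``N + M - 1``, and a final chirp — three FFTs total.
    """
    x = np.asarray(x, dtype=complex)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    m = out_size
    m0 = (m - 1) / 2.0

    ns = np.arange(n)
    ms = np.arange(m)
    # fold the output-centring shift into the input chirp:
    #   n*m' = n*m - n*m0;  n*m = (n^2 + m^2 - (m-n)^2)/2
    a_chirp = np.exp(1j * alpha * (ns * ns / 2.0 - ns * m0))
    b_len = _next_pow2(n + m - 1)
    # chirp kernel exp(-1j*alpha*j^2/2) for j = m - n in [-(n-1), m-1]
    kernel = np.zeros(b_len, dtype=complex)
    j_pos = np.arange(m)
    kernel[:m] = np.exp(-1j * alpha * j_pos * j_pos / 2.0)
    j_neg = np.arange(1, n)
    kernel[b_len - (n - 1):] = np.exp(-1j * alpha * j_neg * j_neg / 2.0)[::-1]

    y = np.zeros(x.shape[:-1] + (b_len,), dtype=complex)
    y[..., :n] = x * a_chirp
    conv = np.fft.ifft(np.fft.fft(y, axis=-1) * np.fft.fft(kernel), axis=-1)
    out = conv[..., :m] * np.exp(1j * alpha * ms * ms / 2.0)
    if phase0 is not None:
        out = out * phase0
    return np.moveaxis(out, -1, axis)


def sized_ft_2d(
    field: np.ndarray,
    input_step: float,
    input_start: float,
    output_step: float,
    out_size: int,
    k: float,
) -> np.ndarray:
    """Evaluate ``sum_j f_j exp(1j * k * s_j . rho_m)`` on an M x M grid.

    ``field`` is ``(..., N, N)`` sampled at ``s = input_start + j*input_step``
    per axis (last axis: sx, second-to-last: sy); output positions are
    ``rho_m = (m - (M-1)/2) * output_step`` per axis, centred on the optical
    axis.  ``output_step`` is arbitrary — it is *not* tied to
    ``1/(N*input_step)``.  Separable: one sized 1D transform per axis.
    """
    field = np.asarray(field, dtype=complex)
    n = field.shape[-1]
    if field.shape[-2] != n:
        raise ValueError("field must be square in its last two axes")
    if n % 2 == 0 or out_size % 2 == 0:
        raise ValueError("sized_ft_2d requires odd input and output sizes")
    alpha = k * input_step * output_step
    rho = (np.arange(out_size) - (out_size - 1) / 2.0) * output_step
    phase0 = np.exp(1j * k * input_start * rho)
    out = sized_ft_1d(field, alpha, phase0, out_size, axis=-1)
    out = sized_ft_1d(out, alpha, phase0, out_size, axis=-2)
    return out
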