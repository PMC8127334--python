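"""Slater-type radial functions and their Fourier-Bessel transforms.

A radial deformation function is R(r) = N r^n exp(-zeta r) with
N = zeta^(n+3)/(n+2)! so that integral R(r) r^2 dr = 1; populations carry
the electron count.  The scattering machinery needs the Fourier-Bessel
transform

    <j_l>(h) = integral R(r) j_l(2 pi h r) r^2 dr

which has a closed form: j_l is a finite sum of r^-(k+1) sin/cos terms and
each integral  int r^m e^(-zeta r) trig(K r) dr  is elementary.  Near h = 0
that closed form cancels catastrophically for l >= 1, so a power series in
(K/zeta) is used below a fixed crossover.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = ["slater_radial_value", "fourier_bessel_slater"]

_SERIES_X = 0.15  # K/zeta crossover between series and closed form


def slater_radial_value(n: int, zeta: float, r):
    """Normalized Slater radial function N r^n exp(-zeta r) (A^-3).

    n >= 0 (integer), zeta > 0 in A^-1, r >= 0 in A.
    """
    if n < 0 or int(n) != n:
        raise ValueError("n must be a non-negative integer")
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    N = zeta ** (n + 3) / math.factorial(n + 2)
    return N * r**n * np.exp(-zeta * r)


@lru_cache(maxsize=None)
def _jl_coeffs(l: int):
    """Coefficients (a_k, b_k) with j_l(x) = sum_k x^-(k+1) (a_k sin x + b_k cos x)."""
    a = {0: np.array([1.0]), 1: np.array([0.0, 1.0])}
    b = {0: np.array([0.0]), 1: np.array([-1.0, 0.0])}
    for ll in range(1, l):
        an = np.zeros(ll + 2)
        bn = np.zeros(ll + 2)
        an[1:] += (2 * ll + 1) * a[ll]
        bn[1:] += (2 * ll + 1) * b[ll]
        an[: ll] -= a[ll - 1]
        bn[: ll] -= b[ll - 1]
        a[ll + 1], b[ll + 1] = an, bn
    return a[l], b[l]


def _fbt_closed(l: int, n: int, zeta: float, K: np.ndarray) -> np.ndarray:
    a, b = _jl_coeffs(l)
    rho2 = zeta * zeta + K * K
    theta = np.arctan2(K, zeta)
    out = np.zeros_like(K)
    for k in range(l + 1):
        if a[k] == 0.0 and b[k] == 0.0:
            continue
        m = n + 1 - k  # power of r left in the integrand
        fact = math.factorial(m)
        amp = fact / rho2 ** ((m + 1) / 2.0)
        term = amp * (a[k] * np.sin((m + 1) * theta) + b[k] * np.cos((m + 1) * theta))
        out += term / K ** (k + 1)
    return out


def _fbt_series(l: int, n: int, zeta: float, K: np.ndarray, nterms: int = 14) -> np.ndarray:
    # j_l(x) = sum_t (-1)^t x^(l+2t) / (2^t t! (2l+2t+1)!!)
    out = np.zeros_like(K)
    for t in range(nterms):
        dfact = math.prod(range(2 * l + 2 * t + 1, 0, -2))
        c = (-1.0) ** t / (2.0**t * math.factorial(t) * dfact)
        out += c * K ** (l + 2 * t) * math.factorial(n + l + 2 * t + 2) / zeta ** (n + l + 2 * t + 3)
    return out


def fourier_bessel_slater(l: int, n: int, zeta: float, h_mag):
    """<j_l>(h) for the normalized Slater radial (dimensionless).

    l in [0, 8], n >= l (integrability of the angular factor), zeta > 0
    in A^-1, h_mag = |h| = 2 sin(theta)/lambda in A^-1.  <j_0>(0) = 1,
    <j_l>(0) = 0 for l >= 1.
    """
    if not 0 <= l <= 8:
        raise ValueError("l out of supported range [0, 8]")
    if n < l:
        raise ValueError("n must be >= l for an integrable multipole radial")
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    h = np.atleast_1d(np.asarray(h_mag, dtype=float))
    if np.any(h < 0):
        raise ValueError("h_mag must be non-negative")
    K = 2.0 * np.pi * h
    norm = zeta ** (n + 3) / math.factorial(n + 2)
    out = np.empty_like(K)
    small = K < _SERIES_X * zeta
    if np.any(small):
        out[small] = norm * _fbt_series(l, n, zeta, K[small])
    if np.any(~small):
        out[~small] = norm * _fbt_closed(l, n, zeta, K[~small])
    if np.isscalar(h_mag) or np.ndim(h_mag) == 0:
        return float(out[0])
    return out
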