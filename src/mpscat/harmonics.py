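"""Density-normalized real spherical harmonics d_lmp, l <= 4.

The multipole formalism expands deformation density on real spherical
harmonics normalized so that each function (l >= 1) transfers exactly one
electron between its positive and negative lobes when its population is 1:

    integral |d_lmp| dOmega = 2      (l >= 1)
    d_00 = 1/(4 pi),  integral d_00 dOmega = 1

The functions are the orthonormal (wavefunction-normalized) real harmonics
y_lmp rescaled by precomputed density-normalization constants.  The
constants are computed once by numerical quadrature and cached; this keeps
the classic source of silent sign/normalization errors out of hand-typed
tables.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

L_MAX = 4

__all__ = ["real_spherical_harmonic", "real_spherical_harmonic_density",
           "density_normalization", "d_lmp_cart", "L_MAX"]


def _check(l: int, m: int, p: int):
    if not 0 <= l <= L_MAX:
        raise ValueError(f"l must be in [0, {L_MAX}], got {l}")
    if not 0 <= m <= l:
        raise ValueError(f"m must be in [0, l], got m={m}, l={l}")
    if p not in (+1, -1):
        raise ValueError("p must be +1 or -1")
    if m == 0 and p == -1:
        raise ValueError("m = 0 has no sine component (use p = +1)")


def real_spherical_harmonic(l, m, p, theta, phi):
    """Orthonormal real spherical harmonic y_lmp (integral y^2 dOmega = 1).

    theta is the polar angle from +z, phi the azimuth from +x.  p = +1
    selects the cos(m phi) component, p = -1 the sin(m phi) component.
    """
    _check(l, m, p)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    y = sph_harm_y(l, m, theta, phi)  # complex Y_l^m(theta, phi)
    if m == 0:
        return y.real
    # Condon-Shortley phase removed so all functions peak positive on +axes
    if p == +1:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    return np.sqrt(2.0) * (-1.0) ** m * y.imag


@lru_cache(maxsize=None)
def density_normalization(l: int, m: int, p: int = 1) -> float:
    """Factor N with d_lmp = N * y_lmp.

    N = 1/sqrt(4 pi) for the monopole (so d_00 = 1/4pi) and
    N = 2 / integral |y_lmp| dOmega for l >= 1.  The integral separates:
    the azimuthal part of |y| integrates to 2 pi (m = 0) or 4 (m >= 1),
    and the polar part is integrated adaptively in u = cos(theta) with the
    quadrature split at the nodes of the associated Legendre factor.
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    _check(l, m, p)
    if l == 0:
        return 1.0 / np.sqrt(4.0 * np.pi)
    phi0 = 0.0 if p == +1 else np.pi / (2.0 * max(m, 1))  # where trig(m phi) = 1

    def f(u):
        return real_spherical_harmonic(l, m, p, np.arccos(np.clip(u, -1, 1)), phi0)

    # locate sign changes of the polar factor
    us = np.linspace(-1.0, 1.0, 2001)
    vals = f(us)
    roots = [float(brentq(f, us[i], us[i + 1]))
             for i in range(len(us) - 1) if vals[i] * vals[i + 1] < 0]
    integral_u, _ = quad(lambda u: abs(f(u)), -1.0, 1.0,
                         points=roots or None, limit=200, epsabs=1e-13)
    phi_part = 2.0 * np.pi if m == 0 else 4.0
    return 2.0 / (integral_u * phi_part)


def real_spherical_harmonic_density(l, m, p, theta, phi):
    """Density-normalized real spherical harmonic d_lmp(theta, phi)."""
    return density_normalization(l, m, p) * real_spherical_harmonic(l, m, p, theta, phi)


def d_lmp_cart(l, m, p, unit_vectors):
    """d_lmp evaluated at Cartesian unit vectors, shape (..., 3)."""
    u = np.asarray(unit_vectors, dtype=float)
    z = np.clip(u[..., 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(u[..., 1], u[..., 0])
    return real_spherical_harmonic_density(l, m, p, theta, phi)
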