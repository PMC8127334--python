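"""Fourier synthesis of density / electrostatic-potential maps.

A map is synthesized as

    rho(x) = (1/V) * Re sum_h F(h) exp(-2 pi i h . x)

where the sum runs over the reflections handed in, optionally expanded to
the full sphere by the symmetry operators and the Friedel relation
(F(hR) = F(h) exp(-2 pi i h . t), F(-h) = conj F(h)).  X-ray maps come
out in e A^-3.  Electron maps come out in A/A^3 from the raw summation and
are rescaled to e A^-1 (x 3.32494) or volts (x 47.8780).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell import IDENTITY, UnitCell
from .constants import E_PER_A_FACTOR, VOLT_PER_F000_DENSITY
from .scattering import StructureFactorSet

__all__ = ["DensityGrid", "PeakList", "fourier_map", "residual_extrema",
           "bond_profile", "grid_shape_for"]


@dataclass
class DensityGrid:
    shape: tuple
    cell: UnitCell
    values: np.ndarray
    units: str  # "e/A^3" | "e/A" | "V" | "raw"
    provenance: str = ""

    @property
    def sigma(self) -> float:
        """RMS of the grid values."""
        return float(np.sqrt(np.mean(self.values**2)))

    def interpolate(self, frac_points) -> np.ndarray:
        """Periodic trilinear interpolation at fractional coordinates."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(frac_points, dtype=float))
        coords = (pts % 1.0).T * np.array(self.shape)[:, None]
        return map_coordinates(self.values, coords, order=3, mode="grid-wrap")


@dataclass
class PeakList:
    peaks: list  # (fractional xyz, height, height/sigma), |height| descending
    sigma: float


def grid_shape_for(cell: UnitCell, d_min: float, oversample: float = 3.0) -> tuple:
    """FFT-friendly grid divisions >= oversample x Nyquist for d_min."""
    def friendly(n):
        while True:
            m = n
            for p in (2, 3, 5):
                while m % p == 0:
                    m //= p
            if m == 1:
                return n
            n += 1
    return tuple(friendly(max(8, math.ceil(oversample * edge / d_min)))
                 for edge in (cell.a, cell.b, cell.c))


def _expand_full_sphere(sf: StructureFactorSet, symops, friedel: bool = True):
    """Expand a unique reflection list over rotations and Friedel pairs."""
    out: dict = {}
    for (h, k, l), F in zip(map(tuple, sf.hkl), sf.f):
        for op in (symops or []):
            hp = tuple(int(v) for v in np.array((h, k, l)) @ op.R)
            Fp = F * np.exp(-2j * math.pi * (np.array((h, k, l)) @ op.t))
            for hh, FF in ((hp, Fp),) + (((tuple(-v for v in hp), np.conj(Fp)),)
                                         if friedel else ()):
                if hh in out:
                    if abs(out[hh] - FF) > 1e-6 * (1.0 + abs(FF)):
                        raise ValueError(
                            f"inconsistent symmetry expansion at {hh}")
                else:
                    out[hh] = FF
        if not symops:
            out[(h, k, l)] = F
    return out


def fourier_map(sf: StructureFactorSet, grid_shape=None, symops=None,
                f000: float = 0.0, include_f000: bool = False,
                units: str | None = None, d_min: float | None = None,
                expand: str = "full") -> DensityGrid:
    """Inverse Fourier synthesis of a structure-factor set.

    ``expand`` is "full" (rotations + Friedel, needs ``symops``),
    "friedel" (add conjugate mates only) or "none" (sum exactly the given
    reflections).  ``units`` defaults to "e/A^3" for X-ray and "e/A" for
    electron sets ("V" also available).  F(000) is omitted unless
    ``include_f000``; for difference coefficients it cancels anyway.
    """
    if sf.cell is None:
        raise ValueError("structure-factor set carries no unit cell")
    cell = sf.cell
    if grid_shape is None:
        dmin = d_min if d_min is not None else float(sf.d_spacings().min())
        grid_shape = grid_shape_for(cell, dmin)
    na, nb, nc = grid_shape
    V = cell.volume

    if expand == "full":
        if symops is None:
            raise ValueError("expand='full' requires the symmetry operator list")
        full = _expand_full_sphere(sf, symops, friedel=True)
    elif expand == "friedel":
        full = _expand_full_sphere(sf, [IDENTITY], friedel=True)
    elif expand == "none":
        full = {tuple(h): F for h, F in zip(map(tuple, sf.hkl), sf.f)}
    else:
        raise ValueError(f"unknown expansion mode {expand!r}")

    grid = np.zeros((na, nb, nc), dtype=complex)
    for (h, k, l), F in full.items():
        if (h, k, l) == (0, 0, 0):
            continue
        if abs(h) * 2 >= na or abs(k) * 2 >= nb or abs(l) * 2 >= nc:
            raise ValueError(
                f"grid {grid_shape} too coarse for reflection {(h, k, l)}")
        grid[h % na, k % nb, l % nc] += F
    if include_f000:
        grid[0, 0, 0] = f000
    # rho(x) = (1/V) sum F exp(-2 pi i h.x): conjugate-transform via ifftn
    values = np.real(np.fft.fftn(grid)) / V

    nref = len(full)
    if units is None:
        units = "e/A^3" if sf.radiation == "xray" else "e/A"
    if sf.radiation == "electron":
        if units == "e/A":
            values = values * E_PER_A_FACTOR
        elif units == "V":
            values = values * VOLT_PER_F000_DENSITY
        elif units != "raw":
            raise ValueError(f"unsupported electron map units {units!r}")
    elif units not in ("e/A^3", "raw"):
        raise ValueError(f"unsupported X-ray map units {units!r}")
    return DensityGrid((na, nb, nc), cell, values, units,
                       provenance=f"{sf.radiation}/{sf.kind}, {nref} coefficients")


def _refine_extremum(values: np.ndarray, idx) -> tuple:
    """Quadratic interpolation of an extremum position and height."""
    shape = values.shape
    pos = np.array(idx, dtype=float)
    height = values[idx]
    for ax in range(3):
        im = list(idx); ip = list(idx)
        im[ax] = (idx[ax] - 1) % shape[ax]
        ip[ax] = (idx[ax] + 1) % shape[ax]
        fm, f0, fp = values[tuple(im)], values[idx], values[tuple(ip)]
        denom = fm - 2.0 * f0 + fp
        if abs(denom) > 1e-300:
            shift = 0.5 * (fm - fp) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            pos[ax] += shift
            height += -0.25 * (fm - fp) * shift
    frac = pos / np.array(shape)
    return frac % 1.0, float(height)


def residual_extrema(grid: DensityGrid, n_peaks: int = 1) -> PeakList:
    """Largest peak(s) and deepest hole(s) with interpolated positions."""
    v = grid.values
    sig = grid.sigma
    flat_max = np.unravel_index(np.argmax(v), v.shape)
    flat_min = np.unravel_index(np.argmin(v), v.shape)
    peaks = []
    for idx in (flat_max, flat_min):
        frac, height = _refine_extremum(v, idx)
        peaks.append((frac, height, height / sig if sig > 0 else 0.0))
    peaks.sort(key=lambda t: -abs(t[1]))
    return PeakList(peaks, sig)


def _fwhm(x: np.ndarray, y: np.ndarray, i_peak: int):
    """Full width at half maximum around y[i_peak] by linear interpolation."""
    half = y[i_peak] / 2.0
    left = right = None
    for i in range(i_peak, 0, -1):
        if (y[i - 1] - half) * (y[i] - half) <= 0 and y[i - 1] < y[i]:
            t = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + t * (x[i] - x[i - 1])
            break
    for i in range(i_peak, len(y) - 1):
        if (y[i + 1] - half) * (y[i] - half) <= 0 and y[i + 1] < y[i]:
            t = (half - y[i]) / (y[i + 1] - y[i])
            right = x[i] + t * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        return None
    return right - left


def bond_profile(grid: DensityGrid, structure, label1: str, label2: str,
                 n_samples: int = 400, pad: float = 0.6) -> dict:
    """Density profile along a bond, with per-atom peak FWHMs.

    Samples the map along the straight segment from atom1 to atom2,
    extended by ``pad`` A beyond each nucleus.  Peaks are the local maxima
    nearest each nucleus; an unresolved peak yields width None.
    """
    a1 = structure.atom(label1)
    a2 = structure.atom(label2)
    M = structure.cell.orthogonalization_matrix()
    dx = a2.xyz - a1.xyz
    dx = dx - np.round(dx)
    length = float(np.linalg.norm(M @ dx))
    upad = pad / length
    ts = np.linspace(-upad, 1.0 + upad, n_samples)
    pts = a1.xyz + np.outer(ts, dx)
    y = grid.interpolate(pts)
    x = ts * length  # distance from atom1 along the bond (A)
    out = {"x": x, "values": y, "length": length}
    for name, t_at in (("atom1", 0.0), ("atom2", 1.0)):
        i_near = int(np.argmin(np.abs(ts - t_at)))
        # walk to the local maximum nearest the nucleus
        i = i_near
        while 0 < i < len(y) - 1:
            if y[i + 1] > y[i]:
                i += 1
            elif y[i - 1] > y[i]:
                i -= 1
            else:
                break
        if abs(x[i] - x[i_near]) > 0.5:
            out[f"{name}_fwhm"] = None
            out[f"{name}_peak"] = None
            continue
        out[f"{name}_peak"] = (float(x[i]), float(y[i]))
        out[f"{name}_fwhm"] = _fwhm(x, y, i)
    return out


def write_ccp4(grid: DensityGrid, path) -> None:
    """Write the map in CCP4/MRC format (via gemmi)."""
    import gemmi

    m = gemmi.FloatGrid(*grid.shape)
    m.set_unit_cell(gemmi.UnitCell(grid.cell.a, grid.cell.b, grid.cell.c,
                                   grid.cell.alpha, grid.cell.beta, grid.cell.gamma))
    arr = np.ascontiguousarray(grid.values, dtype=np.float32)
    m.array[:] = arr
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = m
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def write_text_grid(grid: DensityGrid, path) -> None:
    """Plain-text x y z value dump (fractional coordinates)."""
    na, nb, nc = grid.shape
    with open(path, "w") as fh:
        fh.write(f"# mpscat map {na} {nb} {nc} units={grid.units}\n")
        for i in range(na):
            for j in range(nb):
                for k in range(nc):
                    fh.write(f"{i/na:.6f} {j/nb:.6f} {k/nc:.6f} "
                             f"{grid.values[i, j, k]:.8g}\n")
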