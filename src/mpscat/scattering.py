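"""Atomic form factors and kinematical unit-cell structure factors.

Supports X-ray radiation (form factors in electrons) and electron
radiation (form factors in A) for both the independent-atom model and the
Hansen-Coppens multipolar model.  Electron scattering factors are obtained
from X-ray ones by the Mott-Bethe formula

    f_e(s) = C_MB (Z - f_x(s)) / s^2 ,      C_MB = m e^2 / (8 pi eps0 h^2)

applied either per atom or at the structure-factor level (the two routes
are algebraically identical and are kept as independent code paths for
cross-checking).  Structure factors:

    F(h) = sum_symops sum_atoms occ * f(h') * T(h') * exp(2 pi i (h' . x + h . t))

with h' = R^T h, T the Debye-Waller factor, and aspherical form factors
evaluated with the atom's local frame composed with the operator rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell import CrystalStructure, UnitCell
from .constants import C_MB, VOLT_PER_F000_DENSITY
from .harmonics import d_lmp_cart
from .pseudoatom import ParameterBank, Pseudoatom
from .radial import fourier_bessel_slater
from .tables import f_e_iam, f_x_iam

__all__ = [
    "StructureFactorSet",
    "f_x_multipole",
    "mott_bethe",
    "calc_structure_factors",
    "f000",
    "mean_inner_potential",
    "compare_sf_sets",
]


@dataclass
class StructureFactorSet:
    """Indexed complex structure factors for one radiation/model."""

    hkl: np.ndarray  # (n, 3) int
    f: np.ndarray  # (n,) complex
    radiation: str  # "xray" | "electron"
    kind: str = "dynamic"  # "static" | "dynamic"
    cell: UnitCell | None = None
    scale: str = "absolute"

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.f = np.asarray(self.f, dtype=complex)
        if len(self.f) != len(self.hkl):
            raise ValueError("hkl and F lists differ in length")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    def d_spacings(self) -> np.ndarray:
        gs = self.cell.reciprocal_metric()
        inv_d2 = np.einsum("ij,jk,ik->i", self.hkl, gs, self.hkl)
        return 1.0 / np.sqrt(inv_d2)


# ---------------------------------------------------------------------------
# atomic form factors

def f_x_multipole(pa: Pseudoatom, h_vec) -> complex:
    """Multipolar X-ray form factor (e) at reciprocal Cartesian h (A^-1).

    f(h) = f_core(|h|) + Pv f_valence(|h|/kappa)
         + sum_l 4 pi i^l <j_l>(|h|/kappa'_l) sum_mp P_lmp d_lmp(h^ in local frame)

    Reduces to the real spherical value when all P_lmp vanish.
    """
    h_vec = np.asarray(h_vec, dtype=float)
    single = h_vec.ndim == 1
    hv = np.atleast_2d(h_vec)
    hmag = np.linalg.norm(hv, axis=-1)
    f = pa.core.form_factor(hmag) + pa.pv * pa.valence.form_factor(hmag / pa.kappa)
    f = f.astype(complex)
    if pa.plmp:
        frame = np.eye(3) if pa.frame is None else pa.frame
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(hmag[:, None] > 0, hv / np.where(hmag[:, None] > 0, hmag[:, None], 1.0), 0.0)
        u = np.where(hmag[:, None] > 0, u, np.array([0.0, 0.0, 1.0]))
        ul = u @ frame  # direction cosines in the local frame
        for (l, m, p), pop in pa.plmp.items():
            if pop == 0.0:
                continue
            kp = pa.kappa_prime[l]
            n, z = pa.radials.n_l[l], pa.radials.zeta[l]
            jl = fourier_bessel_slater(l, n, z, hmag / kp)
            ang = d_lmp_cart(l, m, p, ul)
            ang = np.where(hmag > 0, ang, 0.0 if l > 0 else ang)
            f = f + 4.0 * np.pi * (1j**l) * pop * jl * ang
    return f[0] if single else f


def mott_bethe(z, f_x, s):
    """Electron scattering factor (A) from an X-ray one via Mott-Bethe.

    s must be positive; the s -> 0 limit is handled by :func:`f000`.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError(
            "Mott-Bethe is singular at s = 0; use the dedicated F(000) limit")
    return C_MB * (z - f_x) / (s * s)


# ---------------------------------------------------------------------------
# form-factor providers

class IamFormFactors:
    """Tabulated spherical neutral-atom factors (Gaussian sums)."""

    aspherical = False

    def __init__(self, radiation: str, mott_bethe_from_xray: bool = False):
        self.radiation = radiation
        self.mott_bethe_from_xray = mott_bethe_from_xray

    def evaluate(self, atom, h_cart, h_mag, s):
        if self.radiation == "xray":
            return f_x_iam(atom.element, s).astype(complex)
        if self.mott_bethe_from_xray:
            return mott_bethe(atom.element, f_x_iam(atom.element, s), s).astype(complex)
        return f_e_iam(atom.element, s).astype(complex)

    def f_x_at(self, atom, h_cart, s):
        return f_x_iam(atom.element, s).astype(complex)


class BankFormFactors:
    """Multipolar (or IAM*) factors from a pseudoatom bank.

    Electron radiation always goes through the Mott-Bethe conversion of the
    multipolar X-ray factor, as there is no tabulated aspherical electron
    parameterization.
    """

    aspherical = True

    def __init__(self, radiation: str, bank: ParameterBank,
                 structure: CrystalStructure, spherical: bool = False):
        from .pseudoatom import iam_star

        self.radiation = radiation
        pseudo = bank.resolve(structure)
        if spherical:
            pseudo = {k: iam_star(v) for k, v in pseudo.items()}
        self.pseudo = pseudo

    def evaluate(self, atom, h_cart, h_mag, s):
        fx = f_x_multipole(self.pseudo[atom.label], h_cart)
        if self.radiation == "xray":
            return fx
        return C_MB * (atom.element - fx) / (s * s)

    def f_x_at(self, atom, h_cart, s):
        return f_x_multipole(self.pseudo[atom.label], h_cart)


class NuclearFormFactors:
    """Constant point-charge factor f = Z (the nuclear term of Mott-Bethe)."""

    aspherical = False
    radiation = "xray"

    def evaluate(self, atom, h_cart, h_mag, s):
        return np.full(len(s), float(atom.element), dtype=complex)


def form_factor_provider(model, radiation, structure=None, bank=None):
    """Resolve a model spec ("iam", "taam", "iam*", provider) to a provider."""
    if hasattr(model, "evaluate"):
        return model
    if model == "iam":
        return IamFormFactors(radiation)
    if model == "iam_mb":
        return IamFormFactors(radiation, mott_bethe_from_xray=True)
    if model in ("taam", "iam*"):
        if bank is None or structure is None:
            raise ValueError(f"model {model!r} requires a structure and a bank")
        return BankFormFactors(radiation, bank, structure, spherical=(model == "iam*"))
    if model == "nuclear":
        return NuclearFormFactors()
    raise ValueError(f"unknown scattering model {model!r}")


# ---------------------------------------------------------------------------
# structure factors

def _debye_waller(atom, hs_frac, cell, kind):
    """T(h) for one atom over an (n, 3) array of (rotated) indices."""
    if kind == "static":
        return np.ones(len(hs_frac))
    gs = cell.reciprocal_metric()
    inv_d2 = np.einsum("ij,jk,ik->i", hs_frac, gs, hs_frac)
    if atom.adp.mode == "isotropic":
        return np.exp(-2.0 * math.pi**2 * atom.adp.uiso * inv_d2)
    rl = cell.reciprocal_lengths()
    U = atom.adp.uaniso
    hstar = hs_frac * rl  # h_i a*_i
    expo = np.einsum("ij,jk,ik->i", hstar, U, hstar)
    return np.exp(-2.0 * math.pi**2 * expo)


def calc_structure_factors(structure: CrystalStructure, model, hkl,
                           radiation: str = "xray", kind: str = "dynamic",
                           bank: ParameterBank | None = None,
                           eq10: bool = False) -> StructureFactorSet:
    """Kinematical unit-cell structure factors for a reflection list.

    ``model`` is "iam" (Gaussian tables), "taam" / "iam*" (pseudoatom
    bank), or a form-factor provider.  ``eq10`` selects the
    structure-factor-level Mott-Bethe route for electron radiation:
    F_e = C_MB (F_nuclear - F_x) / s^2, where the nuclear-charge term
    carries the same temperature factors as the electronic one.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    if radiation not in ("xray", "electron"):
        raise ValueError(f"unknown radiation {radiation!r}")
    cell = structure.cell
    gs = cell.reciprocal_metric()
    inv_d2 = np.einsum("ij,jk,ik->i", hkl, gs, hkl)
    if np.any(inv_d2 <= 0) and radiation == "electron":
        raise ValueError("s = 0 reflection in an electron set; F(000) is a separate channel")
    s_all = np.sqrt(inv_d2) / 2.0

    if radiation == "electron" and eq10:
        f_nuc = calc_structure_factors(structure, "nuclear", hkl, "xray", kind)
        xmodel = model if model in ("taam", "iam*") else "iam"
        f_x = calc_structure_factors(structure, xmodel, hkl, "xray", kind, bank=bank)
        f = C_MB * (f_nuc.f - f_x.f) / (s_all * s_all)
        return StructureFactorSet(hkl, f, "electron", kind, cell)

    provider = form_factor_provider(model, radiation, structure, bank)
    B = cell.reciprocal_basis()
    F = np.zeros(len(hkl), dtype=complex)
    for op in structure.symops:
        hs = hkl @ op.R  # row-vector action gives R^T h
        h_cart = hs @ B.T
        phase = np.exp(2j * math.pi * (hkl @ op.t))
        for atom in structure.atoms:
            occ = atom.occupancy * structure.site_multiplicity(atom) / len(structure.symops)
            if occ == 0.0:
                continue
            fa = provider.evaluate(atom, h_cart, np.linalg.norm(h_cart, axis=-1), s_all)
            T = _debye_waller(atom, hs, cell, kind)
            F += occ * fa * T * phase * np.exp(2j * math.pi * (hs @ atom.xyz))
    return StructureFactorSet(hkl, F, radiation, kind, cell)


# ---------------------------------------------------------------------------
# F(000) and the mean inner potential

def f000(structure: CrystalStructure, radiation: str = "xray", model="iam",
         bank: ParameterBank | None = None, kind: str = "static") -> float:
    """F(000): electron count (X-ray, e) or potential integral (electron, A).

    The electron-radiation value is the numerical s -> 0 limit of
    C_MB (F_Z - F_x)/s^2 along a*, Richardson-extrapolated; it diverges for
    a charged unit cell.
    """
    if not structure.atoms:
        return 0.0
    if radiation == "xray":
        if model in ("taam", "iam*") and bank is not None:
            pseudo = bank.resolve(structure)
            if model == "iam*":
                from .pseudoatom import iam_star
                pseudo = {k: iam_star(v) for k, v in pseudo.items()}
            return float(sum(
                structure.site_multiplicity(a) * a.occupancy *
                (pseudo[a.label].core.electrons + pseudo[a.label].pv)
                for a in structure.atoms))
        return float(structure.electron_count())
    if radiation != "electron":
        raise ValueError(f"unknown radiation {radiation!r}")
    # net charge check
    if model in ("taam", "iam*") and bank is not None:
        q = f000(structure, "xray") - f000(structure, "xray", model, bank)
        if abs(q) > 1e-6:
            raise ValueError(
                f"unit cell carries net charge {q:.4g} e; electron F(000) diverges")

    s1, s2 = 1e-2, 5e-3
    g1 = _f_e_sum_at_s(structure, model, bank, kind, s1)
    g2 = _f_e_sum_at_s(structure, model, bank, kind, s2)
    # Richardson: error ~ s^2
    return float((g2 * s1**2 - g1 * s2**2) / (s1**2 - s2**2))


def _f_e_sum_at_s(structure, model, bank, kind, s):
    """sum over unit-cell atoms of C_MB (f_x(0) - f_x(s))/s^2 at tiny s.

    The nuclear term is taken as the atom's own f_x(0) rather than Z: a
    neutral atom has f_x(0) = Z exactly, but Gaussian tabulations carry
    ~1e-4 e of spurious charge which would destroy the numeric limit.
    Genuinely charged models are rejected upstream.
    """
    provider = form_factor_provider(
        model if model in ("taam", "iam*") else "iam", "xray", structure, bank)
    num_s = 0.0  # sum mult (Z - f(s))
    num_0 = 0.0  # sum mult (Z - f(0)) = net cell charge (+ tabulation noise)
    for atom in structure.atoms:
        mult = structure.site_multiplicity(atom) * atom.occupancy
        h_cart = np.array([[0.0, 0.0, 2.0 * s], [0.0, 0.0, 0.0]])
        sarr = np.array([s, 0.0])
        fx = provider.f_x_at(atom, h_cart, sarr)
        num_s += mult * (atom.element - fx[0].real)
        num_0 += mult * (atom.element - fx[1].real)
    n_cell_atoms = sum(structure.site_multiplicity(a) for a in structure.atoms)
    if abs(num_0) > max(0.05, 0.01 * n_cell_atoms):
        raise ValueError(
            f"unit cell carries net charge {num_0:.3f} e; electron F(000) diverges")
    # subtract the residual cell charge (tabulation noise) before the limit
    return C_MB * (num_s - num_0) / (s * s)


def mean_inner_potential(f000_e: float, volume: float) -> float:
    """Mean electrostatic potential (V) from electron F(000) (A) and V (A^3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return f000_e / volume * VOLT_PER_F000_DENSITY


# ---------------------------------------------------------------------------
# comparison statistics

def compare_sf_sets(ref: StructureFactorSet, model: StructureFactorSet,
                    n_bins: int = 50) -> dict:
    """R1 and binned sum-|F|^2 ratios between two structure-factor sets.

    R1 = sum ||F_ref| - |F_model|| / sum |F_ref|, overall and per
    resolution bin; bins are equally populated by reflection count ordered
    from low to high resolution, ties going to the lower bin.
    """
    if ref.hkl.shape != model.hkl.shape or np.any(ref.hkl != model.hkl):
        raise ValueError("structure-factor sets are indexed differently")
    a_ref = ref.amplitudes
    a_mod = model.amplitudes
    dF = a_ref - a_mod
    r1 = float(np.sum(np.abs(dF)) / np.sum(a_ref))
    d = ref.d_spacings() if ref.cell is not None else model.d_spacings()
    order = np.argsort(-d, kind="stable")  # low resolution (large d) first
    n = len(order)
    n_bins = min(n_bins, n) or 1
    edges = [round(i * n / n_bins) for i in range(n_bins + 1)]
    bins = []
    for i in range(n_bins):
        idx = order[edges[i]:edges[i + 1]]
        if len(idx) == 0:
            continue
        bins.append({
            "d_max": float(d[idx].max()),
            "d_min": float(d[idx].min()),
            "n": int(len(idx)),
            "r1": float(np.sum(np.abs(dF[idx])) / np.sum(a_ref[idx])),
            "sum_f2_ratio": float(np.sum(a_ref[idx] ** 2) / np.sum(a_mod[idx] ** 2)),
        })
    return {"r1": r1, "bins": bins, "delta_f": dF}
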