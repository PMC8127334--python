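"""Model-comparison metrics: ME/RMSD and the ADP similarity index.

The similarity index S12 measures the non-overlap of the two zero-mean
Gaussian probability densities defined by two ADP tensors:

    R12 = 2^(3/2) (det U1 det U2)^(1/4) / det(U1 + U2)^(1/2)
    S12 = 100 (1 - R12)

on Cartesianized tensors.  S12 = 0 for identical ADPs, grows toward 100
for disjoint ellipsoids, and is symmetric in its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell import AdpSet, UnitCell

__all__ = ["similarity_index", "me_rmsd", "AdpComparison", "compare_adps"]


def similarity_index(u1, u2, cell: UnitCell | None = None) -> float:
    """S12 (percent) between two ADP sets or Cartesian 3x3 tensors.

    Inputs may be :class:`AdpSet` (requires ``cell``) or Cartesian
    symmetric positive-definite matrices.  Non-positive-definite input is
    a domain error, matching the exclusion of NPD refinements from ADP
    statistics.
    """
    def cartesian(u):
        if isinstance(u, AdpSet):
            if cell is None:
                raise ValueError("AdpSet input requires the unit cell")
            return u.u_cart(cell)
        return np.asarray(u, dtype=float)

    U1 = cartesian(u1)
    U2 = cartesian(u2)
    for U in (U1, U2):
        if np.linalg.eigvalsh(U).min() <= 0:
            raise ValueError("similarity index undefined for non-positive-definite ADPs")
    d1 = np.linalg.det(U1)
    d2 = np.linalg.det(U2)
    d12 = np.linalg.det(U1 + U2)
    r12 = 2.0 ** 1.5 * (d1 * d2) ** 0.25 / math.sqrt(d12)
    return float(100.0 * (1.0 - r12))


def me_rmsd(values, reference) -> dict:
    """Mean error and RMS difference of model values against a reference."""
    x = np.asarray(values, dtype=float)
    r = np.asarray(reference, dtype=float)
    if x.shape != r.shape:
        raise ValueError("value and reference lists differ in length")
    if x.size == 0:
        raise ValueError("empty input")
    d = x - r
    return {"me": float(d.mean()), "rmsd": float(np.sqrt(np.mean(d * d)))}


@dataclass
class AdpComparison:
    """Ueq/Uiso agreement (in 10^-3 A^2) and mean S12 over an atom set."""

    me: float
    rmsd: float
    mean_s12: float | None
    n: int


def compare_adps(structure, reference, labels=None,
                 exclude_npd: bool = True) -> AdpComparison:
    """ME/RMSD of Ueq (10^-3 A^2) and mean S12 between two structures.

    Atoms whose model ADP went non-positive definite carry meaningless
    displacement values and are excluded by default, as refinements
    producing NPD ADPs are excluded from displacement statistics.  S12
    terms are averaged over pairs where both ADPs are anisotropic and
    positive definite; None if no such pair exists.
    """
    cell = structure.cell
    if labels is None:
        labels = [a.label for a in structure.atoms]
    ueq_m, ueq_r, s12s = [], [], []
    n_used = 0
    for lab in labels:
        am = structure.atom(lab)
        ar = reference.atom(lab)
        if exclude_npd and am.adp.is_npd(cell):
            continue
        n_used += 1
        ueq_m.append(am.adp.u_eq(cell))
        ueq_r.append(ar.adp.u_eq(reference.cell))
        if am.adp.mode == "anisotropic" and ar.adp.mode == "anisotropic":
            try:
                s12s.append(similarity_index(am.adp.u_cart(cell),
                                             ar.adp.u_cart(reference.cell)))
            except ValueError:
                pass
    if not ueq_m:
        return AdpComparison(me=float("nan"), rmsd=float("nan"),
                             mean_s12=None, n=0)
    stats = me_rmsd(np.array(ueq_m) * 1e3, np.array(ueq_r) * 1e3)
    return AdpComparison(me=stats["me"], rmsd=stats["rmsd"],
                         mean_s12=float(np.mean(s12s)) if s12s else None,
                         n=n_used)
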