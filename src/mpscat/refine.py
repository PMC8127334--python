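"""Gauss-Newton least-squares refinement against |F|^2.

Minimizes  sum_h w_h (Fo^2 - k |Fc|^2)^2 + sum_restraints ((d - d0)/esd)^2
with the weighting scheme

    w = 1 / (sigma^2 + (a P)^2 + b P),   P = (1/3) max(0, Fo^2) + (2/3) Fc^2

over atomic coordinates and displacement parameters selected by one of
four gradually released parameter-set options:

    1: non-H x,y,z,Uiso;            H fully constrained/restrained
    2: non-H x,y,z,Uaniso;          H fully constrained/restrained
    3: + H x,y,z,Uiso free
    4: + H anisotropic Uij

Hydrogen treatment depends on radiation: for X-ray data H atoms ride on
their parent (ideal-geometry regeneration, X-H 0.86 A for N-H and 0.93 A
for aromatic C-H); for electron data H coordinates are free but
distance-restrained to neutron-like targets (1.01 / 1.083 A, esd 0.02 A).
In options 1-2 the H Uiso is tied to the parent's Ueq by a fixed
multiplier.  The overall scale factor k is solved in closed form each
cycle.  Normal equations use analytic derivatives, symmetric solves and
Levenberg damping; non-positive-definite ADPs are reported, not repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell import AdpSet, CrystalStructure
from .scattering import form_factor_provider, _debye_waller

__all__ = [
    "WeightingScheme",
    "DistanceRestraint",
    "RefinementSpec",
    "RefinementResult",
    "weight_of",
    "auto_weights",
    "build_parameters",
    "refine",
    "fit_statistics",
    "connectivity",
    "place_riding_hydrogens",
]

#: default riding X-H distances (A) for X-ray refinement, keyed by parent element
XRAY_XH = {7: 0.86, 6: 0.93}
#: default restrained X-H target distances (A) for electron refinement
ELECTRON_XH = {7: 1.01, 6: 1.083}
ELECTRON_XH_ESD = 0.02


@dataclass
class WeightingScheme:
    a: float = 0.0
    b: float = 0.0
    mode: str = "fixed"  # "fixed" | "auto"


@dataclass(frozen=True)
class DistanceRestraint:
    atom1: str
    atom2: str
    target: float
    esd: float

    def __post_init__(self):
        if self.esd <= 0:
            raise ValueError("restraint esd must be positive")


@dataclass
class RefinementSpec:
    option: int = 2
    radiation: str = "xray"
    model: str = "iam"
    weighting: WeightingScheme = field(default_factory=WeightingScheme)
    restraints: list = field(default_factory=list)
    max_cycles: int = 50
    shift_esd_tol: float = 0.01
    h_uiso_multiplier: float = 1.2
    bank: object = None

    def __post_init__(self):
        if self.option not in (1, 2, 3, 4):
            raise ValueError("option must be 1, 2, 3 or 4")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    r1: float
    wr2: float
    gof: float
    scale: float
    cycles: int
    converged: bool
    npd_atoms: list
    shifts: dict
    esds: dict
    weighting: tuple
    history: list


# ---------------------------------------------------------------------------
# weighting

def weight_of(fo2, sigma_fo2, fc2, a=0.0, b=0.0):
    """SHELX-style weight 1/(sigma^2 + (aP)^2 + bP)."""
    fo2 = np.asarray(fo2, dtype=float)
    sigma = np.asarray(sigma_fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    P = np.maximum(fo2, 0.0) / 3.0 + (2.0 / 3.0) * fc2
    denom = sigma**2 + (a * P) ** 2 + b * P
    if np.any(denom <= 0):
        raise ValueError("non-positive weight denominator (b too negative?)")
    return 1.0 / denom


def _binned_gof(fo2, sigma, fc2, k, a, b, n_bins=10):
    w = weight_of(fo2, sigma, k * fc2, a, b)
    dev = w * (fo2 - k * fc2) ** 2
    order = np.argsort(k * fc2, kind="stable")
    bins = np.array_split(order, n_bins)
    return np.array([math.sqrt(dev[idx].mean()) for idx in bins if len(idx)])


def auto_weights(fo2, sigma, fc2, k=1.0, n_bins=10):
    """(a, b) flattening the intensity-binned goodness of fit.

    Derivative-free search from (0.1, 0); the objective is the variance of
    bin-wise GoF over ``n_bins`` Fc^2-ordered bins, with a penalty keeping
    the overall GoF near unity.  Deterministic given the data.  Degenerate
    data (all Fc^2 equal) falls back to (0, 0).
    """
    from scipy.optimize import minimize

    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    if len(fo2) < 10 * n_bins or np.ptp(fc2) < 1e-12 * max(1.0, np.abs(fc2).max()):
        return 0.0, 0.0

    def objective(ab):
        a, b = abs(ab[0]), abs(ab[1])
        try:
            g = _binned_gof(fo2, sigma, fc2, k, a, b, n_bins)
        except ValueError:
            return 1e12
        overall = g.mean()
        penalty = max(0.0, overall - 1.05) ** 2 + max(0.0, 0.95 - overall) ** 2
        return g.var() + 10.0 * penalty

    res = minimize(objective, x0=[0.1, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
    a, b = abs(res.x[0]), abs(res.x[1])
    if objective([a, b]) >= objective([0.0, 0.0]):
        return 0.0, 0.0
    return float(a), float(b)


# ---------------------------------------------------------------------------
# connectivity and hydrogen constraints

def connectivity(structure: CrystalStructure, cutoff: float = 1.85) -> dict:
    """label -> list of bonded labels (asymmetric unit, minimum image)."""
    G = structure.cell.metric()
    labels = [a.label for a in structure.atoms]
    out = {lab: [] for lab in labels}
    for i, ai in enumerate(structure.atoms):
        for aj in structure.atoms[i + 1:]:
            dx = ai.xyz - aj.xyz
            dx = dx - np.round(dx)
            dist = math.sqrt(max(dx @ G @ dx, 0.0))
            lim = cutoff if (ai.element > 1 and aj.element > 1) else 1.35
            if dist < lim:
                out[ai.label].append(aj.label)
                out[aj.label].append(ai.label)
    return out


def hydrogen_parents(structure: CrystalStructure) -> dict:
    """H label -> parent (covalent non-H partner) label."""
    G = structure.cell.metric()
    parents = {}
    for at in structure.atoms:
        if at.element != 1:
            continue
        best, best_d = None, math.inf
        for other in structure.atoms:
            if other.element == 1:
                continue
            dx = at.xyz - other.xyz
            dx = dx - np.round(dx)
            d = math.sqrt(max(dx @ G @ dx, 0.0))
            if d < best_d:
                best, best_d = other.label, d
        if best is None:
            raise ValueError(f"hydrogen {at.label!r} has no non-H neighbour")
        parents[at.label] = best
    return parents


def place_riding_hydrogens(structure: CrystalStructure, distances=XRAY_XH) -> None:
    """Regenerate ideal H positions on their parents, in place.

    Parents with two non-H neighbours get the H on the external bisector
    (trigonal/aromatic geometry); parents with one non-H neighbour get
    their H set at the ideal 120 deg positions in the plane of the parent,
    its neighbour and the neighbour's furthest other neighbour (planar
    amide geometry).  The X-H distance comes from ``distances`` by parent
    element (default: the X-ray riding values).
    """
    M = structure.cell.orthogonalization_matrix()
    Minv = np.linalg.inv(M)
    conn = connectivity(structure)
    parents = hydrogen_parents(structure)
    by_parent: dict = {}
    for h, p in parents.items():
        by_parent.setdefault(p, []).append(h)
    for p_lab, h_labs in by_parent.items():
        parent = structure.atom(p_lab)
        d = distances.get(parent.element, 1.0)
        heavies = [l for l in conn[p_lab] if structure.atom(l).element > 1]
        p_cart = M @ parent.xyz

        def cart_to(lab):
            dx = structure.atom(lab).xyz - parent.xyz
            dx = dx - np.round(dx)
            v = M @ dx
            return v / np.linalg.norm(v)

        if len(heavies) >= 2:
            u = -(cart_to(heavies[0]) + cart_to(heavies[1]))
            u /= np.linalg.norm(u)
            for h_lab in sorted(h_labs):
                structure.atom(h_lab).xyz = Minv @ (p_cart + d * u)
        elif len(heavies) == 1:
            v1 = cart_to(heavies[0])
            ref_neigh = [l for l in conn[heavies[0]] if l != p_lab]
            if ref_neigh:
                v2 = cart_to(ref_neigh[0])
            else:  # no plane reference: any perpendicular
                v2 = np.array([1.0, 0.0, 0.0])
                if abs(v1 @ v2) > 0.9:
                    v2 = np.array([0.0, 1.0, 0.0])
            perp = v2 - (v2 @ v1) * v1
            perp /= np.linalg.norm(perp)
            cos120, sin120 = -0.5, math.sqrt(3.0) / 2.0
            placements = [v1 * cos120 + perp * sin120, v1 * cos120 - perp * sin120]
            # assign each H to the nearest ideal slot (stable by label order)
            for h_lab in sorted(h_labs):
                h_at = structure.atom(h_lab)
                dx = h_at.xyz - parent.xyz
                dx = dx - np.round(dx)
                cur = M @ dx
                best = max(placements, key=lambda u: (u @ cur))
                placements = [u for u in placements if u is not best]
                h_at.xyz = Minv @ (p_cart + d * best)
        else:
            raise ValueError(f"cannot place H on isolated atom {p_lab!r}")


# ---------------------------------------------------------------------------
# parameterization

@dataclass
class ParameterMap:
    """Free-parameter layout and the constraint map to full atomic shifts."""

    entries: list  # ("scale",) | (i, "x", j) | (i, "uiso") | (i, "uij", k)
    riding: dict  # H atom index -> parent index (position riding)
    uiso_tied: dict  # H atom index -> parent index (Uiso = mult * Ueq)
    restraints: list

    @property
    def n(self) -> int:
        return len(self.entries)


def build_parameters(structure: CrystalStructure, spec: RefinementSpec) -> ParameterMap:
    """Free-parameter list for a refinement option (scale always included)."""
    parents = hydrogen_parents(structure) if any(
        a.element == 1 for a in structure.atoms) else {}
    idx = {a.label: i for i, a in enumerate(structure.atoms)}
    for h_lab, p_lab in parents.items():
        if structure.atom(p_lab).element == 1:
            raise ValueError("inconsistent constraint graph: H riding on H")

    entries = [("scale",)]
    riding: dict = {}
    uiso_tied: dict = {}
    restraints = list(spec.restraints)
    h_free_xyz = spec.option >= 3 or spec.radiation == "electron"
    h_free_uiso = spec.option >= 3
    h_aniso = spec.option >= 4
    non_h_aniso = spec.option >= 2

    for i, at in enumerate(structure.atoms):
        if at.element > 1:
            entries += [(i, "x", j) for j in range(3)]
            if non_h_aniso:
                entries += [(i, "uij", k) for k in range(6)]
            else:
                entries.append((i, "uiso"))
        else:
            p_i = idx[parents[at.label]]
            if h_free_xyz:
                entries += [(i, "x", j) for j in range(3)]
            else:
                riding[i] = p_i
            if h_aniso:
                entries += [(i, "uij", k) for k in range(6)]
            elif h_free_uiso:
                entries.append((i, "uiso"))
            else:
                uiso_tied[i] = p_i
    if spec.radiation == "electron" and parents:
        have = {(r.atom1, r.atom2) for r in restraints} | {
            (r.atom2, r.atom1) for r in restraints}
        for h_lab, p_lab in sorted(parents.items()):
            if (h_lab, p_lab) not in have:
                target = ELECTRON_XH.get(structure.atom(p_lab).element, 1.0)
                restraints.append(DistanceRestraint(h_lab, p_lab, target, ELECTRON_XH_ESD))
    return ParameterMap(entries, riding, uiso_tied, restraints)


def _ueq_weights(atom, cell):
    """Linear weights of Ueq in the atom's stored ADP components."""
    if atom.adp.mode == "isotropic":
        return {"uiso": 1.0}
    N = np.diag(cell.reciprocal_lengths())
    A = cell.orthogonalization_matrix() @ N
    W = (A.T @ A) / 3.0
    keys = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    return {("uij", k): (W[i, j] * (2.0 if i != j else 1.0))
            for k, (i, j) in enumerate(keys)}


# ---------------------------------------------------------------------------
# structure factors with analytic derivatives

_UIJ_KEYS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _sf_and_derivs(structure, provider, hkl, kind, need: set, ff_cache=None):
    """F(h) and dF/dp for the atomic parameters listed in ``need``.

    ``need`` holds tuples (i, "x", j), (i, "uiso"), (i, "uij", k).  Returns
    (F, derivs dict).  ``ff_cache`` may hold per-(symop, atom) form-factor
    arrays: they depend only on the reflection list and the (fixed) local
    frames, not on the refined parameters.
    """
    cell = structure.cell
    B = cell.reciprocal_basis()
    rl = cell.reciprocal_lengths()
    gs = cell.reciprocal_metric()
    nref = len(hkl)
    F = np.zeros(nref, dtype=complex)
    derivs = {key: np.zeros(nref, dtype=complex) for key in need}
    by_atom: dict = {}
    for key in need:
        by_atom.setdefault(key[0], []).append(key)

    for i_op, op in enumerate(structure.symops):
        hs = hkl @ op.R
        h_cart = hs @ B.T
        hmag = np.linalg.norm(h_cart, axis=-1)
        s_all = hmag / 2.0
        inv_d2 = np.einsum("ij,jk,ik->i", hs, gs, hs)
        tphase = np.exp(2j * math.pi * (hkl @ op.t))
        hstar = hs * rl
        for i, atom in enumerate(structure.atoms):
            occ = atom.occupancy * structure.site_multiplicity(atom) / len(structure.symops)
            if occ == 0.0:
                continue
            if ff_cache is not None:
                ck = (i_op, atom.label)
                if ck not in ff_cache:
                    ff_cache[ck] = provider.evaluate(atom, h_cart, hmag, s_all)
                fa = ff_cache[ck]
            else:
                fa = provider.evaluate(atom, h_cart, hmag, s_all)
            T = _debye_waller(atom, hs, cell, kind)
            c = occ * fa * T * tphase * np.exp(2j * math.pi * (hs @ atom.xyz))
            F += c
            for key in by_atom.get(i, ()):
                if key[1] == "x":
                    derivs[key] += 2j * math.pi * hs[:, key[2]] * c
                elif key[1] == "uiso":
                    derivs[key] += -2.0 * math.pi**2 * inv_d2 * c
                else:  # uij
                    a, b = _UIJ_KEYS[key[2]]
                    mult = 2.0 if a != b else 1.0
                    derivs[key] += (-2.0 * math.pi**2 * mult
                                    * hstar[:, a] * hstar[:, b] * c)
    return F, derivs


def _floating_directions(symops) -> np.ndarray:
    """Orthonormal basis (columns) of directions not fixed by symmetry."""
    rows = []
    for op in symops:
        rows.append(op.R - np.eye(3))
    Astack = np.vstack(rows)
    _, sv, vt = np.linalg.svd(Astack)
    null = vt[np.sum(sv > 1e-9):]
    return null.T  # (3, n_float)


def _get_param(structure, key):
    atom = structure.atoms[key[0]]
    if key[1] == "x":
        return atom.xyz[key[2]]
    if key[1] == "uiso":
        return atom.adp.uiso
    a, b = _UIJ_KEYS[key[2]]
    return atom.adp.uaniso[a, b]


def _add_param(structure, key, delta):
    atom = structure.atoms[key[0]]
    if key[1] == "x":
        atom.xyz[key[2]] += delta
    elif key[1] == "uiso":
        atom.adp.uiso += delta
    else:
        a, b = _UIJ_KEYS[key[2]]
        atom.adp.uaniso[a, b] += delta
        atom.adp.uaniso[b, a] = atom.adp.uaniso[a, b]


def _apply_constraints(structure, pmap, spec):
    """Regenerate ridden H positions and tied H Uiso values, in place."""
    if pmap.riding:
        place_riding_hydrogens(structure, XRAY_XH)
    for h_i, p_i in pmap.uiso_tied.items():
        parent = structure.atoms[p_i]
        structure.atoms[h_i].adp.uiso = (
            spec.h_uiso_multiplier * parent.adp.u_eq(structure.cell))


def _promote_adps(structure, spec):
    """Switch stored ADP modes to match the option's parameter set."""
    for at in structure.atoms:
        aniso = (spec.option >= 2 and at.element > 1) or (spec.option >= 4)
        if aniso and at.adp.mode == "isotropic":
            at.adp = AdpSet("anisotropic", uaniso=np.eye(3) * at.adp.uiso)
        # Uiso-refined atoms with an aniso tensor collapse to Ueq
        if not aniso and at.adp.mode == "anisotropic":
            at.adp = AdpSet("isotropic", uiso=at.adp.u_eq(structure.cell))


def _restraint_rows(structure, restraints):
    """Residuals and fractional-coordinate gradients of distance restraints."""
    G = structure.cell.metric()
    rows = []
    for r in restraints:
        a1 = structure.atom(r.atom1)
        a2 = structure.atom(r.atom2)
        dx = a1.xyz - a2.xyz
        dx = dx - np.round(dx)
        d = math.sqrt(max(dx @ G @ dx, 1e-300))
        grad = (G @ dx) / d  # d d/d x1 = -d d/d x2
        rows.append((r, (r.target - d) / r.esd, a1.label, a2.label, grad / r.esd))
    return rows


def fit_statistics(fo2, sigma, fc2, k, weights, n_params):
    """R1 (amplitudes), wR2 and GoF of a scaled |F|^2 fit."""
    fo2 = np.asarray(fo2, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    w = np.asarray(weights, dtype=float)
    fo = np.sqrt(np.maximum(fo2, 0.0))
    fc = math.sqrt(k) * np.sqrt(fc2)
    r1 = float(np.sum(np.abs(fo - fc)) / np.sum(fo))
    num = np.sum(w * (fo2 - k * fc2) ** 2)
    wr2 = float(math.sqrt(num / np.sum(w * fo2**2)))
    n = len(fo2)
    if n <= n_params:
        raise ValueError("GoF undefined: no degrees of freedom (n <= p)")
    gof = float(math.sqrt(num / (n - n_params)))
    return {"r1": r1, "wr2": wr2, "gof": gof}


def refine(structure: CrystalStructure, reflections, spec: RefinementSpec,
           verbose: bool = False) -> RefinementResult:
    """Gauss-Newton refinement of a structure against Fo^2 data.

    ``reflections`` is a structured input: (hkl array (n,3), fo2 (n,),
    sigma (n,)) or an object with those attributes.  Returns a
    :class:`RefinementResult`; the input structure is not modified.
    """
    import logging
    log = logging.getLogger(__name__)

    if hasattr(reflections, "hkl"):
        hkl = np.asarray(reflections.hkl, dtype=int)
        fo2 = np.asarray(reflections.fo2, dtype=float)
        sigma = np.asarray(reflections.sigma, dtype=float)
    else:
        hkl, fo2, sigma = reflections
        hkl = np.asarray(hkl, dtype=int)
        fo2 = np.asarray(fo2, dtype=float)
        sigma = np.asarray(sigma, dtype=float)

    st = structure.copy()
    _promote_adps(st, spec)
    pmap = build_parameters(st, spec)
    if len(fo2) <= pmap.n:
        raise ValueError("fewer observations than free parameters")
    provider = form_factor_provider(spec.model, spec.radiation, st, spec.bank)
    frames_track_geometry = hasattr(provider, "pseudo")

    # parameters whose derivatives are needed: free ones + riding/tied images
    need = set()
    col_terms = {}  # free entry -> [(atomic key, coefficient callable/float)]
    for e, entry in enumerate(pmap.entries):
        if entry == ("scale",):
            continue
        need.add(entry)
        col_terms.setdefault(entry, []).append((entry, 1.0))
    for h_i, p_i in pmap.riding.items():
        for j in range(3):
            key_h = (h_i, "x", j)
            key_p = (p_i, "x", j)
            need.add(key_h)
            if key_p in col_terms:
                col_terms[key_p].append((key_h, 1.0))
    for h_i, p_i in pmap.uiso_tied.items():
        key_h = (h_i, "uiso")
        need.add(key_h)
        wts = _ueq_weights(st.atoms[p_i], st.cell)
        for comp, wval in wts.items():
            key_p = (p_i, "uiso") if comp == "uiso" else (p_i, "uij", comp[1])
            if key_p in col_terms:
                col_terms[key_p].append((key_h, spec.h_uiso_multiplier * wval))

    float_dirs = _floating_directions(st.symops)
    ff_cache: dict = {}
    a_w, b_w = spec.weighting.a, spec.weighting.b
    scale = 1.0
    lam = 1e-8
    history = []
    converged = False
    esds = np.zeros(pmap.n)
    shifts = np.zeros(pmap.n)
    free_entries = pmap.entries

    def objective(stc, k):
        Fc, _ = _sf_and_derivs(stc, provider, hkl, "dynamic", set(), ff_cache)
        fc2 = np.abs(Fc) ** 2
        w = weight_of(fo2, sigma, k * fc2, a_w, b_w)
        rows = _restraint_rows(stc, pmap.restraints)
        return (np.sum(w * (fo2 - k * fc2) ** 2)
                + sum(r[1] ** 2 for r in rows)), fc2

    cycles = 0
    for cycle in range(1, spec.max_cycles + 1):
        cycles = cycle
        _apply_constraints(st, pmap, spec)
        if frames_track_geometry:
            # multipole local frames follow the current geometry
            provider = form_factor_provider(spec.model, spec.radiation, st, spec.bank)
            ff_cache.clear()
        Fc, derivs = _sf_and_derivs(st, provider, hkl, "dynamic", need, ff_cache)
        fc2 = np.abs(Fc) ** 2
        # closed-form scale update
        w = weight_of(fo2, sigma, scale * fc2, a_w, b_w)
        scale = float(np.sum(w * fo2 * fc2) / np.sum(w * fc2**2))
        if spec.weighting.mode == "auto" and cycle == 1:
            a_w, b_w = auto_weights(fo2, sigma, fc2, scale)
            w = weight_of(fo2, sigma, scale * fc2, a_w, b_w)
        sw = np.sqrt(w)
        resid = sw * (fo2 - scale * fc2)

        # Jacobian of the model k|Fc|^2 w.r.t. free parameters
        label_to_idx = {a.label: i for i, a in enumerate(st.atoms)}
        rrows = _restraint_rows(st, pmap.restraints)
        nrow = len(hkl) + len(rrows) + (
            float_dirs.shape[1] if float_dirs.size else 0)
        J = np.zeros((nrow, pmap.n))
        r_all = np.zeros(nrow)
        r_all[: len(hkl)] = resid
        for e, entry in enumerate(free_entries):
            if entry == ("scale",):
                J[: len(hkl), e] = sw * fc2
                continue
            dF = np.zeros(len(hkl), dtype=complex)
            for key, coef in col_terms[entry]:
                dF += coef * derivs[key]
            J[: len(hkl), e] = sw * scale * 2.0 * np.real(np.conj(Fc) * dF)
        # restraint rows (pseudo-observations, weight 1/esd^2 already applied)
        for ri, (r, rv, l1, l2, grad) in enumerate(rrows):
            row = len(hkl) + ri
            r_all[row] = rv
            for lab, sgn in ((l1, 1.0), (l2, -1.0)):
                ia = label_to_idx[lab]
                for j in range(3):
                    key = (ia, "x", j)
                    for e, entry in enumerate(free_entries):
                        if entry == key:
                            # residual = (target - d)/esd; d(residual)/dx = -grad
                            J[row, e] -= -sgn * grad[j]
        # origin-fixing rows along floating directions
        if float_dirs.size:
            big = math.sqrt(np.abs(J[: len(hkl)]).max() ** 2 * len(hkl)) or 1.0
            for fd in range(float_dirs.shape[1]):
                row = len(hkl) + len(rrows) + fd
                e_dir = float_dirs[:, fd]
                for e, entry in enumerate(free_entries):
                    if entry != ("scale",) and entry[1] == "x":
                        J[row, e] = big * e_dir[entry[2]]
                r_all[row] = 0.0

        JtJ = J.T @ J
        Jtr = J.T @ r_all
        obj0 = float(np.sum(r_all**2))
        obj_floor = 1e-18 * float(np.sum(w * fo2**2) + 1.0)
        if obj0 <= 1e3 * obj_floor:  # numerically perfect fit
            converged = True
            history.append({"cycle": cycle, "objective": obj0,
                            "scale": scale, "max_shift_esd": 0.0})
            break
        diag = np.diag(JtJ).copy()
        diag[diag <= 0] = 1.0

        # esds from the (undamped) normal matrix, scaled by GoF
        dof = max(len(hkl) + len(rrows) - pmap.n, 1)
        gof2 = obj0 / dof
        try:
            cov = np.linalg.inv(JtJ)
            esds = np.sqrt(np.maximum(np.diag(cov), 0.0) * gof2)
        except np.linalg.LinAlgError:
            esds = np.full(pmap.n, np.nan)

        def shift_over_esd(dvec):
            with np.errstate(divide="ignore", invalid="ignore"):
                return float(np.nanmax(
                    np.abs(dvec) / np.where(esds > 0, esds, np.inf)))

        accepted = False
        best_obj1 = math.inf
        obj1 = math.inf
        delta = np.zeros(pmap.n)
        lam = max(lam, 1e-10)
        for attempt in range(18):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(diag), Jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = st.copy()
            for e, entry in enumerate(free_entries):
                if entry == ("scale",):
                    continue
                _add_param(trial, entry, delta[e])
            _apply_constraints(trial, pmap, spec)
            k_trial = scale + delta[free_entries.index(("scale",))]
            obj1, _ = objective(trial, k_trial)
            best_obj1 = min(best_obj1, obj1)
            if obj1 <= obj0 * (1.0 + 1e-12) + obj_floor:
                accepted = True
                st = trial
                scale = k_trial
                lam = max(lam / 10.0, 1e-12)
                break
            lam *= 10.0
        shifts = delta
        max_shift = shift_over_esd(delta)
        history.append({"cycle": cycle, "objective": obj0,
                        "scale": scale, "max_shift_esd": max_shift})
        if not accepted:
            # stall with no meaningful objective change: converged fit
            if best_obj1 <= obj0 * (1.0 + 1e-5) + obj_floor:
                converged = True
                break
            raise RuntimeError(
                f"refinement failed to reduce the objective at cycle {cycle} "
                f"(damping {lam:.2g}, condition {np.linalg.cond(JtJ):.3g})")
        if verbose:
            log.info("cycle %d: obj %.6g scale %.4f max shift/esd %.3g",
                     cycle, obj0, scale, max_shift)
        rel_drop = (obj0 - obj1) / (abs(obj0) + obj_floor)
        if max_shift < spec.shift_esd_tol and rel_drop < 1e-6:
            converged = True
            break

    _apply_constraints(st, pmap, spec)
    Fc, _ = _sf_and_derivs(st, provider, hkl, "dynamic", set(), ff_cache)
    fc2 = np.abs(Fc) ** 2
    w = weight_of(fo2, sigma, scale * fc2, a_w, b_w)
    stats = fit_statistics(fo2, sigma, fc2, scale, w, pmap.n)
    npd = [a.label for a in st.atoms
           if a.adp.mode == "anisotropic" and a.adp.is_npd(st.cell)]
    shift_map = {str(e): float(s) for e, s in zip(free_entries, shifts)}
    esd_map = {str(e): float(s) for e, s in zip(free_entries, esds)}
    return RefinementResult(
        structure=st, r1=stats["r1"], wr2=stats["wr2"], gof=stats["gof"],
        scale=scale, cycles=cycles, converged=converged, npd_atoms=npd,
        shifts=shift_map, esds=esd_map, weighting=(a_w, b_w), history=history)
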