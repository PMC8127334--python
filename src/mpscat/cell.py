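"""Unit-cell metrics, symmetry operators, atoms and ADPs.

Coordinates are fractional throughout; Cartesian frames appear only inside
operations.  The orthogonalization convention puts the *a* axis along
Cartesian x and *b* in the xy plane.  Anisotropic displacement parameters
are stored in the CIF U^ij convention: the Debye-Waller exponent is
-2 pi^2 sum_ij U^ij h_i h_j a*_i a*_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "AdpSet",
    "Atom",
    "CrystalStructure",
    "parse_symop",
    "cell_volume_and_metrics",
    "resolution_of",
    "generate_reflections",
    "bond_lengths",
]


class InvalidCellError(ValueError):
    """Raised for degenerate unit-cell parameters."""


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in A, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) deg")
        if np.linalg.det(self.metric()) <= 0:
            raise InvalidCellError("angles are mutually incompatible")

    def metric(self) -> np.ndarray:
        """Direct metric tensor G (A^2)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (A^-2)."""
        return np.linalg.inv(self.metric())

    @property
    def volume(self) -> float:
        """Cell volume in A^3."""
        return math.sqrt(np.linalg.det(self.metric()))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with the direct basis vectors as columns (A).

        Cartesian r = M @ x_fractional; a along x, b in the xy plane.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        a, b, c = self.a, self.b, self.c
        v = self.volume / (a * b * c)
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    def reciprocal_basis(self) -> np.ndarray:
        """Matrix B with the reciprocal basis vectors as columns (A^-1).

        Cartesian scattering vector h_cart = B @ (h, k, l).
        """
        return np.linalg.inv(self.orthogonalization_matrix()).T

    def reciprocal_cell(self) -> "UnitCell":
        """The reciprocal unit cell (lengths in A^-1)."""
        gs = self.reciprocal_metric()
        ra, rb, rc = np.sqrt(np.diag(gs))
        ralpha = math.degrees(math.acos(gs[1, 2] / (rb * rc)))
        rbeta = math.degrees(math.acos(gs[0, 2] / (ra * rc)))
        rgamma = math.degrees(math.acos(gs[0, 1] / (ra * rb)))
        return UnitCell(ra, rb, rc, ralpha, rbeta, rgamma)

    def reciprocal_lengths(self) -> np.ndarray:
        return np.sqrt(np.diag(self.reciprocal_metric()))


@dataclass(frozen=True)
class SymOp:
    """Symmetry operator acting on fractional coordinates: x' = R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # 3 floats (rational values such as 1/2)

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    def __post_init__(self):
        det = round(np.linalg.det(np.array(self.rotation, dtype=float)))
        if det not in (1, -1):
            raise ValueError("symmetry rotation must have determinant +/-1")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return self.R @ np.asarray(xyz, dtype=float) + self.t

    def triplet(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(v) * gemmi.Op.DEN for v in row] for row in self.rotation]
        op.tran = [int(round(v * gemmi.Op.DEN)) for v in self.translation]
        return op.triplet()


def parse_symop(triplet: str) -> SymOp:
    """Parse an xyz-triplet string like ``-x+1/2, y+1/2, -z+1/2``."""
    try:
        op = gemmi.Op(triplet)
    except Exception as exc:  # gemmi raises RuntimeError on bad input
        raise ValueError(f"malformed symmetry operator {triplet!r}: {exc}") from None
    den = gemmi.Op.DEN
    rot = tuple(tuple(v // den for v in row) for row in op.rot)
    if any(v * den != w for row, orow in zip(rot, op.rot) for v, w in zip(row, orow)):
        raise ValueError(f"non-integral rotation in symmetry operator {triplet!r}")
    tran = tuple(v / den for v in op.tran)
    return SymOp(rot, tran)


IDENTITY = SymOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

#: Conventional symbols for the light elements handled by the bundled tables.
ELEMENT_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
             "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17}
Z_SYMBOL = {z: s for s, z in ELEMENT_Z.items()}


@dataclass
class AdpSet:
    """Atomic displacement parameters: isotropic U or CIF-convention U^ij."""

    mode: str = "isotropic"  # "isotropic" | "anisotropic"
    uiso: float = 0.0
    uaniso: np.ndarray | None = None  # symmetric 3x3, CIF U^ij (A^2)

    def __post_init__(self):
        if self.mode not in ("isotropic", "anisotropic"):
            raise ValueError(f"unknown ADP mode {self.mode!r}")
        if self.mode == "anisotropic":
            u = np.asarray(self.uaniso, dtype=float)
            if u.shape == (6,):  # U11 U22 U33 U12 U13 U23
                u = np.array(
                    [[u[0], u[3], u[4]], [u[3], u[1], u[5]], [u[4], u[5], u[2]]]
                )
            if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-12):
                raise ValueError("uaniso must be a symmetric 3x3 tensor")
            self.uaniso = u

    def u_cart(self, cell: UnitCell) -> np.ndarray:
        """Cartesianized displacement tensor (A^2)."""
        if self.mode == "isotropic":
            return np.eye(3) * self.uiso
        N = np.diag(cell.reciprocal_lengths())
        M = cell.orthogonalization_matrix()
        A = M @ N
        return A @ self.uaniso @ A.T

    def u_eq(self, cell: UnitCell) -> float:
        """Equivalent isotropic U = trace(U_cart)/3."""
        if self.mode == "isotropic":
            return self.uiso
        return float(np.trace(self.u_cart(cell)) / 3.0)

    def is_npd(self, cell: UnitCell) -> bool:
        """True iff any eigenvalue of the Cartesianized tensor is <= 0."""
        if self.mode == "isotropic":
            return self.uiso <= 0
        return bool(np.linalg.eigvalsh(self.u_cart(cell)).min() <= 0)

    def copy(self) -> "AdpSet":
        return AdpSet(self.mode, self.uiso,
                      None if self.uaniso is None else self.uaniso.copy())


@dataclass
class Atom:
    """One atom of the asymmetric unit (fractional coordinates)."""

    label: str
    element: int  # atomic number Z
    xyz: np.ndarray
    occupancy: float = 1.0
    adp: AdpSet = field(default_factory=AdpSet)
    type_key: str | None = None
    frame_spec: tuple | None = None  # (ref1_label, ref2_label, convention)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.element < 1:
            raise ValueError("atomic number must be >= 1")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def symbol(self) -> str:
        return Z_SYMBOL.get(self.element, gemmi.Element(self.element).name)

    def copy(self) -> "Atom":
        return Atom(self.label, self.element, self.xyz.copy(), self.occupancy,
                    self.adp.copy(), self.type_key, self.frame_spec)


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operators + asymmetric-unit atom list."""

    cell: UnitCell
    symops: list
    atoms: list

    def __post_init__(self):
        if not self.symops:
            self.symops = [IDENTITY]

    def atom(self, label: str) -> Atom:
        for at in self.atoms:
            if at.label == label:
                return at
        raise KeyError(f"no atom labelled {label!r}")

    def site_multiplicity(self, atom: Atom, tol: float = 1e-6) -> int:
        """Orbit size of the site under the operator set (special positions)."""
        images = []
        for op in self.symops:
            x = op.apply(atom.xyz) % 1.0
            if not any(np.allclose(x, y, atol=tol) or
                       np.allclose(np.abs(x - y), 1.0, atol=tol) for y in images):
                images.append(x)
        return len(images)

    def composition(self) -> dict:
        """Element -> count over the full unit cell (occupancy-weighted)."""
        comp: dict = {}
        for at in self.atoms:
            n = self.site_multiplicity(at) * at.occupancy
            comp[at.element] = comp.get(at.element, 0.0) + n
        return comp

    def electron_count(self) -> float:
        """Total electron count of the unit cell (neutral atoms)."""
        return sum(z * n for z, n in self.composition().items())

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(self.cell, list(self.symops),
                                [a.copy() for a in self.atoms])

    def expand_to_p1(self, tol: float = 1e-6) -> "CrystalStructure":
        """Full-cell structure with identity symmetry only."""
        atoms = []
        for at in self.atoms:
            seen = []
            for i, op in enumerate(self.symops):
                x = op.apply(at.xyz) % 1.0
                if any(np.allclose(x, y, atol=tol) for y in seen):
                    continue
                seen.append(x)
                img = at.copy()
                img.label = f"{at.label}_{i}"
                img.xyz = x
                if at.frame_spec is not None:
                    r1, r2, conv = at.frame_spec
                    img.frame_spec = (f"{r1}_{i}", f"{r2}_{i}", conv)
                if at.adp.mode == "anisotropic":
                    R = op.R
                    img.adp = AdpSet("anisotropic", uaniso=R @ at.adp.uaniso @ R.T)
                atoms.append(img)
        return CrystalStructure(self.cell, [IDENTITY], atoms)


# ---------------------------------------------------------------------------
# operations

def cell_volume_and_metrics(cell: UnitCell) -> dict:
    """Volume, direct/reciprocal metric tensors and the reciprocal cell."""
    G = cell.metric()
    Gstar = cell.reciprocal_metric()
    return {
        "volume": cell.volume,
        "G": G,
        "G_star": Gstar,
        "reciprocal_cell": cell.reciprocal_cell(),
    }


def resolution_of(hkl, cell: UnitCell) -> dict:
    """d-spacing and scattering variables of one reflection.

    Returns d (A), s = sin(theta)/lambda (A^-1) and |h| = 2s = 1/d.
    (0,0,0) maps to d = inf, s = 0.
    """
    h = np.asarray(hkl, dtype=float)
    inv_d2 = float(h @ cell.reciprocal_metric() @ h)
    if inv_d2 <= 0:
        return {"d": math.inf, "s": 0.0, "h_mag": 0.0}
    inv_d = math.sqrt(inv_d2)
    return {"d": 1.0 / inv_d, "s": inv_d / 2.0, "h_mag": inv_d}


def _orbit(hkl: tuple, rotations: list, friedel: bool) -> set:
    orb = set()
    h = np.array(hkl, dtype=int)
    for R in rotations:
        hp = tuple(int(v) for v in h @ R)  # row-vector action: h' = h R
        orb.add(hp)
        if friedel:
            orb.add(tuple(-v for v in hp))
    return orb


def generate_reflections(cell: UnitCell, symops, d_min: float, d_max: float = math.inf,
                         friedel: bool = True) -> list:
    """Unique reflections with d_min <= d <= d_max and their multiplicities.

    Symmetry-equivalent indices (rotation part of the operator set, plus the
    Friedel inverse by default) are merged; the representative is the
    lexicographically largest index of the orbit.  Returns a list of
    ``(hkl, multiplicity)`` with multiplicities summing to the unmerged count.
    """
    if not d_min < d_max:
        raise ValueError("d_min must be smaller than d_max")
    rotations = [op.R for op in (symops or [IDENTITY])]
    gs = cell.reciprocal_metric()
    # exact per-index bounds: |h_i| <= a_i / d_min  (Cauchy-Schwarz on G*)
    bounds = [int(math.floor(length / d_min + 1e-9)) + 1
              for length in (cell.a, cell.b, cell.c)]
    axes = [np.arange(-b, b + 1) for b in bounds]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inv_d2 = np.einsum("ij,jk,ik->i", H, gs, H)
    with np.errstate(divide="ignore"):
        d = 1.0 / np.sqrt(np.where(inv_d2 > 0, inv_d2, np.inf))
    H = H[(d >= d_min - 1e-9) & (d <= d_max + 1e-9)]
    if len(H) == 0:
        return []
    # canonical representative = lexicographic max over the rotation orbit
    images = [H @ R for R in rotations]
    if friedel:
        images += [-im for im in images]
    offset = max(bounds) + 2
    base = 2 * offset + 1

    def encode(A):
        return ((A[:, 0] + offset) * base + (A[:, 1] + offset)) * base + (A[:, 2] + offset)

    codes = np.stack([encode(im) for im in images])
    reps = codes.max(axis=0)
    uniq, counts = np.unique(reps, return_counts=True)
    out = []
    for code, mult in zip(uniq, counts):
        l = int(code % base) - offset
        k = int((code // base) % base) - offset
        h = int(code // (base * base)) - offset
        out.append(((h, k, l), int(mult)))
    return sorted(out, reverse=True)


def bond_lengths(structure: CrystalStructure, bond_list) -> list:
    """Distances (A) for labelled atom pairs, via the direct metric tensor."""
    G = structure.cell.metric()
    out = []
    for la, lb in bond_list:
        dx = structure.atom(la).xyz - structure.atom(lb).xyz
        out.append(float(math.sqrt(max(dx @ G @ dx, 0.0))))
    return out
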