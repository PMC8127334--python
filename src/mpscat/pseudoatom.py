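"""The Hansen-Coppens pseudoatom: core + kappa-scaled valence + multipoles.

A pseudoatom density is

    rho(r) = rho_core(r)
           + Pv kappa^3 rho_valence(kappa r)
           + sum_l kappa'^3 R_l(kappa' r) sum_mp P_lmp d_lmp(theta, phi)

with rho_core and rho_valence spherically averaged free-atom densities
normalized to one electron (stored as Slater-term sums scaled by the shell
electron count), R_l a normalized Slater-type radial function with
predefined n_l and zeta_l, and d_lmp density-normalized real spherical
harmonics evaluated in a local Cartesian frame on the nucleus.  The
populations Pv and P_lmp and the expansion-contraction parameters kappa and
kappa' are the transferable parameters of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .harmonics import L_MAX, d_lmp_cart
from .radial import slater_radial_value

__all__ = [
    "RadialDensitySpec",
    "SlaterRadial",
    "Pseudoatom",
    "ParameterBank",
    "build_local_frame",
    "pseudoatom_density",
    "read_bank",
    "write_bank",
    "iam_star",
]


@dataclass(frozen=True)
class RadialDensitySpec:
    """Spherical shell density as a sum of normalized Slater terms.

    Each term is (coefficient, n, zeta) contributing
    coefficient * N r^n exp(-zeta r) / (4 pi) to the density, so that
    4 pi * integral rho r^2 dr = sum of coefficients = electron count.
    """

    terms: tuple  # ((coef, n, zeta), ...)
    role: str = "core"  # "core" | "valence"

    @property
    def electrons(self) -> float:
        return sum(c for c, _, _ in self.terms)

    def density(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, n, z in self.terms:
            out = out + c * slater_radial_value(n, z, r)
        return out / (4.0 * np.pi)

    def form_factor(self, h_mag):
        """Spherical scattering factor (e) at |h| (A^-1)."""
        from .radial import fourier_bessel_slater

        h = np.asarray(h_mag, dtype=float)
        out = np.zeros_like(h, dtype=float)
        for c, n, z in self.terms:
            out = out + c * fourier_bessel_slater(0, n, z, h)
        return out

    def second_moment(self) -> float:
        """<r^2> weighted by electrons: 4 pi int rho r^4 dr (A^2 e)."""
        # int N r^(n+4) e^(-zr) dr = N (n+4)!/z^(n+5) = (n+4)(n+3)/z^2 per e
        return sum(c * (n + 4) * (n + 3) / (z * z) for c, n, z in self.terms)


@dataclass(frozen=True)
class SlaterRadial:
    """Deformation radial set: n_l and zeta per l (zeta in A^-1)."""

    n_l: tuple  # length L_MAX+1, entries for l = 0..4
    zeta: tuple  # per-l exponents, same length

    def __post_init__(self):
        if len(self.n_l) != len(self.zeta):
            raise ValueError("n_l and zeta must have equal length")
        for l, (n, z) in enumerate(zip(self.n_l, self.zeta)):
            if n < l:
                raise ValueError(f"n_l must be >= l (l={l}, n={n})")
            if z <= 0:
                raise ValueError("zeta must be positive")


@dataclass
class Pseudoatom:
    """One atom's multipole parameter set, with an optional local frame."""

    z: int  # atomic number
    core: RadialDensitySpec
    valence: RadialDensitySpec
    pv: float
    kappa: float = 1.0
    kappa_prime: tuple = (1.0,) * (L_MAX + 1)
    radials: SlaterRadial | None = None
    plmp: dict = field(default_factory=dict)  # (l, m, p) -> population
    frame: np.ndarray | None = None  # 3x3 orthonormal, rows = local axes? see below

    def __post_init__(self):
        if self.kappa <= 0 or any(k <= 0 for k in self.kappa_prime):
            raise ValueError("kappa and kappa' must be positive")
        for (l, m, p) in self.plmp:
            if not 0 <= l <= L_MAX or not 0 <= m <= l or p not in (1, -1):
                raise ValueError(f"invalid multipole index {(l, m, p)}")
        if self.plmp and self.radials is None:
            raise ValueError("multipole populations require a radial spec")
        if abs(self.valence.electrons - 1.0) > 1e-6:
            raise ValueError("valence density must be normalized to one electron")

    @property
    def charge(self) -> float:
        """Net pseudoatom charge Z - (core electrons + Pv)."""
        return self.z - (self.core.electrons + self.pv)

    @property
    def l_list(self):
        return sorted({l for (l, _, _) in self.plmp})

    def with_frame(self, frame: np.ndarray) -> "Pseudoatom":
        return replace(self, frame=np.asarray(frame, dtype=float))


def pseudoatom_density(pa: Pseudoatom, r_vec) -> np.ndarray:
    """Electron density (e A^-3) at Cartesian points r_vec, shape (..., 3).

    Points are in the global Cartesian frame centred on the nucleus; the
    multipole angular functions are evaluated in the pseudoatom's local
    frame (columns of ``pa.frame`` are the local axes in global
    coordinates).  With Pv = Z_valence, all P_lmp = 0 and kappa = kappa' = 1
    the density is the spherical free-atom (IAM*) density.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec, axis=-1)
    rho = pa.core.density(r) + pa.pv * pa.kappa**3 * pa.valence.density(pa.kappa * r)
    if pa.plmp:
        frame = np.eye(3) if pa.frame is None else pa.frame
        local = r_vec @ frame  # components along local axes
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(r[..., None] > 0, local / np.where(r[..., None] > 0, r[..., None], 1.0), 0.0)
        u = np.where(r[..., None] > 0, u, np.array([0.0, 0.0, 1.0]))
        for (l, m, p), pop in pa.plmp.items():
            if pop == 0.0:
                continue
            kp = pa.kappa_prime[l]
            n, z = pa.radials.n_l[l], pa.radials.zeta[l]
            radial = kp**3 * slater_radial_value(n, z, kp * r)
            rho = rho + pop * radial * d_lmp_cart(l, m, p, u)
    return rho


def build_local_frame(atom, structure, frame_spec=None) -> np.ndarray:
    """Right-handed orthonormal local axes for an atom's multipoles.

    ``frame_spec = (ref1, ref2, convention)`` with labels of two reference
    atoms; convention "ZX" (default and only supported): local Z along the
    bond atom->ref1, local X toward ref2 after Gram-Schmidt, Y = Z x X.
    Returns a 3x3 matrix whose *columns* are the local axes expressed in
    the global Cartesian frame (so global = frame @ local coordinates).
    """
    spec = frame_spec if frame_spec is not None else atom.frame_spec
    if spec is None:
        return np.eye(3)
    ref1, ref2, convention = spec
    if convention != "ZX":
        raise ValueError(f"unsupported frame convention {convention!r}")
    M = structure.cell.orthogonalization_matrix()

    def nearest_vec(label):
        # minimum-image Cartesian vector atom -> labelled neighbour
        dx = structure.atom(label).xyz - atom.xyz
        dx = dx - np.round(dx)
        return M @ dx

    v1 = nearest_vec(ref1)
    v2 = nearest_vec(ref2)
    n1 = np.linalg.norm(v1)
    if n1 < 1e-8:
        raise ValueError(f"reference atom {ref1!r} coincides with {atom.label!r}")
    ez = v1 / n1
    ex = v2 - (v2 @ ez) * ez
    nx = np.linalg.norm(ex)
    if nx < 1e-8:
        raise ValueError(
            f"degenerate local frame for {atom.label!r}: references are collinear")
    ex = ex / nx
    ey = np.cross(ez, ex)
    return np.column_stack([ex, ey, ez])


@dataclass
class ParameterBank:
    """type_key -> pseudoatom template (frame applied per structure atom)."""

    entries: dict
    metadata: str = ""

    def get(self, type_key: str) -> Pseudoatom:
        try:
            return self.entries[type_key]
        except KeyError:
            raise KeyError(f"pseudoatom bank has no entry for type {type_key!r}") from None

    def resolve(self, structure) -> dict:
        """label -> frame-dressed Pseudoatom for every atom of a structure."""
        out = {}
        for atom in structure.atoms:
            if atom.type_key is None:
                raise KeyError(f"atom {atom.label!r} has no pseudoatom type key")
            pa = self.get(atom.type_key)
            frame = build_local_frame(atom, structure)
            out[atom.label] = pa.with_frame(frame)
        return out


def iam_star(pa: Pseudoatom) -> Pseudoatom:
    """Spherical-neutral reference built inside the multipole machinery.

    All populations reset to the neutral spherical atom: Pv = Z - core
    electrons, every P_lmp = 0, kappa = kappa' = 1.
    """
    return replace(
        pa,
        pv=pa.z - pa.core.electrons,
        kappa=1.0,
        kappa_prime=(1.0,) * len(pa.kappa_prime),
        plmp={},
    )


# ---------------------------------------------------------------------------
# bank text format
#
# One block per atom type:
#
#   type <key> element <symbol>
#     core    <coef> <n> <zeta>   [repeatable line]
#     valence <coef> <n> <zeta>   [repeatable; coefs sum to 1]
#     Pv <float>
#     kappa <float>
#     kappa_prime <k0> <k1> <k2> <k3> <k4>
#     radial <n0> <n1> <n2> <n3> <n4> zeta <z0> <z1> <z2> <z3> <z4>
#     P <l> <m> <+|-> <population>  [repeatable]
#   end
#
# '#' starts a comment; zeta values are in A^-1.

def write_bank(bank: ParameterBank, path) -> None:
    from .cell import Z_SYMBOL

    lines = ["# mpscat pseudoatom parameter bank"]
    if bank.metadata:
        for ln in bank.metadata.splitlines():
            lines.append(f"# {ln}")
    for key, pa in bank.entries.items():
        lines.append(f"type {key} element {Z_SYMBOL.get(pa.z, pa.z)}")
        for c, n, z in pa.core.terms:
            lines.append(f"  core {c!r} {n} {z!r}")
        for c, n, z in pa.valence.terms:
            lines.append(f"  valence {c!r} {n} {z!r}")
        lines.append(f"  Pv {pa.pv!r}")
        lines.append(f"  kappa {pa.kappa!r}")
        lines.append("  kappa_prime " + " ".join(repr(k) for k in pa.kappa_prime))
        if pa.radials is not None:
            lines.append("  radial " + " ".join(str(n) for n in pa.radials.n_l)
                         + " zeta " + " ".join(repr(z) for z in pa.radials.zeta))
        for (l, m, p), pop in sorted(pa.plmp.items()):
            lines.append(f"  P {l} {m} {'+' if p > 0 else '-'} {pop!r}")
        lines.append("end")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_bank(path) -> ParameterBank:
    from .cell import ELEMENT_Z

    entries: dict = {}
    meta_lines = []
    cur_key = None
    cur: dict = {}

    def finish():
        nonlocal cur_key, cur
        if cur_key is None:
            return
        radials = None
        if "radial_n" in cur:
            radials = SlaterRadial(tuple(cur["radial_n"]), tuple(cur["radial_z"]))
        entries[cur_key] = Pseudoatom(
            z=cur["z"],
            core=RadialDensitySpec(tuple(cur.get("core", ())), "core"),
            valence=RadialDensitySpec(tuple(cur.get("valence", ())), "valence"),
            pv=cur["pv"],
            kappa=cur.get("kappa", 1.0),
            kappa_prime=tuple(cur.get("kappa_prime", (1.0,) * (L_MAX + 1))),
            radials=radials,
            plmp=cur.get("plmp", {}),
        )
        cur_key, cur = None, {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                if raw.lstrip().startswith("#"):
                    meta_lines.append(raw.lstrip("# \t").rstrip())
                continue
            tok = line.split()
            try:
                if tok[0] == "type":
                    finish()
                    cur_key = tok[1]
                    cur = {"z": ELEMENT_Z[tok[3]] if not tok[3].isdigit() else int(tok[3]),
                           "plmp": {}}
                elif tok[0] in ("core", "valence"):
                    cur.setdefault(tok[0], []).append(
                        (float(tok[1]), int(tok[2]), float(tok[3])))
                elif tok[0] == "Pv":
                    cur["pv"] = float(tok[1])
                elif tok[0] == "kappa":
                    cur["kappa"] = float(tok[1])
                elif tok[0] == "kappa_prime":
                    cur["kappa_prime"] = [float(v) for v in tok[1:]]
                elif tok[0] == "radial":
                    i = tok.index("zeta")
                    cur["radial_n"] = [int(v) for v in tok[1:i]]
                    cur["radial_z"] = [float(v) for v in tok[i + 1:]]
                elif tok[0] == "P":
                    l, m = int(tok[1]), int(tok[2])
                    p = +1 if tok[3] == "+" else -1
                    cur["plmp"][(l, m, p)] = float(tok[4])
                elif tok[0] == "end":
                    finish()
                else:
                    raise ValueError(f"unknown directive {tok[0]!r}")
            except (IndexError, KeyError, ValueError) as exc:
                raise ValueError(f"bank parse error at line {lineno}: {exc}") from None
    finish()
    return ParameterBank(entries, metadata="\n".join(meta_lines))
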