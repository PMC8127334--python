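"""Readers and writers: CIF-subset structures, SHELX HKLF4 reflections.

The structure format is a small CIF dialect (parsed with gemmi's CIF
tokenizer): cell parameters, explicit symmetry-operator triplets, an
atom_site loop with fractional coordinates and U_iso, an optional aniso
loop with the six U^ij components, plus custom ``_mpscat_*`` tags for the
pseudoatom type key and the local-frame references that a multipole model
needs and plain CIF has no home for.

Reflections use the fixed-column HKLF4 convention (3I4, 2F8.2): h k l
Fo^2 sigma, terminated by a 0 0 0 record.  Negative Fo^2 are preserved.
"""

from __future__ import annotations

import warnings

import gemmi.cif
import numpy as np

from .cell import AdpSet, Atom, CrystalStructure, ELEMENT_Z, UnitCell, parse_symop

__all__ = ["read_structure", "write_structure", "read_hkl", "write_hkl",
           "HklRecord", "RunConfig"]

_UIJ_ORDER = ("11", "22", "33", "12", "13", "23")


class StructureParseError(ValueError):
    pass


class HklParseError(ValueError):
    pass


def write_structure(structure: CrystalStructure, path, name: str = "mpscat") -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(name)
    cell = structure.cell
    for tag, val in (("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
                     ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
                     ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma)):
        block.set_pair(tag, f"{val:.6f}")
    loop = block.init_loop("_symmetry_equiv_pos_", ["as_xyz"])
    for op in structure.symops:
        loop.add_row([gemmi.cif.quote(op.triplet())])
    tags = ["label", "type_symbol", "fract_x", "fract_y", "fract_z",
            "occupancy", "U_iso_or_equiv", "adp_type"]
    loop = block.init_loop("_atom_site_", tags)
    for at in structure.atoms:
        loop.add_row([
            at.label, at.symbol,
            f"{at.xyz[0]:.6f}", f"{at.xyz[1]:.6f}", f"{at.xyz[2]:.6f}",
            f"{at.occupancy:.4f}", f"{at.adp.u_eq(cell):.6f}",
            "Uani" if at.adp.mode == "anisotropic" else "Uiso"])
    aniso = [at for at in structure.atoms if at.adp.mode == "anisotropic"]
    if aniso:
        loop = block.init_loop("_atom_site_aniso_",
                               ["label"] + [f"U_{ij}" for ij in _UIJ_ORDER])
        for at in aniso:
            u = at.adp.uaniso
            vals = [u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2]]
            loop.add_row([at.label] + [f"{v:.6f}" for v in vals])
    extra = [at for at in structure.atoms if at.type_key or at.frame_spec]
    if extra:
        loop = block.init_loop("_mpscat_atom_site_",
                               ["label", "type_key", "frame_ref1",
                                "frame_ref2", "frame_convention"])
        for at in extra:
            ref1, ref2, conv = at.frame_spec if at.frame_spec else (".", ".", ".")
            loop.add_row([at.label, at.type_key or ".", ref1, ref2, conv])
    doc.write_file(str(path))


def _require(block, tag):
    val = block.find_value(tag)
    if val is None:
        raise StructureParseError(f"missing mandatory tag {tag}")
    return val


def read_structure(path) -> CrystalStructure:
    try:
        doc = gemmi.cif.read_file(str(path))
    except Exception as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from None
    block = doc.sole_block()
    cell = UnitCell(*(float(_require(block, f"_cell_length_{x}")) for x in "abc"),
                    *(float(_require(block, f"_cell_angle_{x}"))
                      for x in ("alpha", "beta", "gamma")))
    symops = []
    for row in block.find_loop("_symmetry_equiv_pos_as_xyz"):
        triplet = gemmi.cif.as_string(row)
        try:
            symops.append(parse_symop(triplet))
        except ValueError as exc:
            raise StructureParseError(str(exc)) from None
    if not symops:
        raise StructureParseError("missing mandatory tag _symmetry_equiv_pos_as_xyz")

    table = block.find("_atom_site_", ["label", "type_symbol", "fract_x",
                                       "fract_y", "fract_z", "occupancy",
                                       "U_iso_or_equiv", "adp_type"])
    if len(table) == 0:
        raise StructureParseError("missing mandatory _atom_site_ loop")
    aniso = {}
    atable = block.find("_atom_site_aniso_",
                        ["label"] + [f"U_{ij}" for ij in _UIJ_ORDER])
    for row in atable:
        u = [float(row[i + 1]) for i in range(6)]
        aniso[row.str(0)] = np.array([[u[0], u[3], u[4]],
                                      [u[3], u[1], u[5]],
                                      [u[4], u[5], u[2]]])
    extras = {}
    etable = block.find("_mpscat_atom_site_",
                        ["label", "type_key", "frame_ref1", "frame_ref2",
                         "frame_convention"])
    for row in etable:
        key = None if row.str(1) in (".", "?") else row.str(1)
        frame = None
        if row.str(2) not in (".", "?"):
            frame = (row.str(2), row.str(3), row.str(4))
        extras[row.str(0)] = (key, frame)

    atoms = []
    for row in table:
        label = row.str(0)
        sym = row.str(1)
        if sym not in ELEMENT_Z:
            z = gemmi.Element(sym).atomic_number
            if z == 0:
                raise StructureParseError(f"unknown element {sym!r} for atom {label!r}")
        else:
            z = ELEMENT_Z[sym]
        xyz = [float(row[i]) for i in (2, 3, 4)]
        occ = float(row[5])
        uiso = float(row[6])
        if label in aniso:
            adp = AdpSet("anisotropic", uaniso=aniso[label])
        else:
            adp = AdpSet("isotropic", uiso=uiso)
        key, frame = extras.get(label, (None, None))
        atoms.append(Atom(label, z, np.array(xyz), occ, adp, key, frame))
    return CrystalStructure(cell, symops, atoms)


# ---------------------------------------------------------------------------
# HKLF4

class HklRecord(tuple):
    """(h, k, l, fo2, sigma) with named access."""

    def __new__(cls, h, k, l, fo2, sigma):
        return super().__new__(cls, (int(h), int(k), int(l), float(fo2), float(sigma)))

    h = property(lambda s: s[0])
    k = property(lambda s: s[1])
    l = property(lambda s: s[2])
    fo2 = property(lambda s: s[3])
    sigma = property(lambda s: s[4])


def write_hkl(records, path) -> None:
    """Write HKLF4 fixed columns (3I4, 2F8.2) with a 0 0 0 terminator.

    ``records`` is an iterable of (h, k, l, fo2, sigma) or an object with
    ``hkl``, ``fo2`` and ``sigma`` arrays.
    """
    if hasattr(records, "hkl"):
        records = [(h, k, l, f, s) for (h, k, l), f, s in
                   zip(records.hkl, records.fo2, records.sigma)]
    with open(path, "w") as fh:
        for h, k, l, fo2, sigma in records:
            fh.write(f"{h:4d}{k:4d}{l:4d}{fo2:8.2f}{sigma:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hkl(path) -> list:
    """Read HKLF4 records; stops at the 0 0 0 terminator.

    Records after the terminator are ignored with a warning.  Column
    misalignment raises :class:`HklParseError` with the line number.
    """
    out = []
    terminated = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if terminated:
                warnings.warn(f"ignoring record after terminator at line {lineno}")
                break
            try:
                h = int(line[0:4])
                k = int(line[4:8])
                l = int(line[8:12])
                fo2 = float(line[12:20])
                sigma = float(line[20:28])
            except (ValueError, IndexError):
                raise HklParseError(
                    f"misaligned HKLF4 record at line {lineno}: {line.rstrip()!r}"
                ) from None
            if h == k == l == 0:
                terminated = True
                continue
            out.append(HklRecord(h, k, l, fo2, sigma))
    return out


# ---------------------------------------------------------------------------
# run configuration

class RunConfig(dict):
    """YAML-serializable run configuration (archived beside outputs).

    Keys: structure, hkl, bank, output, seed, verbosity, and a nested
    ``refine`` mapping (option, radiation, model, dmin, weights, restraints).
    """

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls(data)

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)
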