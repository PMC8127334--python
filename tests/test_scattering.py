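"""Form factors, Mott-Bethe conversion and structure-factor assembly."""

import numpy as np
import pytest

from mpscat.cell import Atom, AdpSet, CrystalStructure, UnitCell, generate_reflections, parse_symop
from mpscat.constants import C_MB
from mpscat.pseudoatom import Pseudoatom, RadialDensitySpec, SlaterRadial, iam_star, pseudoatom_density
from mpscat.scattering import (StructureFactorSet, calc_structure_factors,
                               compare_sf_sets, f000, f_x_multipole,
                               mean_inner_potential, mott_bethe)
from mpscat.tables import f_e_iam, f_x_iam, xray_coefficients


class TestIamTables:
    @pytest.mark.parametrize("el,z", [("H", 1), ("C", 6), ("N", 7), ("O", 8)])
    def test_forward_value_is_z(self, el, z):
        assert f_x_iam(el, 0.0) == pytest.approx(z, abs=0.01)

    def test_monotone_decrease(self):
        s = np.linspace(0, 1.5, 200)
        for el in ("H", "C", "N", "O"):
            f = f_x_iam(el, s)
            assert np.all(np.diff(f) < 0)

    def test_oxygen_coefficient_sum(self):
        co = xray_coefficients("O")
        s = 0.5
        expected = sum(a * np.exp(-b * s * s) for a, b in zip(co["a"], co["b"])) + co["c"]
        assert f_x_iam("O", s) == pytest.approx(expected, rel=1e-14)

    def test_electron_table_positive(self):
        s = np.linspace(0.01, 2.0, 100)
        for el in ("H", "C", "N", "O"):
            assert np.all(f_e_iam(el, s) > 0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            f_x_iam("Xx", 0.1)


def aspherical_pa(frame=None):
    return Pseudoatom(
        z=8,
        core=RadialDensitySpec(((2.0, 1, 22.0),), "core"),
        valence=RadialDensitySpec(((1.0, 2, 7.5),), "valence"),
        pv=6.2, kappa=0.97, kappa_prime=(1.0, 1.05, 0.9, 1.0, 1.1),
        radials=SlaterRadial((1, 2, 2, 3, 4), (8.0, 8.0, 8.0, 9.0, 10.0)),
        plmp={(1, 0, 1): 0.12, (1, 1, -1): -0.05, (2, 0, 1): -0.09,
              (2, 2, 1): 0.04, (3, 2, -1): 0.03, (4, 0, 1): 0.02,
              (0, 0, 1): 0.05},
        frame=frame)


class TestMultipoleFormFactor:
    def test_spherical_is_real(self, rng):
        pa = iam_star(aspherical_pa())
        h = rng.normal(size=(100, 3))
        f = f_x_multipole(pa, h)
        assert np.abs(f.imag).max() == 0.0

    def test_zero_frequency_is_electron_count(self):
        # l >= 1 terms vanish at h = 0; the deformation monopole (P_00) survives
        pa = aspherical_pa(frame=np.eye(3))
        f0 = f_x_multipole(pa, [0.0, 0.0, 0.0])
        expected = pa.core.electrons + pa.pv + pa.plmp[(0, 0, 1)]
        assert f0 == pytest.approx(expected, rel=1e-12)

    def test_brute_force_fourier_oracle(self, rng):
        """Closed-form aspherical f equals 3D numerical Fourier integration."""
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Q *= np.sign(np.linalg.det(Q))
        pa = aspherical_pa(frame=Q)
        nr, nth, nph = 160, 48, 96
        xs, wr = np.polynomial.legendre.leggauss(nr)
        rmax = 6.0
        r = 0.5 * rmax * (xs + 1)
        wr = wr * 0.5 * rmax
        ct, wt = np.polynomial.legendre.leggauss(nth)
        th = np.arccos(ct)
        ph = (np.arange(nph) + 0.5) * 2 * np.pi / nph
        R, T, P = np.meshgrid(r, th, ph, indexing="ij")
        pts = np.stack([R * np.sin(T) * np.cos(P),
                        R * np.sin(T) * np.sin(P), R * np.cos(T)], axis=-1)
        rho = pseudoatom_density(pa, pts)
        w3 = (wr[:, None, None] * R**2) * wt[None, :, None] * (2 * np.pi / nph)
        hs = rng.normal(size=(20, 3)) * 0.5
        for h in hs:
            phase = np.exp(2j * np.pi * (pts @ h))
            oracle = (rho * w3 * phase).sum()
            assert abs(f_x_multipole(pa, h) - oracle) < 1e-4


class TestMottBethe:
    def test_full_screening_gives_zero(self):
        assert mott_bethe(6.0, 6.0, 0.7) == 0.0

    def test_s_zero_rejected(self):
        with pytest.raises(ValueError):
            mott_bethe(6.0, 5.0, 0.0)

    @pytest.mark.parametrize("el,z", [("H", 1), ("C", 6), ("N", 7), ("O", 8)])
    def test_cross_table_agreement(self, el, z):
        """Mott-Bethe from the X-ray table matches the electron table to 3%."""
        s = np.linspace(0.2, 1.5, 53)
        fe_mb = mott_bethe(z, f_x_iam(el, s), s)
        fe_tab = f_e_iam(el, s)
        assert np.abs(fe_mb / fe_tab - 1).max() < 0.03

    def test_ion_low_angle_divergence(self):
        """A net charge q makes f_e ~ C_MB q / s^2 as s -> 0."""
        q = -1.0  # O(-1)-like: one extra electron beyond Z at s=0
        for s in (1e-2, 1e-3):
            f_x_ion = f_x_iam("O", s) - q  # shift forward value by -q
            fe = mott_bethe(8.0, f_x_ion, s)
            assert fe * s * s / (C_MB * q) == pytest.approx(1.0, abs=0.02)


class TestStructureFactors:
    def test_single_atom_amplitude_is_form_factor(self, rng):
        st_ = CrystalStructure(UnitCell(8, 8, 8), [], [Atom("C", 6, [0, 0, 0])])
        hkl = rng.integers(-6, 7, size=(30, 3))
        hkl = hkl[(hkl != 0).any(axis=1)]
        for rad in ("xray", "electron"):
            sf = calc_structure_factors(st_, "iam", hkl, rad, "static")
            gs = st_.cell.reciprocal_metric()
            s = np.sqrt(np.einsum("ij,jk,ik->i", hkl, gs, hkl)) / 2
            f_at = f_x_iam("C", s) if rad == "xray" else f_e_iam("C", s)
            assert np.allclose(sf.amplitudes, np.abs(f_at), rtol=1e-10)

    def test_centrosymmetric_phases(self, toy):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        sf = calc_structure_factors(structure, "taam", hkl, "xray", "dynamic", bank=bank)
        assert np.abs(sf.f.imag).max() < 1e-10 * np.abs(sf.f).max()

    def test_asu_equals_p1_expansion(self, toy):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        p1 = structure.expand_to_p1()
        for rad in ("xray", "electron"):
            for kind in ("static", "dynamic"):
                for model in ("taam", "iam*"):
                    a = calc_structure_factors(structure, model, hkl, rad, kind, bank=bank)
                    b = calc_structure_factors(p1, model, hkl, rad, kind, bank=bank)
                    assert np.abs(a.f - b.f).max() < 1e-10 * np.abs(a.f).max()

    def test_eq9_equals_eq10(self, toy):
        """Per-atom Mott-Bethe assembly equals the structure-factor-level route."""
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 0.83, 8.5)
        hkl = np.array([h for h, _ in refl])
        for kind in ("static", "dynamic"):
            a = calc_structure_factors(structure, "taam", hkl, "electron", kind, bank=bank)
            b = calc_structure_factors(structure, "taam", hkl, "electron", kind,
                                       bank=bank, eq10=True)
            assert np.abs(a.f - b.f).max() < 1e-10 * np.abs(a.f).max()

    def test_friedel_conjugate(self, toy):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        a = calc_structure_factors(structure, "taam", hkl, "electron", "dynamic", bank=bank)
        b = calc_structure_factors(structure, "taam", -hkl, "electron", "dynamic", bank=bank)
        assert np.allclose(b.f, np.conj(a.f), rtol=1e-10, atol=1e-12)

    def test_dynamic_damps_single_atom(self, rng):
        adp = AdpSet("anisotropic", uaniso=np.diag([0.02, 0.03, 0.04]))
        st_ = CrystalStructure(UnitCell(8, 9, 10), [],
                               [Atom("O", 8, [0.1, 0.2, 0.3], adp=adp)])
        hkl = rng.integers(-6, 7, size=(50, 3))
        hkl = hkl[(hkl != 0).any(axis=1)]
        stat = calc_structure_factors(st_, "iam", hkl, "xray", "static")
        dyn = calc_structure_factors(st_, "iam", hkl, "xray", "dynamic")
        assert np.all(dyn.amplitudes <= stat.amplitudes + 1e-12)

    def test_low_resolution_signature(self, toy):
        """IAM amplitudes too large (electron) / too small (X-ray) at low resolution."""
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 0.83, 8.5)
        hkl = np.array([h for h, _ in refl])
        for rad, expect_iam_large in (("electron", True), ("xray", False)):
            truth = calc_structure_factors(structure, "taam", hkl, rad, "dynamic", bank=bank)
            iam = calc_structure_factors(structure, "iam*", hkl, rad, "dynamic", bank=bank)
            ratio = compare_sf_sets(truth, iam, n_bins=10)["bins"][0]["sum_f2_ratio"]
            assert (ratio < 1.0) == expect_iam_large


class TestF000:
    def test_carbamazepine_unit_cell_electron_count(self, rng):
        """C15H12N2O asymmetric unit, Z = 4 -> F_x(000) = 496 e."""
        cell = UnitCell(7.0, 11.0, 14.0, 90, 93, 90)
        symops = [parse_symop(t) for t in ("x, y, z", "-x+1/2, y+1/2, -z+1/2",
                                           "-x, -y, -z", "x+1/2, -y+1/2, z+1/2")]
        atoms = []
        for el, z, n in (("C", 6, 15), ("H", 1, 12), ("N", 7, 2), ("O", 8, 1)):
            for i in range(n):
                atoms.append(Atom(f"{el}{i}", z, rng.uniform(0.02, 0.98, 3)))
        st_ = CrystalStructure(cell, symops, atoms)
        assert f000(st_, "xray") == pytest.approx(496.0)

    def test_empty_structure(self):
        st_ = CrystalStructure(UnitCell(10, 10, 10), [], [])
        assert f000(st_, "xray") == 0.0

    def test_electron_limit_matches_gaussian_analytic(self):
        """Richardson s->0 limit equals C_MB * sum(a_i b_i) for one C atom."""
        import gemmi
        st_ = CrystalStructure(UnitCell(8, 8, 8), [], [Atom("C", 6, [0, 0, 0])])
        it = gemmi.Element("C").it92
        analytic = C_MB * sum(a * b for a, b in zip(it.a, it.b))
        assert f000(st_, "electron") == pytest.approx(analytic, rel=1e-4)

    def test_charged_cell_rejected(self, toy):
        structure, bank = toy
        import dataclasses
        charged = dataclasses.replace(bank.entries["O_carbonyl"], pv=7.45)
        bank2 = type(bank)({**bank.entries, "O_carbonyl": charged}, "")
        with pytest.raises(ValueError, match="charge"):
            f000(structure, "electron", "taam", bank2)


class TestMeanInnerPotential:
    def test_trivials(self):
        assert mean_inner_potential(0.0, 500.0) == 0.0
        v1 = mean_inner_potential(100.0, 500.0)
        assert mean_inner_potential(100.0, 1000.0) == pytest.approx(v1 / 2)


class TestCompareSfSets:
    def _sets(self, cell, hkl, f):
        return StructureFactorSet(hkl, f, "xray", "dynamic", cell)

    def test_identical(self, toy):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        sf = calc_structure_factors(structure, "iam*", hkl, "xray", "dynamic", bank=bank)
        out = compare_sf_sets(sf, sf)
        assert out["r1"] == 0.0
        assert all(b["sum_f2_ratio"] == pytest.approx(1.0) for b in out["bins"])

    def test_uniform_scaling_algebra(self, toy):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        ref = calc_structure_factors(structure, "iam*", hkl, "xray", "dynamic", bank=bank)
        model = self._sets(structure.cell, hkl, 1.1 * ref.f)
        # R1 = sum|1.1F - F| / sum|F_ref| = 0.1 with the reference in the denominator
        out = compare_sf_sets(ref, model)
        assert out["r1"] == pytest.approx(0.1, rel=1e-10)
        for b in out["bins"]:
            assert b["sum_f2_ratio"] == pytest.approx(1 / 1.21, rel=1e-10)

    def test_random_perturbation_formula_oracle(self, toy, rng):
        structure, bank = toy
        refl = generate_reflections(structure.cell, structure.symops, 1.0, 8.5)
        hkl = np.array([h for h, _ in refl])
        ref = calc_structure_factors(structure, "iam*", hkl, "xray", "dynamic", bank=bank)
        pert = self._sets(structure.cell, hkl,
                          ref.f * (1 + 0.05 * rng.normal(size=len(hkl))))
        out = compare_sf_sets(ref, pert)
        oracle = np.sum(np.abs(np.abs(ref.f) - np.abs(pert.f))) / np.sum(np.abs(ref.f))
        assert out["r1"] == pytest.approx(oracle, rel=1e-12)

    def test_mismatched_indices_rejected(self, toy):
        structure, bank = toy
        hkl = np.array([[1, 0, 0], [0, 1, 0]])
        sf = calc_structure_factors(structure, "iam*", hkl, "xray", "dynamic", bank=bank)
        other = self._sets(structure.cell, hkl[::-1], sf.f)
        with pytest.raises(ValueError):
            compare_sf_sets(sf, other)
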