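"""Weighting scheme, parameterization, gradients and Gauss-Newton refinement."""

import numpy as np
import pytest

from mpscat.bench import (DatasetSpec, constraint_consistent_truth,
                          generate_dataset, perturb_structure)
from mpscat.cell import AdpSet
from mpscat.refine import (RefinementSpec, _sf_and_derivs,
                           auto_weights, build_parameters, fit_statistics,
                           place_riding_hydrogens, refine, weight_of)
from mpscat.scattering import form_factor_provider


class TestWeighting:
    def test_statistical_limit(self):
        assert weight_of(100.0, 2.0, 90.0) == pytest.approx(1 / 4.0)

    def test_negative_fo2_hand_evaluation(self):
        # P = (1/3)max(0,-3) + (2/3)9 = 6; w = 1/(sigma^2 + (0.1*6)^2)
        w = weight_of(-3.0, 1.5, 9.0, a=0.1, b=0.0)
        assert w == pytest.approx(1 / (1.5**2 + 0.36))

    def test_monotone_in_a_b(self):
        base = weight_of(50.0, 1.0, 45.0, a=0.05, b=0.1)
        assert weight_of(50.0, 1.0, 45.0, a=0.10, b=0.1) < base
        assert weight_of(50.0, 1.0, 45.0, a=0.05, b=0.5) < base

    def test_negative_denominator_rejected(self):
        with pytest.raises(ValueError):
            weight_of(100.0, 0.1, 90.0, a=0.0, b=-1.0)


class TestAutoWeights:
    def _simulate(self, rng, noise="known"):
        fc2 = rng.uniform(1.0, 400.0, 2000)
        sigma = np.full_like(fc2, 2.0)
        if noise == "known":
            fo2 = fc2 + rng.normal(0, 2.0, fc2.shape)
        else:  # extra amplitude-proportional error
            fo2 = fc2 * (1 + rng.normal(0, 0.08, fc2.shape)) + rng.normal(0, 2.0, fc2.shape)
        return fo2, sigma, fc2

    def test_correct_sigmas_give_small_a(self, rng):
        fo2, sigma, fc2 = self._simulate(rng, "known")
        a, b = auto_weights(fo2, sigma, fc2)
        assert abs(a) < 0.02

    def test_proportional_noise_gives_positive_a(self, rng):
        fo2, sigma, fc2 = self._simulate(rng, "proportional")
        a, b = auto_weights(fo2, sigma, fc2)
        assert a > 0.02

    def test_objective_not_worse_than_start(self, rng):
        from mpscat.refine import _binned_gof
        fo2, sigma, fc2 = self._simulate(rng, "proportional")
        a, b = auto_weights(fo2, sigma, fc2)
        assert _binned_gof(fo2, sigma, fc2, 1.0, a, b).var() <= \
            _binned_gof(fo2, sigma, fc2, 1.0, 0.0, 0.0).var()

    def test_degenerate_fallback(self):
        fo2 = np.full(200, 10.0)
        assert auto_weights(fo2, np.ones(200), np.full(200, 10.0)) == (0.0, 0.0)


class TestBuildParameters:
    def test_option_counts(self, toy):
        structure, bank = toy  # 3 non-H + 3 H atoms
        counts = {}
        for opt in (1, 2, 3, 4):
            spec = RefinementSpec(option=opt, radiation="xray", model="iam")
            counts[opt] = build_parameters(structure, spec).n
        # option 1: scale + 3*(xyz + Uiso) = 1 + 12
        assert counts[1] == 13
        # option 2 upgrades non-H Uiso -> 6 Uij components: + 3*5
        assert counts[2] == counts[1] + 15
        # option 3 frees H xyz + Uiso: + 3*4
        assert counts[3] == counts[2] + 12
        # option 4 upgrades H to Uij: + 3*5
        assert counts[4] == counts[3] + 15

    def test_electron_frees_h_positions_with_restraints(self, toy):
        structure, _ = toy
        spec = RefinementSpec(option=1, radiation="electron", model="iam")
        pmap = build_parameters(structure, spec)
        assert pmap.n == 13 + 9  # H xyz free
        assert len(pmap.restraints) == 3
        targets = sorted(r.target for r in pmap.restraints)
        assert targets == [1.01, 1.01, 1.083]
        assert all(r.esd == 0.02 for r in pmap.restraints)

    def test_riding_regeneration_matches_construction(self, toy):
        """Moving the parent and re-placing H reproduces ideal geometry."""
        from mpscat.cell import bond_lengths
        from mpscat.refine import ELECTRON_XH, hydrogen_parents
        structure, _ = toy
        st_ = structure.copy()
        st_.atom("N1").xyz = st_.atom("N1").xyz + np.array([0.01, -0.005, 0.008])
        place_riding_hydrogens(st_, ELECTRON_XH)
        # distances restored exactly at the ideal values
        for h, p in hydrogen_parents(st_).items():
            d = bond_lengths(st_, [(h, p)])[0]
            assert d == pytest.approx(ELECTRON_XH[st_.atom(p).element], abs=1e-10)
        # the toy geometry is ideal-trigonal: with matching distances the
        # regenerated H positions coincide with the original construction
        st2 = structure.copy()
        place_riding_hydrogens(st2, ELECTRON_XH)
        for lab in ("H1", "H2", "H3"):
            assert np.allclose(st2.atom(lab).xyz, structure.atom(lab).xyz, atol=1e-10)


class TestAnalyticGradients:
    def test_match_central_differences(self, toy):
        structure, bank = toy
        st_ = structure.copy()
        hkl = np.array([[1, 2, 3], [2, -1, 4], [0, 3, -2], [5, 1, 1]])
        provider = form_factor_provider("taam", "electron", st_, bank)
        need = {(0, "x", 1), (2, "x", 0), (1, "uij", 0), (1, "uij", 3),
                (3, "uiso",)}
        need = {(0, "x", 1), (2, "x", 0), (1, "uij", 0), (1, "uij", 3)}
        F0, derivs = _sf_and_derivs(st_, provider, hkl, "dynamic", need)
        eps = 1e-6
        from mpscat.refine import _add_param
        for key in need:
            plus = st_.copy()
            _add_param(plus, key, eps)
            minus = st_.copy()
            _add_param(minus, key, -eps)
            Fp, _ = _sf_and_derivs(plus, provider, hkl, "dynamic", set())
            Fm, _ = _sf_and_derivs(minus, provider, hkl, "dynamic", set())
            fd = (Fp - Fm) / (2 * eps)
            scale = np.abs(fd).max() + 1e-30
            assert np.abs(derivs[key] - fd).max() / scale < 1e-6, key

    def test_uiso_gradient(self, toy):
        structure, bank = toy
        st_ = structure.copy()
        for at in st_.atoms:
            at.adp = AdpSet("isotropic", uiso=at.adp.u_eq(st_.cell))
        hkl = np.array([[1, 2, 3], [2, -1, 4]])
        provider = form_factor_provider("iam*", "xray", st_, bank)
        key = (2, "uiso")
        F0, derivs = _sf_and_derivs(st_, provider, hkl, "dynamic", {key})
        eps = 1e-7
        from mpscat.refine import _add_param
        plus = st_.copy(); _add_param(plus, key, eps)
        minus = st_.copy(); _add_param(minus, key, -eps)
        Fp, _ = _sf_and_derivs(plus, provider, hkl, "dynamic", set())
        Fm, _ = _sf_and_derivs(minus, provider, hkl, "dynamic", set())
        fd = (Fp - Fm) / (2 * eps)
        assert np.abs(derivs[key] - fd).max() / np.abs(fd).max() < 1e-6


class TestFitStatistics:
    def test_perfect_model(self):
        out = fit_statistics([100.0, 25.0], [1, 1], [100.0, 25.0], 1.0, [1, 1], 1)
        assert out["r1"] == 0.0 and out["wr2"] == 0.0

    def test_single_reflection_arithmetic(self):
        out = fit_statistics([100.0, 100.0], [1, 1], [81.0, 100.0], 1.0, [1, 1], 1)
        # R1 = (|10-9| + 0) / 20
        assert out["r1"] == pytest.approx(0.05)

    def test_gof_near_unity_for_true_weights(self, rng):
        n = 2000
        fc2 = rng.uniform(10, 500, n)
        sigma = np.full(n, 3.0)
        fo2 = fc2 + rng.normal(0, 3.0, n)
        w = 1 / sigma**2
        out = fit_statistics(fo2, sigma, fc2, 1.0, w, 10)
        assert out["gof"] == pytest.approx(1.0, abs=0.1)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            fit_statistics([1.0], [1.0], [1.0], 1.0, [1.0], 5)


class TestRefine:
    def test_fixed_point_zero_shifts(self, toy):
        structure, bank = toy
        truth = constraint_consistent_truth(structure)
        data = generate_dataset(truth, bank, DatasetSpec(radiation="electron", d_min=1.0))
        spec = RefinementSpec(option=2, radiation="electron", model="taam", bank=bank)
        res = refine(truth, (data.hkl, data.fo2, data.sigma), spec)
        assert res.r1 < 1e-12
        assert res.converged
        assert max(abs(v) for v in res.shifts.values()) < 1e-10

    def test_parameter_recovery(self, toy):
        """Perturbed start, noiseless aspherical data, option 2."""
        structure, bank = toy
        truth = constraint_consistent_truth(structure)
        data = generate_dataset(truth, bank, DatasetSpec(radiation="electron", d_min=0.83))
        start = perturb_structure(truth, seed=7)
        spec = RefinementSpec(option=2, radiation="electron", model="taam", bank=bank)
        res = refine(start, (data.hkl, data.fo2, data.sigma), spec)
        assert res.converged and res.r1 < 1e-6
        for at in res.structure.atoms:
            ref = truth.atom(at.label)
            if at.element > 1:
                assert np.abs(at.xyz - ref.xyz).max() < 1e-4
                assert (np.abs(at.adp.uaniso - ref.adp.uaniso).max()
                        < 0.01 * np.abs(ref.adp.uaniso).max())

    def test_origin_shift_equivariance(self, toy_p1):
        """In P1 a uniform origin shift leaves R1 unchanged, coordinates shifted."""
        structure, bank = toy_p1
        truth = constraint_consistent_truth(structure)
        data = generate_dataset(truth, bank, DatasetSpec(radiation="electron", d_min=1.0))
        spec = RefinementSpec(option=2, radiation="electron", model="taam", bank=bank)
        res1 = refine(truth, (data.hkl, data.fo2, data.sigma), spec)
        shifted = truth.copy()
        delta = np.array([0.11, -0.07, 0.05])
        for at in shifted.atoms:
            at.xyz = at.xyz + delta
        res2 = refine(shifted, (data.hkl, data.fo2, data.sigma), spec)
        assert res2.r1 == pytest.approx(res1.r1, abs=1e-10)
        for a1, a2 in zip(res1.structure.atoms, res2.structure.atoms):
            assert np.allclose(a2.xyz - a1.xyz, delta, atol=1e-6)

    def test_objective_non_increasing(self, toy):
        structure, bank = toy
        truth = constraint_consistent_truth(structure)
        data = generate_dataset(truth, bank, DatasetSpec(radiation="electron", d_min=1.0))
        start = perturb_structure(truth, seed=3)
        spec = RefinementSpec(option=2, radiation="electron", model="taam", bank=bank)
        res = refine(start, (data.hkl, data.fo2, data.sigma), spec)
        objs = [h["objective"] for h in res.history]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(objs, objs[1:]))

    def test_iam_against_aspherical_xray_shortens_xh(self, toy):
        """Spherical-model X-ray refinement pulls H into the bond (negative ME)."""
        from mpscat.cell import bond_lengths
        from mpscat.refine import hydrogen_parents
        structure, bank = toy
        data = generate_dataset(structure, bank, DatasetSpec(radiation="xray", d_min=0.83))
        start = perturb_structure(structure, seed=5, isotropize=True)
        current = start
        for opt in (1, 2, 3):
            spec = RefinementSpec(option=opt, radiation="xray", model="iam*", bank=bank)
            current = refine(current, (data.hkl, data.fo2, data.sigma), spec).structure
        bonds = sorted((h, p) for h, p in hydrogen_parents(structure).items())
        me = np.mean(np.array(bond_lengths(current, bonds))
                     - np.array(bond_lengths(structure, bonds)))
        assert me < -0.05  # bond shortening, order 0.1 A

    def test_underdetermined_rejected(self, toy):
        structure, bank = toy
        data = generate_dataset(structure, bank, DatasetSpec(radiation="xray", d_min=3.0))
        spec = RefinementSpec(option=4, radiation="xray", model="iam*", bank=bank)
        if len(data.hkl) > 60:
            pytest.skip("shell unexpectedly large")
        with pytest.raises(ValueError):
            refine(structure, (data.hkl, data.fo2, data.sigma), spec)

    def test_npd_reported_not_repaired(self, toy):
        """eIAM at low resolution drives ADPs non-positive definite; reported as such."""
        structure, bank = toy
        data = generate_dataset(structure, bank, DatasetSpec(radiation="electron", d_min=0.83))
        start = perturb_structure(structure, seed=1, isotropize=True)
        current = start
        npd = []
        for opt in (1, 2):
            spec = RefinementSpec(option=opt, radiation="electron", model="iam*", bank=bank)
            res = refine(current, (data.hkl, data.fo2, data.sigma), spec)
            current = res.structure
            npd = res.npd_atoms
        assert npd  # flagged
        for lab in npd:
            assert current.atom(lab).adp.is_npd(current.cell)
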