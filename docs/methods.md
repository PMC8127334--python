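# Methods

This note records the models, conventions and numerical choices behind
`mpscat`, and what the synthetic benchmark does and does not demonstrate.

## The pseudoatom model

An atom's electron density is expanded as

    ρ(r) = ρ_core(r) + P_v κ³ ρ_val(κr) + Σ_{l=0..4} κ′³ R_l(κ′ζ_l r) Σ_{mp} P_lmp d_lmp(θ, φ)

* ρ_core and ρ_val are spherically averaged shell densities normalized to
  one electron, stored as sums of Slater terms `(coefficient, n, ζ)`; the
  coefficient sum carries the shell electron count.
* R_l(r) = N r^{n_l} e^{−ζ_l r} with N = ζ^{n+3}/(n+2)! so that
  ∫R r² dr = 1; populations carry the electron count (the XD-style
  convention, which matches the P_lmp/R_l factorization of the expansion).
* d_lmp are real spherical harmonics under *density* normalization:
  ∫|d| dΩ = 2 for l ≥ 1 (one electron moved from the negative to the
  positive lobe per unit population) and d_00 = 1/4π.  The normalization
  constants are not hand-typed: they are computed on first use from the
  orthonormal harmonics by adaptive quadrature in cos θ split at the
  nodal roots (≈1e-9 accurate, cached).  These constants are the classic
  source of silent errors in multipole codes, which is why they are
  derived rather than tabulated.
* κ′³ multiplies each deformation term, the standard convention; κ and κ′
  rescalings leave electron counts invariant (the cubic prefactor
  compensates the radial dilation), verified by quadrature in the tests.
* Local frames are "Z-then-X with Gram–Schmidt": Z along atom→ref1, X
  toward ref2, Y = Z × X.  Frame references are recorded in the structure
  file; there is no automatic chemical-environment assignment.  During
  refinement the frames follow the current geometry (they are rebuilt each
  cycle), but frame *parameters* are never refined.

## Form factors and the Mott–Bethe conversion

The Fourier transform of each term is analytic.  The l-term contributes
4π i^l ⟨j_l⟩(|h|/κ′) Σ P_lmp d_lmp(ĥ) with
⟨j_l⟩(h) = ∫ R_l(r) j_l(2πhr) r² dr, evaluated in closed form by writing
j_l as a finite x^{−(k+1)}(a sin x + b cos x) sum; each piece reduces to
Γ-function integrals.  Below K/ζ = 0.15 the closed form cancels
catastrophically and a 14-term power series is used instead; the two
branches agree with adaptive quadrature to ~1e-12 across the switch.

Electron scattering factors come from the Mott–Bethe formula
f_e(s) = C_MB (Z − f_x(s))/s² with C_MB = 0.023934 Å (rest electron mass;
a relativistic γ would only rescale the absolute scale, which the
refinement scale factor absorbs, so it is not applied by default).  The
structure-factor-level route — F_e = C_MB (F_nuclear − F_x)/s², with the
point-charge Z term carrying the same temperature factors — is implemented
as an independent code path and agrees with per-atom assembly to 1e-10.

IAM tables: 4-Gaussian X-ray coefficients (via gemmi's IT92 table) and
5-Gaussian electron coefficients (gemmi's C4322).  Hydrogen's X-ray entry
is overridden by the classic free-atom fit: the contracted-H variant in
the IT92 table differs from the exact hydrogen 1s transform by ~18% at
s = 0.2 Å⁻¹, and because Z − f_x for H is small, that error is amplified
roughly tenfold after Mott–Bethe conversion.  With the free-atom entry the
converted X-ray table agrees with the electron table to ≤2% for H, C, N, O
over s = 0.2–1.5 Å⁻¹.

Electron F(000) (the potential integral that fixes the mean inner
potential) is computed as a numeric s → 0 limit with Richardson
extrapolation at s = 10⁻², 5·10⁻³.  Gaussian tabulations carry ~10⁻⁴ e of
spurious net charge per atom which would diverge in (Z − f)/s²; the limit
therefore subtracts the cell's apparent residual charge, after checking it
is consistent with tabulation noise (≤0.01 e per atom).  A genuinely
charged cell raises an error, as its potential integral does not exist.

## Structure factors

F(h) = Σ_ops Σ_atoms occ · f(R^T h) · T(R^T h) · exp(2πi(R^T h·x + h·t)),
evaluated with the equivalent-index trick: rotating h into each atom's own
setting handles both the aspherical form factor (whose local frame would
otherwise need composing with the operator) and the ADP transformation at
once.  ADPs are stored in the CIF U^ij convention; the Debye–Waller
exponent is −2π² Σ U^ij h_i h_j a*_i a*_j.  Special positions are detected
by orbit size and weighted accordingly, though the bundled toy structures
avoid them.  Friedel merging is on by default (kinematical scattering,
no anomalous dispersion, no extinction or absorption).

## Refinement

Gauss–Newton on Σ w (Fo² − k|Fc|²)², with distance restraints entering the
normal equations as pseudo-observations of weight 1/esd².  Details that
matter:

* Analytic derivatives for coordinates, U_iso, U^ij and the scale factor;
  they are validated against central finite differences at 1e-6 relative.
* The scale k is updated by a closed-form linear solve each cycle before
  the nonlinear step, and also carried as a regular column.
* Levenberg damping with an up/down λ schedule; a step is accepted only if
  the full (nonlinearly re-evaluated) objective does not increase.
  Convergence: max |shift|/esd < 0.01 with negligible objective decrease,
  or a numerically perfect fit, or a stall in which no damped step changes
  the objective by more than 10⁻⁵ relative (a constrained minimum).
* esds come from the inverse undamped normal matrix scaled by GoF.
* Floating origin directions (e.g. all of P1, the b axis of polar groups)
  are detected as the common fixed space of the symmetry rotations and
  pinned by zero-shift pseudo-observations, so P1 refinements are
  origin-stable; an overall origin shift maps to an exactly shifted
  solution with identical statistics (tested).
* Hydrogen constraints: X-ray options 1–2 ride H on ideal geometry
  (trigonal bisector or planar-120° construction, N–H 0.86 / C–H 0.93 Å)
  with dF/dx chained to the parent; electron refinements free H positions
  but restrain the X–H distances (1.01 / 1.083 Å, esd 0.02 Å) in every
  option.  In options 1–2, H U_iso = 1.2 × U_eq(parent) — the multiplier
  is a convention of riding-hydrogen practice, configurable, entering the
  Jacobian through the linear U_eq map.
* Negative Fo² are kept in the |F|² residual; amplitude R1 clamps them at
  zero.  NPD ADPs are reported, never repaired, and excluded from
  displacement statistics (their geometry is meaningless).
* The automatic (a, b) weighting search is a Nelder–Mead minimization of
  the variance of bin-wise GoF over ten Fc²-ordered bins, penalized away
  from overall GoF ∉ [0.95, 1.05], started at (0.1, 0).  It targets the
  same goal as the proprietary schemes in mainstream refinement programs —
  normally distributed residuals — without claiming equivalence to any of
  them.

## Fourier maps and metrics

Maps are synthesized as ρ(x) = (1/V) Re Σ_h F(h) e^{−2πi h·x} on an FFT
grid, summing over exactly the reflections supplied after optional
expansion to the full sphere (operator rotations with phase shifts plus
Friedel mates; inconsistent expansions are an error).  Default grid:
⌈3·edge/d_min⌉ rounded up to 2-3-5-smooth sizes, i.e. 3× Nyquist
oversampling.  X-ray maps are e Å⁻³; electron maps are multiplied by
3.32494 (e Å⁻¹) or 47.8780 (V) — the identity
3.32494 = 47.8780/14.39964 (Coulomb constant in V·Å) is asserted in the
tests.  F(000) is omitted except optionally in observed maps, where it
shifts the additive constant only.  Peak/hole positions are refined by
per-axis quadratic interpolation; "σ of the map" is the whole-cell RMS
(the alternative — RMS excluding atom cores — is not used).  Bond profiles
sample the grid by cubic spline interpolation along the bond, padded
0.6 Å past each nucleus, and report FWHMs by linear interpolation at half
height.

The ADP similarity index is S12 = 100(1 − R12),
R12 = 2^{3/2}(det U1 det U2)^{1/4}/det(U1+U2)^{1/2} on Cartesianized
tensors — the overlap integral of the two zero-mean Gaussians — checked
against a numerically evaluated 3D overlap integral at 1e-6.

## The synthetic benchmark

The toy system is a formamide-like planar amide (C, O, N, 3 H) in P2₁/n
(Z = 4, V ≈ 538 Å³) or P1, built at ideal trigonal geometry with
N–H = 1.01 Å and C–H = 1.083 Å so the electron-refinement restraint
targets coincide with the truth.  Anisotropic ADPs have eigenvalues
0.015/0.022/0.030 Å² (non-H) and 0.030/0.040/0.055 Å² (H) in seeded random
orientations — 100 K-like magnitudes with 2:1 anisotropy.

The synthetic bank uses single-ζ hydrogenic-like shells and hand-chosen
aspherical parameters: net charges O −0.45, N −0.32, C +0.37,
H(N) +0.20; contracted hydrogens (κ 1.12–1.15) with bond dipoles
0.10–0.12; heavy-atom quadrupoles up to 0.19 and octupoles up to 0.10.
These magnitudes are within the range that transfer databanks assign to
amide fragments and were fixed, once, so that the spherical-model misfit
against aspherical truth lands where sub-atomic-resolution studies of
small organic molecules put it: R1 ≈ 5% (electron) / 4% (X-ray) for
dynamic structure factors to 0.83 Å.  The bank is a synthetic stand-in —
it reproduces the *class* of density features (charge transfer, lone
pairs, bond dipoles), not any real molecule's values.

Ground truth data are noiseless Fo² from the aspherical model (playing
the role that periodic-DFT structure factors play against experimental
data); σ columns follow the absolute-scale policy σ = 1.0 (electron) /
0.01 (X-ray).  Starting models are jittered by ±0.02 fractional and ±20%
in ADP, inside the Gauss–Newton basin, and refined gradually through
options 1→4, each option starting from the previous result.

What the benchmark shows — the sign-level reproduction of the comparison
experiment: R1(IAM) > R1(TAAM) in every one of the 48 grid cells; electron
IAM biases non-H U_eq low at 0.83 Å (−17% at option 1, with options 2–4
driven fully NPD at toy scale) while the aspherical model's bias is two
orders of magnitude smaller; X-ray spherical refinement shortens X–H bonds
by ≈0.12 Å while the aspherical model recovers them to <0.001 Å; H-atom
U_iso is much less model-sensitive than non-H for electron data.  At
option 1 the electron-IAM X–H bonds (+0.11 Å) are also closer to truth
than the X-ray riding convention (−0.151 Å).

What it does not show: absolute agreement with any published refinement
statistics (those depend on real densities, real data and a 30-atom
molecule); behaviour under dynamical (multi-beam) scattering, which is out
of scope; and, at options 3–4, the "electron IAM bonds are already good"
effect — with 3 hydrogens among 6 atoms, the charged-H leverage on the
electron data is proportionally much larger than in a 30-atom system, and
the toy's free-H electron-IAM bond errors (+0.14 Å) are comparable to the
X-ray ones rather than smaller.  Noise is off by default (the reference
data are exact); Gaussian amplitude noise and proportional-σ policies are
available but the directional conclusions are demonstrated under the
noiseless conditions.

## Problem sizes and determinism

The default comparison grid is 2 radiations × 2 models × 4 options × 3
resolutions (0.83/0.60/0.38 Å; 1065–10652 unique reflections in P2₁/n)
and completes in about a minute on one CPU, with the acceptance script of
similar cost.  All stochastic inputs (ADP orientations, perturbations,
optional noise, dummy coordinates for composition-only structures) draw
from explicit seeds; library code never reads global entropy.
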