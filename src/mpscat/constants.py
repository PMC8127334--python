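"""Physical constants and unit-conversion factors.

All lengths are in angstroms (A) and scattering variables follow the
crystallographic convention s = sin(theta)/lambda (A^-1), |h| = 2s = 1/d.
"""

from __future__ import annotations

#: Mott-Bethe prefactor m e^2 / (8 pi eps0 h^2) in A, non-relativistic
#: electron mass.  f_e(s) = C_MB * (Z - f_x(s)) / s^2.
C_MB = 0.023934

#: Conversion of a Fourier-summed electron structure-factor map
#: (A / A^3) to volts.
VOLT_PER_F000_DENSITY = 47.8780

#: Coulomb constant in V*A per elementary charge (e / (4 pi eps0), with
#: length in A).  Used to express potentials in e/A units.
COULOMB_V_A = 14.39964

#: Conversion of an electron potential map to e A^-1 units:
#: VOLT_PER_F000_DENSITY / COULOMB_V_A.
E_PER_A_FACTOR = 3.32494

#: Bohr radius in A (exact hydrogenic radial scales).
BOHR_A = 0.529177210544
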