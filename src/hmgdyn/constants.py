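"""Physical constants used across the relaxation and RDC forward models.

All internal units are SI: temperatures in K, rates in s^-1, angular
frequencies in rad/s, distances in m, energies in J/mol. Chemical shifts
are handled in ppm at the module boundaries and converted here.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant, J/(mol K)
R_GAS = 8.3145

#: Gyromagnetic ratio of 1H, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: Gyromagnetic ratio of 15N, rad s^-1 T^-1 (negative)
GAMMA_N = -2.7126e7

#: Reduced Planck constant, J s
HBAR = 1.054571817e-34
#: Vacuum permeability, T^2 m^3 / J
MU_0 = 4e-7 * 3.141592653589793


@dataclass(frozen=True)
class PhysicalConstants:
    """Spin-interaction constants for backbone amide 15N relaxation.

    Parameters
    ----------
    r_nh : N-H bond length in Angstrom (1.02 by convention).
    csa : 15N chemical shift anisotropy in ppm (-160 by convention,
        single value for all residues).
    field_mhz : spectrometer 1H Larmor frequency in MHz.
    """

    r_nh: float = 1.02
    csa: float = -160.0
    field_mhz: float = 600.0

    @property
    def omega_h(self) -> float:
        """1H Larmor angular frequency, rad/s."""
        return 2.0 * 3.141592653589793 * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N Larmor angular frequency, rad/s (signed)."""
        return self.omega_h * GAMMA_N / GAMMA_H

    @property
    def d_dipolar(self) -> float:
        """Dipolar interaction constant mu0*hbar*gH*gN/(4 pi r^3), rad/s."""
        r = self.r_nh * 1e-10
        return MU_0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4.0 * 3.141592653589793 * r**3)

    @property
    def c_csa(self) -> float:
        """CSA interaction constant |omega_N|*dsigma/sqrt(3), rad/s."""
        return abs(self.omega_n) * (self.csa * 1e-6) / 3.0**0.5


def n15_larmor_rad(field_mhz: float) -> float:
    """15N Larmor angular frequency magnitude (rad/s) at a 1H field in MHz."""
    return 2.0 * 3.141592653589793 * field_mhz * 1e6 * abs(GAMMA_N) / GAMMA_H


def ppm_to_rad(dw_ppm: float, field_mhz: float) -> float:
    """Convert a 15N shift difference in ppm to rad/s at a 1H field in MHz."""
    return dw_ppm * 1e-6 * n15_larmor_rad(field_mhz)
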