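"""Physical constants and unit conversions used across the package.

All NMR conversions assume amide 15N unless stated otherwise.
"""

import numpy as np

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
GAMMA_N = -2.7126180436e7
#: gamma_H / gamma_N (~ -9.862)
GAMMA_RATIO_HN = GAMMA_H / GAMMA_N

#: 15N Larmor frequency as a fraction of the 1H spectrometer frequency
N15_LARMOR_FRACTION = 0.1013

#: N-H bond length used for dipolar couplings, metres
NH_BOND_LENGTH = 1.02e-10
#: 15N chemical shift anisotropy, dimensionless (ppm * 1e-6)
N15_CSA = -160e-6

HBAR = 1.0545718e-34
MU0_OVER_4PI = 1e-7


def n15_larmor_mhz(field_mhz: float) -> float:
    """15N Larmor frequency (MHz) at a given 1H spectrometer frequency (MHz)."""
    return N15_LARMOR_FRACTION * field_mhz


def ppm_to_rad_s(dw_ppm, field_mhz: float):
    """Convert a 15N shift difference from ppm to rad s^-1 at the given 1H field."""
    return np.asarray(dw_ppm) * n15_larmor_mhz(field_mhz) * 2.0 * np.pi


def rad_s_to_ppm(dw_rad_s, field_mhz: float):
    """Inverse of :func:`ppm_to_rad_s`."""
    return np.asarray(dw_rad_s) / (n15_larmor_mhz(field_mhz) * 2.0 * np.pi)


def dipolar_constant() -> float:
    """N-H dipolar interaction constant d = (mu0/4pi) hbar gammaH gammaN / r^3, rad s^-1."""
    return (
        MU0_OVER_4PI * HBAR * GAMMA_H * abs(GAMMA_N) / NH_BOND_LENGTH**3
    )


def csa_constant(field_mhz: float) -> float:
    """15N CSA interaction constant c = omegaN * |CSA| / sqrt(3), rad s^-1."""
    omega_n = 2.0 * np.pi * n15_larmor_mhz(field_mhz) * 1e6
    return omega_n * abs(N15_CSA) / np.sqrt(3.0)
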