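"""Physical constants and unit conversions.

Internal units are angstrom, picosecond and kT; kcal/mol and mV appear only
at reporting boundaries.
"""

from scipy import constants as _sc

#: Coulomb constant in kcal.A/(mol.e^2)
COULOMB_KCAL = 332.06

#: Gas constant in kcal/(mol.K)
R_KCAL = 1.9872041e-3

#: RT at 300 K in kcal/mol (reporting convention)
RT300_KCAL = 0.59616

#: Avogadro constant (1/mol)
N_AVOGADRO = _sc.N_A

#: Gas constant in J/(mol.K)
R_GAS = _sc.R

#: Faraday constant in C/mol
FARADAY = _sc.physical_constants["Faraday constant"][0]

#: mol/L -> particles/A^3
MOLAR_TO_PER_A3 = N_AVOGADRO * 1e-27


def rt_kcal(temperature: float) -> float:
    """RT in kcal/mol at the given temperature (K)."""
    return R_KCAL * temperature


def rt_over_f_mv(temperature: float) -> float:
    """RT/F in millivolts (thermal voltage) at the given temperature (K)."""
    return R_GAS * temperature / FARADAY * 1e3


def bjerrum_length(temperature: float, dielectric: float) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps kB T) in angstrom.

    The distance at which two unit charges interact with kT in a medium of
    relative permittivity ``dielectric``.
    """
    lb_m = _sc.e**2 / (4.0 * _sc.pi * _sc.epsilon_0 * dielectric * _sc.k * temperature)
    return lb_m * 1e10
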