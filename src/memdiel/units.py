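"""Physical constants and unit conversions.

The I/O boundary uses molecular-dynamics conventions (nm, ps, elementary
charge, unified atomic mass), matching GRO/TRR files; everything spectral is
converted to SI exactly once, here.  In MD units ``1 u nm^2/ps^2 = 1 kJ/mol``,
so the Boltzmann constant below (``KB_MD``) is the familiar
0.00831446 kJ/(mol K).
"""

from __future__ import annotations

from scipy import constants as _const

#: Elementary charge (C)
E_CHARGE = _const.elementary_charge
#: Unified atomic mass unit (kg)
ATOMIC_MASS = _const.atomic_mass
#: Boltzmann constant (J/K)
KB_SI = _const.Boltzmann
#: Vacuum permittivity (F/m)
EPS0_SI = _const.epsilon_0
#: Speed of light (m/s)
C_LIGHT = _const.speed_of_light

#: Boltzmann constant in MD units, u nm^2 ps^-2 K^-1 (= kJ/mol/K numerically)
KB_MD = KB_SI / ATOMIC_MASS * 1e-6  # (J/K) / (kg/u) * (nm/m)^2 (s/ps)^2

NM = 1e-9        # m per nm
PS = 1e-12       # s per ps
FS = 1e-15       # s per fs
THZ = 1e12       # Hz per THz
NM_PER_PS = 1e3  # m/s per nm/ps


def velocity_si(v_nm_ps):
    """nm/ps -> m/s."""
    return v_nm_ps * NM_PER_PS


def wavelength_nm_from_thz(f_thz: float) -> float:
    """Vacuum wavelength (nm) of a frequency given in THz."""
    return C_LIGHT / (f_thz * THZ) / NM
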