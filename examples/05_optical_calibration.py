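"""Optical dielectric constants of the DMPC head and tail by group contribution.

Vogel molar refractions of the chemical units are summed, Lorentz-Lorenz
turns them into refractive indices at three visible wavelengths, a Cauchy
model is solved through the three points and evaluated at 300 THz.  The
resulting eps_inf anchors the Kramers-Kronig reconstruction of each region.
"""

from memdiel.optical_calibration import (
    calibrate_region,
    default_refraction_table,
    head_composition,
    sum_molar_refraction,
    tail_composition,
)

table = default_refraction_table()
for name, comp in (("head", head_composition()), ("tail", tail_composition())):
    R = sum_molar_refraction(comp, table, 589.3)
    rec = calibrate_region(comp)
    print(f"{name}: R(589.3 nm) = {R:.3f} cm^3/mol | M = {rec['M_used']:.2f} g/mol | "
          f"rho = {rec['rho_used']} g/cm^3")
    print(f"   Cauchy A = {rec['A']:.4f}, B = {rec['B']:.1f} nm^2, C = {rec['C']:.3g} nm^4")
    print(f"   eps_inf(300 THz) = {rec['eps_inf']:.4f}")
print("head eps_inf > tail eps_inf: the polar headgroup region is optically denser,")
print("matching the ordering of the near-infrared spectra of the two moieties")
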