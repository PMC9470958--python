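"""Reconstruct eps'(w) from eps''(w) by the discrete Kramers-Kronig transform.

The Lorentzian pair is an exact KK pair, so the Maclaurin (alternating-point)
principal-value rule can be judged against the known answer; the roundtrip
eps'' -> eps' -> eps'' doubles as the data-quality diagnostic used in reports.
"""

import numpy as np

from memdiel.kramers_kronig import KKConfig, kk_real_from_imag, kk_roundtrip_error
from memdiel.spectra import DielectricSpectrum

f0, gam, S, eps_inf = 10.0, 1.5, 300.0, 2.0
f = np.linspace(f0 / 20, 20 * f0, 2048)
den = (f0**2 - f**2) ** 2 + (gam * f) ** 2
eps_imag = S * gam * f / den
eps_real_exact = eps_inf + S * (f0**2 - f**2) / den

spec = DielectricSpectrum(f_thz=f, eps_imag=eps_imag)
cfg = KKConfig(eps_inf=eps_inf)
out = kk_real_from_imag(spec, cfg)

away = np.abs(f - f0) > gam
err = (np.abs(out.eps_real - eps_real_exact) / np.abs(eps_real_exact))[away]
print(f"Lorentzian pair on {len(f)} points, resonance {f0} THz, width {gam} THz")
print(f"max rel. error of reconstructed eps' away from resonance: {err.max():.2%}")
print(f"eps' anchor recovered at high f: {out.eps_real[-1]:.3f} (eps_inf = {eps_inf})")

diag = kk_roundtrip_error(spec, cfg)
print(f"roundtrip eps''->eps'->eps'' diagnostic: max {diag['max_rel']:.2%}, "
      f"L2 {diag['l2_rel']:.2%} (small = causal, well-resolved spectrum)")
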