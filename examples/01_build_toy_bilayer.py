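"""Build the synthetic membrane and write it in the formats real data uses.

The toy system is a stratified slab of charged, harmonically tethered
oscillators: head strata outside, tail strata meeting at the midplane, a
Debye-like water analogue beyond the lipid extremes.  Its permittivity is
known in closed form, which is what makes it useful as ground truth.
"""

import os
import tempfile

from memdiel.synthetic_data import (
    ToyBilayerConfig,
    build_toy_bilayer,
    lateral_box_edge,
    simulate_langevin,
    write_system_files,
)

cfg = ToyBilayerConfig()
system = build_toy_bilayer(cfg)

edge = lateral_box_edge(cfg.lipids_per_leaflet, cfg.area_per_lipid_nm2)
print(f"lateral box edge: {edge:.2f} nm "
      f"({cfg.lipids_per_leaflet} lipid analogues x {cfg.area_per_lipid_nm2} nm^2)")
print(f"atoms: {system.n_atoms}")
for s in system.strata:
    lo, hi = s.z_spans[0]
    print(f"  {s.label:6s} span {lo:.1f}..{hi:.1f} nm | {s.count} oscillators | "
          f"f0 = {s.f0_thz:.1f} THz | gamma = {s.gamma_per_ps:.0f} /ps | "
          f"q = {s.charge_e} e")

out = tempfile.mkdtemp(prefix="memdiel_")
write_system_files(system, os.path.join(out, "toy.gro"), os.path.join(out, "charges.csv"))
simulate_langevin(system, os.path.join(out, "toy.h5"), seed=0, n_frames=200)
print(f"wrote GRO + charge CSV + 200-frame HDF5 trajectory under {out}")
print("(the spans above are what the layering stage must rediscover from data)")
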