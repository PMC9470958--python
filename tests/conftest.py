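"""Shared fixtures: small synthetic systems and the packaged DMPC topology."""

import numpy as np
import pytest

from memdiel import dmpc, trajectory_io as tio
from memdiel.synthetic_data import ToyBilayerConfig, build_toy_bilayer

WATER_GRO = """\
one TIP3P water
    3
    1SOL     OW    1   0.500   0.500   0.500  0.1000 -0.2000  0.3000
    1SOL    HW1    2   0.570   0.520   0.560
    1SOL    HW2    3   0.430   0.520   0.560
   1.00000   1.00000   1.00000
"""


@pytest.fixture()
def water_gro(tmp_path):
    path = tmp_path / "water.gro"
    path.write_text(WATER_GRO)
    return str(path)


@pytest.fixture(scope="session")
def dmpc_topology():
    top, _ = tio.read_structure(dmpc.fixture_structure_path())
    return tio.attach_charges(top, dmpc.fixture_charges_path())


@pytest.fixture(scope="session")
def toy_system():
    """Default-geometry toy bilayer (construction only, no dynamics)."""
    return build_toy_bilayer(ToyBilayerConfig())


@pytest.fixture(scope="session")
def small_toy_system():
    """Toy bilayer scaled down for quick dynamics in unit tests."""
    cfg = ToyBilayerConfig(
        lipids_per_leaflet=16, n_frames=2000, save_every=2,
        head_count=96, tail_count=96, water_count=64, seed=11,
    )
    return build_toy_bilayer(cfg)
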