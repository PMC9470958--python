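"""DMPC-specific configuration: ordinal scheme, head/tail split, fixtures.

DMPC (dimyristoylphosphatidylcholine) has 46 heavy atoms: the phosphocholine
and glycerol/ester head (choline N + 5 C, phosphate P + 4 O, glycerol C1-C3,
two ester COO groups) and two 14-carbon myristoyl chains.  The ordinal
scheme below numbers the heavy atoms 1..46 from the choline nitrogen down
the chains; it is one documented ordering exposed as configuration - any
bijective scheme works, mirrored leaflet atoms share the ordinal of their
name.

The packaged single-molecule fixture is a *synthetic* extended geometry (it
is not an equilibrated structure) carrying CHARMM36-style atom names, and
the packaged charge table holds simplified CHARMM36-like charges that are
group-wise neutral by construction.
"""

from __future__ import annotations

import importlib.resources

__all__ = [
    "ORDINAL_SCHEME",
    "HEAD_ATOM_NAMES",
    "fixture_structure_path",
    "fixture_charges_path",
]

_CHAIN2 = [f"C2{k}" for k in range(3, 15)]   # C23..C214
_CHAIN3 = [f"C3{k}" for k in range(3, 15)]   # C33..C314

#: Heavy-atom ordinals 1..46, head to tail.
ORDINAL_SCHEME: tuple[str, ...] = tuple(
    ["N", "C13", "C14", "C15", "C12", "C11",
     "P", "O13", "O14", "O11", "O12",
     "C1", "C2", "C3",
     "O21", "C21", "O22", "C22",
     "O31", "C31", "O32", "C32"]
    + _CHAIN2 + _CHAIN3
)

#: Hydrophilic-head heavy atoms: phosphocholine + glycerol + ester carbonyls.
#: The dividing line runs between the ester groups and the acyl chains; the
#: alpha carbons C22/C32 open the hydrophobic tail.
HEAD_ATOM_NAMES: frozenset[str] = frozenset(
    ["N", "C13", "C14", "C15", "C12", "C11",
     "P", "O13", "O14", "O11", "O12",
     "C1", "C2", "C3",
     "O21", "C21", "O22",
     "O31", "C31", "O32"]
)


def _data_path(name: str) -> str:
    return str(importlib.resources.files("memdiel.data").joinpath(name))


def fixture_structure_path() -> str:
    """Path of the packaged synthetic single-DMPC GRO file."""
    return _data_path("dmpc_single.gro")


def fixture_charges_path() -> str:
    """Path of the packaged DMPC + TIP3P-water charge CSV."""
    return _data_path("charges_dmpc_tip3p.csv")
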