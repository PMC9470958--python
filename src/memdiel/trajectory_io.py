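"""Structure, charge and trajectory input for the dielectric pipeline.

The spectral estimator needs, for every atom and every stored frame, the
instantaneous velocity and the fixed partial charge.  Coordinate formats
(GRO/PDB/XTC/TRR) carry no charges, so charges arrive in a sidecar CSV keyed
by ``(residue name, atom name)``.

Supported inputs
----------------
* structure: GRO (parsed here, fixed-column, with velocities) or PDB
  (via MDAnalysis);
* frames: TRR/XTC and friends via MDAnalysis, plus a self-describing HDF5
  dialect (datasets ``/time``, ``/box``, ``/positions``, ``/velocities``;
  attributes ``units`` and ``dt_fs``) written by :mod:`memdiel.synthetic_data`;
* charges: CSV with header ``residue,atom,charge_e,mass_u``.

Units at this boundary are the GROMACS conventions: nm, ps, nm/ps,
elementary charge, unified atomic mass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "TrajectoryMeta",
    "StructureParseError",
    "TrajectoryError",
    "ChargeCoverageError",
    "read_structure",
    "attach_charges",
    "stream_frames",
    "read_charge_table",
    "write_hdf5_trajectory",
    "write_gro",
    "infer_element",
]

# Water residue names recognised across force fields / file dialects.
WATER_RESNAMES = {"SOL", "TIP3", "TIP3P", "WAT", "HOH", "SPC"}

#: Documented atom-name -> element map.  Two-letter special cases are matched
#: first (on the name stripped of digits, upper-cased), then the first letter.
#: Anything else is an explicit error -- no silent guessing.
ELEMENT_SPECIAL = {
    "OW": "O", "HW": "H", "MW": "M",
    "CL": "Cl", "NA": "Na", "MG": "Mg", "CA2": "Ca", "ZN": "Zn", "K": "K",
}
ELEMENT_FIRST_LETTER = {"C": "C", "H": "H", "O": "O", "N": "N", "P": "P", "S": "S"}

STANDARD_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Na": 22.990, "Mg": 24.305, "K": 39.098,
    "Ca": 40.078, "Zn": 65.38, "M": 0.0,
}


class StructureParseError(ValueError):
    """A structure file violated its format; message carries the line number."""


class TrajectoryError(ValueError):
    """A trajectory cannot feed the pipeline (missing velocities, ragged dt...)."""


class ChargeCoverageError(KeyError):
    """The charge table does not cover every atom of the topology."""


def infer_element(atom_name: str) -> str:
    """Infer the chemical element from an atom name.

    Raises ``ValueError`` for names outside the documented mapping.
    """
    stripped = "".join(ch for ch in atom_name if not ch.isdigit()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    for key, elem in ELEMENT_SPECIAL.items():
        if stripped.startswith(key):
            return elem
    first = stripped[0]
    if first in ELEMENT_FIRST_LETTER:
        return ELEMENT_FIRST_LETTER[first]
    raise ValueError(
        f"unknown element for atom name {atom_name!r}; extend the mapping "
        "table in memdiel.trajectory_io if this name is legitimate"
    )


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the simulated system."""

    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    molecule_id: int
    charge: float = np.nan  # elementary charges; NaN until attach_charges
    mass: float = np.nan    # u

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Topology:
    """Ordered atom list plus optional bonds and molecule classification."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] | None = None
    molecule_kinds: dict[int, str] = field(default_factory=dict)  # molecule_id -> lipid|water|other

    def __post_init__(self) -> None:
        ids = [a.atom_id for a in self.atoms]
        if ids != list(range(len(ids))):
            raise ValueError("atom_ids must be dense 0..N-1 in file order")
        if not self.molecule_kinds:
            self.molecule_kinds = {
                a.molecule_id: ("water" if a.residue_name.upper() in WATER_RESNAMES else "lipid")
                for a in self.atoms
            }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms])

    def atoms_of_kind(self, kind: str) -> np.ndarray:
        """Indices of atoms whose molecule is classified as ``kind``."""
        return np.array(
            [a.atom_id for a in self.atoms if self.molecule_kinds[a.molecule_id] == kind],
            dtype=int,
        )

    def heavy_neighbor(self, atom_id: int) -> int | None:
        """Bonded heavy partner of a hydrogen, if bonds are available."""
        if self.bonds is None:
            return None
        partners = [j for i, j in self.bonds if i == atom_id] + [
            i for i, j in self.bonds if j == atom_id
        ]
        heavy = [p for p in partners if self.atoms[p].is_heavy]
        if len(heavy) != 1:
            raise ValueError(
                f"hydrogen atom {atom_id} must have exactly one bonded heavy atom, "
                f"found {len(heavy)}"
            )
        return heavy[0]


@dataclass
class Frame:
    """One stored trajectory frame (nm, ps, nm/ps)."""

    time: float
    box: np.ndarray                # (3,) nm
    positions: np.ndarray          # (N, 3) nm
    velocities: np.ndarray | None  # (N, 3) nm/ps or None

    def validate(self, n_atoms: int) -> None:
        if self.positions.shape != (n_atoms, 3):
            raise ValueError(
                f"frame has {self.positions.shape[0]} atoms, topology has {n_atoms}"
            )
        if self.velocities is not None and self.velocities.shape != (n_atoms, 3):
            raise ValueError("velocity array shape mismatch")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")


@dataclass(frozen=True)
class TrajectoryMeta:
    """Frame count and uniform frame interval."""

    n_frames: int
    dt_fs: float          # frame interval, fs

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    @property
    def t_sim_ns(self) -> float:
        """Total sampled length in ns (n_frames x dt)."""
        return self.n_frames * self.dt_fs * 1e-6


# ---------------------------------------------------------------------------
# structure readers
# ---------------------------------------------------------------------------

def _parse_gro(path: str) -> tuple[Topology, Frame]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path}: GRO file needs >= 3 lines, got {len(lines)}")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise StructureParseError(f"{path}, line 2: expected atom count") from exc
    if len(lines) < n_atoms + 3:
        raise StructureParseError(
            f"{path}: header announces {n_atoms} atoms but file ends at line {len(lines)}"
        )
    atoms: list[AtomRecord] = []
    positions = np.empty((n_atoms, 3))
    velocities = np.zeros((n_atoms, 3))
    has_velocities = False
    residue_key_to_mol: dict[tuple[int, str], int] = {}
    for i in range(n_atoms):
        lineno = i + 3
        line = lines[i + 2]
        if len(line) < 44:
            raise StructureParseError(
                f"{path}, line {lineno}: truncated GRO atom record ({len(line)} chars)"
            )
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            positions[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line) >= 68:
                velocities[i] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                has_velocities = True
        except ValueError as exc:
            raise StructureParseError(f"{path}, line {lineno}: malformed field ({exc})") from exc
        key = (resid, resname)
        mol_id = residue_key_to_mol.setdefault(key, len(residue_key_to_mol))
        try:
            element = infer_element(name)
        except ValueError as exc:
            raise StructureParseError(f"{path}, line {lineno}: {exc}") from exc
        atoms.append(
            AtomRecord(
                atom_id=i, name=name, element=element, residue_id=resid,
                residue_name=resname, molecule_id=mol_id,
                mass=STANDARD_MASS[element],
            )
        )
    box_line = lines[n_atoms + 2].split()
    if len(box_line) < 3:
        raise StructureParseError(f"{path}, line {n_atoms + 3}: malformed box line")
    box = np.array([float(x) for x in box_line[:3]])
    frame = Frame(time=0.0, box=box, positions=positions,
                  velocities=velocities if has_velocities else None)
    return Topology(atoms=atoms), frame


def _parse_pdb(path: str) -> tuple[Topology, Frame]:
    import MDAnalysis as mda

    u = mda.Universe(path)
    atoms = []
    residue_key_to_mol: dict[tuple[int, str], int] = {}
    for i, at in enumerate(u.atoms):
        key = (int(at.resid), str(at.resname))
        mol_id = residue_key_to_mol.setdefault(key, len(residue_key_to_mol))
        element = infer_element(str(at.name))
        atoms.append(
            AtomRecord(atom_id=i, name=str(at.name), element=element,
                       residue_id=int(at.resid), residue_name=str(at.resname),
                       molecule_id=mol_id, mass=STANDARD_MASS[element])
        )
    box = u.dimensions[:3] / 10.0 if u.dimensions is not None else np.ones(3)
    frame = Frame(time=0.0, box=np.asarray(box, dtype=float),
                  positions=u.atoms.positions / 10.0, velocities=None)
    return Topology(atoms=atoms), frame


def read_structure(path: str, fmt: str | None = None) -> tuple[Topology, Frame]:
    """Read a GRO or PDB structure; returns the topology and its frame.

    Elements are inferred from atom names through the documented mapping and
    an unknown name raises rather than guessing.  The returned frame carries
    velocities only if the file does (GRO optionally stores them).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").upper()
    fmt = fmt.upper()
    if fmt == "GRO":
        return _parse_gro(path)
    if fmt == "PDB":
        return _parse_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r} (GRO or PDB)")


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def read_charge_table(path: str) -> pd.DataFrame:
    """Load a ``residue,atom,charge_e,mass_u`` CSV."""
    table = pd.read_csv(path, comment="#")
    required = {"residue", "atom", "charge_e", "mass_u"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"charge table {path} lacks columns {sorted(missing)}")
    return table


def attach_charges(topology: Topology, charge_table: pd.DataFrame | str) -> Topology:
    """Return a topology with charges/masses filled from the sidecar table.

    Every ``(residue name, atom name)`` pair of the topology must appear in
    the table; missing keys are reported together in one error.
    """
    if isinstance(charge_table, str):
        charge_table = read_charge_table(charge_table)
    lookup = {
        (str(r.residue), str(r.atom)): (float(r.charge_e), float(r.mass_u))
        for r in charge_table.itertuples()
    }
    missing = sorted(
        {(a.residue_name, a.name) for a in topology.atoms} - set(lookup)
    )
    if missing:
        raise ChargeCoverageError(
            f"charge table misses {len(missing)} (residue, atom) keys: {missing[:8]}..."
        )
    new_atoms = [
        replace(a, charge=lookup[(a.residue_name, a.name)][0],
                mass=lookup[(a.residue_name, a.name)][1])
        for a in topology.atoms
    ]
    return Topology(atoms=new_atoms, bonds=topology.bonds,
                    molecule_kinds=dict(topology.molecule_kinds))


def net_molecule_charges(topology: Topology) -> dict[int, float]:
    """Net charge per molecule (e); useful as a sanity report after attach."""
    out: dict[int, float] = {}
    for a in topology.atoms:
        out[a.molecule_id] = out.get(a.molecule_id, 0.0) + a.charge
    return out


# ---------------------------------------------------------------------------
# frame streams
# ---------------------------------------------------------------------------

_DT_RTOL = 1e-6


def _check_uniform_dt(times_ps: Sequence[float]) -> float:
    dts = np.diff(np.asarray(times_ps, dtype=float))
    if len(dts) == 0:
        raise TrajectoryError("need at least two frames to define dt")
    dt = dts[0]
    if dt <= 0:
        raise TrajectoryError("non-increasing frame times")
    bad = np.nonzero(np.abs(dts - dt) > _DT_RTOL * abs(dt))[0]
    if bad.size:
        raise TrajectoryError(
            f"non-uniform frame interval at frame {int(bad[0]) + 1}: "
            f"dt={dts[bad[0]]:g} ps vs {dt:g} ps"
        )
    return dt


def _stream_hdf5(path: str, topology: Topology) -> tuple[TrajectoryMeta, Iterator[Frame]]:
    import h5py

    with h5py.File(path, "r") as h5:
        times = np.asarray(h5["/time"])
        n_frames = times.shape[0]
        if "velocities" not in h5:
            raise TrajectoryError(
                "velocity-less trajectory cannot feed the flux-flux estimator"
            )
        if h5["/positions"].shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"trajectory has {h5['/positions'].shape[1]} atoms, "
                f"topology has {topology.n_atoms}"
            )
    dt_ps = _check_uniform_dt(times)

    def gen() -> Iterator[Frame]:
        with h5py.File(path, "r") as h5:
            t = np.asarray(h5["/time"])
            box = np.asarray(h5["/box"])
            pos = h5["/positions"]
            vel = h5["/velocities"]
            chunk = max(1, int(2**22 // max(1, topology.n_atoms * 3)))
            for start in range(0, n_frames, chunk):
                stop = min(start + chunk, n_frames)
                p = pos[start:stop]
                v = vel[start:stop]
                for k in range(stop - start):
                    frame = Frame(time=float(t[start + k]), box=box[start + k],
                                  positions=p[k], velocities=v[k])
                    frame.validate(topology.n_atoms)
                    yield frame

    return TrajectoryMeta(n_frames=n_frames, dt_fs=dt_ps * 1e3), gen()


def _stream_mda(path: str, topology: Topology) -> tuple[TrajectoryMeta, Iterator[Frame]]:
    import MDAnalysis as mda

    n = topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.load_new(path)
    if not u.trajectory.ts.has_velocities:
        raise TrajectoryError(
            "velocity-less trajectory cannot feed the flux-flux estimator "
            "(XTC stores no velocities; use TRR or the HDF5 dialect)"
        )
    times = [ts.time for ts in u.trajectory]
    dt_ps = _check_uniform_dt(times)

    def gen() -> Iterator[Frame]:
        for ts in u.trajectory:
            frame = Frame(
                time=float(ts.time), box=np.asarray(ts.dimensions[:3]) / 10.0,
                positions=ts.positions / 10.0, velocities=ts.velocities / 10.0,
            )
            frame.validate(n)
            yield frame

    return TrajectoryMeta(n_frames=len(times), dt_fs=dt_ps * 1e3), gen()


def stream_frames(path: str, topology: Topology) -> tuple[TrajectoryMeta, Iterator[Frame]]:
    """Open a trajectory and return ``(meta, frame iterator)``.

    The frame interval is computed from the stored times and verified uniform
    (relative tolerance 1e-6); trajectories without velocities are rejected,
    because the current autocorrelation route has nothing to work with.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in {".h5", ".hdf5"}:
        return _stream_hdf5(path, topology)
    return _stream_mda(path, topology)


# ---------------------------------------------------------------------------
# writers (repo HDF5 dialect + minimal GRO)
# ---------------------------------------------------------------------------

def write_hdf5_trajectory(
    path: str,
    times_ps: np.ndarray,
    box_nm: np.ndarray,
    positions_nm: Iterable[np.ndarray],
    velocities_nm_ps: Iterable[np.ndarray],
    n_atoms: int,
) -> None:
    """Write the repo trajectory dialect.

    ``positions_nm`` / ``velocities_nm_ps`` may be arrays ``(n_frames, N, 3)``
    or iterables of per-frame ``(N, 3)`` arrays (streamed to disk).
    """
    import h5py

    times_ps = np.asarray(times_ps, dtype=float)
    n_frames = times_ps.shape[0]
    box_nm = np.asarray(box_nm, dtype=float)
    if box_nm.ndim == 1:
        box_nm = np.broadcast_to(box_nm, (n_frames, 3))
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=times_ps)
        h5.create_dataset("box", data=box_nm)
        dpos = h5.create_dataset("positions", shape=(n_frames, n_atoms, 3), dtype="f8")
        dvel = h5.create_dataset("velocities", shape=(n_frames, n_atoms, 3), dtype="f8")
        for k, (p, v) in enumerate(zip(positions_nm, velocities_nm_ps)):
            dpos[k] = p
            dvel[k] = v
        h5.attrs["units"] = "time: ps; box, positions: nm; velocities: nm/ps"
        if n_frames > 1:
            h5.attrs["dt_fs"] = float((times_ps[1] - times_ps[0]) * 1e3)


def write_gro(path: str, topology: Topology, frame: Frame, title: str = "memdiel system") -> None:
    """Write a GRO file (with velocities when the frame has them)."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{topology.n_atoms:5d}\n")
        for a in topology.atoms:
            x, y, z = frame.positions[a.atom_id]
            line = f"{(a.residue_id % 100000):5d}{a.residue_name:<5s}{a.name:>5s}{(a.atom_id + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            if frame.velocities is not None:
                vx, vy, vz = frame.velocities[a.atom_id]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")
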