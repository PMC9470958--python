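"""Membrane-like synthetic systems with known dielectric ground truth.

Real membrane trajectories come from long all-atom MD runs; for testing the
dielectric pipeline we instead build a *stratified slab of thermalized charged
damped oscillators*.  Each stratum (head / tail / water analogue) is a lattice
of independent particles of charge ``±q`` tethered harmonically to anchor
sites and propagated by Langevin dynamics:

    dv = -w0^2 (x - x0) dt - gamma v dt + sqrt(2 gamma kB T / m) dW

The linear-response permittivity of such a stratum is exactly Lorentzian,

    eps''(w) = S gamma w / ((w0^2 - w^2)^2 + gamma^2 w^2),
    eps'(w)  = eps_inf + S (w0^2 - w^2) / ((w0^2 - w^2)^2 + gamma^2 w^2),
    S        = N q^2 / (eps0 V m),

an exact Kramers-Kronig pair, so every stage of the pipeline (layering,
flux-flux spectra, KK reconstruction, band scanning) can be checked against
closed forms.  A water analogue is emulated as a low-frequency, strongly
damped (Debye-like) stratum so that the head-above-water crossing structure
of a hydrated bilayer appears in the synthetic landscape too.

Default geometry mirrors a DMPC-in-water setup: 64 lipid analogues per
leaflet at 0.606 nm^2 each, head span 0.8 nm and tail span 1.2 nm per
monolayer, 310 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import units
from .trajectory_io import (
    AtomRecord,
    Frame,
    Topology,
    write_gro,
    write_hdf5_trajectory,
)

__all__ = [
    "StratumSpec",
    "ToyBilayerConfig",
    "ToySystem",
    "lateral_box_edge",
    "build_toy_bilayer",
    "build_oscillator_gas",
    "simulate_frames",
    "simulate_langevin",
    "analytic_dielectric",
    "write_system_files",
]


def lateral_box_edge(lipids_per_leaflet: int, area_per_lipid_nm2: float) -> float:
    """Edge (nm) of the square lateral box holding one leaflet."""
    if lipids_per_leaflet <= 0 or area_per_lipid_nm2 <= 0:
        raise ValueError("lipid count and area per lipid must be positive")
    return math.sqrt(lipids_per_leaflet * area_per_lipid_nm2)


@dataclass
class StratumSpec:
    """One oscillator stratum (pooled over both leaflets)."""

    label: str                      # head | tail | water
    z_spans: list[tuple[float, float]]  # nm, one (lo, hi) per leaflet
    atom_indices: np.ndarray        # into the topology
    charge_e: float                 # magnitude; atoms alternate +/-q
    mass_u: float
    omega0_rad_ps: float            # angular natural frequency, rad/ps
    gamma_per_ps: float             # friction, 1/ps
    anchors_nm: np.ndarray          # (n, 3) anchor lattice

    def __post_init__(self) -> None:
        if self.gamma_per_ps <= 0:
            raise ValueError("friction must be positive")
        if len(self.atom_indices) == 0:
            raise ValueError("stratum must contain oscillators")

    @property
    def count(self) -> int:
        return len(self.atom_indices)

    @property
    def f0_thz(self) -> float:
        return self.omega0_rad_ps / (2 * math.pi)

    def span_volume_nm3(self, area_nm2: float) -> float:
        return area_nm2 * sum(hi - lo for lo, hi in self.z_spans)


@dataclass
class ToyBilayerConfig:
    """Construction and simulation parameters of the toy membrane.

    The defaults are the study conditions: DMPC-like geometry (64 lipid
    analogues per leaflet, 0.606 nm^2 each; 0.8 nm head and 1.2 nm tail span
    per monolayer; 1 nm water margin) at 310 K.  Strata resonances are placed
    at 8 THz (head), 14 THz (tail) and an overdamped 1 THz water analogue so
    that a 1 fs Langevin step integrates all of them stably.
    """

    lipids_per_leaflet: int = 64
    area_per_lipid_nm2: float = 0.606
    head_span_nm: float = 0.8
    tail_span_nm: float = 1.2
    water_margin_nm: float = 1.0
    temperature_K: float = 310.0
    dt_fs: float = 1.0              # integration step
    n_frames: int = 25_000
    save_every: int = 2             # frame interval = save_every * dt
    seed: int = 0
    # per-leaflet oscillator counts
    head_count: int = 384
    tail_count: int = 384
    water_count: int = 128
    # oscillator parameters (charge e, mass u, f0 THz, gamma 1/ps)
    head_osc: tuple[float, float, float, float] = (1.2, 8.0, 8.0, 10.0)
    tail_osc: tuple[float, float, float, float] = (0.4, 12.0, 14.0, 10.0)
    water_osc: tuple[float, float, float, float] = (0.8, 10.0, 1.0, 30.0)

    def __post_init__(self) -> None:
        for name in ("lipids_per_leaflet", "area_per_lipid_nm2", "head_span_nm",
                     "tail_span_nm", "water_margin_nm", "dt_fs",
                     "n_frames", "save_every", "head_count", "tail_count",
                     "water_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # T = 0 is the deterministic (ringdown) limit and is allowed
        if self.temperature_K < 0:
            raise ValueError("temperature_K must be non-negative")


@dataclass
class ToySystem:
    """Topology + anchor frame + strata, ready to simulate."""

    topology: Topology
    anchor_frame: Frame
    strata: list[StratumSpec]
    config: ToyBilayerConfig
    # flattened per-atom oscillator parameters
    omega0: np.ndarray = field(repr=False, default=None)   # rad/ps
    gamma: np.ndarray = field(repr=False, default=None)    # 1/ps

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def area_nm2(self) -> float:
        return float(self.anchor_frame.box[0] * self.anchor_frame.box[1])

    def stratum(self, label: str) -> StratumSpec:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(label)


def _lattice(count: int, edge: float, z_lo: float, z_hi: float) -> np.ndarray:
    """``count`` points on a regular lattice filling the stratum box.

    At least 8 z-levels, so the lattice traces the stratum span closely
    enough for the layering stage to recover it; an even level count keeps
    the levels off the stratum midpoint, which for the default geometry
    would sit exactly on a 0.2 nm slab edge.
    """
    span = z_hi - z_lo
    nz = max(8, round((count * span * span / (edge * edge)) ** (1.0 / 3.0)))
    nz += nz % 2
    nxy = math.ceil(math.sqrt(count / nz))
    while nxy * nxy * nz < count:
        nxy += 1
    xs = (np.arange(nxy) + 0.5) * (edge / nxy)
    zs = (np.arange(nz) + 0.5) * (span / nz) + z_lo
    gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return pts[:count]


_STRATA_RESNAMES = {"head": "HED", "tail": "TAL", "water": "WTR"}
# suffix 1 = +q, 2 = -q, so the (residue, atom)-keyed sidecar charge table
# can represent the alternating signs
_STRATA_ATOMNAMES = {"head": "OH", "tail": "CT", "water": "OW"}

#: Head-region atom names of the toy bilayer (for layering.define_regions).
TOY_HEAD_NAMES: frozenset[str] = frozenset({"OH1", "OH2"})


def build_toy_bilayer(config: ToyBilayerConfig | None = None) -> ToySystem:
    """Build the mirrored two-leaflet oscillator slab.

    Head strata sit outside, tail strata inside (meeting at the midplane
    z = 0) and water strata extend ``water_margin_nm`` beyond the lipid
    extremes; the construction is mirror-symmetric about z = 0.  Oscillators
    alternate charge sign within each stratum so every stratum is neutral.
    """
    config = config or ToyBilayerConfig()
    edge = lateral_box_edge(config.lipids_per_leaflet, config.area_per_lipid_nm2)
    z_tail = config.tail_span_nm
    z_head = z_tail + config.head_span_nm
    z_top = z_head + config.water_margin_nm
    spans = {
        "tail": (0.0, z_tail),
        "head": (z_tail, z_head),
        "water": (z_head, z_top),
    }
    if not (0.0 < z_tail < z_head < z_top):
        raise ValueError("strata spans overlap or are empty")
    params = {"head": config.head_osc, "tail": config.tail_osc, "water": config.water_osc}
    counts = {"head": config.head_count, "tail": config.tail_count,
              "water": config.water_count}

    atoms: list[AtomRecord] = []
    anchors: list[np.ndarray] = []
    strata: list[StratumSpec] = []
    omega0_parts: list[np.ndarray] = []
    gamma_parts: list[np.ndarray] = []
    mol_id = 0
    for label in ("head", "tail", "water"):
        q, m, f0, gam = params[label]
        omega0 = 2 * math.pi * f0
        lo, hi = spans[label]
        top = _lattice(counts[label], edge, lo, hi)
        bottom = top * np.array([1.0, 1.0, -1.0])  # mirror leaflet
        pts = np.vstack([top, bottom])
        idx0 = len(atoms)
        resname = _STRATA_RESNAMES[label]
        base = _STRATA_ATOMNAMES[label]
        for k in range(len(pts)):
            sign = 1 if k % 2 == 0 else -1
            name = f"{base}{1 if sign > 0 else 2}"
            atoms.append(
                AtomRecord(atom_id=idx0 + k, name=name,
                           element="O" if base.startswith("O") else "C",
                           residue_id=mol_id + 1, residue_name=resname,
                           molecule_id=mol_id, charge=sign * q, mass=m)
            )
            mol_id += 1
        anchors.append(pts)
        strata.append(
            StratumSpec(label=label, z_spans=[(lo, hi), (-hi, -lo)],
                        atom_indices=np.arange(idx0, idx0 + len(pts)),
                        charge_e=q, mass_u=m, omega0_rad_ps=omega0,
                        gamma_per_ps=gam, anchors_nm=pts)
        )
        omega0_parts.append(np.full(len(pts), omega0))
        gamma_parts.append(np.full(len(pts), gam))

    anchor_arr = np.vstack(anchors)
    box = np.array([edge, edge, 2 * z_top])
    topology = Topology(
        atoms=atoms,
        molecule_kinds={a.molecule_id: ("water" if a.residue_name == "WTR" else "lipid")
                        for a in atoms},
    )
    frame = Frame(time=0.0, box=box, positions=anchor_arr.copy(),
                  velocities=np.zeros_like(anchor_arr))
    return ToySystem(topology=topology, anchor_frame=frame, strata=strata,
                     config=config, omega0=np.concatenate(omega0_parts),
                     gamma=np.concatenate(gamma_parts))


def build_oscillator_gas(
    count: int = 64,
    charge_e: float = 1.0,
    mass_u: float = 10.0,
    f0_thz: float = 8.0,
    gamma_per_ps: float = 10.0,
    edge_nm: float = 4.0,
    span_nm: float = 4.0,
    temperature_K: float = 310.0,
    dt_fs: float = 1.0,
    n_frames: int = 100_000,
    save_every: int = 1,
    seed: int = 0,
) -> ToySystem:
    """Single homogeneous stratum of charged oscillators (the Green-Kubo oracle).

    One box of volume ``edge^2 * span`` filled with ``count`` independent
    tethered oscillators whose exact permittivity is the Lorentzian of
    :func:`analytic_dielectric`; used to pin the estimator normalization.
    """
    cfg = ToyBilayerConfig(
        lipids_per_leaflet=1, area_per_lipid_nm2=edge_nm * edge_nm,
        head_span_nm=span_nm, tail_span_nm=span_nm, water_margin_nm=span_nm,
        temperature_K=temperature_K, dt_fs=dt_fs, n_frames=n_frames,
        save_every=save_every, seed=seed,
    )
    omega0 = 2 * math.pi * f0_thz
    pts = _lattice(count, edge_nm, 0.0, span_nm)
    atoms = [
        AtomRecord(atom_id=k, name=f"OG{1 if k % 2 == 0 else 2}", element="O",
                   residue_id=k + 1, residue_name="GAS", molecule_id=k,
                   charge=charge_e if k % 2 == 0 else -charge_e, mass=mass_u)
        for k in range(count)
    ]
    stratum = StratumSpec(
        label="gas", z_spans=[(0.0, span_nm)], atom_indices=np.arange(count),
        charge_e=charge_e, mass_u=mass_u, omega0_rad_ps=omega0,
        gamma_per_ps=gamma_per_ps, anchors_nm=pts,
    )
    topology = Topology(atoms=atoms, molecule_kinds={a.molecule_id: "lipid" for a in atoms})
    frame = Frame(time=0.0, box=np.array([edge_nm, edge_nm, span_nm]),
                  positions=pts.copy(), velocities=np.zeros_like(pts))
    return ToySystem(topology=topology, anchor_frame=frame, strata=[stratum],
                     config=cfg, omega0=np.full(count, omega0),
                     gamma=np.full(count, gamma_per_ps))


# ---------------------------------------------------------------------------
# Langevin propagation (BAOAB splitting)
# ---------------------------------------------------------------------------

_NOISE_CHUNK = 4096


def _atom_generators(seed: int, n_atoms: int) -> list[np.random.Generator]:
    # Counter-based streams: one Philox keyed by (master seed, atom index),
    # so changing the atom count never reshuffles other atoms' noise.
    return [
        np.random.Generator(np.random.Philox(key=(int(seed) << 32) + i))
        for i in range(n_atoms)
    ]


def simulate_frames(
    system: ToySystem,
    seed: int | None = None,
    n_frames: int | None = None,
    equil_steps: int = 2000,
    initial_displacement_nm: np.ndarray | None = None,
) -> Iterator[Frame]:
    """Yield thermalized Langevin frames of the toy system.

    BAOAB splitting with the exact Ornstein-Uhlenbeck solution for the O
    step; per-atom counter-based noise streams make the run reproducible
    (same seed => bit-identical trajectory).  Stability requires
    ``dt * omega0 < 0.1`` and ``dt * gamma < 0.1``; outside that range the
    call is refused rather than silently degraded.

    ``initial_displacement_nm`` replaces the Gibbs draw of the initial
    displacements (shape (N, 3)); with temperature 0 this produces the
    deterministic damped ringdown of the tethered oscillators.
    """
    cfg = system.config
    seed = cfg.seed if seed is None else seed
    n_frames = cfg.n_frames if n_frames is None else n_frames
    dt = cfg.dt_fs * 1e-3  # ps
    w0 = system.omega0
    gam = system.gamma
    if np.max(dt * w0) >= 0.1 or np.max(dt * gam) >= 0.1:
        raise ValueError(
            f"unstable Langevin step: need dt*omega0 < 0.1 and dt*gamma < 0.1, "
            f"got {np.max(dt * w0):.3f} and {np.max(dt * gam):.3f}"
        )
    masses = system.topology.masses
    kT = units.KB_MD * cfg.temperature_K          # u nm^2/ps^2
    sig_v = np.sqrt(kT / masses)                  # nm/ps, per component
    c1 = np.exp(-gam * dt)[:, None]
    c2 = (sig_v * np.sqrt(1.0 - np.exp(-2 * gam * dt)))[:, None]
    w0sq = (w0 ** 2)[:, None]
    anchors = system.anchor_frame.positions
    n = system.n_atoms

    gens = _atom_generators(seed, n)
    # start drawn from the exact Gibbs marginals, then a short burn-in
    init = np.stack([g.standard_normal(6) for g in gens])
    sig_x = (np.sqrt(kT / masses) / w0)[:, None]
    if initial_displacement_nm is not None:
        u = np.array(initial_displacement_nm, dtype=float)
        equil_steps = 0
    else:
        u = init[:, :3] * sig_x
    v = init[:, 3:] * sig_v[:, None]
    if kT == 0.0 and initial_displacement_nm is not None:
        v = np.zeros_like(v)

    total_steps = equil_steps + n_frames * cfg.save_every
    step = 0
    frame_idx = 0
    box = system.anchor_frame.box
    while step < total_steps:
        chunk = min(_NOISE_CHUNK, total_steps - step)
        noise = np.empty((chunk, n, 3))
        for i, g in enumerate(gens):
            noise[:, i, :] = g.standard_normal((chunk, 3))
        for k in range(chunk):
            v += (-0.5 * dt) * w0sq * u
            u += (0.5 * dt) * v
            v = c1 * v + c2 * noise[k]
            u += (0.5 * dt) * v
            v += (-0.5 * dt) * w0sq * u
            step += 1
            if step > equil_steps and (step - equil_steps) % cfg.save_every == 0:
                yield Frame(
                    time=(frame_idx + 1) * cfg.save_every * dt,
                    box=box, positions=anchors + u, velocities=v.copy(),
                )
                frame_idx += 1


def simulate_langevin(
    system: ToySystem,
    path: str,
    seed: int | None = None,
    n_frames: int | None = None,
) -> None:
    """Run the Langevin dynamics and write the repo HDF5 trajectory dialect."""
    import h5py

    cfg = system.config
    n_frames = cfg.n_frames if n_frames is None else n_frames
    dt_frame_ps = cfg.dt_fs * 1e-3 * cfg.save_every
    times = (np.arange(n_frames) + 1) * dt_frame_ps
    n = system.n_atoms
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=times)
        h5.create_dataset("box", data=np.broadcast_to(system.anchor_frame.box, (n_frames, 3)))
        dpos = h5.create_dataset("positions", shape=(n_frames, n, 3), dtype="f8")
        dvel = h5.create_dataset("velocities", shape=(n_frames, n, 3), dtype="f8")
        for k, frame in enumerate(simulate_frames(system, seed=seed, n_frames=n_frames)):
            dpos[k] = frame.positions
            dvel[k] = frame.velocities
        h5.attrs["units"] = "time: ps; box, positions: nm; velocities: nm/ps"
        h5.attrs["dt_fs"] = float(dt_frame_ps * 1e3)
        h5.attrs["seed"] = int(cfg.seed if seed is None else seed)


def write_system_files(system: ToySystem, gro_path: str, charges_path: str) -> None:
    """Write the anchor structure as GRO plus the sidecar charge CSV."""
    write_gro(gro_path, system.topology, system.anchor_frame, title="memdiel toy bilayer")
    rows = ["residue,atom,charge_e,mass_u"]
    seen = set()
    for a in system.topology.atoms:
        key = (a.residue_name, a.name, round(a.charge, 9))
        if key in seen:
            continue
        seen.add(key)
        rows.append(f"{a.residue_name},{a.name},{a.charge},{a.mass}")
    with open(charges_path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# closed-form ground truth
# ---------------------------------------------------------------------------

def analytic_dielectric(
    spec: StratumSpec,
    volume_m3: float,
    f_grid_thz: np.ndarray,
    eps_inf: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact permittivity of one oscillator stratum on a frequency grid.

    Returns ``(eps_real, eps_imag)``; the pair satisfies the Kramers-Kronig
    relations exactly, with oscillator strength
    ``S = N q^2 / (eps0 V m)`` (angular-frequency units, s^-2).
    """
    f = np.asarray(f_grid_thz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency grid must be positive")
    omega = 2 * math.pi * f * units.THZ
    w0 = spec.omega0_rad_ps / units.PS
    gam = spec.gamma_per_ps / units.PS
    S = oscillator_strength(spec, volume_m3)
    denom = (w0 ** 2 - omega ** 2) ** 2 + (gam * omega) ** 2
    eps_imag = S * gam * omega / denom
    eps_real = eps_inf + S * (w0 ** 2 - omega ** 2) / denom
    return eps_real, eps_imag


def oscillator_strength(spec: StratumSpec, volume_m3: float) -> float:
    """``S = N q^2/(eps0 V m)`` in SI angular-frequency units (s^-2)."""
    q = spec.charge_e * units.E_CHARGE
    m = spec.mass_u * units.ATOMIC_MASS
    return spec.count * q * q / (units.EPS0_SI * volume_m3 * m)
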