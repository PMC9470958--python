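"""Sub-nanometre slab partition of an equilibrated bilayer.

The membrane normal is z and the bilayer midplane is put at z = 0 by
re-centering every frame on the lipid centre of mass.  Layering is *static*:
each atom is assigned once, by the time mean of its z coordinate, and keeps
that slab for the whole spectral calculation - per-frame reassignment would
make the slab currents J_L(t) discontinuous.  Slabs are half-open
``[lo, hi)`` intervals of fixed thickness (0.2 nm by default), classified as
head, tail or water by where their centre falls relative to the per-leaflet
head/tail dividing line; layering itself is defined on heavy atoms, with
hydrogens following their bonded (or nearest same-residue) heavy atom and
water molecules following their oxygen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trajectory_io import Frame, Topology

__all__ = [
    "AtomProfile",
    "RegionBounds",
    "LayerPartition",
    "average_z_profile",
    "ordinal_map",
    "define_regions",
    "assign_layers",
]


@dataclass
class AtomProfile:
    """Time-mean z position of every atom, bilayer midplane at z = 0."""

    mean_z: np.ndarray          # (N,), nm; all atoms
    heavy_mask: np.ndarray      # (N,) bool
    lipid_mask: np.ndarray      # (N,) bool
    n_frames: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mean_z)):
            raise ValueError("non-finite mean z positions")

    @property
    def leaflet(self) -> np.ndarray:
        """'top' for atoms with mean z >= 0, else 'bottom'."""
        return np.where(self.mean_z >= 0, "top", "bottom")


@dataclass(frozen=True)
class RegionBounds:
    """Per-leaflet head/tail boundaries (nm); water lies beyond the extremes."""

    z_div_top: float      # head/tail dividing line, top leaflet (> 0)
    z_lip_top: float      # outer lipid extreme, top leaflet
    z_div_bottom: float   # (< 0)
    z_lip_bottom: float

    @property
    def head_span_top(self) -> float:
        return self.z_lip_top - self.z_div_top

    @property
    def tail_span_top(self) -> float:
        return self.z_div_top

    @property
    def head_span_bottom(self) -> float:
        return self.z_div_bottom - self.z_lip_bottom

    @property
    def tail_span_bottom(self) -> float:
        return -self.z_div_bottom

    @property
    def lipid_span(self) -> float:
        return self.z_lip_top - self.z_lip_bottom


@dataclass
class LayerPartition:
    """Slab edges, static atom->slab map and region labels."""

    edges: np.ndarray           # (n_slabs + 1,), strictly increasing, nm
    spacing: float              # nm
    slab_of_atom: np.ndarray    # (N,) int
    region_labels: list[str]    # per slab: head | tail | water
    area_nm2: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("slab edges must be strictly increasing")
        n = len(self.edges) - 1
        if len(self.region_labels) != n:
            raise ValueError("one region label per slab required")
        if self.slab_of_atom.min() < 0 or self.slab_of_atom.max() >= n:
            raise ValueError("atom mapped outside the slab range")

    @property
    def n_slabs(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def slab_volume_nm3(self) -> float:
        return self.area_nm2 * self.spacing

    @property
    def slab_volume_m3(self) -> float:
        return self.slab_volume_nm3 * 1e-27

    def atom_counts(self) -> np.ndarray:
        return np.bincount(self.slab_of_atom, minlength=self.n_slabs)

    def slabs_of_region(self, region: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.region_labels) if r == region],
                        dtype=int)

    def lipid_slab_count(self) -> int:
        return int(sum(1 for r in self.region_labels if r in ("head", "tail")))


def average_z_profile(
    frames: Iterable[Frame],
    topology: Topology,
    recenter: bool = True,
) -> AtomProfile:
    """Time-mean z of every atom, with per-frame re-centering on the lipid COM.

    Re-centering (default on) removes slow drift of the whole membrane along
    the normal; it can be switched off for trajectories that are already
    centred.
    """
    lipid_idx = topology.atoms_of_kind("lipid")
    if lipid_idx.size == 0:
        raise ValueError("no lipid atoms in topology; cannot define the bilayer frame")
    masses = topology.masses
    w = masses[lipid_idx]
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        w = np.ones(lipid_idx.size)
    z_sum = np.zeros(topology.n_atoms)
    n_frames = 0
    for frame in frames:
        z = frame.positions[:, 2]
        if recenter:
            z = z - np.average(z[lipid_idx], weights=w)
        z_sum += z
        n_frames += 1
    if n_frames == 0:
        raise ValueError("empty frame stream")
    return AtomProfile(
        mean_z=z_sum / n_frames,
        heavy_mask=topology.heavy_mask,
        lipid_mask=np.isin(np.arange(topology.n_atoms), lipid_idx),
        n_frames=n_frames,
    )


def ordinal_map(topology: Topology, scheme: Sequence[str]) -> np.ndarray:
    """Ordinal number (1-based) of every lipid heavy atom, -1 elsewhere.

    ``scheme`` is the ordered heavy-atom name list of the lipid; mirrored
    atoms in the two leaflets share the ordinal of their name.  A lipid heavy
    atom whose name is missing from the scheme is an error.
    """
    order = {name: i + 1 for i, name in enumerate(scheme)}
    if len(order) != len(scheme):
        raise ValueError("duplicate names in ordinal scheme")
    out = np.full(topology.n_atoms, -1, dtype=int)
    for a in topology.atoms:
        if not a.is_heavy or topology.molecule_kinds[a.molecule_id] != "lipid":
            continue
        if a.name not in order:
            raise ValueError(f"heavy atom name {a.name!r} missing from ordinal scheme")
        out[a.atom_id] = order[a.name]
    return out


def define_regions(
    profile: AtomProfile,
    topology: Topology,
    head_atom_names: set[str],
) -> RegionBounds:
    """Locate the per-leaflet head/tail dividing line and lipid extremes.

    The dividing line of a leaflet is the midpoint between the innermost
    head atom and the outermost tail atom (by mean |z|); the tail span is
    measured from the bilayer midplane, matching the monolayer decomposition
    thickness = head span + tail span.
    """
    if not head_atom_names:
        raise ValueError("empty head atom-name set")
    names = np.array([a.name for a in topology.atoms])
    heavy_lipid = profile.heavy_mask & profile.lipid_mask
    is_head = np.isin(names, sorted(head_atom_names)) & heavy_lipid
    is_tail = heavy_lipid & ~is_head
    if not is_head.any() or not is_tail.any():
        raise ValueError("head/tail split is degenerate (one side empty)")
    z = profile.mean_z

    def leaflet_bounds(sign: float) -> tuple[float, float]:
        mask = heavy_lipid & ((z >= 0) if sign > 0 else (z < 0))
        head_z = np.abs(z[mask & is_head])
        tail_z = np.abs(z[mask & is_tail])
        if head_z.size == 0 or tail_z.size == 0:
            raise ValueError("a leaflet lacks head or tail atoms")
        z_div = 0.5 * (head_z.min() + tail_z.max())
        z_top = np.abs(z[mask]).max()
        if not z_div < z_top:
            raise ValueError("degenerate leaflet: dividing line at the lipid extreme")
        return float(z_div), float(z_top)

    div_top, lip_top = leaflet_bounds(+1.0)
    div_bot, lip_bot = leaflet_bounds(-1.0)
    return RegionBounds(z_div_top=div_top, z_lip_top=lip_top,
                        z_div_bottom=-div_bot, z_lip_bottom=-lip_bot)


def _hydrogen_parents(topology: Topology, mean_z: np.ndarray) -> np.ndarray:
    """Heavy atom each hydrogen follows (bond if known, else nearest in residue)."""
    parent = np.arange(topology.n_atoms)
    by_mol: dict[int, list[int]] = {}
    for a in topology.atoms:
        if a.is_heavy:
            by_mol.setdefault(a.molecule_id, []).append(a.atom_id)
    for a in topology.atoms:
        if a.is_heavy:
            continue
        if topology.bonds is not None:
            parent[a.atom_id] = topology.heavy_neighbor(a.atom_id)
            continue
        heavies = by_mol.get(a.molecule_id, [])
        if not heavies:
            raise ValueError(f"hydrogen {a.atom_id} has no heavy atom in its molecule")
        dz = np.abs(mean_z[heavies] - mean_z[a.atom_id])
        parent[a.atom_id] = heavies[int(np.argmin(dz))]
    return parent


def assign_layers(
    profile: AtomProfile,
    topology: Topology,
    spacing: float,
    box: np.ndarray,
    bounds: RegionBounds,
    water_margin: float = 1.0,
    water_per_slab: bool = True,
) -> LayerPartition:
    """Slice the system into slabs of width ``spacing`` and map every atom.

    The lipid region ``[z_lip_bottom, z_lip_top]`` is cut into
    ``ceil(span/spacing)`` contiguous slabs; water continues outward with the
    same spacing (or as one slab per side if ``water_per_slab`` is off) and
    is extended, if needed, so that every atom falls inside some slab.
    Assignment is by mean z, half-open ``[lo, hi)`` with ties going to the
    upper slab.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    span = bounds.lipid_span
    if spacing > span:
        raise ValueError(f"spacing {spacing} nm exceeds the lipid span {span:.3f} nm")
    n_lipid = math.ceil(span / spacing - 1e-9)
    # centre the overhang of the last slab, so symmetric bounds give slabs
    # mirror-symmetric about the midplane
    overhang = 0.5 * (n_lipid * spacing - span)
    lipid_edges = bounds.z_lip_bottom - overhang + spacing * np.arange(n_lipid + 1)

    # hydrogens (incl. water H) follow their parent heavy atom's mean z
    parent = _hydrogen_parents(topology, profile.mean_z)
    z = profile.mean_z[parent]
    z_min, z_max = float(z.min()), float(z.max())

    def outward(edge: float, target: float, direction: float) -> np.ndarray:
        reach = max(water_margin, direction * (target - edge) + 1e-9)
        n = math.ceil(reach / spacing - 1e-9)
        if not water_per_slab:
            return np.array([edge + direction * n * spacing])
        return edge + direction * spacing * np.arange(1, n + 1)

    upper = outward(lipid_edges[-1], z_max, +1.0)
    lower = outward(lipid_edges[0], z_min, -1.0)[::-1]
    edges = np.concatenate([lower, lipid_edges, upper])

    slab = np.searchsorted(edges, z, side="right") - 1
    slab = np.clip(slab, 0, len(edges) - 2)   # outermost slabs absorb boundary hits

    centers = 0.5 * (edges[:-1] + edges[1:])
    labels = []
    for c in centers:
        if c >= 0:
            if c < bounds.z_div_top:
                labels.append("tail")
            elif c < bounds.z_lip_top:
                labels.append("head")
            else:
                labels.append("water")
        else:
            if c > bounds.z_div_bottom:
                labels.append("tail")
            elif c > bounds.z_lip_bottom:
                labels.append("head")
            else:
                labels.append("water")
    return LayerPartition(edges=edges, spacing=spacing, slab_of_atom=slab,
                          region_labels=labels, area_nm2=float(box[0] * box[1]))
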