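"""High-level composition of the pipeline stages.

Convenience wrappers that chain layering -> per-slab Green-Kubo spectra ->
smoothing -> region pooling -> Kramers-Kronig, for a frame source that can be
re-opened (a trajectory file or a reproducible simulator).  Two passes are
made over the frames: a profile pass to build the static slab partition and a
production pass to accumulate the slab currents, mirroring how one works with
an on-disk MD trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .bandscan import BandReport, BandThresholds, region_aggregate, waveguide_bands
from .kramers_kronig import KKConfig, kk_real_from_imag
from .layering import LayerPartition, assign_layers, average_z_profile, define_regions
from .spectra import (
    DielectricSpectrum,
    PhysicalContext,
    collect_currents,
    smooth_spectrum,
    spectrum_from_current,
)
from .trajectory_io import Frame, Topology

__all__ = ["build_partition", "layered_spectra", "region_spectra_with_kk"]


def build_partition(
    frames: Iterable[Frame],
    topology: Topology,
    head_atom_names: set[str],
    box: np.ndarray,
    spacing_nm: float = 0.2,
    water_margin_nm: float = 1.0,
) -> LayerPartition:
    """Profile pass: time-mean z -> region bounds -> static slab partition."""
    profile = average_z_profile(frames, topology)
    bounds = define_regions(profile, topology, head_atom_names)
    return assign_layers(profile, topology, spacing_nm, box, bounds,
                         water_margin=water_margin_nm)


def layered_spectra(
    frames: Iterable[Frame],
    topology: Topology,
    partition: LayerPartition,
    temperature_K: float,
    dt_frame_s: float,
    max_lag: int | None = None,
    window_thz: float | None = None,
) -> list[DielectricSpectrum]:
    """Production pass: slab currents -> eps'' spectra (optionally smoothed)."""
    series = collect_currents(frames, topology, partition.slab_of_atom,
                              partition.n_slabs, dt_frame_s)
    ctx = PhysicalContext(temperature_K=temperature_K,
                          volume_m3=partition.slab_volume_m3)
    specs = spectrum_from_current(series, ctx, max_lag=max_lag)
    for s, region in zip(specs, partition.region_labels):
        s.region = region
    if window_thz is not None:
        specs = [smooth_spectrum(s, window_thz) for s in specs]
    return specs


def region_spectra_with_kk(
    slab_spectra: list[DielectricSpectrum],
    eps_inf: dict[str, float] | float = 1.0,
    kk_tail_policy: str = "zero-pad",
) -> dict[str, DielectricSpectrum]:
    """Pool slabs into region means and reconstruct eps' by Kramers-Kronig."""
    regions = region_aggregate(slab_spectra)
    out = {}
    for label, spec in regions.items():
        e_inf = eps_inf[label] if isinstance(eps_inf, dict) else eps_inf
        out[label] = kk_real_from_imag(
            spec, KKConfig(eps_inf=e_inf, tail_policy=kk_tail_policy)
        )
    return out
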